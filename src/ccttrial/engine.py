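"""The adaptive difficulty engine.

One L2-penalised logistic classifier per (exercise, difficulty level)
predicts the probability that a user with a given cognitive status completes
that exercise at that level. Level selection picks the hardest level whose
predicted success probability clears a cut-off (default 65%), which keeps
training near the user's peak performance. Every completed exercise is
appended to the matching classifier's training data and that classifier is
refit immediately, so the policy adapts online as the user improves.

The basic comparator policy has no learning system: a fixed subset of
exercises, always at the easiest level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .catalog import (DEFAULT_BASIC_IDS, ExerciseSpec, default_catalog,
                      difficulty)

N_FEATURES = 4  # the four standardised cognitive-status subscores


@dataclass(frozen=True)
class CognitiveStatus:
    """Four digital-test-battery subscores, standardised to the reference
    population (mean 0, SD 1): processing speed, memory span, short-term
    memory, logical reasoning."""

    processing_speed: float
    memory_span: float
    short_term_memory: float
    logical_reasoning: float

    def as_array(self) -> np.ndarray:
        a = np.array([self.processing_speed, self.memory_span,
                      self.short_term_memory, self.logical_reasoning],
                     dtype=float)
        if not np.isfinite(a).all():
            raise ValueError("cognitive status must be finite")
        return a

    @classmethod
    def from_array(cls, a) -> "CognitiveStatus":
        a = np.asarray(a, dtype=float)
        return cls(*a.tolist())


@dataclass(frozen=True)
class TrainingRecord:
    """One completed exercise attempt — the engine's learning signal."""

    participant_id: str
    exercise_id: int
    level: int
    success: bool
    session_index: int = 0


# ---------------------------------------------------------------------------
# Penalised logistic fitting
# ---------------------------------------------------------------------------

def _nll(beta, X, y, lam):
    z = X @ beta
    # y log p + (1-y) log(1-p) in softplus form; y may be fractional
    # (weighted success/failure pseudo-observations)
    ll = -np.sum(y * np.logaddexp(0.0, -z) + (1.0 - y) * np.logaddexp(0.0, z))
    return -ll + 0.5 * lam * beta @ beta


def _newton_damped(X, y, lam, beta0, tol=1e-8, max_iter=100):
    """Globally safeguarded Newton: step-halving on the objective."""
    beta = beta0.astype(float).copy()
    obj = _nll(beta, X, y, lam)
    for _ in range(max_iter):
        p = expit(X @ beta)
        grad = X.T @ (p - y) + lam * beta
        if np.abs(grad).max() <= tol:
            break
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        H.flat[::H.shape[0] + 1] += lam
        step = np.linalg.solve(H, grad)
        t = 1.0
        for _ in range(40):
            new = beta - t * step
            new_obj = _nll(new, X, y, lam)
            if new_obj <= obj + 1e-12:
                beta, obj = new, new_obj
                break
            t *= 0.5
        else:  # pragma: no cover - cannot trigger for convex objective
            break
    return beta


def _newton(X, y, lam, beta0, tol=1e-8, max_iter=100):
    """Minimise the L2-penalised logistic deviance by Newton steps.

    The objective is strictly convex (ridge on the full coefficient vector,
    intercept included), so the optimum is unique and the solver is
    deterministic for any starting point. Full Newton steps are taken on
    the (cheap) fast path; if the gradient norm ever grows the solver
    restarts with objective-safeguarded damped steps.
    """
    beta = beta0.astype(float).copy()
    Xt = X.T
    prev_gnorm = np.inf
    for _ in range(max_iter):
        p = expit(X @ beta)
        grad = Xt @ (p - y) + lam * beta
        gnorm = np.abs(grad).max()
        if gnorm <= tol:
            return beta
        if gnorm > 2.0 * prev_gnorm:
            return _newton_damped(X, y, lam, beta0, tol, max_iter)
        prev_gnorm = gnorm
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        H.flat[::H.shape[0] + 1] += lam
        beta = beta - np.linalg.solve(H, grad)
    return _newton_damped(X, y, lam, beta0, tol, max_iter)


def fit_logistic(features, outcomes, l2_penalty=1.0):
    """Fit an L2-penalised logistic regression, returning ``(intercept,
    coef_1..coef_p)`` as one vector.

    The ridge penalty applies to the intercept as well as the slopes, which
    guarantees finite coefficients even on perfectly separable (or
    all-success) training sets. Optimisation starts from the zero vector and
    runs Newton steps to gradient infinity-norm 1e-8, so the fit is fully
    deterministic.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(outcomes, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    if len(X) == 0:
        raise ValueError("training set must contain at least one observation")
    if len(X) != len(y):
        raise ValueError("features and outcomes disagree in length")
    if not np.isfinite(X).all():
        raise ValueError("non-finite features")
    if l2_penalty <= 0:
        raise ValueError("l2_penalty must be > 0")
    Xd = np.column_stack([np.ones(len(X)), X])
    return _newton(Xd, y, l2_penalty, np.zeros(Xd.shape[1]))


# ---------------------------------------------------------------------------
# Engine state
# ---------------------------------------------------------------------------

class _Classifier:
    """Training data + fitted coefficients for one (exercise, level).

    Rows are stored in a preallocated buffer (intercept column included) so
    the per-result append + refit cycle stays cheap in long simulations.
    """

    __slots__ = ("_Xd", "_y", "n", "beta", "n_prior")

    def __init__(self, X, y, lam, n_prior):
        X = np.asarray(X, dtype=float).reshape(-1, N_FEATURES)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) == 0:
            raise ValueError("empty prior: classifier is unfittable")
        self.n = len(y)
        cap = max(64, 2 * self.n)
        self._Xd = np.empty((cap, N_FEATURES + 1))
        self._Xd[:self.n, 0] = 1.0
        self._Xd[:self.n, 1:] = X
        self._y = np.empty(cap)
        self._y[:self.n] = y
        self.n_prior = n_prior
        self.beta = _newton(self._Xd[:self.n], self._y[:self.n], lam,
                            np.zeros(N_FEATURES + 1))

    @property
    def X(self):
        return self._Xd[:self.n, 1:]

    @property
    def y(self):
        return self._y[:self.n]

    def refit(self, lam):
        self.beta = _newton(self._Xd[:self.n], self._y[:self.n], lam,
                            self.beta)

    def append(self, x, success):
        if self.n == len(self._y):
            self._Xd = np.concatenate([self._Xd, np.empty_like(self._Xd)])
            self._y = np.concatenate([self._y, np.empty_like(self._y)])
        self._Xd[self.n, 0] = 1.0
        self._Xd[self.n, 1:] = x
        self._y[self.n] = 1.0 if success else 0.0
        self.n += 1

    def copy(self):
        c = _Classifier.__new__(_Classifier)
        c._Xd = self._Xd[:self.n].copy()
        c._y = self._y[:self.n].copy()
        c.n = self.n
        c.beta = self.beta.copy()
        c.n_prior = self.n_prior
        return c


def default_prior(exercise: ExerciseSpec, level: int, spacing: float = 0.5,
                  size: int = 8, l2_penalty: float = 1.0):
    """Cold-start pseudo-observations anchoring level ``level`` at its
    design difficulty.

    Points sit on the all-equal status direction around the level's
    difficulty ``d``, with fractional outcomes (weighted success/failure
    pairs): mostly successes above ``d``, mostly failures below. The
    outcomes carry a small linear correction chosen so that the ridge fit
    of the pseudo-data reproduces the designed response curve
    ``p = logistic(mean status - d)`` exactly — the cold-start policy then
    selects the level the difficulty design intends for any status, and
    online results take over from there.
    """
    d = difficulty(level, exercise.n_levels, spacing)
    half = size // 2
    offsets = 0.5 * np.arange(1, half + 1)
    u = np.concatenate([d + offsets, d - offsets])
    X = np.repeat(u[:, None], N_FEATURES, axis=1)
    # target coefficients: intercept -d, slope 1/N on each feature.
    # The penalised score equations require residuals c_i = p(u_i) - y_i
    # with sum(c) = lam*d and sum(c*u) = -lam/N; solve for c = alpha+gamma*u.
    lam = l2_penalty
    n = len(u)
    su, suu = u.sum(), (u * u).sum()
    A = np.array([[n, su], [su, suu]])
    b = np.array([lam * d, -lam / N_FEATURES])
    alpha, gamma = np.linalg.solve(A, b)
    y = expit(u - d) - (alpha + gamma * u)
    if (y < 0).any() or (y > 1).any():  # fall back to plain banded outcomes
        y = np.clip(y, 0.0, 1.0)
    return X, y


class EngineState:
    """The adaptive policy's memory: every classifier plus its data.

    Instances are built with :func:`init_engine`; in a simulated trial each
    adaptive-arm participant carries their own engine (the deployed software
    retrains locally on that user's results).
    """

    def __init__(self, exercises, classifiers, cutoff, l2_penalty,
                 level_spacing):
        self.exercises: dict[int, ExerciseSpec] = {
            e.exercise_id: e for e in exercises}
        self._clf: dict[tuple[int, int], _Classifier] = classifiers
        self.cutoff = float(cutoff)
        self.l2_penalty = float(l2_penalty)
        self.level_spacing = float(level_spacing)
        self.refit_count = 0
        self.records: list[TrainingRecord] = []

    # -- queries ------------------------------------------------------------

    def _classifier(self, exercise_id, level) -> _Classifier:
        try:
            return self._clf[(exercise_id, level)]
        except KeyError:
            raise KeyError(f"no classifier for exercise {exercise_id} "
                           f"level {level}") from None

    def predict_success(self, exercise_id, level, status) -> float:
        """Predicted success probability, strictly inside (0, 1)."""
        clf = self._classifier(exercise_id, level)
        x = status.as_array() if isinstance(status, CognitiveStatus) \
            else np.asarray(status, dtype=float)
        return float(expit(clf.beta[0] + clf.beta[1:] @ x))

    def predict_all_levels(self, exercise_id, status) -> np.ndarray:
        ex = self.exercises.get(exercise_id)
        if ex is None:
            raise KeyError(f"unknown exercise {exercise_id}")
        x = status.as_array() if isinstance(status, CognitiveStatus) \
            else np.asarray(status, dtype=float)
        B = np.stack([self._clf[(exercise_id, lv)].beta
                      for lv in range(1, ex.n_levels + 1)])
        return expit(B[:, 0] + B[:, 1:] @ x)

    def select_level(self, exercise_id, status) -> int:
        """The hardest level predicted to clear the cut-off; level 1 when
        none does."""
        p = self.predict_all_levels(exercise_id, status)
        ok = np.nonzero(p >= self.cutoff)[0]
        return int(ok[-1]) + 1 if len(ok) else 1

    # -- updates ------------------------------------------------------------

    def record_result(self, record: TrainingRecord, status) -> "EngineState":
        """Append one completed exercise to its classifier's training data
        and refit that classifier; all others are untouched."""
        ex = self.exercises.get(record.exercise_id)
        if ex is None:
            raise KeyError(f"unknown exercise {record.exercise_id}")
        if not 1 <= record.level <= ex.n_levels:
            raise KeyError(f"level {record.level} outside exercise "
                           f"{record.exercise_id}'s range")
        clf = self._clf[(record.exercise_id, record.level)]
        x = status.as_array() if isinstance(status, CognitiveStatus) \
            else np.asarray(status, dtype=float)
        clf.append(x, record.success)
        clf.refit(self.l2_penalty)
        self.refit_count += 1
        self.records.append(record)
        return self

    def plan_session(self, status, duration_minutes, task_minutes=3.0):
        """Round-robin over the catalogue, each exercise at its selected
        level, truncated to the session duration."""
        if duration_minutes <= 0:
            raise ValueError("duration must be > 0")
        n_tasks = max(1, int(duration_minutes // task_minutes))
        order = sorted(self.exercises)
        plan = []
        for k in range(n_tasks):
            eid = order[k % len(order)]
            plan.append((eid, self.select_level(eid, status)))
        return plan

    # -- bookkeeping --------------------------------------------------------

    def clone(self) -> "EngineState":
        """Independent deep copy (fresh per-participant engine)."""
        st = EngineState.__new__(EngineState)
        st.exercises = dict(self.exercises)
        st._clf = {k: c.copy() for k, c in self._clf.items()}
        st.cutoff = self.cutoff
        st.l2_penalty = self.l2_penalty
        st.level_spacing = self.level_spacing
        st.refit_count = self.refit_count
        st.records = list(self.records)
        return st

    def coefficients(self, exercise_id, level) -> np.ndarray:
        return self._classifier(exercise_id, level).beta.copy()

    def training_size(self, exercise_id, level) -> int:
        return len(self._classifier(exercise_id, level).y)

    # -- serialisation ------------------------------------------------------

    SERIAL_VERSION = 1

    def to_json(self) -> str:
        payload = {
            "version": self.SERIAL_VERSION,
            "cutoff": self.cutoff,
            "l2_penalty": self.l2_penalty,
            "level_spacing": self.level_spacing,
            "refit_count": self.refit_count,
            "exercises": [
                {"exercise_id": e.exercise_id, "name": e.name,
                 "function_weights": list(e.function_weights),
                 "n_levels": e.n_levels}
                for e in self.exercises.values()],
            "classifiers": [
                {"exercise_id": eid, "level": lv,
                 "n_prior": c.n_prior,
                 "X": c.X.tolist(), "y": c.y.tolist(),
                 "beta": c.beta.tolist()}
                for (eid, lv), c in sorted(self._clf.items())],
            "records": [
                {"participant_id": r.participant_id,
                 "exercise_id": r.exercise_id, "level": r.level,
                 "success": bool(r.success),
                 "session_index": r.session_index}
                for r in self.records],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "EngineState":
        d = json.loads(text)
        if d.get("version") != cls.SERIAL_VERSION:
            raise ValueError("unsupported engine serialisation version")
        exercises = [ExerciseSpec(e["exercise_id"], e["name"],
                                  tuple(e["function_weights"]), e["n_levels"])
                     for e in d["exercises"]]
        st = cls.__new__(cls)
        st.exercises = {e.exercise_id: e for e in exercises}
        st._clf = {}
        for c in d["classifiers"]:
            clf = _Classifier.__new__(_Classifier)
            X = np.asarray(c["X"], dtype=float).reshape(-1, N_FEATURES)
            y = np.asarray(c["y"], dtype=float)
            clf.n = len(y)
            clf._Xd = np.column_stack([np.ones(len(y)), X])
            clf._y = y.copy()
            clf.beta = np.asarray(c["beta"], dtype=float)
            clf.n_prior = c["n_prior"]
            st._clf[(c["exercise_id"], c["level"])] = clf
        st.cutoff = d["cutoff"]
        st.l2_penalty = d["l2_penalty"]
        st.level_spacing = d["level_spacing"]
        st.refit_count = d["refit_count"]
        st.records = [TrainingRecord(r["participant_id"], r["exercise_id"],
                                     r["level"], r["success"],
                                     r["session_index"])
                      for r in d["records"]]
        return st


def init_engine(exercises=None, prior=None, cutoff=0.65, l2_penalty=1.0,
                level_spacing=0.5, prior_size=8) -> EngineState:
    """Build an engine with every classifier fitted on its cold-start prior.

    ``prior`` may be ``None`` (level-anchored default pseudo-observations),
    or a mapping ``(exercise_id, level) -> (features, outcomes)``. An empty
    prior for any classifier is refused: the classifier would be unfittable.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    if l2_penalty <= 0:
        raise ValueError("l2_penalty must be > 0")
    exercises = list(exercises) if exercises is not None else default_catalog()
    classifiers = {}
    for ex in exercises:
        for lv in range(1, ex.n_levels + 1):
            if prior is None:
                X, y = default_prior(ex, lv, level_spacing, prior_size,
                                     l2_penalty)
            else:
                try:
                    X, y = prior[(ex.exercise_id, lv)]
                except KeyError:
                    raise ValueError(
                        f"no prior for exercise {ex.exercise_id} level {lv}"
                    ) from None
            X = np.asarray(X, dtype=float)
            if X.size == 0:
                raise ValueError(
                    f"empty prior for exercise {ex.exercise_id} level {lv}")
            classifiers[(ex.exercise_id, lv)] = _Classifier(
                X, y, l2_penalty, n_prior=len(np.atleast_1d(y)))
    return EngineState(exercises, classifiers, cutoff, l2_penalty,
                       level_spacing)


def replay(exercises, log, statuses, cutoff=0.65, l2_penalty=1.0,
           level_spacing=0.5, prior=None, prior_size=8) -> EngineState:
    """Rebuild an engine by replaying a training-record log from the prior.

    ``statuses`` maps participant_id to the CognitiveStatus used at record
    time. Deterministic fitting makes the result identical to the engine
    that produced the log.
    """
    st = init_engine(exercises, prior=prior, cutoff=cutoff,
                     l2_penalty=l2_penalty, level_spacing=level_spacing,
                     prior_size=prior_size)
    for rec in log:
        st.record_result(rec, statuses[rec.participant_id])
    return st


# ---------------------------------------------------------------------------
# Module-level operation wrappers
# ---------------------------------------------------------------------------

def predict_success(engine: EngineState, exercise_id, level, status):
    return engine.predict_success(exercise_id, level, status)


def select_level(engine: EngineState, exercise_id, status):
    return engine.select_level(exercise_id, status)


def record_result(engine: EngineState, record: TrainingRecord, status):
    return engine.record_result(record, status)


def plan_session(engine: EngineState, status, duration_minutes,
                 task_minutes=3.0):
    return engine.plan_session(status, duration_minutes, task_minutes)


def bcct_select_level(exercise_id, basic_ids=DEFAULT_BASIC_IDS) -> int:
    """The basic programme's fixed policy: always the easiest level."""
    if exercise_id not in basic_ids:
        raise KeyError(f"exercise {exercise_id} is not in the basic catalogue")
    return 1
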