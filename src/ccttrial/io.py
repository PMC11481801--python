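"""File formats: CSV schemas, provenance headers, validation.

Every output CSV starts with comment lines recording the root seed and the
configuration digest, so any file can be traced to the run that produced
it; readers skip those lines transparently. The missing-value token is the
empty string; files are UTF-8 with one header row.
"""

from __future__ import annotations

import pandas as pd

#: column dictionary: subjects.csv
SUBJECTS_COLUMNS = {
    "participant_id": "opaque id",
    "household_id": "opaque id, shared by couples",
    "group": "IG | CG",
    "age": "years",
    "sex": "female | male",
    "education_level": "primary | secondary | higher | university",
    "cognitive_hours": "hours/week",
    "physical_hours": "hours/week",
    "social_hours": "hours/week",
    "vascular_risk": "0..4 risk-factor count",
    "medication_score": "-2..+2 sum score",
    "phq9": "0..27",
    "charlson": "0..24",
    "moca_t0": "0..30",
    "moca_t6": "0..30, empty if missing",
    "clinical_reason": "free text, empty if none",
}

#: column dictionary: training_log.csv
TRAINING_LOG_COLUMNS = {
    "participant_id": "opaque id",
    "group": "IG | CG",
    "month_index": "1..months",
    "session_index": "1..n, per participant",
    "exercise_id": "1..10",
    "level": "1..n_levels",
    "success": "0 | 1",
}

#: column dictionary: ueq.csv (26 answer columns + ids)
UEQ_COLUMNS = {"participant_id": "opaque id", "group": "IG | CG",
               **{f"item_{i}": "1..7" for i in range(1, 27)}}


def write_table(df: pd.DataFrame, path, seed=None, config_hash=None,
                label=None) -> None:
    """Write a CSV with provenance comment lines."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if label:
            fh.write(f"# {label}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a CSV produced by :func:`write_table` (comments skipped)."""
    return pd.read_csv(path, comment="#")


def read_provenance(path) -> dict[str, str]:
    """Extract the seed / config-hash comment lines from a CSV."""
    out = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                out[k.strip()] = v.strip()
    return out


def validate_subjects(df: pd.DataFrame) -> list[str]:
    """Exhaustive schema check of a subject table; returns every problem."""
    problems = []
    required = [c for c in SUBJECTS_COLUMNS
                if c not in ("clinical_reason", "moca_t6")]
    for col in required:
        if col not in df.columns:
            problems.append(f"missing column: {col}")
    if problems:
        return problems
    bad_group = set(df["group"].dropna()) - {"IG", "CG"}
    if bad_group:
        problems.append(f"invalid group labels: {sorted(bad_group)}")
    for col, lo, hi in (("moca_t0", 0, 30), ("phq9", 0, 27),
                        ("vascular_risk", 0, 4), ("charlson", 0, 24)):
        v = df[col].dropna()
        if ((v < lo) | (v > hi)).any():
            problems.append(f"{col} outside [{lo}, {hi}]")
    if "moca_t6" in df.columns:
        v = df["moca_t6"].dropna()
        if ((v < 0) | (v > 30)).any():
            problems.append("moca_t6 outside [0, 30]")
    for col in ("cognitive_hours", "physical_hours", "social_hours"):
        if (df[col].dropna() < 0).any():
            problems.append(f"{col} negative")
    dup = df["participant_id"].duplicated()
    if dup.any():
        problems.append(f"duplicate participant ids: "
                        f"{sorted(df.loc[dup, 'participant_id'])}")
    return problems


def validate_ueq(df: pd.DataFrame) -> list[str]:
    problems = []
    for col in UEQ_COLUMNS:
        if col not in df.columns:
            problems.append(f"missing column: {col}")
    for col in (c for c in df.columns if c.startswith("item_")):
        v = df[col].dropna()
        if ((v < 1) | (v > 7)).any():
            problems.append(f"{col} outside 1..7")
    return problems
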