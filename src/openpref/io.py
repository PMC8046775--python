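"""Trial-table schema, parameter files and result serialisation.

The interchange format is a plain CSV with one row per trial and a
one-line header.  Times are stored in seconds; ``delay_s`` is measured from
the first response (``t1_s`` is stored separately so the literal
decay-clock convention remains computable).
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import ModelParams

#: column -> (dtype kind, validator description)
TRIAL_COLUMNS = {
    "participant": "str",
    "experiment": "int",
    "block": "int",
    "condition": "str",
    "t1_s": "float",
    "delay_s": "float",
    "first_response": "str",
    "rating": "int",
    "is_catch": "bool",
    "scale_max": "float",
}
_CONDITIONS = {"choice", "no_choice", "catch"}
_RESPONSES = {"L", "R"}


class SchemaError(ValueError):
    """Raised when a trial table violates the schema; carries row details."""


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly coerce) a trial table against the schema."""
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    df = df.copy()
    problems = []

    def check(mask: pd.Series, msg: str):
        if mask.any():
            lines = (df.index[mask] + 2).tolist()[:5]  # 1-based + header
            problems.append(f"{msg} (lines {lines}{'...' if mask.sum() > 5 else ''})")

    df["is_catch"] = df["is_catch"].astype(bool)
    for col in ("t1_s", "delay_s", "scale_max"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        check(df[col].isna(), f"non-numeric {col}")
    rating = pd.to_numeric(df["rating"], errors="coerce")
    check(rating.isna() | (rating != rating.round()), "rating must be integer")
    df["rating"] = rating
    check(~df["condition"].isin(_CONDITIONS),
          f"condition must be one of {sorted(_CONDITIONS)}")
    check(~df["first_response"].isin(_RESPONSES),
          "first_response must be L or R")
    check(df["delay_s"] <= 0, "delay_s must be positive")
    check(np.abs(df["rating"]) > df["scale_max"],
          "rating exceeds the scale bound")
    if problems:
        raise SchemaError("; ".join(problems))
    df["rating"] = df["rating"].astype(int)
    return df


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial CSV/TSV."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return validate_trials(pd.read_csv(path, sep=sep))


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    validate_trials(df).to_csv(path, index=False)


def read_osf_trials(path: str | Path) -> pd.DataFrame:
    """Adapter for a locally downloaded copy of the deposited study data.

    Expects per-experiment CSVs with at least participant, condition, timing
    and rating columns; maps common column spellings onto the package
    schema.  Raises a descriptive error when the layout is not recognised
    (the deposited layout cannot be introspected offline, so this adapter is
    best-effort).
    """
    df = pd.read_csv(path)
    aliases = {
        "participant": ["participant", "subject", "subj", "id"],
        "condition": ["condition", "cond"],
        "t1_s": ["t1_s", "t1", "choice_time", "rt1"],
        "delay_s": ["delay_s", "delay", "t2_minus_t1", "soa"],
        "first_response": ["first_response", "choice", "response1"],
        "rating": ["rating", "preference", "pref", "response2"],
    }
    cols = {}
    lower = {c.lower(): c for c in df.columns}
    for target, cands in aliases.items():
        for c in cands:
            if c in lower:
                cols[target] = lower[c]
                break
        else:
            raise SchemaError(
                f"cannot map column {target!r} from {sorted(df.columns)}")
    out = df[[cols[k] for k in cols]].rename(
        columns={v: k for k, v in cols.items()})
    smax = float(np.abs(out["rating"]).max())
    out["scale_max"] = 30.0 if smax > 10 else 10.0
    out["experiment"] = 1 if smax > 10 else 2
    out["block"] = 0
    out["is_catch"] = False
    cond = out["condition"].astype(str).str.lower().str.strip()
    out["condition"] = np.where(cond.str.startswith("c"), "choice", "no_choice")
    return validate_trials(out)


# ---------------------------------------------------------------------------
# parameters and results
# ---------------------------------------------------------------------------

def read_params(path: str | Path) -> ModelParams:
    with open(path) as fh:
        return ModelParams.from_dict(yaml.safe_load(fh))


def write_params(params: ModelParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_bundled_params(name: str) -> ModelParams:
    """Load a parameter set shipped with the package.

    Names: ``table3_exp1``, ``table3_exp2``, ``exp1_emulation``,
    ``exp2_emulation``.
    """
    ref = resources.files("openpref") / "params" / f"{name}.yaml"
    return ModelParams.from_dict(yaml.safe_load(ref.read_text()))


def config_hash(obj) -> str:
    """Short deterministic hash of a JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
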