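"""Tree-inventory file schemas, run configuration and provenance helpers.

The on-disk inventory schema is a plain UTF-8 CSV with header
``tree_id,population_id,zone,in_reserve,dbh_t0_cm,dbh_t1_cm,debark_frac,
prun_frac,wd_g_cm3,lma_g_m2`` ("." decimal separator, no thousands
separators). In memory the same table uses unit-free column names
(dbh_t0, debark, ...); AGR is derived from the two DBH columns. Every
artifact a pipeline stage writes embeds the run seed and a configuration
hash so reruns are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "CSV_COLUMNS",
    "RunConfig",
    "read_tree_table",
    "write_tree_table",
    "write_json",
    "config_hash",
    "setup_logging",
]

#: on-disk name -> in-memory name
CSV_COLUMNS = {
    "tree_id": "tree_id",
    "population_id": "population_id",
    "zone": "zone",
    "in_reserve": "in_reserve",
    "dbh_t0_cm": "dbh_t0",
    "dbh_t1_cm": "dbh_t1",
    "debark_frac": "debark",
    "prun_frac": "prun",
    "wd_g_cm3": "wd",
    "lma_g_m2": "lma",
}
_INVERSE = {v: k for k, v in CSV_COLUMNS.items()}


class RunConfig(BaseModel):
    """One pipeline invocation's parameters; round-trips losslessly."""

    model_config = ConfigDict(extra="forbid")

    command: str
    input: Optional[str] = None
    output_dir: str = "results"
    model: str = "0"
    spec_json: Optional[str] = None
    chains: int = Field(default=4, ge=2)
    iters: int = Field(default=20_000, ge=2000)
    seed: int = 0
    prior_overrides: Dict[str, list] = Field(default_factory=dict)
    criterion: str = "waic"
    welch: bool = False

    def to_json(self) -> str:
        return self.model_dump_json()

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.model_validate_json(text)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.to_json().encode()).hexdigest()[:12]


def read_tree_table(path) -> pd.DataFrame:
    """Read and validate an inventory CSV into the in-memory schema.

    AGR is recomputed from the two DBH columns. Row-level violations are
    aggregated and reported together with 1-based data row numbers.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df.rename(columns=CSV_COLUMNS)[list(CSV_COLUMNS.values())]
    df["in_reserve"] = df["in_reserve"].map(
        lambda v: str(v).strip().lower() in ("true", "1", "yes")
    )
    df["agr"] = df["dbh_t1"] - df["dbh_t0"]

    problems: List[str] = []
    def check(mask: pd.Series, message: str, hint: str = "") -> None:
        rows = (np.flatnonzero(mask.to_numpy()) + 1).tolist()
        if rows:
            problems.append(f"rows {rows}: {message}{hint}")

    check(df["dbh_t0"] < 2, "dbh_t0_cm below the 2 cm census threshold")
    check(df["agr"] <= -1, "AGR <= -1 cm: log(AGR+1) response undefined")
    for col in ("debark", "prun"):
        bad = (df[col] < 0) | (df[col] > 1)
        hint = ""
        if ((df[col] > 1) & (df[col] <= 100)).any():
            hint = " (values in (1, 100] look like percent: divide by 100)"
        check(bad, f"{_INVERSE[col]} outside [0, 1]", hint)
    check(df["wd"] <= 0, "wd_g_cm3 must be positive")
    check(df["lma"] <= 0, "lma_g_m2 must be positive")
    if problems:
        raise ValueError(f"{path}: invalid inventory:\n  " + "\n  ".join(problems))
    cols = list(CSV_COLUMNS.values())
    cols.insert(cols.index("debark"), "agr")
    return df[cols]


def write_tree_table(records: pd.DataFrame, path, meta: Optional[Dict] = None) -> None:
    """Write an inventory in the on-disk schema, with a provenance comment."""
    out = records.rename(columns=_INVERSE)[list(CSV_COLUMNS)]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if meta:
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        out.to_csv(fh, index=False)


def write_json(payload: Dict, path, meta: Optional[Dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    body = dict(payload)
    if meta:
        body["_meta"] = meta
    path.write_text(json.dumps(body, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s %(message)s",
    )
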