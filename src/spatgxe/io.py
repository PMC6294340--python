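"""Subject-table validation, configuration, and format writers.

Every output file embeds the pipeline seed and a hash of the configuration
that produced it, so a rerun with an identical config is byte-identical
and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SUBJECT_COLUMNS",
    "PipelineConfig",
    "read_subjects",
    "validate_subjects",
    "write_tsv",
    "write_json",
    "write_geojson",
]

SUBJECT_COLUMNS = (
    "id", "x_birth", "y_birth", "x_age5", "y_age5", "x_age7", "y_age7",
    "case", "event_age", "sex", "pc1", "pc2", "pc3", "famhx", "prs",
    "samp_prob", "res_stratum",
)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (paths, tessellation, model, seed)."""

    subjects: str
    out_dir: str
    boundary: str | None = None
    sumstats: str | None = None
    vcf: str | None = None
    n_min: int = 100
    resolution: float = 1000.0
    which_age: str = "birth"
    model: int = 3
    age_band_years: float = 5.0
    mh_weighted: bool = True
    theta_bounds: tuple[float, float] = (1e-8, 10.0)
    objective: str = "ml"
    seed: int = 0

    def validate_paths(self) -> None:
        for name in ("subjects", "boundary", "sumstats", "vcf"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path '{name}' does not exist: {p}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def read_subjects(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def validate_subjects(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Type-check the subject table and apply the stated exclusion rules.

    Returns the validated records plus a report of exclusion counts per
    rule (flow-chart style accounting). Missing mandatory columns raise a
    schema error naming them; duplicate subject ids are an error.
    """
    missing = [c for c in SUBJECT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"subject table missing mandatory column(s): {missing}")
    dup = table["id"][table["id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate subject ids: {dup[:10]}")

    report: dict[str, int] = {}
    df = table.copy()

    num_cols = [
        "x_birth", "y_birth", "x_age5", "y_age5", "x_age7", "y_age7",
        "event_age", "pc1", "pc2", "pc3", "prs", "samp_prob",
    ]
    df[num_cols] = df[num_cols].apply(pd.to_numeric, errors="coerce")
    rules = {
        "non_finite_coordinates": ~df[["x_birth", "y_birth", "x_age5", "y_age5",
                                       "x_age7", "y_age7"]].notna().all(axis=1),
        "non_positive_event_age": ~(df["event_age"] > 0),
        "invalid_case_flag": ~df["case"].isin([0, 1]),
        "invalid_sampling_probability": ~((df["samp_prob"] > 0) & (df["samp_prob"] <= 1)),
        "missing_covariates": ~df[["sex", "pc1", "pc2", "pc3", "famhx", "prs"]]
        .notna().all(axis=1),
    }
    drop = pd.Series(False, index=df.index)
    for rule, mask in rules.items():
        newly = mask & ~drop
        n = int(newly.sum())
        if n:
            report[rule] = n
        drop |= mask
    kept = df.loc[~drop].reset_index(drop=True)
    report["n_input"] = len(table)
    report["n_retained"] = len(kept)
    if drop.any():
        logger.info("excluded %d subject(s): %s", int(drop.sum()), report)
    return kept, report


def _metadata(config: PipelineConfig | None, seed: int | None) -> dict:
    md = {}
    if config is not None:
        md["config_hash"] = config.config_hash()
        md["seed"] = config.seed
    elif seed is not None:
        md["seed"] = seed
    return md


def write_tsv(df: pd.DataFrame, path, config: PipelineConfig | None = None,
              seed: int | None = None) -> None:
    """TSV with a '#' metadata header line (config hash + seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        md = _metadata(config, seed)
        if md:
            fh.write("# " + json.dumps(md, sort_keys=True) + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_json(obj: dict, path, config: PipelineConfig | None = None,
               seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    md = _metadata(config, seed)
    if md:
        obj = {**obj, "metadata": {**obj.get("metadata", {}), **md}}
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_geojson(gj: dict, path, config: PipelineConfig | None = None,
                  seed: int | None = None) -> None:
    write_json(gj, path, config, seed)
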