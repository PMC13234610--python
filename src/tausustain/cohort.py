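"""Cohort tables, run configuration, and model-bundle serialization.

The pipeline's tabular input is a long (tidy) CSV: one row per scan, with
``subject_id``, ``visit_index`` (0 = baseline), ``time_from_baseline`` in
years, ``group`` (``control``/``patient``) and one column per region.
Baseline and follow-up scans share this layout so they can be processed
identically.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .events import EventSet

__all__ = [
    "REQUIRED_COLUMNS",
    "CANONICAL_REGIONS",
    "CohortTable",
    "RunConfig",
    "CohortError",
    "ModelFileError",
    "read_cohort_table",
    "write_cohort_table",
    "save_model",
    "load_model",
    "table_digest",
]

REQUIRED_COLUMNS = ("subject_id", "visit_index", "time_from_baseline", "group")

#: The study's 10 unilateral lobar composite regions (left/right hemisphere).
CANONICAL_REGIONS = (
    "frontal_l",
    "frontal_r",
    "parietal_l",
    "parietal_r",
    "lateral_temporal_l",
    "lateral_temporal_r",
    "occipital_l",
    "occipital_r",
    "medial_temporal_l",
    "medial_temporal_r",
)

MODEL_FILE_VERSION = 1


class CohortError(ValueError):
    """Raised for malformed cohort tables."""


class ModelFileError(ValueError):
    """Raised for unreadable or inconsistent model files."""


@dataclass
class CohortTable:
    """Validated long-format cohort: one row per scan.

    ``data`` holds the metadata columns plus one numeric column per region;
    ``regions`` preserves the region column order from the source header.
    """

    data: pd.DataFrame
    regions: tuple[str, ...]

    def __post_init__(self) -> None:
        self.regions = tuple(self.regions)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise CohortError(f"missing required column {col!r}")
        for region in self.regions:
            if region not in df.columns:
                raise CohortError(f"missing region column {region!r}")
        bad_group = ~df["group"].isin(["control", "patient"])
        if bad_group.any():
            row = int(np.nonzero(bad_group.to_numpy())[0][0])
            raise CohortError(
                f"unknown group label {df['group'].iloc[row]!r} at row {row} (column 'group')"
            )
        dup = df.duplicated(subset=["subject_id", "visit_index"])
        if dup.any():
            row = int(np.nonzero(dup.to_numpy())[0][0])
            raise CohortError(
                f"duplicate (subject_id, visit_index) = "
                f"({df['subject_id'].iloc[row]!r}, {df['visit_index'].iloc[row]}) at row {row}"
            )
        if (df["visit_index"].to_numpy() < 0).any():
            raise CohortError("negative visit_index")
        t = df["time_from_baseline"].to_numpy(dtype=float)
        if (t < 0).any():
            raise CohortError("negative time_from_baseline")
        base = df["visit_index"].to_numpy() == 0
        if not np.allclose(t[base], 0.0):
            raise CohortError("visit_index 0 must have time_from_baseline = 0")
        for region in self.regions:
            col = pd.to_numeric(df[region], errors="coerce").to_numpy(dtype=float)
            if np.isnan(col).any():
                row = int(np.nonzero(np.isnan(col))[0][0])
                raise CohortError(
                    f"missing or non-numeric value at row {row}, column {region!r}"
                )

    # -- views -----------------------------------------------------------
    def values(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Region-value matrix (rows = scans, columns = regions)."""
        df = self.data if mask is None else self.data.loc[mask]
        return df[list(self.regions)].to_numpy(dtype=float)

    def baseline_mask(self) -> np.ndarray:
        return (self.data["visit_index"] == 0).to_numpy()

    def group_mask(self, group: str) -> np.ndarray:
        return (self.data["group"] == group).to_numpy()

    def control_baseline(self) -> pd.DataFrame:
        m = self.baseline_mask() & self.group_mask("control")
        return self.data.loc[m]

    def patient_baseline(self) -> pd.DataFrame:
        m = self.baseline_mask() & self.group_mask("patient")
        return self.data.loc[m]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class RunConfig:
    """Pipeline configuration; one seed drives every stochastic step."""

    regions: tuple[str, ...] | None = None
    n_thresholds: int = 2  # thresholds per region (R)
    max_subtypes: int = 3
    em_startpoints: int = 10
    em_tol: float = 1e-6  # relative log-likelihood change
    em_max_iter: int = 100
    mcmc_iters: int = 5000
    mcmc_burn_frac: float = 0.1
    cv_folds: int = 5
    prob_threshold: float = 0.5  # poor-fit exclusion on max subtype posterior
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_thresholds < 1:
            raise ValueError("n_thresholds must be >= 1")
        if not 0.0 <= self.prob_threshold <= 1.0:
            raise ValueError("prob_threshold must be in [0, 1]")
        if self.regions is not None:
            self.regions = tuple(self.regions)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["regions"] is not None:
            d["regions"] = list(d["regions"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


# -- CSV I/O -------------------------------------------------------------

def read_cohort_table(path: str | Path) -> CohortTable:
    """Read and validate a long-format cohort CSV.

    Region columns are every header column beyond the required four, in
    header order.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing required column(s) {missing}")
    regions = tuple(c for c in df.columns if c not in REQUIRED_COLUMNS)
    if not regions:
        raise CohortError(f"{path}: no region columns found")
    df["subject_id"] = df["subject_id"].astype(str)
    try:
        df["visit_index"] = df["visit_index"].astype(int)
    except (TypeError, ValueError) as exc:
        raise CohortError(f"{path}: non-integer visit_index ({exc})") from exc
    return CohortTable(data=df.reset_index(drop=True), regions=regions)


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    cols = list(REQUIRED_COLUMNS) + list(table.regions)
    table.data[cols].to_csv(path, index=False)


def table_digest(table: CohortTable) -> str:
    """SHA-256 over the canonical CSV rendering of the table."""
    cols = list(REQUIRED_COLUMNS) + list(table.regions)
    payload = table.data[cols].to_csv(index=False).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()


# -- model bundle serialization ------------------------------------------
# A single JSON document; floats round-trip exactly (json emits shortest
# repr, which Python parses back bit-identically).

def save_model(
    path: str | Path,
    *,
    event_set: EventSet,
    subtype_model=None,
    zscore_model=None,
    config: RunConfig | None = None,
    input_digest: str | None = None,
) -> None:
    from .model import SubtypeModel  # local import to avoid cycle
    from .zscore import ZScoreModel

    doc: dict = {
        "format": "tausustain-model",
        "version": MODEL_FILE_VERSION,
        "provenance": {
            "created": _dt.datetime.now(_dt.timezone.utc).isoformat(),
            "seed": None if config is None else config.seed,
            "input_digest": input_digest,
        },
        "event_set": event_set.to_dict(),
    }
    if subtype_model is not None:
        doc["subtype_model"] = subtype_model.to_dict()
    if zscore_model is not None:
        doc["zscore_model"] = zscore_model.to_dict()
    if config is not None:
        doc["config"] = config.to_dict()
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> dict:
    """Load a model bundle; returns a dict with deserialized components."""
    from .model import SubtypeModel
    from .zscore import ZScoreModel

    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFileError(f"cannot read model file {path}: {exc}") from exc
    if doc.get("format") != "tausustain-model":
        raise ModelFileError(f"{path}: not a tausustain model file")
    if doc.get("version") != MODEL_FILE_VERSION:
        raise ModelFileError(
            f"{path}: unsupported model file version {doc.get('version')!r}"
        )
    out: dict = {"provenance": doc.get("provenance", {})}
    try:
        es = EventSet.from_dict(doc["event_set"])
    except (KeyError, ValueError) as exc:
        raise ModelFileError(f"{path}: bad event set ({exc})") from exc
    out["event_set"] = es
    if "subtype_model" in doc:
        sm = SubtypeModel.from_dict(doc["subtype_model"], es)
        if sm.event_set.n_events != es.n_events:
            raise ModelFileError(f"{path}: subtype model / event set mismatch")
        out["subtype_model"] = sm
    if "zscore_model" in doc:
        zm = ZScoreModel.from_dict(doc["zscore_model"])
        if tuple(zm.regions) != tuple(es.regions):
            raise ModelFileError(f"{path}: z-score model regions do not match event set")
        out["zscore_model"] = zm
    if "config" in doc:
        out["config"] = RunConfig.from_dict(doc["config"])
    return out
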