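"""Per-scan subtype and stage assignment, poor-fit exclusion, and the
deviation-from-sequence (event imperfection) statistic.

Each scan is assigned to the subtype with the highest posterior probability
and then to the highest-probability stage within that subtype; scans whose
maximum subtype posterior falls below a probability threshold (default 50%)
are flagged as poorly fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import SubtypeModel, stage_log_likelihoods, subject_log_likelihood

__all__ = [
    "AssignmentRecord",
    "assign",
    "assign_matrix",
    "sequence_deviation",
    "records_to_frame",
]


@dataclass
class AssignmentRecord:
    """Subtype/stage call for a single scan."""

    subject_id: str
    visit_index: int
    subtype_posterior: np.ndarray  # P(c | x), sums to 1
    subtype: int  # argmax posterior (ties -> lowest index)
    stage_posterior: np.ndarray  # P(k | x, subtype), length N+1
    stage: int  # argmax (ties -> lowest stage)
    excluded: bool  # max subtype posterior < threshold
    stage_zero: bool
    deviation: int | None = None
    event_mismatch: np.ndarray | None = None  # per-event bool flags


def assign(
    x: np.ndarray,
    model: SubtypeModel,
    prob_threshold: float = 0.5,
    subject_id: str = "",
    visit_index: int = 0,
) -> AssignmentRecord:
    """Assign one scan; see :func:`assign_matrix` for the vectorized form."""
    recs = assign_matrix(
        np.atleast_2d(np.asarray(x, dtype=float)),
        model,
        prob_threshold,
        subject_ids=[subject_id],
        visit_indices=[visit_index],
    )
    return recs[0]


def assign_matrix(
    Z: np.ndarray,
    model: SubtypeModel,
    prob_threshold: float = 0.5,
    subject_ids=None,
    visit_indices=None,
    with_deviation: bool = True,
) -> list[AssignmentRecord]:
    """Assign every row of a z-matrix under a fitted model.

    Posterior over subtypes is f_c P(x|S_c) / sum f P(x|S); the stage
    posterior is the normalized stage likelihood within the chosen subtype.
    """
    if not 0.0 <= prob_threshold <= 1.0:
        raise ValueError("prob_threshold must be in [0, 1]")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n = Z.shape[0]
    subject_ids = (
        [str(j) for j in range(n)] if subject_ids is None else list(subject_ids)
    )
    visit_indices = [0] * n if visit_indices is None else list(visit_indices)
    logm, _ = subject_log_likelihood(Z, model)
    joint = logm + np.log(model.fractions)
    post = np.exp(joint - logsumexp(joint, axis=1)[:, None])
    chat = np.argmax(post, axis=1)  # np.argmax ties -> lowest index
    stage_ll = {
        c: stage_log_likelihoods(Z, model.sequences[c], model.event_set, model.sigma)
        for c in np.unique(chat)
    }
    records: list[AssignmentRecord] = []
    for j in range(n):
        c = int(chat[j])
        sl = stage_ll[c][j]
        sp = np.exp(sl - logsumexp(sl))
        k = int(np.argmax(sp))
        rec = AssignmentRecord(
            subject_id=str(subject_ids[j]),
            visit_index=int(visit_indices[j]),
            subtype_posterior=post[j],
            subtype=c,
            stage_posterior=sp,
            stage=k,
            excluded=bool(post[j].max() < prob_threshold),
            stage_zero=(k == 0),
        )
        if with_deviation:
            d, flags = sequence_deviation(Z[j], model, rec)
            rec.deviation, rec.event_mismatch = d, flags
        records.append(rec)
    return records


def sequence_deviation(
    x: np.ndarray, model: SubtypeModel, record: AssignmentRecord
) -> tuple[int, np.ndarray]:
    """Events contradicting the prefix implied by the assigned stage.

    Each event (i, r) is *achieved* iff x_i >= z_ir (closed threshold); the
    assigned stage expects exactly the first k events of the subtype's
    sequence.  The deviation is the Hamming distance between the observed and
    expected achievement vectors (0..N).
    """
    es = model.event_set
    x = np.asarray(x, dtype=float).ravel()
    achieved = np.array([x[i] >= es.thresholds[i][r] for i, r in es.events])
    seq = np.asarray(model.sequences[record.subtype])
    expected = np.zeros(es.n_events, dtype=bool)
    expected[seq[: record.stage]] = True
    mismatch = achieved != expected
    return int(mismatch.sum()), mismatch


def records_to_frame(records: list[AssignmentRecord]) -> pd.DataFrame:
    """Flatten assignment records into a tidy table (one row per scan)."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "visit_index": r.visit_index,
            "subtype": r.subtype,
            "stage": r.stage,
            "max_subtype_prob": float(r.subtype_posterior.max()),
            "excluded": r.excluded,
            "stage_zero": r.stage_zero,
            "deviation": r.deviation,
        }
        for c, p in enumerate(r.subtype_posterior):
            row[f"p_subtype_{c + 1}"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)
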