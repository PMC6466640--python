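"""Contour conformity metrics and cohort slice-wise summaries.

The Jaccard conformity index (JCI) is intersection over union of two
binary masks; the Dice similarity coefficient (DSC) is twice the
intersection over the sum of areas.  Both derive from the same pixel
counts, so DSC = 2 JCI / (1 + JCI) identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConformityScore:
    jci: float
    dsc: float
    slice_offset: int


def _counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(a & b))
    return inter, int(a.sum()), int(b.sum())


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """|a n b| / |a u b|; two empty masks score 1 (degenerate, logged)."""
    inter, na, nb = _counts(a, b)
    union = na + nb - inter
    if union == 0:
        log.debug("jaccard of two empty masks: returning 1 by convention")
        return 1.0
    return inter / union


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2 |a n b| / (|a| + |b|); two empty masks score 1 (degenerate)."""
    inter, na, nb = _counts(a, b)
    if na + nb == 0:
        log.debug("dice of two empty masks: returning 1 by convention")
        return 1.0
    return 2.0 * inter / (na + nb)


def score_pair(a: np.ndarray, b: np.ndarray, slice_offset: int = 0) -> ConformityScore:
    j = jaccard(a, b)
    return ConformityScore(jci=j, dsc=2.0 * j / (1.0 + j), slice_offset=slice_offset)


def prostate_reference_slice(prostate_masks: np.ndarray) -> int:
    """Slice holding the most anterior (minimum-row) prostate pixel.

    This slice is the z-origin for all slice-offset reporting.  Ties go to
    the more inferior (lower-index) slice.
    """
    masks = np.asarray(prostate_masks, bool)
    best_k, best_row = None, None
    for k in range(masks.shape[0]):
        rows = np.nonzero(masks[k].any(axis=1))[0]
        if rows.size == 0:
            continue
        r = int(rows.min())
        if best_row is None or r < best_row:
            best_k, best_row = k, r
    if best_k is None:
        raise ValueError("prostate structure is empty on every slice")
    return best_k


def cohort_summary(scores: "pd.DataFrame | list[tuple[int, float]]",
                   min_scans: int = 5, value: str = "jci") -> pd.DataFrame:
    """Per-slice-offset mean and standard error over a cohort of scans.

    ``scores`` is either a DataFrame with columns ``slice_offset`` and the
    metric column, or a list of (slice_offset, value) pairs.  Offsets with
    fewer than ``min_scans`` contributing scores are dropped (their means
    would carry large errors).  SE uses the n-1 sample standard deviation.
    The overall mean across retained rows is stored in ``df.attrs["mean"]``.
    """
    if not isinstance(scores, pd.DataFrame):
        scores = pd.DataFrame(scores, columns=["slice_offset", value])
    if scores.empty:
        raise ValueError("no scores supplied")
    g = scores.groupby("slice_offset")[value]
    out = pd.DataFrame({
        "n": g.size(),
        "mean": g.mean(),
        "se": g.std(ddof=1) / np.sqrt(g.size()),
    })
    out.loc[out["n"] == 1, "se"] = np.nan
    out = out[out["n"] >= min_scans]
    retained = scores[scores["slice_offset"].isin(out.index)]
    out.attrs["mean"] = float(retained[value].mean()) if len(retained) else float("nan")
    return out
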