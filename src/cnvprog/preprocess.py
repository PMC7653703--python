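"""Profile normalization, DLRS quality control and centralization.

The derivative log ratio spread (DLRS) estimates probe-level noise from
lag-1 differences of consecutive probes within a chromosome: differencing
cancels the piecewise-constant copy-number signal, and a robust scale
estimate of the differences, divided by 1.349 * sqrt(2) (the IQR of a
standard normal times the variance inflation of a difference), recovers
the per-probe Gaussian noise sd. Arrays noisier than 0.47 are excluded;
the homozygosity-based LOH caller additionally requires DLRS below 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import iqr

from .genome import ProbeMap

__all__ = [
    "QCMetrics",
    "normalize_profile",
    "normalize_matrix",
    "compute_dlrs",
    "apply_qc",
    "centralize_profile",
    "DLRS_EXCLUDE_THRESHOLD",
    "DLRS_LOH_THRESHOLD",
]

DLRS_EXCLUDE_THRESHOLD = 0.47
DLRS_LOH_THRESHOLD = 0.30

_IQR_NORMAL = 1.349  # IQR of N(0, 1)
_DIFF_SCALE = _IQR_NORMAL * np.sqrt(2.0)


class EmptyProfileError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class QCMetrics:
    sample_id: str
    dlrs: float

    @property
    def passes_qc(self) -> bool:
        return self.dlrs <= DLRS_EXCLUDE_THRESHOLD

    @property
    def loh_eligible(self) -> bool:
        return self.dlrs < DLRS_LOH_THRESHOLD


def normalize_profile(values: np.ndarray, method: str = "median") -> np.ndarray:
    """Center a log2-ratio profile so its typical level sits at zero.

    ``method`` is "median" (default) or "mode" (half-sample mode estimate);
    both are pure shifts, so probe-to-probe differences are preserved.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if not finite.any():
        raise EmptyProfileError("profile has no finite values")
    if method == "median":
        center = float(np.median(v[finite]))
    elif method == "mode":
        center = _half_sample_mode(v[finite])
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return v - center


def _half_sample_mode(x: np.ndarray) -> float:
    """Robust mode via recursive half-sample shrinking."""
    x = np.sort(x)
    while len(x) > 3:
        h = len(x) // 2
        widths = x[h:] - x[: len(x) - h]
        i = int(np.argmin(widths))
        x = x[i : i + h + 1]
    return float(np.mean(x))


def normalize_matrix(l2r: pd.DataFrame, method: str = "median") -> pd.DataFrame:
    """Column-wise (per-sample) normalization of a probes x samples matrix."""
    out = l2r.copy()
    for col in out.columns:
        out[col] = normalize_profile(out[col].to_numpy(), method=method)
    return out


def compute_dlrs(values: np.ndarray, probe_map: ProbeMap, sample_id: str = "") -> QCMetrics:
    """Derivative log ratio spread of one profile.

    Differences are taken only between genomically consecutive probes of
    the same chromosome, so segment steps at chromosome boundaries never
    contribute; DLRS = IQR(diffs) / (1.349 * sqrt(2)).
    """
    v = np.asarray(values, dtype=float)
    if len(v) != len(probe_map):
        raise ValueError("profile length does not match probe map")
    if len(v) < 3:
        raise InsufficientDataError("need at least 3 probes for DLRS")
    same_chrom = np.diff(probe_map.chrom) == 0
    diffs = np.diff(v)[same_chrom]
    if len(diffs) < 2:
        raise InsufficientDataError("too few within-chromosome differences")
    return QCMetrics(sample_id=sample_id, dlrs=float(iqr(diffs) / _DIFF_SCALE))


def compute_dlrs_matrix(l2r: pd.DataFrame, probe_map: ProbeMap) -> list[QCMetrics]:
    return [compute_dlrs(l2r[c].to_numpy(), probe_map, sample_id=str(c)) for c in l2r.columns]


def apply_qc(
    metrics: list[QCMetrics],
    threshold: float = DLRS_EXCLUDE_THRESHOLD,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Partition samples into kept and excluded by the DLRS gate.

    Exclusion is strict (DLRS > threshold); a sample exactly at the
    threshold is kept. Returns (kept ids, excluded ids, report frame).
    """
    kept, excluded, rows = [], [], []
    for m in metrics:
        ok = m.dlrs <= threshold
        (kept if ok else excluded).append(m.sample_id)
        rows.append({
            "sample_id": m.sample_id,
            "dlrs": m.dlrs,
            "kept": ok,
            "loh_eligible": ok and m.dlrs < DLRS_LOH_THRESHOLD,
            "reason": "" if ok else f"DLRS {m.dlrs:.3f} > {threshold}",
        })
    report = pd.DataFrame(rows, columns=["sample_id", "dlrs", "kept", "loh_eligible", "reason"])
    return kept, excluded, report


class MissingSegmentationError(ValueError):
    pass


def centralize_profile(
    values: np.ndarray,
    segments: pd.DataFrame,
    min_alteration_mb: float = 5.0,
    gain_threshold: float = 0.25,
    loss_threshold: float = -0.25,
    level_bin_width: float = 0.1,
    purity: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Shift a profile so the inferred copy-neutral level sits at zero.

    Centralization fires only for profiles carrying at least one altered
    segment (|mean| beyond the calling thresholds) spanning at least
    ``min_alteration_mb``: large events can displace a median-centered
    baseline (in a tumor with most of its genome gained, the median sits
    on the gained level). Segment means are grouped into levels at
    ``level_bin_width`` log2 resolution with genomic-span weights; each
    level is then tried as the copy-neutral candidate, and the one whose
    competing levels best fit the integer copy-dosage ladder
    log2((2 + purity * k) / 2), k in {-2..2}, span-weighted, is declared
    neutral. A lone dominant level thereby maps to neutral (matching the
    length-weighted-mode intuition), while a majority-gain genome is still
    centered correctly because a level 0.585 below the mode fits the
    ladder as neutral-vs-gain, whereas the converse does not. Returns
    (shifted profile, offset applied).

    ``segments`` needs columns start, end (bp) and mean_l2r for this sample.
    """
    if segments is None or len(segments) == 0:
        raise MissingSegmentationError("no segments available for centralization")
    means = segments["mean_l2r"].to_numpy(dtype=float)
    spans = (segments["end"].to_numpy(dtype=float)
             - segments["start"].to_numpy(dtype=float) + 1.0)
    altered = (means >= gain_threshold) | (means <= loss_threshold)
    large = altered & (spans >= min_alteration_mb * 1e6)
    if not large.any():
        return np.asarray(values, dtype=float), 0.0
    bins = np.round(means / level_bin_width).astype(int)
    level_of: dict[int, float] = {}
    span_of: dict[int, float] = {}
    for b in np.unique(bins):
        sel = bins == b
        level_of[b] = float(np.average(means[sel], weights=spans[sel]))
        span_of[b] = float(spans[sel].sum())
    ladder = np.array([np.log2((2.0 + purity * k) / 2.0) for k in (-1, 0, 1, 2)
                       if 2.0 + purity * k > 0])
    best = None
    for b, cand in level_of.items():
        misfit = sum(
            span_of[o] * float(np.min(np.abs((level_of[o] - cand) - ladder)))
            for o in level_of)
        key = (misfit, -span_of[b], abs(cand))  # ties: larger span, then nearer zero
        if best is None or key < best[0]:
            best = (key, cand)
    level = best[1]
    return np.asarray(values, dtype=float) - level, -level
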