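"""Modern-analog assessment with the squared chord distance.

The squared chord distance d(p, q) = Σ_k (√p_k − √q_k)² is the standard
pollen dissimilarity measure; on the percent scale (rows summing to 100) it
ranges from 0 (identical assemblages) to 200 (fully disjoint). It is
symmetric and zero only for equal assemblages, but does not satisfy the
triangle inequality in general, so it is a dissimilarity rather than a
metric. A fossil sample with a small minimum distance to a calibration set
has a good modern analog in that set; era summaries average the minimum
distance over samples whose age-interval midpoint falls in a year range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io_formats import CalibrationSet, FossilRecord, ValidationError, _normalize_name

logger = logging.getLogger(__name__)


@dataclass
class AnalogResult:
    """Per-fossil-sample nearest-analog distances against one calibration set."""

    sample_ids: list[str]
    intervals: list[tuple[int, int]]
    min_distance: np.ndarray
    nearest_site: list[str]
    calibration_label: str = ""

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([(a + b) / 2.0 for a, b in self.intervals])


def squared_chord_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Squared chord distance between two percent assemblages (same taxon order)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError("assemblages must share taxon order and length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValidationError("abundances must be non-negative")
    return float(np.sum((np.sqrt(p) - np.sqrt(q)) ** 2))


def chord_distance_matrix(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Pairwise squared chord distances between row-assemblages of P and Q."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if np.any(P < 0) or np.any(Q < 0):
        raise ValidationError("abundances must be non-negative")
    return cdist(np.sqrt(P), np.sqrt(Q), metric="sqeuclidean")


def min_analog_series(fossil: FossilRecord, cal: CalibrationSet,
                      scale: str = "percent") -> AnalogResult:
    """Minimum squared chord distance of each fossil sample to a calibration set.

    Requires taxa harmonized (same taxon set after trimming/case-folding);
    ties are broken by the first calibration site in file order. Distances
    are on the percent scale (0-200) by default; ``scale="proportion"``
    computes on proportions instead (values 100× smaller).
    """
    if cal.pollen.n_samples == 0:
        raise ValidationError("empty calibration set")
    if scale not in ("percent", "proportion"):
        raise ValidationError("scale must be 'percent' or 'proportion'")
    f_taxa = [_normalize_name(t) for t in fossil.samples.taxa]
    c_taxa = [_normalize_name(t) for t in cal.pollen.taxa]
    if set(f_taxa) != set(c_taxa):
        raise ValidationError("taxa not harmonized between fossil record and "
                              "calibration set")
    order = [c_taxa.index(t) for t in f_taxa]
    div = 100.0 if scale == "proportion" else 1.0
    D = chord_distance_matrix(fossil.samples.values / div,
                              cal.pollen.values[:, order] / div)
    nearest = D.argmin(axis=1)  # first index wins ties
    return AnalogResult(
        sample_ids=list(fossil.samples.ids),
        intervals=list(fossil.intervals),
        min_distance=D[np.arange(D.shape[0]), nearest],
        nearest_site=[cal.pollen.ids[j] for j in nearest],
        calibration_label=cal.label,
    )


def era_mean_min_distance(result: AnalogResult, start: float, end: float) -> float:
    """Mean minimum distance over samples with interval midpoint in [start, end]."""
    mid = result.midpoints
    mask = (mid >= start) & (mid <= end)
    if not mask.any():
        raise ValidationError(f"no samples with midpoints in [{start}, {end}]")
    return float(result.min_distance[mask].mean())
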