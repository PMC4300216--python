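"""Tabular formats for pollen-climate work: matrices, climate tables, records.

The pipeline's interchange format is plain CSV (comma-separated, UTF-8,
``.`` decimal). A pollen matrix CSV has a header row whose first column is
``id`` followed by taxon names, and one row per site or core sample. A
climate table CSV has ``id`` followed by climate-variable columns (monthly
mean temperatures, °C). A fossil-record CSV is a pollen matrix whose first
three columns are ``id``, ``start_year``, ``end_year`` (calendar years AD,
intervals inclusive on both ends).

Percent matrices must have rows summing to 100. On file input a slack of
±0.5 is tolerated (legacy datasets are rounded) and the row is silently
renormalized with a logged warning; internally constructed matrices are held
to 1e-6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: slack accepted when reading percent CSVs from disk (rows renormalized)
PERCENT_TOL_READ = 0.5
#: slack required of internally built percent matrices
PERCENT_TOL_INTERNAL = 1e-6


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


def _normalize_name(name: str) -> str:
    return name.strip().casefold()


@dataclass
class PollenMatrix:
    """Sites/samples × taxa matrix of pollen counts or percentages.

    Parameters
    ----------
    ids : list of str
        Site or sample identifiers, one per row.
    taxa : list of str
        Taxon names, one per column; unique.
    values : ndarray of shape (n_rows, n_taxa)
        Non-negative counts (grains) or percentages (rows sum to 100).
    kind : {"counts", "percent"}
    """

    ids: list[str]
    taxa: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.taxa = [str(t) for t in self.taxa]
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("counts", "percent"):
            raise ValidationError(f"kind must be 'counts' or 'percent', got {self.kind!r}")
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.ids), len(self.taxa)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.ids)} ids × {len(self.taxa)} taxa"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("taxon names must be unique")
        if np.any(~np.isfinite(self.values)):
            raise ValidationError("values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("pollen values must be non-negative")
        if self.kind == "percent":
            sums = self.values.sum(axis=1)
            bad = np.abs(sums - 100.0) > PERCENT_TOL_INTERNAL
            if np.any(bad):
                i = int(np.argmax(bad))
                raise ValidationError(
                    f"percent row {self.ids[i]!r} sums to {sums[i]:.6g}, not 100"
                )

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="id"),
                            columns=self.taxa)

    def copy(self) -> "PollenMatrix":
        return PollenMatrix(list(self.ids), list(self.taxa), self.values.copy(), self.kind)


@dataclass
class ClimateTable:
    """Per-site climate values (°C) aligned one-to-one with a pollen matrix."""

    site_ids: list[str]
    data: pd.DataFrame  # columns = climate variables
    normal_period: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.site_ids = [str(i) for i in self.site_ids]
        if len(self.site_ids) != len(self.data):
            raise ValidationError("site_ids length must match table rows")
        if self.data.isna().any().any():
            raise ValidationError("climate table must have no missing values")

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def values_for(self, variable: str) -> np.ndarray:
        if variable not in self.data.columns:
            raise ValidationError(f"climate variable {variable!r} not present "
                                  f"(have {list(self.data.columns)})")
        return self.data[variable].to_numpy(dtype=float)


@dataclass
class CalibrationSet:
    """Paired pollen percentages and per-site climate: the training object.

    Synthetic sets additionally carry their generating provenance
    (`expected_proportions`, `taxon_groups`, `total_grains`) so that
    disturbance scenarios can be applied without re-passing the species model.
    """

    pollen: PollenMatrix
    climate: ClimateTable
    label: str = ""
    expected_proportions: np.ndarray | None = None
    taxon_groups: list[str] | None = None
    total_grains: int | None = None

    def __post_init__(self) -> None:
        if self.pollen.kind != "percent":
            raise ValidationError("calibration pollen must be percentages")
        if self.pollen.ids != self.climate.site_ids:
            raise ValidationError("pollen and climate site orderings differ")

    @property
    def n_sites(self) -> int:
        return self.pollen.n_samples


@dataclass
class FossilRecord:
    """Down-core pollen samples with varve-year age intervals (years AD)."""

    samples: PollenMatrix
    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.samples.kind != "percent":
            raise ValidationError("fossil samples must be percentages")
        if len(self.intervals) != self.samples.n_samples:
            raise ValidationError("one age interval per sample required")
        self.intervals = [(int(a), int(b)) for a, b in self.intervals]
        prev_end = None
        for start, end in self.intervals:
            if end < start:
                raise ValidationError(f"interval ({start}, {end}) has end < start")
            if prev_end is not None and start <= prev_end:
                raise ValidationError("intervals must be ordered and non-overlapping")
            prev_end = end

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([(a + b) / 2.0 for a, b in self.intervals])


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_pollen_matrix(path, kind: str) -> PollenMatrix:
    """Read a pollen matrix CSV (header of taxon names, first column ``id``).

    Percent rows summing to 100 ± 0.5 are accepted and renormalized with a
    logged warning; rows further off are a validation error.
    """
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValidationError(f"negative pollen values in {path}")
    if kind == "percent":
        sums = values.sum(axis=1)
        off = np.abs(sums - 100.0) > PERCENT_TOL_READ
        if np.any(off):
            i = int(np.argmax(off))
            raise ValidationError(
                f"percent row {df.index[i]!r} sums to {sums[i]:.6g}; "
                f"outside 100 ± {PERCENT_TOL_READ}"
            )
        drift = np.abs(sums - 100.0) > PERCENT_TOL_INTERNAL
        if np.any(drift):
            logger.warning("renormalizing %d percent rows within 100 ± %.1f",
                           int(drift.sum()), PERCENT_TOL_READ)
            values = values / sums[:, None] * 100.0
    return PollenMatrix(list(df.index.astype(str)), list(df.columns), values, kind)


def write_pollen_matrix(m: PollenMatrix, path) -> None:
    m.to_dataframe().to_csv(path)


def read_climate_table(path, normal_period: tuple[int, int] | None = None) -> ClimateTable:
    df = pd.read_csv(path, index_col=0)
    return ClimateTable(list(df.index.astype(str)), df.reset_index(drop=True),
                        normal_period)


def write_climate_table(t: ClimateTable, path) -> None:
    out = t.data.copy()
    out.insert(0, "id", t.site_ids)
    out.to_csv(path, index=False)


def read_fossil_record(path) -> FossilRecord:
    """Read a fossil CSV with ``id,start_year,end_year,<taxa...>`` columns."""
    df = pd.read_csv(path, index_col=0)
    for col in ("start_year", "end_year"):
        if col not in df.columns:
            raise ValidationError(f"fossil CSV missing {col!r} column")
    intervals = list(zip(df["start_year"].astype(int), df["end_year"].astype(int)))
    taxa = [c for c in df.columns if c not in ("start_year", "end_year")]
    values = df[taxa].to_numpy(dtype=float)
    sums = values.sum(axis=1)
    off = np.abs(sums - 100.0) > PERCENT_TOL_READ
    if np.any(off):
        raise ValidationError("fossil percent rows must sum to 100 ± 0.5")
    values = values / sums[:, None] * 100.0
    samples = PollenMatrix(list(df.index.astype(str)), taxa, values, "percent")
    return FossilRecord(samples, intervals)


def write_fossil_record(rec: FossilRecord, path) -> None:
    df = rec.samples.to_dataframe()
    df.insert(0, "start_year", [a for a, _ in rec.intervals])
    df.insert(1, "end_year", [b for _, b in rec.intervals])
    df.to_csv(path)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def to_percentages(m: PollenMatrix) -> PollenMatrix:
    """Convert a count matrix to percentages (each row rescaled to sum 100)."""
    if m.kind != "counts":
        raise ValidationError("to_percentages expects a counts matrix")
    sums = m.values.sum(axis=1)
    zero = sums <= 0
    if np.any(zero):
        i = int(np.argmax(zero))
        raise ValidationError(f"sample {m.ids[i]!r} has zero pollen sum")
    return PollenMatrix(list(m.ids), list(m.taxa), m.values / sums[:, None] * 100.0,
                        "percent")


def harmonize_taxa(a: PollenMatrix, b: PollenMatrix) -> tuple[PollenMatrix, PollenMatrix]:
    """Expand two matrices onto the union of their taxa, zero-filling absences.

    Taxa are matched exactly after whitespace trimming and case-folding
    (synonym resolution is curator work, not done here). The output column
    order is ``a``'s taxa followed by taxa unique to ``b``, in ``b``'s order.
    Every original value is preserved; added cells are exactly 0.
    """
    for m in (a, b):
        norm = [_normalize_name(t) for t in m.taxa]
        if len(set(norm)) != len(norm):
            raise ValidationError("duplicate taxon names after case-normalization")
    a_norm = {_normalize_name(t): t for t in a.taxa}
    union = list(a.taxa) + [t for t in b.taxa if _normalize_name(t) not in a_norm]

    def _expand(m: PollenMatrix) -> PollenMatrix:
        lookup = {_normalize_name(t): j for j, t in enumerate(m.taxa)}
        out = np.zeros((m.n_samples, len(union)))
        for j, t in enumerate(union):
            k = lookup.get(_normalize_name(t))
            if k is not None:
                out[:, j] = m.values[:, k]
        return PollenMatrix(list(m.ids), union, out, m.kind)

    return _expand(a), _expand(b)


def exclude_taxa_renormalize(m: PollenMatrix, taxa: Sequence[str]) -> PollenMatrix:
    """Drop named taxa from a percent matrix and rescale rows to sum 100.

    Used for disturbance-indicator sensitivity analyses (e.g. repeating an
    analysis with ragweed and grasses omitted). A row consisting entirely of
    excluded taxa cannot be renormalized and is an error.
    """
    if m.kind != "percent":
        raise ValidationError("exclude_taxa_renormalize expects percentages")
    drop = {_normalize_name(t) for t in taxa}
    have = {_normalize_name(t) for t in m.taxa}
    missing = drop - have
    if missing:
        # tolerated so that re-applying the same exclusion list is a no-op
        logger.info("exclusion taxa not present (ignored): %s", sorted(missing))
    keep = [j for j, t in enumerate(m.taxa) if _normalize_name(t) not in drop]
    values = m.values[:, keep]
    sums = values.sum(axis=1)
    dead = sums <= 0
    if np.any(dead):
        i = int(np.argmax(dead))
        raise ValidationError(
            f"sample {m.ids[i]!r} consists entirely of excluded taxa"
        )
    return PollenMatrix(list(m.ids), [m.taxa[j] for j in keep],
                        values / sums[:, None] * 100.0, "percent")
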