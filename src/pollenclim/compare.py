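"""Reconstruction versus instrumental series: alignment, tests, trends.

A down-core reconstruction is a sequence of multi-year samples; to compare
it with an annual instrumental record, the instrumental values are averaged
over each sample's varve-year interval ("cumulative averaging"). Two-sample
and paired location tests, a variance-ratio test, an OLS warming trend, a
centered moving average, period means by interval midpoint, and a
variance-captured (signal retention) ratio complete the toolkit, plus a
regression splice for extending a short station record from a longer
correlated neighbour.

Location tests default to Welch's unequal-variance form (the degrees of
freedom printed in this problem's reference comparisons match
Welch-Satterthwaite, not the pooled form); ``equal_var=True`` restores
pooled Student's t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .io_formats import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class InstrumentalSeries:
    """Annual values (°C) of one climate variable over a contiguous year range."""

    variable: str
    start_year: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValidationError("values must be a non-empty 1-D array")
        if np.any(~np.isfinite(self.values)):
            raise ValidationError("instrumental series may not contain gaps")

    @property
    def end_year(self) -> int:
        return self.start_year + len(self.values) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def window(self, start: int, end: int) -> np.ndarray:
        if start < self.start_year or end > self.end_year:
            raise ValidationError(f"[{start}, {end}] outside series range "
                                  f"[{self.start_year}, {self.end_year}]")
        return self.values[start - self.start_year: end - self.start_year + 1]

    @classmethod
    def read_csv(cls, path, variable: str | None = None) -> "InstrumentalSeries":
        df = pd.read_csv(path)
        if "year" not in df.columns:
            raise ValidationError("instrumental CSV needs a 'year' column")
        value_col = variable or [c for c in df.columns if c != "year"][0]
        df = df.sort_values("year")
        years = df["year"].to_numpy(dtype=int)
        if not np.all(np.diff(years) == 1):
            raise ValidationError("instrumental series has year gaps")
        return cls(value_col, int(years[0]), df[value_col].to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        pd.DataFrame({"year": self.years, self.variable: self.values}).to_csv(
            path, index=False)


@dataclass
class ReconstructionSeries:
    """Per-sample reconstructed values with varve-year age intervals."""

    intervals: list[tuple[int, int]]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.intervals) != len(self.values):
            raise ValidationError("one value per interval required")
        prev_end = None
        for start, end in self.intervals:
            if end < start:
                raise ValidationError("interval end before start")
            if prev_end is not None and start <= prev_end:
                raise ValidationError("intervals must be ordered, non-overlapping")
            prev_end = end

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([(a + b) / 2.0 for a, b in self.intervals])

    @classmethod
    def read_csv(cls, path) -> "ReconstructionSeries":
        df = pd.read_csv(path)
        value_col = [c for c in df.columns
                     if c not in ("id", "start_year", "end_year")][0]
        return cls(list(zip(df["start_year"].astype(int), df["end_year"].astype(int))),
                   df[value_col].to_numpy(dtype=float))

    def to_csv(self, path, value_name: str = "value") -> None:
        pd.DataFrame({
            "start_year": [a for a, _ in self.intervals],
            "end_year": [b for _, b in self.intervals],
            value_name: self.values,
        }).to_csv(path, index=False)


@dataclass
class ComparisonReport:
    """Outcome of one statistical comparison."""

    test: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    mean_a: float | None = None
    mean_b: float | None = None
    sd_a: float | None = None
    sd_b: float | None = None
    n_a: int | None = None
    n_b: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_to_intervals(series: InstrumentalSeries, rec: ReconstructionSeries):
    """Average the annual series over each sample's age interval.

    Returns (reconstruction values, interval-mean instrumental values,
    retained intervals); samples not fully inside the series range are
    dropped with a log message.
    """
    rec_vals, instr_means, kept = [], [], []
    for (start, end), v in zip(rec.intervals, rec.values):
        if start < series.start_year or end > series.end_year:
            logger.info("dropping sample %s-%s: outside instrumental range", start, end)
            continue
        rec_vals.append(v)
        instr_means.append(series.window(start, end).mean())
        kept.append((start, end))
    if not kept:
        raise ValidationError("no samples overlap the instrumental series")
    return np.array(rec_vals), np.array(instr_means), kept


# ---------------------------------------------------------------------------
# Statistical kernels
# ---------------------------------------------------------------------------

def welch_t_test(a, b, equal_var: bool = False) -> ComparisonReport:
    """Two-sample t-test on means, Welch's unequal-variance form by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("both groups need n >= 2")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        df = float(na + nb - 2)
        name = "student_t"
    else:
        se2 = va / na + vb / nb
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        name = "welch_t"
    p = 2.0 * stats.t.sf(abs(t), df)
    return ComparisonReport(name, float(t), float(df), float(p),
                            mean_a=float(a.mean()), mean_b=float(b.mean()),
                            sd_a=float(np.sqrt(va)), sd_b=float(np.sqrt(vb)),
                            n_a=na, n_b=nb)


def variance_f_test(a, b) -> ComparisonReport:
    """Two-sided F-test of equal variances, F = s_a² / s_b²."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("both groups need n >= 2")
    if b.var(ddof=1) == 0:
        raise ValidationError("second group has zero variance")
    return variance_f_test_from_summary(float(a.std(ddof=1)), float(b.std(ddof=1)),
                                        len(a) - 1, len(b) - 1)


def variance_f_test_from_summary(sd_a: float, sd_b: float,
                                 df_a: int, df_b: int) -> ComparisonReport:
    """F-test from summary standard deviations and degrees of freedom.

    Two-sided p-value by doubling the smaller tail of the F(df_a, df_b) law.
    """
    if sd_b <= 0:
        raise ValidationError("sd_b must be positive")
    F = (sd_a / sd_b) ** 2
    p = 2.0 * min(stats.f.cdf(F, df_a, df_b), stats.f.sf(F, df_a, df_b))
    return ComparisonReport("variance_f", float(F), (float(df_a), float(df_b)),
                            float(min(p, 1.0)),
                            sd_a=sd_a, sd_b=sd_b, n_a=df_a + 1, n_b=df_b + 1)


def paired_t_test(diffs) -> ComparisonReport:
    """One-sample t-test on paired differences (df = n − 1)."""
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    if n < 2:
        raise ValidationError("need at least 2 paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    else:
        t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return ComparisonReport("paired_t", float(t), float(n - 1), float(p),
                            mean_a=float(d.mean()), sd_a=float(sd), n_a=n)


def ols_trend(series: InstrumentalSeries) -> ComparisonReport:
    """OLS warming trend of an annual series; statistic = t on the slope.

    The report's ``mean_a`` carries the slope (°C/yr) and ``mean_b`` the
    total change, slope × (span − 1) °C, over the record.
    """
    n = len(series.values)
    if n < 3:
        raise ValidationError("trend needs at least 3 years")
    res = stats.linregress(series.years, series.values)
    t = np.inf if res.stderr == 0 else res.slope / res.stderr
    p = 0.0 if not np.isfinite(t) else 2.0 * stats.t.sf(abs(t), n - 2)
    return ComparisonReport("ols_trend", float(t), float(n - 2), float(p),
                            mean_a=float(res.slope),
                            mean_b=float(res.slope * (n - 1)),
                            n_a=n)


def moving_average(values, window: int = 5) -> np.ndarray:
    """Centered moving average; ends truncated to the available points."""
    if window < 1 or window % 2 == 0:
        raise ValidationError("window must be a positive odd integer")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def period_mean(rec: ReconstructionSeries, start: float, end: float) -> float:
    """Mean of samples whose interval midpoint lies in [start, end]."""
    mask = (rec.midpoints >= start) & (rec.midpoints <= end)
    if not mask.any():
        raise ValidationError(f"no samples with midpoints in [{start}, {end}]")
    return float(rec.values[mask].mean())


def variance_captured(rec_aligned, instr_aligned) -> float:
    """Percent of aligned instrumental variance retained by the reconstruction.

    100 × var(reconstruction) / var(instrumental) over the paired samples; a
    direct signal-retention ratio (low values mean attenuation).
    """
    rec_aligned = np.asarray(rec_aligned, dtype=float)
    instr_aligned = np.asarray(instr_aligned, dtype=float)
    vi = instr_aligned.var(ddof=1)
    if vi == 0:
        raise ValidationError("instrumental values have zero variance")
    return float(100.0 * rec_aligned.var(ddof=1) / vi)


def extend_series_by_regression(
    target_partial: InstrumentalSeries,
    reference_full: InstrumentalSeries,
) -> tuple[InstrumentalSeries, float]:
    """Splice a short station record onto a longer correlated neighbour.

    OLS of the target on the reference over their overlap years; reference
    years missing from the target are filled with fitted values, observed
    target years are kept verbatim. Returns the extended series and the
    regression's adjusted r².
    """
    overlap_start = max(target_partial.start_year, reference_full.start_year)
    overlap_end = min(target_partial.end_year, reference_full.end_year)
    n_overlap = overlap_end - overlap_start + 1
    if n_overlap < 10:
        raise ValidationError(f"only {max(n_overlap, 0)} overlap years; need >= 10")
    yt = target_partial.window(overlap_start, overlap_end)
    xr = reference_full.window(overlap_start, overlap_end)
    fit = sm.OLS(yt, sm.add_constant(xr)).fit()
    r2_adj = float(fit.rsquared_adj)

    start = min(target_partial.start_year, reference_full.start_year)
    end = max(target_partial.end_year, reference_full.end_year)
    years = np.arange(start, end + 1)
    values = np.full(years.shape, np.nan)
    ref_mask = (years >= reference_full.start_year) & (years <= reference_full.end_year)
    values[ref_mask] = fit.params[0] + fit.params[1] * reference_full.values
    tgt_mask = (years >= target_partial.start_year) & (years <= target_partial.end_year)
    values[tgt_mask] = target_partial.values
    if np.any(~np.isfinite(values)):
        raise ValidationError("extension leaves gaps: series ranges are disjoint")
    extended = InstrumentalSeries(target_partial.variable, start, values)
    return extended, r2_adj
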