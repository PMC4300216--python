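"""Synthetic pollen-climate data with known ground truth.

Emulates the structure of a Minnesota-style calibration study: ~133 sites
along a climate gradient, taxa with unimodal (Gaussian) responses to two
monthly mean temperatures, a disturbance-perturbed "modern" twin of the
calibration set paired to warmer climate normals, and a varve-dated
down-core record spanning AD 1116-2002 with Medieval-warm / Little-Ice-Age
-cool / post-1850-warming structure.

Every generator is reproducible bit-for-bit from (parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CalibrationSet,
    ClimateTable,
    FossilRecord,
    PollenMatrix,
    ValidationError,
    to_percentages,
)

logger = logging.getLogger(__name__)

GROUPS = ("ruderal", "arboreal", "herb")

#: February / May mean-temperature gradients (°C) spanned by the site network
DEFAULT_GRADIENTS: dict[str, tuple[float, float]] = {
    "feb_mean_temp": (-16.0, -6.0),
    "may_mean_temp": (8.0, 18.0),
}

#: grains counted per sample; typical pollen-sum practice
DEFAULT_TOTAL_GRAINS = 300

#: monthly normals warming injected into the "modern" twin (°C):
#: late-20th-century minus mid-19th-century February and May means
DEFAULT_CLIMATE_OFFSET: dict[str, float] = {
    "feb_mean_temp": 2.07,
    "may_mean_temp": 1.57,
}

#: land-clearance abundance multipliers by ecological group
DEFAULT_FACTORS: dict[str, float] = {"ruderal": 3.0, "arboreal": 0.6, "herb": 0.8}


@dataclass
class SpeciesResponseModel:
    """Unimodal taxon responses to a set of climate variables.

    Each taxon k has, per variable v, a Gaussian response with optimum
    ``optima[k, v]`` (°C), tolerance ``tolerances[k, v]`` (°C, > 0) and a
    shared height ``heights[k]`` (> 0); responses multiply across variables.
    Taxa carry an ecological group flag used by disturbance scenarios.
    """

    taxa: list[str]
    variables: list[str]
    optima: np.ndarray       # (n_taxa, n_vars)
    tolerances: np.ndarray   # (n_taxa, n_vars)
    heights: np.ndarray      # (n_taxa,)
    groups: list[str]
    gradient_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.optima = np.asarray(self.optima, dtype=float)
        self.tolerances = np.asarray(self.tolerances, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if np.any(self.tolerances <= 0):
            raise ValidationError("tolerances must be > 0")
        if np.any(self.heights <= 0):
            raise ValidationError("heights must be > 0")
        for g in GROUPS:
            if g not in self.groups:
                raise ValidationError(f"at least one taxon per group required; missing {g!r}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


@dataclass
class ClimateHistory:
    """Annual February/May mean temperatures over a year range.

    Built from a segmented history: a Medieval-warm baseline, a Little Ice
    Age step change, and a post-1850 linear warming ramp, plus white
    interannual noise.
    """

    years: np.ndarray
    data: pd.DataFrame  # columns feb_mean_temp, may_mean_temp, indexed like years
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if len(self.years) != len(self.data):
            raise ValidationError("one row per year required")
        if not np.all(np.diff(self.years) == 1):
            raise ValidationError("history must cover every year in range")

    @property
    def start(self) -> int:
        return int(self.years[0])

    @property
    def end(self) -> int:
        return int(self.years[-1])

    def mean_over(self, start: int, end: int) -> pd.Series:
        mask = (self.years >= start) & (self.years <= end)
        if not mask.any():
            raise ValidationError(f"no history years in [{start}, {end}]")
        return self.data.loc[mask].mean()


def default_history(
    seed: int = 0,
    start: int = 1116,
    end: int = 2002,
    baseline: dict[str, float] | None = None,
    lia_delta: float = -1.0,
    lia_start: int = 1450,
    lia_end: int = 1850,
    ramp_total: float = 2.0,
    noise_sd: float = 1.0,
) -> ClimateHistory:
    """Segmented last-millennium climate: MCA level, LIA step, modern ramp.

    The Medieval baseline sits at the calibration gradient centre; the LIA
    (1450-1850) is ``lia_delta`` cooler; 1850 onward warms linearly by
    ``ramp_total`` °C over the remaining span. White noise with sd
    ``noise_sd`` °C is added independently per year and variable.
    """
    if baseline is None:
        baseline = {v: (lo + hi) / 2.0 for v, (lo, hi) in DEFAULT_GRADIENTS.items()}
    years = np.arange(start, end + 1)
    rng = np.random.default_rng(seed)
    cols = {}
    ramp_span = max(end - 1850, 1)
    for v, base in baseline.items():
        level = np.full(years.shape, base, dtype=float)
        lia = (years >= lia_start) & (years <= lia_end)
        level[lia] += lia_delta
        post = years > 1850
        level[post] = base + lia_delta + ramp_total * (years[post] - 1850) / ramp_span
        cols[v] = level + rng.normal(0.0, noise_sd, size=years.shape)
    params = dict(seed=seed, start=start, end=end, baseline=baseline,
                  lia_delta=lia_delta, lia_start=lia_start, lia_end=lia_end,
                  ramp_total=ramp_total, noise_sd=noise_sd)
    return ClimateHistory(years, pd.DataFrame(cols), params)


@dataclass
class DisturbanceScenario:
    """Land-clearance perturbation of a calibration set.

    ``factors`` multiply expected abundances by ecological group (ruderal
    taxa expand, arboreal and native-herb taxa retreat); ``climate_offset``
    shifts the climate normals paired with the pollen (°C), emulating the
    warmer late-20th-century normals of a conventional core-top set.
    """

    factors: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FACTORS))
    climate_offset: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLIMATE_OFFSET))

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.factors.values()):
            raise ValidationError("disturbance factors must be > 0")

    @classmethod
    def identity(cls) -> "DisturbanceScenario":
        return cls(factors={g: 1.0 for g in GROUPS},
                   climate_offset={})


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_species_pool(
    n_taxa: int,
    gradient_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    tolerance_range: tuple[float, float] = (1.0, 4.0),
    height_range: tuple[float, float] = (0.5, 2.0),
) -> SpeciesResponseModel:
    """Draw a random taxon pool with unimodal responses along each gradient.

    Optima are uniform on each gradient, tolerances uniform on
    ``tolerance_range`` (°C), heights log-uniform on ``height_range``, and
    group labels assigned round-robin so groups are climate-neutral in
    expectation.
    """
    if n_taxa < 3:
        raise ValidationError("a transfer function needs at least 3 taxa")
    if gradient_ranges is None:
        gradient_ranges = dict(DEFAULT_GRADIENTS)
    rng = np.random.default_rng(seed)
    variables = list(gradient_ranges)
    optima = np.column_stack([
        rng.uniform(lo, hi, size=n_taxa) for lo, hi in gradient_ranges.values()
    ])
    tolerances = rng.uniform(*tolerance_range, size=(n_taxa, len(variables)))
    heights = np.exp(rng.uniform(np.log(height_range[0]), np.log(height_range[1]),
                                 size=n_taxa))
    groups = [GROUPS[k % len(GROUPS)] for k in range(n_taxa)]
    taxa = [f"taxon_{k:03d}" for k in range(n_taxa)]
    return SpeciesResponseModel(taxa, variables, optima, tolerances, heights,
                                groups, gradient_ranges)


def expected_assemblage(model: SpeciesResponseModel, climate: dict[str, float]) -> np.ndarray:
    """Expected pollen proportions at a climate point.

    Raw abundance of taxon k is ``c_k * prod_v exp(-(x_v - u_kv)^2 / (2 t_kv^2))``,
    normalized to sum to 1.
    """
    x = np.array([float(climate[v]) for v in model.variables])
    for j, v in enumerate(model.variables):
        lo, hi = model.gradient_ranges.get(v, (-np.inf, np.inf))
        span = hi - lo
        if np.isfinite(span) and not (lo - 3 * span <= x[j] <= hi + 3 * span):
            raise ValidationError(f"{v}={x[j]} is outside ±3 gradient spans")
    z = (x[None, :] - model.optima) / model.tolerances
    raw = model.heights * np.exp(-0.5 * (z ** 2).sum(axis=1))
    total = raw.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValidationError("all taxon abundances underflowed to zero")
    return raw / total


def sample_counts(p: np.ndarray, total: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Multinomial pollen counts with ``total`` grains and cell probabilities p."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValidationError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValidationError("proportions must sum to 1")
    if total < 1:
        raise ValidationError("total grains must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multinomial(int(total), p / p.sum())


def sample_site_climates(
    n_sites: int,
    gradient_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    jitter_sd: float = 0.6,
) -> pd.DataFrame:
    """Per-site climates along a shared geographic gradient.

    A single latent position per site (latitude-like) maps onto each
    variable's gradient, plus independent jitter, so monthly temperatures
    are strongly but not perfectly correlated across sites — as they are
    across a real station network.
    """
    if gradient_ranges is None:
        gradient_ranges = dict(DEFAULT_GRADIENTS)
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, size=n_sites)
    cols = {
        v: lo + t * (hi - lo) + rng.normal(0.0, jitter_sd, size=n_sites)
        for v, (lo, hi) in gradient_ranges.items()
    }
    return pd.DataFrame(cols)


def generate_calibration(
    model: SpeciesResponseModel,
    n_sites: int = 133,
    climate_field: pd.DataFrame | None = None,
    total: int = DEFAULT_TOTAL_GRAINS,
    seed: int = 0,
    label: str = "1870-synthetic",
) -> CalibrationSet:
    """Generate a sites × taxa calibration set along the climate gradient.

    Per site: expected assemblage at the site's climate, multinomial grain
    counts, percentages. The attached climate table is the generating truth.
    """
    if n_sites < 10:
        raise ValidationError("need at least 10 sites for downstream fitting")
    rng = np.random.default_rng(seed)
    if climate_field is None:
        climate_field = sample_site_climates(
            n_sites, model.gradient_ranges, seed=rng.integers(2**31))
    climate_field = climate_field.reset_index(drop=True)
    if len(climate_field) != n_sites:
        raise ValidationError("climate_field rows must equal n_sites")
    props = np.stack([
        expected_assemblage(model, climate_field.iloc[i].to_dict())
        for i in range(n_sites)
    ])
    counts = np.stack([sample_counts(props[i], total, rng) for i in range(n_sites)])
    ids = [f"site_{i:03d}" for i in range(n_sites)]
    pollen = to_percentages(PollenMatrix(ids, list(model.taxa), counts, "counts"))
    climate = ClimateTable(ids, climate_field[model.variables].copy())
    return CalibrationSet(pollen, climate, label=label,
                          expected_proportions=props,
                          taxon_groups=list(model.groups),
                          total_grains=int(total))


def apply_disturbance(
    cal: CalibrationSet,
    scen: DisturbanceScenario,
    seed: int = 0,
) -> CalibrationSet:
    """Produce the disturbed "modern" twin of a synthetic calibration set.

    Each site's expected abundances are multiplied by its taxon-group factor
    and renormalized, grain counts are resampled, and the climate table is
    shifted by the scenario's normals offset.
    """
    if cal.expected_proportions is None or cal.taxon_groups is None:
        raise ValidationError(
            "apply_disturbance needs a synthetic calibration set carrying "
            "expected proportions and taxon groups")
    factors = np.array([scen.factors.get(g, 1.0) for g in cal.taxon_groups])
    if np.any(factors <= 0):
        raise ValidationError("disturbance factors must be > 0")
    props = cal.expected_proportions * factors[None, :]
    props = props / props.sum(axis=1, keepdims=True)
    total = cal.total_grains or DEFAULT_TOTAL_GRAINS
    rng = np.random.default_rng(seed)
    counts = np.stack([sample_counts(props[i], total, rng)
                       for i in range(cal.n_sites)])
    pollen = to_percentages(
        PollenMatrix(list(cal.pollen.ids), list(cal.pollen.taxa), counts, "counts"))
    data = cal.climate.data.copy()
    for v, off in scen.climate_offset.items():
        if v in data.columns:
            data[v] = data[v] + off
    climate = ClimateTable(list(cal.climate.site_ids), data)
    return CalibrationSet(pollen, climate, label="modern-synthetic",
                          expected_proportions=props,
                          taxon_groups=list(cal.taxon_groups),
                          total_grains=total)


def generate_downcore(
    model: SpeciesResponseModel,
    history: ClimateHistory,
    interval_years: int = 4,
    total: int = DEFAULT_TOTAL_GRAINS,
    seed: int = 0,
) -> tuple[FossilRecord, pd.DataFrame]:
    """Down-core record sampled at contiguous ``interval_years`` intervals.

    Each sample's assemblage is generated from the mean climate over its
    interval; the returned truth table holds those interval means aligned
    with the samples, for parameter-recovery tests.
    """
    if interval_years < 1:
        raise ValidationError("interval_years must be >= 1")
    rng = np.random.default_rng(seed)
    intervals: list[tuple[int, int]] = []
    year = history.start
    while year <= history.end:
        end = min(year + interval_years - 1, history.end)
        intervals.append((year, end))
        year = end + 1
    if intervals and intervals[-1][1] - intervals[-1][0] + 1 < interval_years:
        logger.info("final interval %s shorter than %d years",
                    intervals[-1], interval_years)
    rows, truth = [], []
    for start, end in intervals:
        mean = history.mean_over(start, end)
        props = expected_assemblage(model, mean.to_dict())
        rows.append(sample_counts(props, total, rng))
        truth.append({"start_year": start, "end_year": end, **mean.to_dict()})
    ids = [f"sample_{i:03d}" for i in range(len(intervals))]
    counts = PollenMatrix(ids, list(model.taxa), np.stack(rows), "counts")
    record = FossilRecord(to_percentages(counts), intervals)
    return record, pd.DataFrame(truth)
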