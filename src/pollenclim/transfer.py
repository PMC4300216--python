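"""Weighted-averaging partial least squares (WA-PLS) transfer functions.

WA-PLS relates a sites × taxa matrix of pollen percentages to a single
climate variable. Component 1 is classical weighted averaging: taxon scores
are abundance-weighted means of the climate variable, site scores are
abundance-weighted means of the taxon scores, and a final regression
("deshrinking") maps scores back to climate units. Higher components repeat
the extraction on the regression residuals, capturing structure that plain
weighted averaging misses; two components (WA-PLS2) is the conventional
choice for pollen.

The estimator follows scikit-learn conventions (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) and composes with
sklearn model selection. Cross-validation helpers implement leave-one-out
and the bootstrap RMSEP decomposition (s1: within-site spread of
out-of-bag predictions; s2: systematic out-of-bag error).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .io_formats import CalibrationSet, PollenMatrix, ValidationError, _normalize_name

logger = logging.getLogger(__name__)


class DegenerateComponentError(ValueError):
    """A component's site scores have (weighted) spread below tolerance."""


class WAPLS(BaseEstimator, RegressorMixin):
    """WA-PLS regression of a climate variable on pollen percentages.

    Parameters
    ----------
    n_components : int, default 2
        Number of WA-PLS components (WA-PLS2 by convention).
    sqrt_transform : bool, default False
        Square-root transform pollen values before fitting/prediction
        (down-weights dominant taxa).

    Attributes
    ----------
    taxon_scores_ : ndarray of shape (n_components, n_kept_taxa)
        Per-component taxon scores (component 1's are the WA optima).
    ortho_coefs_ : list of ndarray
        Per component, projection coefficients on earlier standardized
        components (Gram-Schmidt under site weights).
    score_means_, score_sds_ : ndarray of shape (n_components,)
        Weighted standardization transforms of the site scores.
    coef_ : ndarray of shape (n_components + 1,)
        Final weighted-least-squares coefficients (intercept first); the
        deshrinking regression.
    fitted_ : ndarray of shape (n_sites,)
        Apparent (training-set) predictions.
    rmse_app_ : float
        Apparent root-mean-square error (°C).
    keep_idx_ : ndarray
        Indices of training taxa with nonzero column sums (others dropped).
    """

    #: weighted site-score sd below which a component carries no gradient
    _SD_TOL = 1e-12

    def __init__(self, n_components: int = 2, sqrt_transform: bool = False):
        self.n_components = n_components
        self.sqrt_transform = sqrt_transform

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (sites × taxa)")
        n, k = X.shape
        if len(y) != n:
            raise ValidationError("X and y lengths differ")
        if np.any(X < 0):
            raise ValidationError("pollen values must be non-negative")
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")
        if n < self.n_components + 2:
            raise ValidationError(
                f"need at least n_components + 2 = {self.n_components + 2} sites")
        if np.ptp(y) == 0:
            raise ValidationError("climate variable is constant")
        if self.sqrt_transform:
            X = np.sqrt(X)

        col_sums = X.sum(axis=0)
        keep = col_sums > 0
        if np.any(~keep):
            logger.warning("dropping %d taxa with zero column sums", int((~keep).sum()))
        if keep.sum() < 3:
            raise ValidationError("need at least 3 taxa with nonzero column sums")
        self.keep_idx_ = np.flatnonzero(keep)
        Y = X[:, keep]
        yk = Y.sum(axis=0)
        yi = Y.sum(axis=1)
        if np.any(yi <= 0):
            raise ValidationError("a site has zero pollen sum")
        w = yi / yi.sum()

        taxon_scores, ortho_coefs, means, sds, comps = [], [], [], [], []
        r = y.copy()
        beta = None
        for a in range(self.n_components):
            u = (Y * r[:, None]).sum(axis=0) / yk
            s = (Y @ u) / yi
            coefs = np.empty(a)
            for b in range(a):
                coefs[b] = np.sum(w * s * comps[b])
                s = s - coefs[b] * comps[b]
            mu = float(np.sum(w * s))
            sd = float(np.sqrt(np.sum(w * (s - mu) ** 2)))
            if sd < self._SD_TOL:
                raise DegenerateComponentError(
                    f"component {a + 1} is degenerate (site-score sd {sd:.3g})")
            s = (s - mu) / sd
            taxon_scores.append(u)
            ortho_coefs.append(coefs)
            means.append(mu)
            sds.append(sd)
            comps.append(s)
            # deshrinking: weighted least squares of y on components 1..a+1
            design = np.column_stack([np.ones(n)] + comps)
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
            r = y - design @ beta

        self.taxon_scores_ = np.stack(taxon_scores)
        self.ortho_coefs_ = ortho_coefs
        self.score_means_ = np.array(means)
        self.score_sds_ = np.array(sds)
        self.coef_ = beta
        self.site_weights_ = w
        self.n_features_in_ = k
        self.fitted_ = design @ beta
        self.residuals_ = self.fitted_ - y
        self.rmse_app_ = float(np.sqrt(np.mean(self.residuals_ ** 2)))
        return self

    # -- scoring ------------------------------------------------------------

    def _scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} taxa columns, got {X.shape}")
        if self.sqrt_transform:
            X = np.sqrt(X)
        Y = X[:, self.keep_idx_]
        yi = Y.sum(axis=1)
        if np.any(yi <= 0):
            raise ValidationError("a sample has zero pollen sum over the training taxa")
        comps = []
        for a in range(self.n_components):
            s = (Y @ self.taxon_scores_[a]) / yi
            for b, c in enumerate(self.ortho_coefs_[a]):
                s = s - c * comps[b]
            s = (s - self.score_means_[a]) / self.score_sds_[a]
            comps.append(s)
        return np.column_stack(comps)

    def predict(self, X) -> np.ndarray:
        scores = self._scores(X)
        return self.coef_[0] + scores @ self.coef_[1:]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "sqrt_transform": self.sqrt_transform,
            "taxon_names": list(getattr(self, "taxon_names_", [])),
            "variable": getattr(self, "variable_", None),
            "keep_idx": self.keep_idx_.tolist(),
            "n_features_in": int(self.n_features_in_),
            "taxon_scores": self.taxon_scores_.tolist(),
            "ortho_coefs": [c.tolist() for c in self.ortho_coefs_],
            "score_means": self.score_means_.tolist(),
            "score_sds": self.score_sds_.tolist(),
            "coef": self.coef_.tolist(),
            "rmse_app": self.rmse_app_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WAPLS":
        tf = cls(n_components=d["n_components"], sqrt_transform=d["sqrt_transform"])
        tf.keep_idx_ = np.asarray(d["keep_idx"], dtype=int)
        tf.n_features_in_ = d["n_features_in"]
        tf.taxon_scores_ = np.asarray(d["taxon_scores"], dtype=float)
        tf.ortho_coefs_ = [np.asarray(c, dtype=float) for c in d["ortho_coefs"]]
        tf.score_means_ = np.asarray(d["score_means"], dtype=float)
        tf.score_sds_ = np.asarray(d["score_sds"], dtype=float)
        tf.coef_ = np.asarray(d["coef"], dtype=float)
        tf.rmse_app_ = d["rmse_app"]
        if d.get("taxon_names"):
            tf.taxon_names_ = list(d["taxon_names"])
        if d.get("variable"):
            tf.variable_ = d["variable"]
        return tf

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "WAPLS":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


#: a fitted WAPLS is the pipeline's transfer-function object
TransferFunction = WAPLS


@dataclass
class CVResult:
    """Cross-validation summary for one calibration set and variable."""

    predicted: np.ndarray
    observed: np.ndarray
    rmse_app: float
    rmsep_loo: float | None = None
    rmsep_boot: float | None = None
    s1: float | None = None
    s2: float | None = None
    n_boot: int | None = None
    seed: int | None = None

    @property
    def residuals(self) -> np.ndarray:
        return self.predicted - self.observed

    @property
    def mean_bias(self) -> float:
        return float(np.mean(self.residuals))


# ---------------------------------------------------------------------------
# Module-level operations over CalibrationSets
# ---------------------------------------------------------------------------

def fit_wapls(cal: CalibrationSet, variable: str, n_components: int = 2,
              sqrt_transform: bool = False) -> WAPLS:
    """Fit a WA-PLS transfer function to a calibration set."""
    tf = WAPLS(n_components=n_components, sqrt_transform=sqrt_transform)
    tf.fit(cal.pollen.values, cal.climate.values_for(variable))
    tf.taxon_names_ = list(cal.pollen.taxa)
    tf.variable_ = variable
    return tf


def predict(tf: WAPLS, pollen: PollenMatrix) -> np.ndarray:
    """Apply a transfer function to a (harmonized) pollen matrix.

    The matrix's taxa must match the training taxa as a set (after trimming
    and case-folding); columns are reordered if needed. Taxa present in the
    samples but unknown to the model must be zero-filled in first (see
    :func:`pollenclim.io_formats.harmonize_taxa`).
    """
    training = getattr(tf, "taxon_names_", None)
    if training is None:
        return tf.predict(pollen.values)
    norm_have = {_normalize_name(t): j for j, t in enumerate(pollen.taxa)}
    try:
        order = [norm_have[_normalize_name(t)] for t in training]
    except KeyError as exc:
        raise ValidationError(
            f"pollen matrix lacks training taxon {exc.args[0]!r}; "
            "harmonize taxa first") from None
    extra = set(norm_have) - {_normalize_name(t) for t in training}
    if extra:
        dropped = pollen.values[:, [norm_have[t] for t in extra]].sum()
        if dropped > 0:
            logger.warning("ignoring %d non-training taxa carrying %.3g%% pollen",
                           len(extra), dropped / pollen.n_samples)
    return tf.predict(pollen.values[:, order])


def loo_cross_validate(cal: CalibrationSet, variable: str,
                       n_components: int = 2, sqrt_transform: bool = False) -> CVResult:
    """Leave-one-out cross-validation: refit without each site, predict it."""
    X = cal.pollen.values
    y = cal.climate.values_for(variable)
    n = len(y)
    full = WAPLS(n_components, sqrt_transform).fit(X, y)
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        m = idx != i
        tf = WAPLS(n_components, sqrt_transform).fit(X[m], y[m])
        preds[i] = tf.predict(X[i:i + 1])[0]
    return CVResult(predicted=preds, observed=y,
                    rmse_app=full.rmse_app_,
                    rmsep_loo=float(np.sqrt(np.mean((preds - y) ** 2))))


def bootstrap_rmsep(cal: CalibrationSet, variable: str, n_components: int = 2,
                    n_boot: int = 1000, seed: int = 0,
                    sqrt_transform: bool = False) -> CVResult:
    """Bootstrap RMSEP with the s1/s2 decomposition.

    Each cycle resamples sites with replacement as the training set and
    predicts the out-of-bag sites. s2 is the rms over sites of the mean
    out-of-bag error (systematic component); s1 the rms of the per-site sd
    of out-of-bag predictions (sampling component); RMSEP_boot =
    sqrt(s1² + s2²).
    """
    X = cal.pollen.values
    y = cal.climate.values_for(variable)
    n = len(y)
    full = WAPLS(n_components, sqrt_transform).fit(X, y)
    rng = np.random.default_rng(seed)
    preds = np.full((n_boot, n), np.nan)
    for b in range(n_boot):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        tf = WAPLS(n_components, sqrt_transform).fit(X[boot], y[boot])
        preds[b, oob] = tf.predict(X[oob])
    counts = np.sum(~np.isnan(preds), axis=0)
    if np.any(counts < 2):
        bad = int(np.argmin(counts))
        raise ValidationError(
            f"site index {bad} appeared out-of-bag only {counts[bad]} time(s) "
            f"after {n_boot} cycles; increase n_boot")
    with np.errstate(invalid="ignore"):
        mean_pred = np.nanmean(preds, axis=0)
        sd_pred = np.nanstd(preds, axis=0, ddof=1)
    s2 = float(np.sqrt(np.mean((mean_pred - y) ** 2)))
    s1 = float(np.sqrt(np.mean(sd_pred ** 2)))
    return CVResult(predicted=mean_pred, observed=y,
                    rmse_app=full.rmse_app_,
                    rmsep_boot=float(np.hypot(s1, s2)),
                    s1=s1, s2=s2, n_boot=n_boot, seed=seed)
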