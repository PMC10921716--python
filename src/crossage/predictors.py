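"""Cross-sectional age-predictor families and aging-divergence extraction.

Every predictor produces a per-subject raw age proxy; the aging-divergence
prediction (``delta_hat``) is always the residual of that proxy regressed on
chronological age, which makes it mean-zero and uncorrelated with age by
construction (OLS orthogonality).

Families
--------
``mlr``     ordinary least squares of age on markers
``ridge``   cross-validated ridge regression (markers z-scored, intercept
            unpenalized)
``pc1``     first principal component of the pre-selected, z-scored markers,
            rescaled to the age scale
``equal``   sign-preserving equal weights derived from an MLR fit
``random``  sign-preserving uniform random weights
``kd``      precision-weighted combination of reversed regressions
            (marker-on-age), i.e. the Klemera-Doubal-style estimate
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge

from .synthgen import CohortData

__all__ = [
    "LinearAgeModel",
    "KDFit",
    "DeltaPrediction",
    "bonferroni_threshold",
    "preselect_markers",
    "fit_mlr",
    "fit_ridge_cv",
    "fit_kd",
    "predict_kd",
    "fit_pc1",
    "make_equal_weights",
    "sample_random_weights",
    "predict_delta",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = np.logspace(-3, 4, 50)

#: reversed-regression slopes below this (relative) size are dropped
KD_SLOPE_TOL = 1e-8


@dataclass
class LinearAgeModel:
    """A linear age proxy: ``proxy = intercept + markers @ weights``."""

    method: str
    markers: list[str]
    intercept: float
    weights: np.ndarray
    ridge_lambda: float | None = None
    pc_rescale: tuple[float, float] | None = None  # (mean_C, sd_C)
    draw_index: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != len(self.markers):
            raise ValueError("weight vector and marker subset disagree")
        if self.ridge_lambda is not None and self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")

    def predict(self, data: CohortData) -> np.ndarray:
        return self.intercept + data.marker_matrix(self.markers) @ self.weights

    def to_json(self) -> str:
        payload = {
            "method": self.method,
            "markers": self.markers,
            "intercept": self.intercept,
            "weights": self.weights.tolist(),
            "ridge_lambda": self.ridge_lambda,
            "pc_rescale": list(self.pc_rescale) if self.pc_rescale else None,
            "draw_index": self.draw_index,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "LinearAgeModel":
        payload = json.loads(text)
        rescale = payload.pop("pc_rescale")
        return cls(
            pc_rescale=tuple(rescale) if rescale else None,
            **payload,
        )


@dataclass
class KDFit:
    """Per-marker reversed regressions: ``x_j = q_j + k_j * age + noise``."""

    markers: list[str]
    q: np.ndarray
    k: np.ndarray
    s: np.ndarray  # residual sd, denominator n - 2

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if not (len(self.markers) == self.q.size == self.k.size == self.s.size):
            raise ValueError("inconsistent KD fit arrays")
        if np.any(self.s <= 0):
            raise ValueError("residual sd must be > 0 for every retained marker")


@dataclass
class DeltaPrediction:
    """Raw age proxy plus its residual-on-age aging-divergence prediction."""

    method: str
    proxy: np.ndarray
    delta_hat: np.ndarray
    degenerate: bool = False
    draw_index: int | None = None


# ---------------------------------------------------------------------------
# marker pre-selection
# ---------------------------------------------------------------------------


def bonferroni_threshold(alpha_fw: float, m: int) -> float:
    """Per-marker two-sided p-value threshold at family-wise level alpha_fw."""
    return alpha_fw / m


def preselect_markers(data: CohortData, alpha_fw: float = 0.05) -> list[str]:
    """Markers univariately correlated with age at the Bonferroni level.

    Pearson correlation with a two-sided t-test on n - 2 degrees of freedom;
    a marker is kept when p < alpha_fw / m.  Constant marker columns are
    skipped with a warning.
    """
    if data.n < 4:
        raise ValueError("need at least 4 subjects for pre-selection")
    threshold = bonferroni_threshold(alpha_fw, data.n_markers)
    selected = []
    for name in data.marker_names:
        x = data.markers[name].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"marker {name!r} is constant; skipped", stacklevel=2)
            continue
        r, p = stats.pearsonr(x, data.age)
        if p < threshold:
            selected.append(name)
    return selected


# ---------------------------------------------------------------------------
# linear fitters
# ---------------------------------------------------------------------------


def _design(data: CohortData, subset: list[str]) -> np.ndarray:
    x = data.marker_matrix(subset)
    return np.column_stack([np.ones(data.n), x])


def fit_mlr(data: CohortData, subset: list[str] | None = None) -> LinearAgeModel:
    """Ordinary least squares of chronological age on the marker subset."""
    subset = list(subset) if subset is not None else data.marker_names
    if data.n <= len(subset) + 1:
        raise ValueError("need n > number of markers + 1 for OLS")
    design = _design(data, subset)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the offending columns via QR pivoting
        from scipy.linalg import qr as scipy_qr

        _, _, piv = scipy_qr(design, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        names = ["intercept"] + subset
        raise ValueError(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(names[j] for j in bad)
        )
    coef, *_ = np.linalg.lstsq(design, data.age, rcond=None)
    return LinearAgeModel(
        method="mlr", markers=subset, intercept=float(coef[0]), weights=coef[1:]
    )


def _cv_folds(n: int, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return [np.sort(a) for a in np.array_split(rng.permutation(n), folds)]


def fit_ridge_cv(
    data: CohortData,
    subset: list[str] | None = None,
    folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
) -> LinearAgeModel:
    """Ridge regression of age on z-scored markers, penalty chosen by CV.

    The grid value minimizing the mean cross-validated squared error is
    selected (smallest such value on ties); the final model is refit on all
    data at that penalty and its weights are mapped back to the original
    marker scale.  The intercept is never penalized.
    """
    subset = list(subset) if subset is not None else data.marker_names
    if folds < 2:
        raise ValueError("folds must be >= 2")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(
        lambda_grid, dtype=float
    )
    if grid.size == 0:
        raise ValueError("lambda_grid must be non-empty")
    grid = np.sort(grid)

    x = data.marker_matrix(subset)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [subset[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant markers cannot be z-scored: {bad}")
    z = (x - mean) / sd
    y = data.age

    fold_idx = _cv_folds(data.n, folds, seed)
    cv_error = np.zeros(grid.size)
    for test in fold_idx:
        train = np.setdiff1d(np.arange(data.n), test)
        for g, lam in enumerate(grid):
            model = Ridge(alpha=lam, solver="svd")
            model.fit(z[train], y[train])
            resid = y[test] - model.predict(z[test])
            cv_error[g] += float(resid @ resid)
    cv_error /= data.n

    best = float(grid[int(np.argmin(cv_error))])  # argmin returns first=smallest
    final = Ridge(alpha=best, solver="svd")
    final.fit(z, y)
    w_std = np.asarray(final.coef_, dtype=float)
    weights = w_std / sd
    intercept = float(final.intercept_ - mean @ weights)
    return LinearAgeModel(
        method="ridge",
        markers=subset,
        intercept=intercept,
        weights=weights,
        ridge_lambda=best,
    )


def fit_kd(data: CohortData, subset: list[str] | None = None) -> KDFit:
    """Reversed regression of each marker on age.

    Markers whose slope is negligible relative to the marker/age spread, or
    whose residual sd is zero, are dropped with a warning — their
    precision weight ``k^2 / s^2`` would be degenerate.
    """
    subset = list(subset) if subset is not None else data.marker_names
    if data.n < 4:
        raise ValueError("need at least 4 subjects for reversed regressions")
    c = data.age
    sd_c = c.std(ddof=1)
    kept, qs, ks, ss = [], [], [], []
    for name in subset:
        x = data.markers[name].to_numpy(dtype=float)
        k = float(np.cov(x, c, ddof=1)[0, 1] / c.var(ddof=1))
        q = float(x.mean() - k * c.mean())
        resid = x - q - k * c
        s = float(np.sqrt(resid @ resid / (data.n - 2)))
        if abs(k) < KD_SLOPE_TOL * x.std(ddof=1) / sd_c:
            warnings.warn(
                f"marker {name!r}: reversed-regression slope ~ 0; dropped",
                stacklevel=2,
            )
            continue
        if s == 0:
            warnings.warn(
                f"marker {name!r}: zero residual sd (deterministic in age); dropped",
                stacklevel=2,
            )
            continue
        kept.append(name)
        qs.append(q)
        ks.append(k)
        ss.append(s)
    if not kept:
        raise ValueError("no usable markers for the KD fit")
    return KDFit(markers=kept, q=np.array(qs), k=np.array(ks), s=np.array(ss))


def predict_kd(fit: KDFit, data: CohortData) -> np.ndarray:
    """Precision-weighted age estimate from the reversed regressions.

    Minimizes ``sum_j ((x_j - q_j - k_j * BA) / s_j)^2`` per subject::

        BA = sum_j (x_j - q_j) k_j / s_j^2  /  sum_j k_j^2 / s_j^2
    """
    if not fit.markers:
        raise ValueError("empty marker set")
    x = data.marker_matrix(fit.markers)
    w = fit.k / fit.s**2
    return (x - fit.q) @ w / float(fit.k @ (fit.k / fit.s**2))


def fit_pc1(
    data: CohortData,
    alpha_fw: float = 0.05,
    subset: list[str] | None = None,
) -> LinearAgeModel:
    """First-principal-component age score rescaled to the age scale.

    Markers are pre-selected (unless a subset is given), z-scored, and
    projected on the first principal component; the standardized score is
    sign-oriented to correlate positively with age and mapped to years via
    ``proxy = score * sd_C + mean_C`` using the training sample moments.
    """
    selected = list(subset) if subset is not None else preselect_markers(data, alpha_fw)
    if len(selected) < 2:
        raise ValueError(
            f"PC1 needs at least 2 selected markers, got {len(selected)}"
        )
    x = data.marker_matrix(selected)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    z = (x - mean) / sd

    pca = PCA(n_components=1)
    score = pca.fit_transform(z)[:, 0]
    loadings = pca.components_[0]
    if np.corrcoef(score, data.age)[0, 1] < 0:
        score, loadings = -score, -loadings

    score_sd = score.std(ddof=1)
    mu_c = float(data.age.mean())
    sigma_c = float(data.age.std(ddof=1))
    # proxy = (z @ loadings) / score_sd * sigma_c + mu_c, as explicit weights
    weights = sigma_c * loadings / (score_sd * sd)
    intercept = mu_c - float(mean @ weights)
    return LinearAgeModel(
        method="pc1",
        markers=selected,
        intercept=intercept,
        weights=weights,
        pc_rescale=(mu_c, sigma_c),
    )


def make_equal_weights(mlr: LinearAgeModel) -> LinearAgeModel:
    """Sign-preserving equal weights: mean absolute MLR coefficient.

    Every weight becomes ``sign(w_j) * mean(|w|)``; the intercept is excluded
    from the mean and set to 0 (residualization on age makes it irrelevant).
    """
    if len(mlr.markers) < 1:
        raise ValueError("need at least one marker weight")
    magnitude = float(np.mean(np.abs(mlr.weights)))
    return LinearAgeModel(
        method="equal",
        markers=list(mlr.markers),
        intercept=0.0,
        weights=np.sign(mlr.weights) * magnitude,
    )


def sample_random_weights(
    signs: np.ndarray,
    markers: list[str],
    n_draws: int = 1000,
    seed: int = 0,
) -> list[LinearAgeModel]:
    """Sign-preserving standard-uniform random weight draws."""
    signs = np.asarray(signs, dtype=float)
    if signs.size == 0:
        raise ValueError("sign vector must be non-empty")
    if signs.size != len(markers):
        raise ValueError("sign vector and marker list disagree")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(size=(n_draws, signs.size))
    return [
        LinearAgeModel(
            method="random",
            markers=list(markers),
            intercept=0.0,
            weights=np.sign(signs) * draws[d],
            draw_index=d,
        )
        for d in range(n_draws)
    ]


# ---------------------------------------------------------------------------
# aging-divergence extraction
# ---------------------------------------------------------------------------


def _residualize_on_age(proxy: np.ndarray, age: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(age.shape[0]), age])
    coef, *_ = np.linalg.lstsq(design, proxy, rcond=None)
    return proxy - design @ coef


def predict_delta(
    model: "LinearAgeModel | KDFit | np.ndarray",
    data: CohortData,
) -> DeltaPrediction:
    """Extract the aging-divergence prediction from any age proxy.

    Accepts a fitted linear model, a KD fit, or a precomputed proxy array;
    ``delta_hat`` is the OLS residual of the proxy on age.
    """
    draw_index = None
    if isinstance(model, LinearAgeModel):
        proxy = model.predict(data)
        method = model.method
        draw_index = model.draw_index
    elif isinstance(model, KDFit):
        proxy = predict_kd(model, data)
        method = "kd"
    else:
        proxy = np.asarray(model, dtype=float)
        method = "proxy"
        if proxy.shape[0] != data.n:
            raise ValueError("proxy length does not match cohort size")

    degenerate = bool(np.std(proxy) == 0)
    if degenerate:
        warnings.warn(
            "constant age proxy: delta_hat is identically zero", stacklevel=2
        )
        delta_hat = np.zeros(data.n)
    else:
        delta_hat = _residualize_on_age(proxy, data.age)
    return DeltaPrediction(
        method=method,
        proxy=proxy,
        delta_hat=delta_hat,
        degenerate=degenerate,
        draw_index=draw_index,
    )
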