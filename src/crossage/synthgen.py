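"""Synthetic cohort generators.

Three families of synthetic inputs are produced here:

* :func:`gen_example1` — a single true marker ``X`` (loaded on the latent
  aging divergence) paired with an observationally identical false marker
  ``X_prime`` (loaded on an irrelevant latent instead).
* :func:`gen_example2` — four three-marker cohorts (scenarios A–D) that are
  indistinguishable from the observable ``(X, C)`` joint distribution but
  differ in how marker weights relate to the aging divergence.
* :func:`gen_lls_like` — a high-dimensional cohort with left-truncated
  survival outcomes on the age timescale, calibrated to the descriptive
  statistics of a middle-aged epidemiological study (n=2267, mean age 59.2,
  sd 6.7, 59 markers, ~309 deaths over ~16.3 years of follow-up).

All generators return :class:`CohortData` and are bit-reproducible for a
fixed seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SimParams1",
    "ScenarioTable",
    "MarkerArchitecture",
    "LLSLikeParams",
    "CohortData",
    "SCENARIOS",
    "gen_example1",
    "derive_scenario_noise",
    "gen_example2",
    "gen_lls_like",
    "expected_event_fraction",
    "calibrate_baseline_hazard",
]

SCENARIOS = ("A", "B", "C", "D")

#: column names with a reserved meaning in the CSV exchange format; every
#: other column is treated as a marker.
_RESERVED_COLUMNS = (
    "id",
    "age",
    "sex",
    "entry_age",
    "exit_age",
    "event",
    "delta",
    "bioage",
    "lambda",
)


class ParameterError(ValueError):
    """Raised when a simulation parameter set violates its invariants."""


def _as_variance(value: float, values_are_sd: bool) -> float:
    return float(value) ** 2 if values_are_sd else float(value)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimParams1:
    """Parameters of the additive true-marker / false-marker generator.

    The printed magnitudes of the dispersion parameters are ambiguous between
    variances and standard deviations; ``values_are_sd`` switches the
    interpretation (default: values are variances).
    """

    n: int = 1000
    mu: float = 50.0
    var_c: float = 10.0
    var_delta: float = 3.0
    var_lambda: float = 3.0
    var_eps: float = 2.0
    alpha: float = 1.0
    beta: float = 1.0
    seed: int = 0
    values_are_sd: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError(f"n must be >= 2, got {self.n}")
        for name in ("var_c", "var_delta", "var_lambda", "var_eps"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    def variances(self) -> dict[str, float]:
        """Dispersion parameters on the variance scale."""
        return {
            name: _as_variance(getattr(self, name), self.values_are_sd)
            for name in ("var_c", "var_delta", "var_lambda", "var_eps")
        }


@dataclass(frozen=True)
class ScenarioTable:
    """Coefficient grid defining the four three-marker scenarios.

    ``beta_c`` is shared across scenarios (this is what makes the four data
    sets observationally indistinguishable); ``beta_delta`` varies.  Noise
    variances are derived, not stored: see :func:`derive_scenario_noise`.
    """

    beta_c: tuple[float, ...] = (10.0, 3.0, 5.0)
    beta_delta: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "A": (10.0, 3.0, 5.0),
            "B": (-10.0, -3.0, -5.0),
            "C": (0.0, 10.0, -1.0),
            "D": (9.0, 5.0, 5.0),
        }
    )
    mu: float = 50.0
    var_c: float = 10.0
    var_delta: float = 5.0
    base_noise_var: float = 1000.0
    n: int = 1000
    seed: int = 0
    values_are_sd: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError(f"n must be >= 2, got {self.n}")
        if self.base_noise_var <= 0:
            raise ParameterError("base_noise_var must be > 0")
        m = len(self.beta_c)
        for s, betas in self.beta_delta.items():
            if len(betas) != m:
                raise ParameterError(
                    f"scenario {s!r}: {len(betas)} delta-slopes for {m} markers"
                )

    @property
    def n_markers(self) -> int:
        return len(self.beta_c)

    def variances(self) -> dict[str, float]:
        return {
            "var_c": _as_variance(self.var_c, self.values_are_sd),
            "var_delta": _as_variance(self.var_delta, self.values_are_sd),
        }


@dataclass(frozen=True)
class MarkerArchitecture:
    """Mixture law for per-marker coefficients in the high-dimensional cohort.

    Each marker is independently assigned one of four types:

    ``c_only``
        loaded on chronological age only (``beta_delta = 0``);
    ``c_delta``
        loaded on both, with the sign of the age slope shared;
    ``delta_only``
        loaded on the aging divergence only (``beta_c = 0``);
    ``null``
        pure noise.

    Slope magnitudes are uniform draws from the stated ranges, with a random
    sign per marker; marker noise is unit-variance Gaussian.
    """

    share_c_only: float = 0.35
    share_c_delta: float = 0.25
    share_delta_only: float = 0.15
    share_null: float = 0.25
    beta_c_range: tuple[float, float] = (0.05, 0.15)
    beta_delta_range: tuple[float, float] = (0.05, 0.15)

    def __post_init__(self) -> None:
        shares = self.shares()
        if any(s < 0 for s in shares.values()):
            raise ParameterError("mixture shares must be >= 0")
        if abs(sum(shares.values()) - 1.0) > 1e-9:
            raise ParameterError(
                f"mixture shares must sum to 1, got {sum(shares.values())}"
            )

    def shares(self) -> dict[str, float]:
        return {
            "c_only": self.share_c_only,
            "c_delta": self.share_c_delta,
            "delta_only": self.share_delta_only,
            "null": self.share_null,
        }


@dataclass(frozen=True)
class LLSLikeParams:
    """Parameters of the high-dimensional survival cohort emulator.

    Mortality follows a Gompertz baseline hazard ``a * exp(b * age)`` on the
    age timescale, multiplied by ``exp(gamma * delta + sex_loghr * sex)``.
    Subjects enter the risk set at their baseline age (left truncation) and
    are administratively censored ``admin_censor_years`` later.
    """

    n: int = 2267
    mean_age: float = 59.2
    sd_age: float = 6.7
    m: int = 59
    architecture: MarkerArchitecture = field(default_factory=MarkerArchitecture)
    var_delta: float = 25.0
    gompertz_a: float = 3e-5
    gompertz_b: float = 0.095
    gamma: float = 0.1
    sex_loghr: float = float(np.log(1.6))
    admin_censor_years: float = 16.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError(f"n must be >= 2, got {self.n}")
        if self.m < 1:
            raise ParameterError("m must be >= 1")
        if self.gompertz_a <= 0:
            raise ParameterError("gompertz_a must be > 0")
        if self.admin_censor_years <= 0:
            raise ParameterError("admin_censor_years must be > 0")
        if self.var_delta < 0:
            raise ParameterError("var_delta must be >= 0")


# ---------------------------------------------------------------------------
# the universal exchange object
# ---------------------------------------------------------------------------


@dataclass
class CohortData:
    """Per-subject table: chronological age, markers, optional truth/survival.

    ``markers`` keeps its column labels; everything else is a plain array.
    Where truth is present the row-wise identity ``bioage = age + delta``
    holds exactly; where survival is present ``exit_age > entry_age``.
    """

    age: np.ndarray
    markers: pd.DataFrame
    delta: np.ndarray | None = None
    bioage: np.ndarray | None = None
    lam: np.ndarray | None = None
    sex: np.ndarray | None = None
    entry_age: np.ndarray | None = None
    exit_age: np.ndarray | None = None
    event: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        n = self.age.shape[0]
        if self.markers.shape[0] != n:
            raise ValueError("marker table and age vector disagree on n")
        if self.markers.shape[1] < 1:
            raise ValueError("at least one marker column is required")
        for name in ("delta", "bioage", "lam", "sex", "entry_age", "exit_age", "event"):
            value = getattr(self, name)
            if value is not None:
                value = np.asarray(value, dtype=float)
                if value.shape[0] != n:
                    raise ValueError(f"column {name!r} has wrong length")
                if np.isnan(value).any():
                    raise ValueError(f"column {name!r} contains missing values")
                setattr(self, name, value)
        if np.isnan(self.age).any() or self.markers.isna().any().any():
            raise ValueError("missing values are not allowed")
        if self.delta is not None and self.bioage is not None:
            if not np.array_equal(self.bioage, self.age + self.delta):
                raise ValueError("truth columns violate bioage = age + delta")
        if self.entry_age is not None and self.exit_age is not None:
            if not np.all(self.exit_age > self.entry_age):
                raise ValueError("exit_age must exceed entry_age for every subject")

    @property
    def n(self) -> int:
        return self.age.shape[0]

    @property
    def n_markers(self) -> int:
        return self.markers.shape[1]

    @property
    def marker_names(self) -> list[str]:
        return list(self.markers.columns)

    def has_truth(self) -> bool:
        return self.delta is not None

    def has_survival(self) -> bool:
        return all(
            getattr(self, name) is not None
            for name in ("entry_age", "exit_age", "event")
        )

    def marker_matrix(self, subset: list[str] | None = None) -> np.ndarray:
        frame = self.markers if subset is None else self.markers[list(subset)]
        return frame.to_numpy(dtype=float)

    def with_markers(self, markers: pd.DataFrame) -> "CohortData":
        """Copy of this cohort with the marker table replaced."""
        return dataclasses.replace(self, markers=markers)

    # -- CSV exchange -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"id": np.arange(self.n), "age": self.age})
        for name in ("sex", "entry_age", "exit_age", "event"):
            value = getattr(self, name)
            if value is not None:
                out[name] = value
        for col in self.markers.columns:
            out[col] = self.markers[col].to_numpy()
        if self.delta is not None:
            out["delta"] = self.delta
        if self.bioage is not None:
            out["bioage"] = self.bioage
        if self.lam is not None:
            out["lambda"] = self.lam
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortData":
        marker_cols = [c for c in frame.columns if c not in _RESERVED_COLUMNS]

        def col(name):
            return frame[name].to_numpy(dtype=float) if name in frame else None

        return cls(
            age=frame["age"].to_numpy(dtype=float),
            markers=frame[marker_cols].astype(float).reset_index(drop=True),
            delta=col("delta"),
            bioage=col("bioage"),
            lam=col("lambda"),
            sex=col("sex"),
            entry_age=col("entry_age"),
            exit_age=col("exit_age"),
            event=col("event"),
        )

    @classmethod
    def read_csv(cls, path) -> "CohortData":
        # round_trip parsing keeps the exact truth identity across a CSV cycle
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_example1(params: SimParams1) -> CohortData:
    """Generate the true-marker / false-marker pair.

    Independent draws ``C ~ N(mu, var_c)``, ``delta ~ N(0, var_delta)``,
    ``lambda ~ N(0, var_lambda)`` and two noise vectors with variance
    ``var_eps`` are combined into::

        B       = C + delta
        X       = alpha + beta * (C + delta)  + eps
        X_prime = alpha + beta * (C + lambda) + eps_prime

    so ``(X, C)`` and ``(X_prime, C)`` share all observable moments while
    only ``X`` carries information on the aging divergence.
    """
    v = params.variances()
    rng = np.random.default_rng(params.seed)
    c = rng.normal(params.mu, np.sqrt(v["var_c"]), params.n)
    delta = rng.normal(0.0, np.sqrt(v["var_delta"]), params.n)
    lam = rng.normal(0.0, np.sqrt(v["var_lambda"]), params.n)
    eps = rng.normal(0.0, np.sqrt(v["var_eps"]), params.n)
    eps_prime = rng.normal(0.0, np.sqrt(v["var_eps"]), params.n)

    x = params.alpha + params.beta * (c + delta) + eps
    x_prime = params.alpha + params.beta * (c + lam) + eps_prime
    markers = pd.DataFrame({"X": x, "X_prime": x_prime})
    return CohortData(age=c, markers=markers, delta=delta, bioage=c + delta, lam=lam)


def derive_scenario_noise(table: ScenarioTable) -> dict[tuple[str, int], float]:
    """Noise variance per (scenario, marker) equalizing observable moments.

    For each marker ``i`` the total non-age variance is fixed at
    ``T_i = max_s beta_delta[s, i]^2 * var_delta + base_noise_var``; the
    scenario-specific noise variance is then ``T_i - beta_delta[s, i]^2 *
    var_delta``.  Under the max rule every variance is >= ``base_noise_var``
    and ``var(X_i)`` is identical across scenarios, which (with shared
    ``beta_c`` and Gaussian components) makes the four data sets
    observationally indistinguishable.
    """
    var_delta = table.variances()["var_delta"]
    out: dict[tuple[str, int], float] = {}
    for i in range(table.n_markers):
        delta_vars = {
            s: table.beta_delta[s][i] ** 2 * var_delta for s in table.beta_delta
        }
        total = max(delta_vars.values()) + table.base_noise_var
        for s, dv in delta_vars.items():
            noise = total - dv
            if noise < 0:  # unreachable under the max rule; guards overrides
                raise ParameterError(
                    f"negative noise variance for scenario {s}, marker {i + 1}"
                )
            out[(s, i)] = noise
    return out


def gen_example2(table: ScenarioTable, scenario: str) -> CohortData:
    """Generate one three-marker scenario cohort with truth columns.

    ``X_i = beta_c[i] * C + beta_delta[scenario, i] * delta + eps_i`` with
    noise variances from :func:`derive_scenario_noise`.  The seed stream is
    shared across scenarios so that matched seeds yield matched ``C`` and
    ``delta`` draws.
    """
    if scenario not in table.beta_delta:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {sorted(table.beta_delta)}"
        )
    v = table.variances()
    noise = derive_scenario_noise(table)
    rng = np.random.default_rng(table.seed)
    c = rng.normal(table.mu, np.sqrt(v["var_c"]), table.n)
    delta = rng.normal(0.0, np.sqrt(v["var_delta"]), table.n)
    cols = {}
    for i in range(table.n_markers):
        eps = rng.normal(0.0, np.sqrt(noise[(scenario, i)]), table.n)
        cols[f"marker_{i + 1}"] = (
            table.beta_c[i] * c + table.beta_delta[scenario][i] * delta + eps
        )
    return CohortData(
        age=c, markers=pd.DataFrame(cols), delta=delta, bioage=c + delta
    )


def _draw_marker_coefficients(
    arch: MarkerArchitecture, m: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (beta_c, beta_delta) per marker from the architecture mixture."""
    types = list(arch.shares())
    probs = np.array([arch.shares()[t] for t in types])
    assignment = rng.choice(len(types), size=m, p=probs)
    signs = rng.choice([-1.0, 1.0], size=m)
    beta_c = rng.uniform(*arch.beta_c_range, size=m)
    beta_delta = rng.uniform(*arch.beta_delta_range, size=m)
    bc = np.zeros(m)
    bd = np.zeros(m)
    for j in range(m):
        kind = types[assignment[j]]
        if kind in ("c_only", "c_delta"):
            bc[j] = signs[j] * beta_c[j]
        if kind in ("delta_only", "c_delta"):
            bd[j] = signs[j] * beta_delta[j]
    return bc, bd


def _gompertz_death_ages(
    rng: np.random.Generator,
    entry_age: np.ndarray,
    log_rr: np.ndarray,
    a: float,
    b: float,
) -> np.ndarray:
    """Inverse-CDF draw of death age conditional on survival to entry.

    With hazard ``a * exp(b * t) * exp(log_rr)`` the conditional survival is
    ``exp(-R * a/b * (exp(b*t) - exp(b*entry)))``; solving ``S = U`` gives a
    closed-form quantile function.
    """
    u = rng.uniform(size=entry_age.shape[0])
    rr = np.exp(log_rr)
    return np.log(np.exp(b * entry_age) - b * np.log(u) / (a * rr)) / b


def gen_lls_like(params: LLSLikeParams) -> CohortData:
    """Generate the high-dimensional cohort with left-truncated survival."""
    rng = np.random.default_rng(params.seed)
    c = rng.normal(params.mean_age, params.sd_age, params.n)
    sex = rng.integers(0, 2, params.n).astype(float)
    delta = rng.normal(0.0, np.sqrt(params.var_delta), params.n)
    bc, bd = _draw_marker_coefficients(params.architecture, params.m, rng)
    noise = rng.standard_normal((params.n, params.m))
    x = np.outer(c, bc) + np.outer(delta, bd) + noise
    markers = pd.DataFrame(x, columns=[f"marker_{j + 1}" for j in range(params.m)])

    log_rr = params.gamma * delta + params.sex_loghr * sex
    death_age = _gompertz_death_ages(
        rng, c, log_rr, params.gompertz_a, params.gompertz_b
    )
    censor_age = c + params.admin_censor_years
    event = (death_age <= censor_age).astype(float)
    exit_age = np.minimum(death_age, censor_age)
    return CohortData(
        age=c,
        markers=markers,
        delta=delta,
        bioage=c + delta,
        sex=sex,
        entry_age=c.copy(),
        exit_age=exit_age,
        event=event,
    )


# ---------------------------------------------------------------------------
# hazard calibration
# ---------------------------------------------------------------------------


def expected_event_fraction(params: LLSLikeParams, n_nodes: int = 40) -> float:
    """Population death fraction within the follow-up window, by quadrature.

    Integrates ``1 - S(entry + tau | entry)`` over the Gaussian laws of entry
    age and the aging divergence and the two sexes using Gauss-Hermite nodes;
    independent of the Monte-Carlo generator, so it doubles as an oracle.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    weights = weights / weights.sum()
    ages = params.mean_age + params.sd_age * nodes
    deltas = np.sqrt(params.var_delta) * nodes

    a, b, tau = params.gompertz_a, params.gompertz_b, params.admin_censor_years
    cum = (a / b) * (np.exp(b * (ages + tau)) - np.exp(b * ages))  # baseline
    total = 0.0
    for sex, p_sex in ((0.0, 0.5), (1.0, 0.5)):
        rr = np.exp(params.gamma * deltas + params.sex_loghr * sex)
        death_prob = 1.0 - np.exp(-np.outer(cum, rr))
        total += p_sex * weights @ death_prob @ weights
    return float(total)


def calibrate_baseline_hazard(
    params: LLSLikeParams,
    target_events: float = 309,
    target_n: float = 2267,
    bracket: tuple[float, float] = (1e-9, 1e-2),
) -> LLSLikeParams:
    """Return params with ``gompertz_a`` set to hit the target event fraction.

    Bisection (via Brent's method) of :func:`expected_event_fraction` in
    ``gompertz_a``, which is strictly monotone.
    """
    from scipy.optimize import brentq

    target = target_events / target_n

    def objective(a: float) -> float:
        return expected_event_fraction(dataclasses.replace(params, gompertz_a=a)) - target

    a_star = brentq(objective, *bracket, xtol=1e-12, rtol=1e-10)
    return dataclasses.replace(params, gompertz_a=float(a_star))
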