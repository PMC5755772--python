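"""Synthetic cohort generator.

No patient-level data were released for the study cohort, so every downstream
stage is exercised on synthetic tables that reproduce the published marginal
summaries and carry a configurable *planted* dependence structure:

* each continuous variable is a moment-matched truncated normal on its
  published [MIN, MAX] range (the published mean and SD are matched to within
  0.1% by numerically solving for the parent normal's location and scale);
* the spine deformity index is a zero-inflated count: a point mass at 0 plus
  a truncated-geometric tail on 1..19, with the zero probability and tail
  decay jointly moment-matched to the published mean 2.03 / SD 4.05 (this
  also reproduces the published median of 0);
* dependence between continuous variables is a Gaussian copula with a
  block-structured latent correlation (bone-turnover block, bone-density
  block, quality links, age vs years-since-menopause);
* binary outcomes (Romberg positivity, fracture status) are independent coins
  with probability logistic(intercept + coefficients · standardized latents);
  by default fracture loads on low bone density, low TBS, high bone strain
  and a shared latent balance trait that also drives Romberg positivity.
  Intercepts are calibrated by Gauss–Hermite quadrature so the default
  prevalences (fracture 0.25, Romberg 0.30) hold marginally.

Sampling is deterministic for a fixed (seed, config): each variable draws its
raw normals from its own named substream, so adding a variable or outcome
does not perturb the others' draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import (
    BINARY,
    CONTINUOUS,
    CohortSchema,
    CohortTable,
    VariableSpec,
    default_schema,
)

SDI_MAX = 19  # largest spine deformity index observed in the cohort

BALANCE_LATENT = "Balance"


class InfeasibleMarginalError(ValueError):
    """Moment targets cannot be met by the marginal family on its range."""


def _substream(seed: int, name: str) -> np.random.Generator:
    # crc32 gives a stable per-name offset; masked to stay within 2**31
    return np.random.default_rng([int(seed), zlib.crc32(name.encode()) & 0x7FFFFFFF])


# ---------------------------------------------------------------------------
# marginal families
# ---------------------------------------------------------------------------

def fit_truncated_normal(
    target_mean: float,
    target_sd: float,
    lower: float,
    upper: float,
    name: str = "",
) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lower, upper]-truncated normal matches the
    target mean and SD to within 0.1% relative error.

    Solved by least squares on (mu, log sigma) against the analytic truncated
    moments; raises :class:`InfeasibleMarginalError` when the targets cannot
    be realised on the interval (e.g. SD larger than the interval supports).
    """
    if not lower < target_mean < upper:
        raise InfeasibleMarginalError(
            f"{name or 'variable'}: target mean {target_mean} outside ({lower}, {upper})"
        )
    if target_sd <= 0:
        raise InfeasibleMarginalError(f"{name or 'variable'}: target SD must be > 0")

    def trunc_moments(mu: float, sigma: float) -> tuple[float, float]:
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        with np.errstate(all="ignore"):  # solver may probe degenerate corners
            m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        if not (np.isfinite(m) and np.isfinite(v)):
            return np.inf, np.inf
        return float(m), float(np.sqrt(v))

    def residuals(x: np.ndarray) -> np.ndarray:
        m, s = trunc_moments(x[0], float(np.exp(x[1])))
        return np.array([(m - target_mean) / target_sd, (s - target_sd) / target_sd])

    x0 = np.array([target_mean, np.log(target_sd)])
    sol = optimize.least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
    m, s = trunc_moments(mu, sigma)
    if abs(m - target_mean) > 1e-3 * max(abs(target_mean), target_sd) or abs(
        s - target_sd
    ) > 1e-3 * target_sd:
        raise InfeasibleMarginalError(
            f"{name or 'variable'}: truncated-normal moment match failed "
            f"(achieved mean {m:.4g}, SD {s:.4g}; targets {target_mean}, {target_sd})"
        )
    return mu, sigma


def fit_zero_inflated_counts(
    target_mean: float,
    target_sd: float,
    max_count: int = SDI_MAX,
    name: str = "SDI",
) -> tuple[float, float]:
    """(p_zero, theta) of a zero-inflated truncated-geometric count.

    pmf: P(0) = p_zero, P(k) ∝ (1 − p_zero)·theta**(k−1) for k = 1..max_count.
    theta is solved from the scale-free second-to-first-moment ratio, then
    p_zero from the mean.
    """
    k = np.arange(1, max_count + 1, dtype=float)
    ratio = (target_sd**2 + target_mean**2) / target_mean

    def tail_moments(theta: float) -> tuple[float, float]:
        q = theta ** (k - 1)
        q = q / q.sum()
        return float(k @ q), float((k**2) @ q)

    def f(theta: float) -> float:
        m1, m2 = tail_moments(theta)
        return m2 / m1 - ratio

    lo, hi = 1e-9, 1 - 1e-12
    if f(lo) * f(hi) > 0:
        raise InfeasibleMarginalError(
            f"{name}: moment targets outside the zero-inflated family's reach"
        )
    theta = float(optimize.brentq(f, lo, hi, xtol=1e-14))
    m1, _ = tail_moments(theta)
    p_zero = 1.0 - target_mean / m1
    if not 0.0 <= p_zero <= 1.0:
        raise InfeasibleMarginalError(f"{name}: implied p_zero {p_zero:.3f} outside [0,1]")
    return p_zero, theta


@dataclass(frozen=True)
class MarginalModel:
    """Fitted marginal distribution of one continuous variable."""

    variable: str
    family: str  # "truncated-normal" | "zero-inflated-count"
    mu: float = 0.0
    sigma: float = 1.0
    lower: float = 0.0
    upper: float = 1.0
    p_zero: float | None = None
    theta: float | None = None

    @classmethod
    def from_spec(cls, spec: VariableSpec) -> "MarginalModel":
        if spec.name == "SDI":
            p_zero, theta = fit_zero_inflated_counts(
                spec.target_mean, spec.target_sd, int(spec.max_allowed), spec.name
            )
            return cls(
                variable=spec.name, family="zero-inflated-count",
                lower=spec.min_allowed, upper=spec.max_allowed,
                p_zero=p_zero, theta=theta,
            )
        mu, sigma = fit_truncated_normal(
            spec.target_mean, spec.target_sd, spec.min_allowed, spec.max_allowed, spec.name
        )
        return cls(
            variable=spec.name, family="truncated-normal",
            mu=mu, sigma=sigma, lower=spec.min_allowed, upper=spec.max_allowed,
        )

    def pmf(self) -> np.ndarray:
        """Probability mass over 0..upper (count family only)."""
        if self.family != "zero-inflated-count":
            raise ValueError("pmf only defined for the count family")
        k = np.arange(1, int(self.upper) + 1, dtype=float)
        tail = self.theta ** (k - 1)
        tail = tail / tail.sum() * (1.0 - self.p_zero)
        return np.concatenate([[self.p_zero], tail])

    def moments(self) -> tuple[float, float]:
        """Exact mean and SD implied by the fitted parameters."""
        if self.family == "zero-inflated-count":
            p = self.pmf()
            k = np.arange(len(p), dtype=float)
            m = float(k @ p)
            return m, float(np.sqrt((k - m) ** 2 @ p))
        a = (self.lower - self.mu) / self.sigma
        b = (self.upper - self.mu) / self.sigma
        m, v = stats.truncnorm.stats(a, b, loc=self.mu, scale=self.sigma, moments="mv")
        return float(m), float(np.sqrt(v))

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile transform of copula uniforms into this marginal."""
        if self.family == "zero-inflated-count":
            cum = np.cumsum(self.pmf())
            idx = np.searchsorted(cum, u, side="left")
            return np.clip(idx, 0, int(self.upper)).astype(float)
        a = (self.lower - self.mu) / self.sigma
        b = (self.upper - self.mu) / self.sigma
        x = stats.truncnorm.ppf(u, a, b, loc=self.mu, scale=self.sigma)
        return np.clip(x, self.lower, self.upper)


# ---------------------------------------------------------------------------
# dependence structure
# ---------------------------------------------------------------------------

def nearest_psd_correlation(corr: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to a (numerically) PSD correlation matrix
    by alternating eigenvalue clipping and unit-diagonal rescaling."""
    c = np.array(corr, dtype=float)
    c = (c + c.T) / 2.0
    for _ in range(100):
        w, v = np.linalg.eigh(c)
        if w.min() >= -tol:
            break
        w = np.clip(w, 0.0, None)
        c = (v * w) @ v.T
        d = np.sqrt(np.clip(np.diag(c), 1e-12, None))
        c = c / np.outer(d, d)
        np.fill_diagonal(c, 1.0)
    return c


@dataclass(frozen=True)
class OutcomeModel:
    """One binary outcome: coin with probability logistic(a + coef·latents).

    ``prevalence`` is the marginal target; the intercept is calibrated from it
    at sampling time by Gauss–Hermite quadrature over the Gaussian linear
    predictor, so edits to the coefficients keep the prevalence stable.
    """

    name: str
    coefficients: Mapping[str, float]
    prevalence: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"{self.name}: prevalence must be in (0,1)")


@dataclass(frozen=True)
class DependenceModel:
    """Latent Gaussian-copula correlation plus binary-outcome models.

    ``latent_names`` lists the continuous variables followed by any extra
    purely latent traits (the balance trait that couples Romberg and
    fracture).  The correlation matrix has unit diagonal and is projected to
    the nearest PSD correlation on construction.
    """

    latent_names: tuple[str, ...]
    correlation: np.ndarray
    outcomes: tuple[OutcomeModel, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.correlation, dtype=float)
        if c.shape != (len(self.latent_names), len(self.latent_names)):
            raise ValueError("correlation shape does not match latent names")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("latent correlation must have unit diagonal")
        object.__setattr__(self, "correlation", nearest_psd_correlation(c))
        for om in self.outcomes:
            unknown = set(om.coefficients) - set(self.latent_names)
            if unknown:
                raise ValueError(
                    f"outcome {om.name!r} references unknown latents {sorted(unknown)}"
                )

    def coefficient_vector(self, outcome: OutcomeModel) -> np.ndarray:
        return np.array(
            [outcome.coefficients.get(n, 0.0) for n in self.latent_names], dtype=float
        )


# Default planted structure.  Pairwise latent correlations:
# bone-turnover block (CTX, ALP, BAP), bone-density block (both BMDs and the
# neck T/Z scores), quality links (TBS vs bone strain negative, bone strain
# vs density negative), and the near-deterministic age vs years-since-
# menopause link.  Everything else is left at zero.
_DEFAULT_BLOCKS: list[tuple[str, str, float]] = [
    ("CTX", "ALP", 0.6), ("CTX", "BAP", 0.6), ("ALP", "BAP", 0.6),
    ("BMD_Lumbar", "BMD_Neck", 0.7), ("BMD_Lumbar", "Tscore_Neck", 0.7),
    ("BMD_Lumbar", "Zscore_Neck", 0.7), ("BMD_Neck", "Tscore_Neck", 0.7),
    ("BMD_Neck", "Zscore_Neck", 0.7), ("Tscore_Neck", "Zscore_Neck", 0.7),
    ("TBS", "BS_Lumbar", -0.5),
    ("BS_Lumbar", "BMD_Lumbar", -0.4), ("BS_Lumbar", "BMD_Neck", -0.4),
    ("Age", "YrsSinceMenopause", 0.9),
]

# Fracture loads on poor bone quantity (negative density loadings), poor
# quality (low TBS, high strain) and the balance trait; Romberg loads on the
# balance trait with a mild age effect.
_DEFAULT_OUTCOMES: list[tuple[str, dict[str, float], float]] = [
    ("Romberg", {BALANCE_LATENT: 1.2, "Age": 0.3}, 0.30),
    (
        "Fracture",
        {
            "BMD_Lumbar": -0.8,
            "BMD_Neck": -0.5,
            "TBS": -0.6,
            "BS_Lumbar": 0.7,
            BALANCE_LATENT: 1.0,
        },
        0.25,
    ),
]


def default_dependence(schema: CohortSchema | None = None) -> DependenceModel:
    schema = schema or default_schema()
    names = tuple(v.name for v in schema.continuous) + (BALANCE_LATENT,)
    idx = {n: i for i, n in enumerate(names)}
    corr = np.eye(len(names))
    for a, b, rho in _DEFAULT_BLOCKS:
        if a in idx and b in idx:
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    outcomes = tuple(
        OutcomeModel(name, coefs, prev)
        for name, coefs, prev in _DEFAULT_OUTCOMES
        if name in schema.names
    )
    return DependenceModel(latent_names=names, correlation=corr, outcomes=outcomes)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full synthetic-cohort configuration; deterministic given (seed, config)."""

    n_records: int = 125
    seed: int = 0
    schema: CohortSchema = field(default_factory=default_schema)
    marginals: tuple[MarginalModel, ...] = ()
    dependence: DependenceModel | None = None

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be positive")
        if not self.marginals:
            fitted = tuple(MarginalModel.from_spec(v) for v in self.schema.continuous)
            object.__setattr__(self, "marginals", fitted)
        if self.dependence is None:
            object.__setattr__(self, "dependence", default_dependence(self.schema))

    def marginal(self, name: str) -> MarginalModel:
        for m in self.marginals:
            if m.variable == name:
                return m
        raise KeyError(name)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _calibrate_intercept(
    target_prevalence: float, predictor_sd: float, n_quad: int = 80
) -> float:
    """Intercept a with E[logistic(a + sd·Z)] = target, Z ~ N(0,1)."""
    if predictor_sd < 1e-12:
        return float(special.logit(target_prevalence))
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    weights = weights / weights.sum()

    def mean_prob(a: float) -> float:
        return float(weights @ special.expit(a + predictor_sd * nodes))

    return float(
        optimize.brentq(lambda a: mean_prob(a) - target_prevalence, -40.0, 40.0)
    )


def plant_outcomes(
    latents: pd.DataFrame,
    dependence: DependenceModel,
    seed: int,
) -> pd.DataFrame:
    """Draw the binary outcome columns from the standardized latent matrix.

    Each outcome is an independent Bernoulli draw per record with probability
    logistic(intercept + coefficients·latents); intercepts are calibrated to
    the configured marginal prevalences.  Each outcome uses its own named
    random substream.
    """
    if list(latents.columns) != list(dependence.latent_names):
        raise ValueError("latent columns do not match the dependence model")
    z = latents.to_numpy()
    out = {}
    for om in dependence.outcomes:
        c = dependence.coefficient_vector(om)
        predictor_sd = float(np.sqrt(c @ dependence.correlation @ c))
        a = _calibrate_intercept(om.prevalence, predictor_sd)
        p = special.expit(a + z @ c)
        rng = _substream(seed, f"outcome:{om.name}")
        out[om.name] = (rng.random(len(latents)) < p).astype(int)
    return pd.DataFrame(out, index=latents.index)


def sample_latents(config: GeneratorConfig) -> pd.DataFrame:
    """Standardized latent Gaussian matrix with the configured correlation."""
    dep = config.dependence
    n, p = config.n_records, len(dep.latent_names)
    raw = np.empty((n, p))
    for j, name in enumerate(dep.latent_names):
        raw[:, j] = _substream(config.seed, f"latent:{name}").standard_normal(n)
    # jitter keeps the Cholesky factor defined after PSD projection
    chol = np.linalg.cholesky(dep.correlation + 1e-10 * np.eye(p))
    z = raw @ chol.T
    return pd.DataFrame(z, columns=list(dep.latent_names))


def sample_cohort(config: GeneratorConfig | None = None) -> CohortTable:
    """Draw a full synthetic cohort table.

    Continuous columns arise from the Gaussian copula (probability transform
    of the latent normals through each fitted marginal's quantile function);
    binary columns from :func:`plant_outcomes`.
    """
    config = config or GeneratorConfig()
    schema = config.schema
    latents = sample_latents(config)
    u = pd.DataFrame(
        stats.norm.cdf(latents.to_numpy()), columns=latents.columns
    )
    data = {}
    for v in schema.continuous:
        data[v.name] = config.marginal(v.name).ppf(u[v.name].to_numpy())
    outcomes = plant_outcomes(latents, config.dependence, config.seed)
    for v in schema.binary:
        data[v.name] = outcomes[v.name].to_numpy()
    df = pd.DataFrame(data)
    df.insert(0, schema.id_field, [f"P{i + 1:05d}" for i in range(len(df))])
    return CohortTable(schema, df)
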