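"""Generalized multivariate logistic growth-curve structural model.

Each attribute k follows a linear-in-time trajectory on the log-odds scale,

    logit P(alpha_rtk = 1) = (gamma00_k + u0_rk) + (gamma10_k + u1_rk) * t_rt,

where ``gamma00_k`` is the population average initial log-odds, ``gamma10_k``
the average weekly growth rate, and the person-level deviations
``(u0_r1, u1_r1, ..., u0_rK, u1_rK) ~ MVN(0, G)`` couple attributes through
the KP x KP covariance matrix G (P = 2 random effects per attribute,
intercept-then-slope nested within attribute).

Mastery indicators are Bernoulli given the logit: the level-2 residual with
variance pi^2/3 is the variance implied by the logistic link (latent-response
formulation), not an extra additive normal term — adding one would
double-count.  ``ResidualSpec(explicit=True)`` enables the explicit-residual
variant for sensitivity analysis only.

The conditional-at-mean trajectory (:func:`mean_trajectory`, random effects
at zero) is distinct from the population-marginal mastery proportion
(:func:`marginal_mastery_probability`, integrating over MVN(0, G)); the
marginal is attenuated toward 0.5 and the gap grows with time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import expit

__all__ = [
    "FixedEffects",
    "GMatrix",
    "PersonRandomEffects",
    "ResidualSpec",
    "effect_labels",
    "mastery_logit",
    "mastery_probability",
    "corr_to_cov",
    "cov_to_corr",
    "mean_trajectory",
    "stacked_dummy_predictor",
    "marginal_mastery_probability",
    "center_times",
]

#: Residual variance implied by the standard logistic distribution.
LOGISTIC_VARIANCE = math.pi ** 2 / 3


def effect_labels(n_attributes: int, attribute_ids=None) -> tuple:
    """Canonical random-effect labels: (u0_A1, u1_A1, u0_A2, ...)."""
    if attribute_ids is None:
        attribute_ids = [f"A{k + 1}" for k in range(n_attributes)]
    return tuple(f"u{p}_{a}" for a in attribute_ids for p in (0, 1))


@dataclass(frozen=True)
class FixedEffects:
    """Average initial levels (gamma00) and slopes (gamma10), one per attribute."""

    gamma00: np.ndarray
    gamma10: np.ndarray
    attribute_ids: tuple = None

    def __post_init__(self):
        g00 = np.atleast_1d(np.asarray(self.gamma00, dtype=float))
        g10 = np.atleast_1d(np.asarray(self.gamma10, dtype=float))
        if g00.shape != g10.shape or g00.ndim != 1:
            raise ValueError("gamma00 and gamma10 must be 1-d arrays of equal length")
        if not (np.isfinite(g00).all() and np.isfinite(g10).all()):
            raise ValueError("fixed effects must be finite")
        object.__setattr__(self, "gamma00", g00)
        object.__setattr__(self, "gamma10", g10)
        ids = self.attribute_ids or tuple(f"A{k + 1}" for k in range(g00.size))
        object.__setattr__(self, "attribute_ids", tuple(ids))

    @property
    def n_attributes(self) -> int:
        return self.gamma00.size

    @classmethod
    def from_csv(cls, path) -> "FixedEffects":
        frame = pd.read_csv(path)
        return cls(
            gamma00=frame["gamma00"].to_numpy(),
            gamma10=frame["gamma10"].to_numpy(),
            attribute_ids=tuple(frame["attribute"]),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"attribute": self.attribute_ids, "gamma00": self.gamma00, "gamma10": self.gamma10}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class GMatrix:
    """KP x KP random-effect covariance matrix, P = 2 effects per attribute."""

    covariance: np.ndarray
    labels: tuple = None
    _psd_tol: float = field(default=1e-10, repr=False)

    def __post_init__(self):
        cov = np.asarray(self.covariance, dtype=float)
        if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
            raise ValueError("covariance must be square")
        if cov.shape[0] % 2 != 0:
            raise ValueError("dimension must be 2K (intercept+slope per attribute)")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if (np.diag(cov) < 0).any():
            raise ValueError("variances must be nonnegative")
        if np.linalg.eigvalsh(cov).min() < -self._psd_tol * max(1.0, np.abs(cov).max()):
            raise ValueError("covariance must be positive semi-definite")
        object.__setattr__(self, "covariance", cov)
        labels = self.labels or effect_labels(cov.shape[0] // 2)
        if len(labels) != cov.shape[0]:
            raise ValueError("labels length mismatch")
        object.__setattr__(self, "labels", tuple(labels))

    @property
    def n_attributes(self) -> int:
        return self.covariance.shape[0] // 2

    @classmethod
    def from_csv(cls, path) -> "GMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(covariance=frame.to_numpy(dtype=float), labels=tuple(frame.columns))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.covariance, index=list(self.labels), columns=list(self.labels)).to_csv(
            path
        )


@dataclass(frozen=True)
class PersonRandomEffects:
    """One person's deviations: u0 (initial level) and u1 (slope), length K."""

    u0: np.ndarray
    u1: np.ndarray

    def __post_init__(self):
        u0 = np.atleast_1d(np.asarray(self.u0, dtype=float))
        u1 = np.atleast_1d(np.asarray(self.u1, dtype=float))
        if u0.shape != u1.shape:
            raise ValueError("u0 and u1 must have equal length")
        object.__setattr__(self, "u0", u0)
        object.__setattr__(self, "u1", u1)

    @classmethod
    def zero(cls, n_attributes: int) -> "PersonRandomEffects":
        return cls(np.zeros(n_attributes), np.zeros(n_attributes))

    @classmethod
    def from_stacked(cls, stacked) -> "PersonRandomEffects":
        stacked = np.asarray(stacked, dtype=float)
        return cls(stacked[0::2], stacked[1::2])

    def stacked(self) -> np.ndarray:
        """Interleaved (u0_A1, u1_A1, u0_A2, ...) vector matching G's ordering."""
        out = np.empty(2 * self.u0.size)
        out[0::2] = self.u0
        out[1::2] = self.u1
        return out


@dataclass(frozen=True)
class ResidualSpec:
    """Level-2 residual: pi^2/3 per element, zero cross-covariances.

    ``explicit=False`` (default) treats the residual as the variance implied
    by the Bernoulli-with-logit link; ``explicit=True`` adds a normal
    disturbance of this variance to the linear predictor (sensitivity
    analysis only — doubles the residual variability).
    """

    level2_residual_variance: float = LOGISTIC_VARIANCE
    explicit: bool = False


def mastery_logit(fixed: FixedEffects, re: PersonRandomEffects, attribute: int, time):
    """Linear predictor of mastery for one attribute: Eq-style beta0 + beta1*t."""
    if not 0 <= attribute < fixed.n_attributes:
        raise IndexError(f"attribute index {attribute} out of range")
    time = np.asarray(time, dtype=float)
    return (fixed.gamma00[attribute] + re.u0[attribute]) + (
        fixed.gamma10[attribute] + re.u1[attribute]
    ) * time


def mastery_probability(logit):
    """Logistic transform of the mastery linear predictor."""
    return expit(np.asarray(logit, dtype=float))


def corr_to_cov(correlations, variances, labels=None) -> GMatrix:
    """Build G from a correlation matrix and per-effect variances."""
    corr = np.asarray(correlations, dtype=float)
    var = np.asarray(variances, dtype=float)
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    if (np.abs(corr) > 1 + 1e-12).any():
        raise ValueError("correlations must lie in [-1, 1]")
    if (var < 0).any():
        raise ValueError("variances must be nonnegative")
    sd = np.sqrt(var)
    return GMatrix(corr * np.outer(sd, sd), labels=labels)


def cov_to_corr(g: GMatrix) -> np.ndarray:
    """Correlation matrix of G; requires strictly positive variances."""
    cov = g.covariance if isinstance(g, GMatrix) else np.asarray(g, dtype=float)
    d = np.diag(cov)
    if (d <= 0).any():
        raise ValueError("all variances must be positive to form correlations")
    sd = np.sqrt(d)
    return cov / np.outer(sd, sd)


def mean_trajectory(fixed: FixedEffects, occasion_means) -> np.ndarray:
    """K x T mastery probabilities at the occasion-mean times, random effects zero.

    This is the conditional-at-mean trajectory; because the logistic is
    nonlinear it is *not* the population-average mastery proportion (see
    :func:`marginal_mastery_probability`).
    """
    times = np.asarray(occasion_means, dtype=float)
    logits = fixed.gamma00[:, None] + fixed.gamma10[:, None] * times[None, :]
    return expit(logits)


def stacked_dummy_predictor(fixed: FixedEffects, re: PersonRandomEffects, attribute: int, time):
    """Stacked-outcome formulation: attribute dummies select the trajectory.

    Evaluates ``sum_j A_j * [(gamma00_j + u0_j) + (gamma10_j + u1_j) * t]``
    with dummy ``A_j = 1`` iff ``j == attribute``; algebraically identical to
    :func:`mastery_logit`, provided as the estimation-side parameterization.
    """
    if not 0 <= attribute < fixed.n_attributes:
        raise IndexError(f"attribute index {attribute} out of range")
    time = np.asarray(time, dtype=float)
    dummies = np.zeros(fixed.n_attributes)
    dummies[attribute] = 1.0
    per_attr = (fixed.gamma00 + re.u0)[:, None] + (fixed.gamma10 + re.u1)[:, None] * np.atleast_1d(
        time
    )[None, :]
    out = dummies @ per_attr
    return out.reshape(np.shape(time)) if np.ndim(time) else float(out[0])


def marginal_mastery_probability(
    fixed: FixedEffects, g: GMatrix, attribute: int, time, n_nodes: int = 41
):
    """Population-marginal mastery proportion E_u[logistic(eta)] at given times.

    The linear predictor is Gaussian with mean ``gamma00 + gamma10 * t`` and
    variance ``s00 + 2 t s01 + t^2 s11`` from the attribute's 2 x 2 block of
    G; the 1-D integral is evaluated by Gauss-Hermite quadrature.
    """
    if not 0 <= attribute < fixed.n_attributes:
        raise IndexError(f"attribute index {attribute} out of range")
    time = np.asarray(time, dtype=float)
    i0, i1 = 2 * attribute, 2 * attribute + 1
    cov = g.covariance
    var = cov[i0, i0] + 2 * time * cov[i0, i1] + time ** 2 * cov[i1, i1]
    mu = fixed.gamma00[attribute] + fixed.gamma10[attribute] * time
    nodes, weights = hermegauss(n_nodes)
    weights = weights / weights.sum()
    vals = expit(mu[..., None] + np.sqrt(var)[..., None] * nodes)
    out = vals @ weights
    return float(out) if out.ndim == 0 else out


def center_times(times, occasion_means) -> np.ndarray:
    """Center time scores at the medial occasion mean (recommended for fitting

    when the initial-level parameters are poorly informed; off by default to
    match the simulation design)."""
    means = np.asarray(occasion_means, dtype=float)
    return np.asarray(times, dtype=float) - means[(means.size - 1) // 2]
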