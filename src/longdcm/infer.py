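"""Bayesian estimation of the joint longitudinal diagnostic model by MCMC.

The sampler is a blocked Metropolis-within-Gibbs scheme:

* **Latent mastery profiles** — for every person-occasion cell the 2^K
  latent class is drawn exactly from its categorical full conditional,
  combining the LCDM likelihood of the occasion's item responses with the
  growth-model prior logit of each attribute.  This is the exact Bernoulli
  full conditional of each indicator, sampled jointly over the profile.
* **Item parameters** — scalar random-walk Metropolis within the
  monotonicity region (mains >= 0, interaction >= -min(mains)), using
  per-class sufficient statistics so a step costs O(2^K).
* **Fixed effects and person random effects** — scalar random-walk
  Metropolis on the logistic-Bernoulli mastery likelihood; random-effect
  coordinates are proposed for all persons at once and accepted per person
  (persons are conditionally independent given G).
* **G** — conjugate inverse-Wishart full conditional given the random
  effects.

Random-walk step sizes adapt during burn-in toward a 20-45% acceptance
rate and are frozen afterward, preserving detailed balance for the kept
draws.  Monotonicity truncation pins the labeling of mastery, so no
post-hoc relabeling is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from scipy.stats import invwishart

from .growth import FixedEffects, GMatrix, effect_labels
from .measurement import ItemParameters, QMatrix, enumerate_profiles

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorSamples",
    "fit",
    "posterior_mastery_probability",
    "classify",
]

logger = logging.getLogger(__name__)

MAX_LOGIT = 35.0  # linear predictors are clipped here (with a logged warning)


def _log1pexp(x):
    return np.logaddexp(0.0, x)


def _clip_logit(x):
    if np.any(np.abs(x) > MAX_LOGIT):
        if not getattr(_clip_logit, "_warned", False):
            logger.warning("linear predictor clipped at +/-%s (reported once)", MAX_LOGIT)
            _clip_logit._warned = True
        return np.clip(x, -MAX_LOGIT, MAX_LOGIT)
    return x


@dataclass(frozen=True)
class PriorSpec:
    """Priors for all sampled blocks.

    Item intercepts are Normal; main effects Normal truncated to [0, inf);
    interactions Normal truncated to the monotonicity region (the joint item
    prior is the product of the normal kernels times the region indicator).
    Fixed effects get a diffuse Normal.  G gets an inverse-Wishart with
    ``g_df`` degrees of freedom and ``g_scale`` scale matrix (defaults:
    KP + 2 and the identity, resolved at fit time);
    :meth:`with_g_center` centers the prior mean on a supplied matrix.
    """

    intercept_mean: float = 0.0
    intercept_sd: float = 2.0
    main_mean: float = 0.0
    main_sd: float = 2.0
    interaction_mean: float = 0.0
    interaction_sd: float = 2.0
    gamma_mean: float = 0.0
    gamma_sd: float = 10.0
    g_df: float = None
    g_scale: np.ndarray = None

    def __post_init__(self):
        for name in ("intercept_sd", "main_sd", "interaction_sd", "gamma_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_g_center(self, g: GMatrix, weight: float = 1.0) -> "PriorSpec":
        """Inverse-Wishart prior whose mean is ``g`` with ``weight`` pseudo-persons."""
        p = g.covariance.shape[0]
        return replace(self, g_df=p + 1 + weight, g_scale=g.covariance * weight)

    def resolve_g(self, dim: int):
        df = self.g_df if self.g_df is not None else dim + 2
        if df <= dim - 1:
            raise ValueError(f"g_df must exceed KP - 1 = {dim - 1}")
        scale = self.g_scale if self.g_scale is not None else np.eye(dim)
        scale = np.asarray(scale, dtype=float)
        if scale.shape != (dim, dim):
            raise ValueError("g_scale dimension mismatch")
        return float(df), scale


@dataclass(frozen=True)
class McmcConfig:
    """Chain settings.  ``init`` is one of ``random | truth | heuristic``.

    ``sample_items`` / ``sample_growth`` fix the corresponding block at its
    initial value (useful for conditional runs and diagnostics).
    """

    n_chains: int = 3
    n_iterations: int = 4000
    n_burnin: int = 2000
    thin: int = 1
    seed: int = 0
    init: str = "heuristic"
    sample_items: bool = True
    sample_growth: bool = True
    store_u: bool = False
    adapt_interval: int = 50
    target_accept: float = 0.3
    init_jitter: float = 0.1

    def __post_init__(self):
        if not self.n_iterations > self.n_burnin >= 0:
            raise ValueError("need n_iterations > n_burnin >= 0")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.init not in ("random", "truth", "heuristic"):
            raise ValueError(f"unknown init mode {self.init!r}")

    @classmethod
    def desk(cls, **overrides) -> "McmcConfig":
        """Short-chain preset for desk-scale runs (2 chains x 1500, 750 burn-in)."""
        base = dict(n_chains=2, n_iterations=1500, n_burnin=750)
        base.update(overrides)
        return cls(**base)

    @property
    def n_kept(self) -> int:
        return (self.n_iterations - self.n_burnin + self.thin - 1) // self.thin


@dataclass
class PosteriorSamples:
    """Post-burn-in draws for all blocks, indexed (chain, iteration, ...)."""

    item_labels: list
    item_draws: np.ndarray  # (chains, kept, J)
    gamma_labels: list
    gamma_draws: np.ndarray  # (chains, kept, 2K): gamma00 then gamma10 per attribute
    g_labels: list
    g_draws: np.ndarray  # (chains, kept, 2K, 2K)
    alpha_draws: np.ndarray  # (chains, kept, N, T, K) uint8
    u_draws: np.ndarray = None  # (chains, kept, N, 2K) if stored
    acceptance: dict = field(default_factory=dict)
    config: McmcConfig = None
    priors: PriorSpec = None

    @property
    def n_attributes(self) -> int:
        return self.gamma_draws.shape[-1] // 2

    def scalar_chains(self) -> dict:
        """Chains x iterations matrix for every scalar monitored parameter.

        Covers item parameters, fixed effects, and the unique entries of G —
        the parameter set whose convergence is diagnosed.
        """
        out = {}
        for j, name in enumerate(self.item_labels):
            out[name] = self.item_draws[:, :, j]
        for j, name in enumerate(self.gamma_labels):
            out[name] = self.gamma_draws[:, :, j]
        dim = self.g_draws.shape[-1]
        for a in range(dim):
            for b in range(a, dim):
                out[f"G[{self.g_labels[a]},{self.g_labels[b]}]"] = self.g_draws[:, :, a, b]
        return out

    def gelman_rubin(self, sqrt: bool = False) -> dict:
        from .evaluate import gelman_rubin

        return {name: gelman_rubin(draws, sqrt=sqrt) for name, draws in self.scalar_chains().items()}

    def summary(self) -> "pd.DataFrame":
        import pandas as pd

        from .evaluate import gelman_rubin

        rows = []
        for name, draws in self.scalar_chains().items():
            flat = draws.reshape(-1)
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1) if flat.size > 1 else 0.0,
                    "q2.5": np.percentile(flat, 2.5),
                    "q50": np.percentile(flat, 50),
                    "q97.5": np.percentile(flat, 97.5),
                    "rhat": gelman_rubin(draws) if draws.shape[0] >= 2 and draws.shape[1] >= 2 else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def posterior_mean_items(self) -> np.ndarray:
        return self.item_draws.reshape(-1, self.item_draws.shape[-1]).mean(axis=0)

    def posterior_mean_gamma(self) -> np.ndarray:
        return self.gamma_draws.reshape(-1, self.gamma_draws.shape[-1]).mean(axis=0)

    def posterior_mean_g(self) -> np.ndarray:
        return self.g_draws.reshape(-1, *self.g_draws.shape[-2:]).mean(axis=0)


# ---------------------------------------------------------------------------
# item-parameter bookkeeping


class _ItemBlock:
    """Flat parameter vector over all items plus per-class design patterns."""

    def __init__(self, qmatrix: QMatrix, priors: PriorSpec):
        self.q = qmatrix
        profiles = enumerate_profiles(qmatrix.n_attributes)  # (C, K)
        self.profiles = profiles
        specs = []  # (item, kind, key, pattern over classes)
        for i in range(qmatrix.n_items):
            measured = qmatrix.measured(i)
            specs.append((i, "intercept", None, np.ones(profiles.shape[0])))
            for k in measured:
                specs.append((i, "main", int(k), profiles[:, k].astype(float)))
            if measured.size >= 2:
                for a_idx in range(measured.size):
                    for b_idx in range(a_idx + 1, measured.size):
                        a, b = int(measured[a_idx]), int(measured[b_idx])
                        specs.append(
                            (i, "interaction", (a, b), (profiles[:, a] * profiles[:, b]).astype(float))
                        )
        self.specs = specs
        self.labels = []
        for i, kind, key, _ in specs:
            item_id = qmatrix.item_ids[i]
            if kind == "intercept":
                self.labels.append(f"lambda0[{item_id}]")
            elif kind == "main":
                self.labels.append(f"lambda1[{item_id},{qmatrix.attribute_ids[key]}]")
            else:
                a, b = key
                self.labels.append(
                    f"lambda2[{item_id},{qmatrix.attribute_ids[a]},{qmatrix.attribute_ids[b]}]"
                )
        self.priors = priors
        mean = {"intercept": priors.intercept_mean, "main": priors.main_mean,
                "interaction": priors.interaction_mean}
        sd = {"intercept": priors.intercept_sd, "main": priors.main_sd,
              "interaction": priors.interaction_sd}
        self.prior_mean = np.array([mean[kind] for _, kind, _, _ in specs])
        self.prior_sd = np.array([sd[kind] for _, kind, _, _ in specs])
        # per-item index lookup for support checks
        self.item_param_idx = {}
        for j, (i, kind, key, _) in enumerate(specs):
            self.item_param_idx.setdefault(i, {})[(kind, key)] = j

    @property
    def n_params(self) -> int:
        return len(self.specs)

    def vector_from_items(self, items) -> np.ndarray:
        theta = np.empty(self.n_params)
        for j, (i, kind, key, _) in enumerate(self.specs):
            if kind == "intercept":
                theta[j] = items[i].intercept
            elif kind == "main":
                theta[j] = items[i].main_effects[key]
            else:
                theta[j] = items[i].interactions[key]
        return theta

    def items_from_vector(self, theta, enforce_monotone: bool = True):
        items = []
        for i in range(self.q.n_items):
            idx = self.item_param_idx[i]
            intercept = theta[idx[("intercept", None)]]
            mains = {k: theta[j] for (kind, k), j in idx.items() if kind == "main"}
            inters = {k: theta[j] for (kind, k), j in idx.items() if kind == "interaction"}
            items.append(
                ItemParameters(intercept, mains, inters, enforce_monotone=enforce_monotone)
            )
        return items

    def class_logits(self, theta) -> np.ndarray:
        logits = np.zeros((self.q.n_items, self.profiles.shape[0]))
        for j, (i, _, _, pattern) in enumerate(self.specs):
            logits[i] += theta[j] * pattern
        return logits

    def in_support(self, theta, j, value) -> bool:
        """Monotonicity region check for setting parameter j to ``value``."""
        i, kind, key, _ = self.specs[j]
        idx = self.item_param_idx[i]
        if kind == "intercept":
            return True
        if kind == "main":
            if value < 0:
                return False
            for (k2, key2), j2 in idx.items():
                if k2 == "interaction" and key in key2:
                    other = key2[0] if key2[1] == key else key2[1]
                    other_main = theta[idx[("main", other)]]
                    if theta[j2] < -min(value, other_main):
                        return False
            return True
        a, b = key
        bound = -min(theta[idx[("main", a)]], theta[idx[("main", b)]])
        return value >= bound


# ---------------------------------------------------------------------------
# single chain


def _score_init_alpha(data, qmatrix) -> np.ndarray:
    """Heuristic start: mastery if the within-attribute score beats 0.35.

    0.35 sits between the non-mastery (0.18) and single-mastery (0.50)
    correct-response rates of the reference item parameters.
    """
    q = qmatrix.entries  # (I, K)
    counts = q.sum(axis=0)  # items per attribute
    score = data.responses @ q / counts  # (N, T, K)
    return (score > 0.35).astype(np.int8)


def _init_state(data, qmatrix, block, priors, config, rng):
    n, t, _ = data.responses.shape
    k = qmatrix.n_attributes
    dim = 2 * k
    if config.init == "truth":
        if data.true_alpha is None or data.design is None:
            raise ValueError("truth initialization requires a generated data set with truth block")
        alpha = np.array(data.true_alpha, dtype=np.int8)
        theta = block.vector_from_items(data.design.item_parameters)
        fx = data.design.fixed_effects
        gamma = np.concatenate([fx.gamma00, fx.gamma10])
        u = np.array(data.true_u, dtype=float)
        g = np.array(data.design.g.covariance, dtype=float)
        return alpha, theta, gamma, u, g
    if config.init == "random":
        alpha = (rng.random((n, t, k)) < 0.5).astype(np.int8)
        theta = np.empty(block.n_params)
        for j, (_, kind, _, _) in enumerate(block.specs):
            if kind == "intercept":
                theta[j] = rng.normal(-1.0, 0.5)
            elif kind == "main":
                theta[j] = abs(rng.normal(1.0, 0.5))
            else:
                theta[j] = 0.0
        gamma = np.concatenate([rng.normal(0, 1, k), rng.normal(0, 0.05, k)])
    else:  # heuristic
        alpha = _score_init_alpha(data, qmatrix)
        theta = np.empty(block.n_params)
        for j, (_, kind, _, _) in enumerate(block.specs):
            theta[j] = {"intercept": -1.0, "main": 1.0, "interaction": 0.1}[kind]
        first = alpha[:, 0, :].mean(axis=0).clip(0.02, 0.98)
        last = alpha[:, -1, :].mean(axis=0).clip(0.02, 0.98)
        span = max(data.times.mean(axis=0)[-1] - data.times.mean(axis=0)[0], 1.0)
        g00 = np.log(first / (1 - first))
        g10 = (np.log(last / (1 - last)) - g00) / span
        gamma = np.concatenate([g00, g10])
        # dispersed starts across chains
        theta = theta + config.init_jitter * rng.standard_normal(theta.size)
        for j, (_, kind, _, _) in enumerate(block.specs):
            if kind == "main":
                theta[j] = max(theta[j], 0.01)
            elif kind == "interaction":
                theta[j] = max(theta[j], 0.0)
        gamma = gamma + config.init_jitter * rng.standard_normal(gamma.size)
    u = np.zeros((n, dim))
    g = np.eye(dim) * 0.1
    return alpha, theta, gamma, u, g


def _run_chain(data, qmatrix, block, priors, config, seed_seq):
    rng = np.random.default_rng(seed_seq)
    x = data.responses.astype(float)  # (N, T, I)
    n, t, n_items = x.shape
    k = qmatrix.n_attributes
    dim = 2 * k
    c = 2 ** k
    profiles = block.profiles.astype(float)  # (C, K)
    times = data.times  # (N, T)
    xf = x.reshape(n * t, n_items)
    weights = 2 ** np.arange(k)

    alpha, theta, gamma, u, g = _init_state(data, qmatrix, block, priors, config, rng)
    g_df0, g_scale0 = priors.resolve_g(dim)
    logits_ic = block.class_logits(theta)  # (I, C)
    g_prec = np.linalg.inv(g)

    # adaptive step sizes
    step_theta = np.full(block.n_params, 0.3)
    step_gamma = np.concatenate([np.full(k, 0.2), np.full(k, 0.02)])
    step_u = np.tile([0.5, 0.05], k)
    step_shift = np.tile([0.2, 0.02], k)
    scale_groups = [(jj,) for jj in range(dim)]
    scale_groups += [tuple(range(0, dim, 2)), tuple(range(1, dim, 2)), tuple(range(dim))]
    step_scale = np.full(len(scale_groups), 0.2)
    step_ujoint = np.array([0.3])
    acc_theta = np.zeros(block.n_params)
    acc_gamma = np.zeros(dim)
    acc_u = np.zeros(dim)
    acc_shift = np.zeros(dim)
    acc_scale = np.zeros(len(scale_groups))
    acc_ujoint = np.zeros(1)
    prop_count = 0

    kept = config.n_kept
    out_theta = np.empty((kept, block.n_params))
    out_gamma = np.empty((kept, dim))
    out_g = np.empty((kept, dim, dim))
    out_alpha = np.empty((kept, n, t, k), dtype=np.uint8)
    out_u = np.empty((kept, n, dim)) if config.store_u else None
    total_acc = {"items": [0, 0], "gamma": [0, 0], "u": [0, 0]}

    def eta_attr(kk):
        """(N, T) mastery logit for attribute kk given current gamma, u."""
        b0 = gamma[kk] + u[:, 2 * kk]
        b1 = gamma[k + kk] + u[:, 2 * kk + 1]
        return _clip_logit(b0[:, None] + b1[:, None] * times)

    store_idx = 0
    for it in range(config.n_iterations):
        # ---- latent classes: exact categorical full conditional ------------
        logpi = -_log1pexp(-logits_ic)  # log P(correct | class)
        log1mpi = -_log1pexp(logits_ic)
        ll = xf @ (logpi - log1mpi) + log1mpi.sum(axis=0)[None, :]  # (NT, C)
        eta = np.stack([eta_attr(kk) for kk in range(k)], axis=-1)  # (N, T, K)
        ll = ll + eta.reshape(n * t, k) @ profiles.T
        gumbel = -np.log(-np.log(rng.random((n * t, c))))
        classes = np.argmax(ll + gumbel, axis=1)
        alpha = block.profiles[classes].reshape(n, t, k).astype(np.int8)

        # ---- item parameters: scalar RW Metropolis -------------------------
        if config.sample_items:
            onehot_counts = np.zeros((c, n_items))
            np.add.at(onehot_counts, classes, xf)  # n1[c, i]
            class_totals = np.bincount(classes, minlength=c).astype(float)
            n0 = class_totals[:, None] - onehot_counts
            z = rng.standard_normal(block.n_params)
            logu = np.log(rng.random(block.n_params))
            for j in range(block.n_params):
                i_item = block.specs[j][0]
                pattern = block.specs[j][3]
                prop = theta[j] + step_theta[j] * z[j]
                if not block.in_support(theta, j, prop):
                    continue
                cur_logit = logits_ic[i_item]
                new_logit = cur_logit + (prop - theta[j]) * pattern
                d_ll = (
                    onehot_counts[:, i_item] @ (-_log1pexp(-new_logit) + _log1pexp(-cur_logit))
                    + n0[:, i_item] @ (-_log1pexp(new_logit) + _log1pexp(cur_logit))
                )
                d_lp = -0.5 * (
                    (prop - block.prior_mean[j]) ** 2 - (theta[j] - block.prior_mean[j]) ** 2
                ) / block.prior_sd[j] ** 2
                if logu[j] < d_ll + d_lp:
                    theta[j] = prop
                    logits_ic[i_item] = new_logit
                    acc_theta[j] += 1
                    total_acc["items"][0] += 1
            total_acc["items"][1] += block.n_params

        if config.sample_growth:
            # ---- fixed effects: scalar RW Metropolis -----------------------
            for jj in range(dim):
                kk = jj % k
                is_slope = jj >= k
                cur_eta = eta_attr(kk)
                a_k = alpha[:, :, kk]
                prop = gamma[jj] + step_gamma[jj] * rng.standard_normal()
                delta = prop - gamma[jj]
                new_eta = cur_eta + (delta * times if is_slope else delta)
                d_ll = np.sum(a_k * (new_eta - cur_eta) - _log1pexp(new_eta) + _log1pexp(cur_eta))
                d_lp = -0.5 * (
                    (prop - priors.gamma_mean) ** 2 - (gamma[jj] - priors.gamma_mean) ** 2
                ) / priors.gamma_sd ** 2
                if np.log(rng.random()) < d_ll + d_lp:
                    gamma[jj] = prop
                    acc_gamma[jj] += 1
                    total_acc["gamma"][0] += 1
            total_acc["gamma"][1] += dim

            # ---- random effects: per-person vectorized coordinate MH -------
            for jj in range(dim):
                kk, is_slope = jj // 2, jj % 2 == 1
                cur_eta = eta_attr(kk)  # (N, T)
                a_k = alpha[:, :, kk]
                delta = step_u[jj] * rng.standard_normal(n)  # (N,)
                new_eta = cur_eta + (delta[:, None] * times if is_slope else delta[:, None])
                d_ll = np.sum(
                    a_k * (new_eta - cur_eta) - _log1pexp(new_eta) + _log1pexp(cur_eta), axis=1
                )
                pu = u @ g_prec[jj]  # (N,)
                d_lp = -0.5 * (2 * delta * pu + delta ** 2 * g_prec[jj, jj])
                accept = np.log(rng.random(n)) < d_ll + d_lp
                u[accept, jj] += delta[accept]
                acc_u[jj] += accept.mean()
                total_acc["u"][0] += int(accept.sum())
            total_acc["u"][1] += dim * n

            # ---- interweaving translation: gamma vs mean random effect ----
            # Shifting gamma by delta and every person's matching u by -delta
            # leaves the likelihood untouched; acceptance is prior-driven.
            # This breaks the strong posterior trade-off between a fixed
            # effect and the average of its random effects.
            for jj in range(dim):
                kk, p = jj // 2, jj % 2
                gamma_idx = p * k + kk
                delta = step_shift[jj] * rng.standard_normal()
                s_j = (u @ g_prec)[:, jj].sum()
                d_lp_u = -0.5 * (-2 * delta * s_j + n * delta ** 2 * g_prec[jj, jj])
                gnew = gamma[gamma_idx] + delta
                d_lp_g = -0.5 * (
                    (gnew - priors.gamma_mean) ** 2 - (gamma[gamma_idx] - priors.gamma_mean) ** 2
                ) / priors.gamma_sd ** 2
                if np.log(rng.random()) < d_lp_u + d_lp_g:
                    gamma[gamma_idx] = gnew
                    u[:, jj] -= delta
                    acc_shift[jj] += 1

            # ---- joint per-person u update, preconditioned by chol(G) ------
            # Coordinate moves fight the strong cross-attribute correlations
            # in G (up to 0.9); proposing all 2K effects of a person at once
            # along the current G Cholesky respects that geometry.
            chol_g = np.linalg.cholesky(g)
            delta_u = step_ujoint[0] * rng.standard_normal((n, dim)) @ chol_g.T
            u_new = u + delta_u
            d_ll = np.zeros(n)
            for kk in range(k):
                b0 = gamma[kk] + u_new[:, 2 * kk]
                b1 = gamma[k + kk] + u_new[:, 2 * kk + 1]
                new_eta = _clip_logit(b0[:, None] + b1[:, None] * times)
                cur_eta = eta_attr(kk)
                a_k = alpha[:, :, kk]
                d_ll += np.sum(
                    a_k * (new_eta - cur_eta) - _log1pexp(new_eta) + _log1pexp(cur_eta), axis=1
                )
            d_lp = -0.5 * (
                np.einsum("nd,de,ne->n", u_new, g_prec, u_new)
                - np.einsum("nd,de,ne->n", u, g_prec, u)
            )
            accept = np.log(rng.random(n)) < d_ll + d_lp
            u[accept] = u_new[accept]
            acc_ujoint[0] += accept.mean()
            total_acc["u"][0] += int(accept.sum())
            total_acc["u"][1] += n

            # ---- parameter-expansion scale moves ---------------------------
            # Jointly rescale a group S of random-effect columns and the
            # matching rows/columns of G: u_j -> c u_j (j in S), G' = D G D
            # with D = diag(d), d_j = c on S.  The MVN quadratic form is
            # invariant and the u-prior volume change cancels against the u
            # Jacobian, so acceptance combines the likelihood, the
            # inverse-Wishart prior on G, and the G Jacobian
            # (dim + 1) |S| log c.  Groups: each column alone, all
            # intercepts, all slopes, everything — so the random-effect
            # spread and G can escape a low-variance basin together without
            # breaking the cross-attribute correlation structure.
            for gi, group in enumerate(scale_groups):
                logc = step_scale[gi] * rng.standard_normal()
                c_fac = np.exp(logc)
                scal = np.ones(dim)
                scal[list(group)] = c_fac
                u_new = u * scal[None, :]
                d_ll = 0.0
                for kk in {j // 2 for j in group}:
                    b0 = gamma[kk] + u_new[:, 2 * kk]
                    b1 = gamma[k + kk] + u_new[:, 2 * kk + 1]
                    new_eta = _clip_logit(b0[:, None] + b1[:, None] * times)
                    cur_eta = eta_attr(kk)
                    a_k = alpha[:, :, kk]
                    d_ll += np.sum(
                        a_k * (new_eta - cur_eta) - _log1pexp(new_eta) + _log1pexp(cur_eta)
                    )
                new_prec = g_prec * np.outer(1.0 / scal, 1.0 / scal)
                d_lg = (
                    -(g_df0 + dim + 1) * len(group) * logc
                    - 0.5 * ((g_scale0 * new_prec).sum() - (g_scale0 * g_prec).sum())
                )
                jac = (dim + 1) * len(group) * logc
                if np.log(rng.random()) < d_ll + d_lg + jac:
                    u = u_new
                    g = g * np.outer(scal, scal)
                    g_prec = new_prec
                    acc_scale[gi] += 1

            # ---- G: conjugate inverse-Wishart ------------------------------
            s_post = g_scale0 + u.T @ u
            g = invwishart.rvs(df=g_df0 + n, scale=s_post, random_state=rng)
            g_prec = np.linalg.inv(g)

        prop_count += 1
        if it < config.n_burnin and prop_count % config.adapt_interval == 0:
            for steps, acc in (
                (step_theta, acc_theta),
                (step_gamma, acc_gamma),
                (step_u, acc_u),
                (step_shift, acc_shift),
                (step_scale, acc_scale),
                (step_ujoint, acc_ujoint),
            ):
                rate = acc / config.adapt_interval
                steps *= np.exp(0.6 * (rate - config.target_accept))
                acc[:] = 0.0

        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            out_theta[store_idx] = theta
            out_gamma[store_idx] = gamma
            out_g[store_idx] = g
            out_alpha[store_idx] = alpha
            if out_u is not None:
                out_u[store_idx] = u
            store_idx += 1

    return out_theta, out_gamma, out_g, out_alpha, out_u, total_acc


def fit(data, qmatrix: QMatrix = None, priors: PriorSpec = None, config: McmcConfig = None
        ) -> PosteriorSamples:
    """Fit the joint model to a longitudinal response set.

    Parameters
    ----------
    data
        A :class:`~longdcm.simulate.LongitudinalResponseSet` (or object with
        ``responses`` (N, T, I) and ``times`` (N, T)).
    qmatrix
        Defaults to ``data.design.qmatrix`` when the data carry a design.
    priors, config
        Default :class:`PriorSpec` / :class:`McmcConfig`.
    """
    if qmatrix is None:
        if getattr(data, "design", None) is None:
            raise ValueError("qmatrix required when data carry no design")
        qmatrix = data.design.qmatrix
    if data.responses.shape[1] < 2:
        raise ValueError("at least two measurement occasions are required")
    if data.responses.shape[2] != qmatrix.n_items:
        raise ValueError("response item dimension inconsistent with Q-matrix")
    priors = priors or PriorSpec()
    config = config or McmcConfig()

    k = qmatrix.n_attributes
    block = _ItemBlock(qmatrix, priors)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    per_chain = [_run_chain(data, qmatrix, block, priors, config, s) for s in seeds]

    gamma_labels = [f"gamma00[{a}]" for a in qmatrix.attribute_ids] + [
        f"gamma10[{a}]" for a in qmatrix.attribute_ids
    ]
    acc = {}
    for name in ("items", "gamma", "u"):
        tot = np.sum([ch[5][name] for ch in per_chain], axis=0)
        acc[name] = float(tot[0] / tot[1]) if tot[1] else np.nan
    return PosteriorSamples(
        item_labels=block.labels,
        item_draws=np.stack([ch[0] for ch in per_chain]),
        gamma_labels=gamma_labels,
        gamma_draws=np.stack([ch[1] for ch in per_chain]),
        g_labels=list(effect_labels(k, qmatrix.attribute_ids)),
        g_draws=np.stack([ch[2] for ch in per_chain]),
        alpha_draws=np.stack([ch[3] for ch in per_chain]),
        u_draws=np.stack([ch[4] for ch in per_chain]) if config.store_u else None,
        acceptance=acc,
        config=config,
        priors=priors,
    )


def posterior_mastery_probability(samples: PosteriorSamples) -> np.ndarray:
    """Posterior mastery probability: mean of sampled indicators, (N, T, K)."""
    if samples.alpha_draws is None or samples.alpha_draws.size == 0:
        raise ValueError("no mastery indicator draws present")
    return samples.alpha_draws.reshape(-1, *samples.alpha_draws.shape[2:]).mean(axis=0)


def classify(prob, cutpoint: float = 0.5) -> np.ndarray:
    """Mastery status: 1 iff the probability strictly exceeds the cutpoint."""
    prob = np.asarray(prob, dtype=float)
    if ((prob < 0) | (prob > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return (prob > cutpoint).astype(np.int8)
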