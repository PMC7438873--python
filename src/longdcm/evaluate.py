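"""Evaluation criteria: convergence, classification accuracy, recovery, ANOVA.

The Gelman-Rubin statistic is implemented literally as

    R_hat = (n - 1)/n + (1/n) * B / W,

with ``W`` the mean of the within-chain sample variances and ``B`` equal to
``n`` times the sample variance of the chain means (the standard
between-chain variance).  This equals the classical variance-ratio PSRF
without the square root; pass ``sqrt=True`` for the square-root convention.
The default convergence threshold is 1.2 on whichever convention is used.

Classification accuracy follows the 0.5-cutpoint rule: probability bias
against the generating probability, correct-classification rates
conditioned on the true status, and Cohen's kappa — reported as missing
whenever the true or estimated status has a single level, in which case
chance-corrected agreement is undefined.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "gelman_rubin",
    "replication_converged",
    "bias",
    "mse",
    "cohens_kappa",
    "classification_report",
    "anova_partial_eta2",
    "effect_size_label",
]

RHAT_THRESHOLD = 1.2

#: Cohen's partial eta^2 conventions: small / medium / large.
EFFECT_SIZE_THRESHOLDS = (0.01, 0.06, 0.14)


def gelman_rubin(chains, sqrt: bool = False) -> float:
    """Potential scale reduction factor over an (m, n) chains matrix.

    Degenerate case: all chains constant at a common value gives
    ``(n - 1)/n``; zero within-chain variance with nonzero between-chain
    variance is flagged as ``inf``.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be a 2-d (m, n) matrix")
    m, n = chains.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 chains of length >= 2")
    w = chains.var(axis=1, ddof=1).mean()
    b = n * chains.mean(axis=1).var(ddof=1)
    if w == 0:
        rhat = (n - 1) / n if b == 0 else np.inf
    else:
        rhat = (n - 1) / n + b / (n * w)
    return float(np.sqrt(rhat)) if sqrt else float(rhat)


def replication_converged(rhats, threshold: float = RHAT_THRESHOLD) -> bool:
    """A replication converges iff every monitored R-hat is below threshold."""
    values = np.asarray(
        list(rhats.values()) if isinstance(rhats, dict) else rhats, dtype=float
    )
    if values.size == 0:
        raise ValueError("no R-hat values supplied")
    return bool(np.all(np.isfinite(values)) and values.max() < threshold)


def _paired(estimates, truths):
    est = np.asarray(estimates, dtype=float).ravel()
    tru = np.asarray(truths, dtype=float).ravel()
    if tru.size == 1:
        tru = np.full_like(est, tru[0])
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must have matching lengths")
    return est, tru


def bias(estimates, truths) -> float:
    """Mean of (estimate - truth) over all replications x parameters."""
    est, tru = _paired(estimates, truths)
    return float((est - tru).mean())


def mse(estimates, truths) -> float:
    """Mean of (estimate - truth)^2 over all replications x parameters."""
    est, tru = _paired(estimates, truths)
    return float(((est - tru) ** 2).mean())


def cohens_kappa(truth, prediction) -> float:
    """Chance-corrected agreement between two binary ratings.

    Returns ``nan`` when either rating has a single observed level (kappa is
    then undefined) or when chance agreement is exactly 1.
    """
    truth = np.asarray(truth).ravel()
    pred = np.asarray(prediction).ravel()
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction must be aligned")
    if truth.size == 0:
        return float("nan")
    if np.unique(truth).size < 2 or np.unique(pred).size < 2:
        return float("nan")
    p_o = (truth == pred).mean()
    levels = np.union1d(np.unique(truth), np.unique(pred))
    p_e = sum((truth == lv).mean() * (pred == lv).mean() for lv in levels)
    if p_e == 1:
        return float("nan")
    return float((p_o - p_e) / (1 - p_e))


def classification_report(
    true_alpha,
    est_prob,
    cutpoint: float = 0.5,
    true_prob=None,
    attribute_ids=None,
) -> pd.DataFrame:
    """Per (attribute, occasion) classification accuracy table.

    Parameters
    ----------
    true_alpha, est_prob
        (N, T, K) true mastery indicators and posterior mastery
        probabilities.
    true_prob
        Optional (N, T, K) generating mastery probabilities; when given, the
        probability bias ``mean(est_prob - true_prob)`` is reported.
    """
    from .infer import classify

    true_alpha = np.asarray(true_alpha)
    est_prob = np.asarray(est_prob, dtype=float)
    if true_alpha.shape != est_prob.shape or true_alpha.ndim != 3:
        raise ValueError("true_alpha and est_prob must both be (N, T, K)")
    if true_prob is not None and np.asarray(true_prob).shape != est_prob.shape:
        raise ValueError("true_prob shape mismatch")
    est_status = classify(est_prob, cutpoint)
    n, t, k = true_alpha.shape
    ids = attribute_ids or [f"A{j + 1}" for j in range(k)]
    rows = []
    for occ in range(t):
        for kk in range(k):
            truth = true_alpha[:, occ, kk]
            pred = est_status[:, occ, kk]
            masters = truth == 1
            rows.append(
                {
                    "occasion": occ + 1,
                    "attribute": ids[kk],
                    "prob_bias": float((est_prob[:, occ, kk] - np.asarray(true_prob)[:, occ, kk]).mean())
                    if true_prob is not None
                    else np.nan,
                    "rate_true_masters": float(pred[masters].mean()) if masters.any() else np.nan,
                    "rate_true_nonmasters": float((1 - pred[~masters]).mean())
                    if (~masters).any()
                    else np.nan,
                    "kappa": cohens_kappa(truth, pred),
                    "n_masters": int(masters.sum()),
                    "n_nonmasters": int((~masters).sum()),
                }
            )
    return pd.DataFrame(rows)


def effect_size_label(eta2: float) -> str:
    """Cohen's convention: 0.01 small, 0.06 medium, 0.14 large."""
    small, medium, large = EFFECT_SIZE_THRESHOLDS
    if not np.isfinite(eta2) or eta2 < small:
        return "negligible"
    if eta2 < medium:
        return "small"
    if eta2 < large:
        return "medium"
    return "large"


def anova_partial_eta2(
    frame: pd.DataFrame,
    outcome: str,
    factors,
    include_interactions: bool = True,
) -> pd.DataFrame:
    """Factorial ANOVA with partial eta^2 per term.

    Fits ``outcome ~ main effects + two-way interactions`` over categorical
    factors and reports ``SS_effect / (SS_effect + SS_residual)`` for each
    term.  Factors with a single observed level are rejected.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    factors = list(factors)
    if not factors:
        raise ValueError("at least one factor required")
    data = frame[[outcome] + factors].dropna()
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    terms = [f"C({f})" for f in factors]
    if include_interactions and len(factors) > 1:
        terms += [
            f"C({a}):C({b})" for i, a in enumerate(factors) for b in factors[i + 1:]
        ]
    model = smf.ols(f"{outcome} ~ " + " + ".join(terms), data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss_resid = float(table.loc["Residual", "sum_sq"])
    # a constant outcome has no variance to apportion; guard against the
    # 0/0 float noise the decomposition would otherwise produce
    ss_total = float(((data[outcome] - data[outcome].mean()) ** 2).sum())
    degenerate = ss_total <= 1e-12 * max(1.0, float(data[outcome].abs().max()) ** 2)
    rows = []
    for term in table.index:
        if term == "Residual":
            continue
        ss = float(table.loc[term, "sum_sq"])
        if degenerate:
            eta2 = 0.0
        else:
            eta2 = ss / (ss + ss_resid) if (ss + ss_resid) > 0 else 0.0
        rows.append(
            {
                "effect": term.replace("C(", "").replace(")", ""),
                "sum_sq": ss,
                "df": float(table.loc[term, "df"]),
                "F": float(table.loc[term, "F"]),
                "p": float(table.loc[term, "PR(>F)"]),
                "partial_eta2": eta2,
                "label": effect_size_label(eta2),
            }
        )
    return pd.DataFrame(rows)
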