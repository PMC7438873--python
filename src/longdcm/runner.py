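"""Study orchestration: replicate cells of the simulation design end to end.

Each replication is generate -> fit -> diagnose; replications whose maximum
R-hat exceeds the threshold are discarded from the condition summaries (the
convergence rate itself is always reported).  Every replication's randomness
is a pure function of ``(base_seed, cell_index, replication)``, so any
single replication can be re-run in isolation and replication-level
parallelism cannot change results.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import evaluate as ev
from .infer import McmcConfig, PosteriorSamples, PriorSpec, fit, posterior_mastery_probability
from .simulate import SimulationDesign, generate

__all__ = [
    "StudyGrid",
    "derive_seed",
    "recovery_summary",
    "run_replication",
    "run_condition",
    "run_study",
    "default_grid",
]

logger = logging.getLogger(__name__)

_FACTOR_COLUMNS = ("g_design", "growth_pattern", "n_persons", "n_occasions")


def derive_seed(base_seed: int, *key) -> int:
    """Deterministic child seed (< 2^31) for a (cell, replication, stream) key."""
    state = np.random.SeedSequence([int(base_seed), *map(int, key)]).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


@dataclass(frozen=True)
class StudyGrid:
    """Factorial study: a list of design-factor cells, replicated.

    The default grid is the full 2 (G) x 2 (growth) x 3 (N) x 2 (occasions)
    factorial; the ``desk`` preset trims replications to 3 with short chains.
    """

    cells: tuple
    replications: int = 100
    base_seed: int = 0
    mcmc: McmcConfig = field(default_factory=McmcConfig)

    def __post_init__(self):
        if len(self.cells) < 1:
            raise ValueError("grid needs at least one cell")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        object.__setattr__(self, "cells", tuple(dict(c) for c in self.cells))

    @classmethod
    def desk(cls, cells=None, base_seed: int = 0, replications: int = 3) -> "StudyGrid":
        return cls(
            cells=tuple(cells) if cells is not None else default_grid(),
            replications=replications,
            base_seed=base_seed,
            mcmc=McmcConfig.desk(),
        )


def default_grid():
    return tuple(
        {"g_design": g, "growth_pattern": p, "n_persons": n, "n_occasions": t}
        for g in ("equal", "unequal")
        for p in ("even", "uneven")
        for n in (100, 200, 300)
        for t in (3, 5)
    )


def _item_truth_sets(design: SimulationDesign):
    """True values grouped into the three item-parameter sets."""
    sets = {"lambda0": [], "lambda_main": [], "lambda_interaction": []}
    for item in design.item_parameters:
        sets["lambda0"].append(item.intercept)
        sets["lambda_main"].extend(v for _, v in sorted(item.main_effects.items()))
        sets["lambda_interaction"].extend(v for _, v in sorted(item.interactions.items()))
    return {k: np.asarray(v) for k, v in sets.items() if v}


def recovery_summary(samples: PosteriorSamples, design: SimulationDesign) -> pd.DataFrame:
    """Per parameter-set error of posterior means against generating truth.

    Sets: item intercepts / mains / interactions (pooled over items), the
    per-attribute growth intercepts and slopes, and the G variances and
    covariances grouped by kind.
    """
    rows = []
    theta_hat = samples.posterior_mean_items()
    kinds = [lbl.split("[")[0] for lbl in samples.item_labels]
    kind_map = {"lambda0": "lambda0", "lambda1": "lambda_main", "lambda2": "lambda_interaction"}
    truth_sets = _item_truth_sets(design)
    for short, name in kind_map.items():
        idx = [j for j, k in enumerate(kinds) if k == short]
        if not idx or name not in truth_sets:
            continue
        est, tru = theta_hat[idx], truth_sets[name]
        rows.append({"parameter_set": name, "bias": ev.bias(est, tru), "mse": ev.mse(est, tru),
                     "n": len(idx)})

    gamma_hat = samples.posterior_mean_gamma()
    k = design.qmatrix.n_attributes
    for kk, attr in enumerate(design.qmatrix.attribute_ids):
        rows.append({"parameter_set": f"gamma00_{attr}",
                     "bias": gamma_hat[kk] - design.fixed_effects.gamma00[kk],
                     "mse": (gamma_hat[kk] - design.fixed_effects.gamma00[kk]) ** 2, "n": 1})
        rows.append({"parameter_set": f"gamma10_{attr}",
                     "bias": gamma_hat[k + kk] - design.fixed_effects.gamma10[kk],
                     "mse": (gamma_hat[k + kk] - design.fixed_effects.gamma10[kk]) ** 2, "n": 1})

    g_hat = samples.posterior_mean_g()
    g_true = design.g.covariance
    dim = g_true.shape[0]
    groups = {"g_var_intercept": [], "g_var_slope": [], "g_cov": []}
    for a in range(dim):
        for b in range(a, dim):
            pair = (g_hat[a, b], g_true[a, b])
            if a == b:
                groups["g_var_intercept" if a % 2 == 0 else "g_var_slope"].append(pair)
            else:
                groups["g_cov"].append(pair)
    for name, pairs in groups.items():
        est = np.array([p[0] for p in pairs])
        tru = np.array([p[1] for p in pairs])
        rows.append({"parameter_set": name, "bias": ev.bias(est, tru), "mse": ev.mse(est, tru),
                     "n": len(pairs)})
    return pd.DataFrame(rows)


def run_replication(
    design: SimulationDesign,
    config: McmcConfig,
    priors: PriorSpec = None,
    truth_centered_g_prior: bool = True,
    rhat_threshold: float = ev.RHAT_THRESHOLD,
) -> dict:
    """Generate one data set, fit it, and score it against the truth."""
    start = time.perf_counter()
    data = generate(design)
    priors = priors or PriorSpec()
    if truth_centered_g_prior and priors.g_scale is None:
        priors = priors.with_g_center(design.g)
    samples = fit(data, priors=priors, config=config)
    rhats = samples.gelman_rubin()
    converged = ev.replication_converged(rhats, threshold=rhat_threshold)
    est_prob = posterior_mastery_probability(samples)
    report = ev.classification_report(
        data.true_alpha, est_prob, true_prob=data.true_mastery_prob,
        attribute_ids=list(design.qmatrix.attribute_ids),
    )
    recovery = recovery_summary(samples, design)
    elapsed = time.perf_counter() - start
    rhat_max = max(rhats.values())
    logger.info(
        "replication seed=%d converged=%s max_rhat=%.3f accept=%s wall=%.1fs",
        design.seed, converged, rhat_max, samples.acceptance, elapsed,
    )
    return {
        "converged": converged,
        "max_rhat": float(rhat_max),
        "classification": report,
        "recovery": recovery,
        "acceptance": samples.acceptance,
        "wall_seconds": elapsed,
        "samples": samples,
        "data": data,
    }


def run_condition(
    cell: dict,
    replications: int,
    base_seed: int = 0,
    cell_index: int = 0,
    mcmc: McmcConfig = None,
    priors: PriorSpec = None,
    truth_centered_g_prior: bool = True,
    rhat_threshold: float = ev.RHAT_THRESHOLD,
    keep_samples: bool = False,
) -> dict:
    """Replicate one design cell and aggregate converged replications."""
    mcmc = mcmc or McmcConfig()
    reps = []
    for rep in range(replications):
        design = SimulationDesign.from_factors(
            seed=derive_seed(base_seed, cell_index, rep, 0), **cell
        )
        rep_config = replace(mcmc, seed=derive_seed(base_seed, cell_index, rep, 1))
        result = run_replication(
            design, rep_config, priors, truth_centered_g_prior, rhat_threshold
        )
        if not keep_samples:
            result.pop("samples")
            result.pop("data")
        result["replication"] = rep
        reps.append(result)

    converged = [r for r in reps if r["converged"]]
    used = converged
    summary = {
        "cell": dict(cell),
        "replications": replications,
        "n_converged": len(converged),
        "convergence_rate": len(converged) / replications,
        "per_replication": reps,
        "status": "ok" if converged else "all replications non-converged",
    }
    if used:
        cls = pd.concat([r["classification"] for r in used])
        summary["classification"] = (
            cls.groupby(["occasion", "attribute"], as_index=False)
            .mean(numeric_only=True)
            .assign(n_replications=len(used))
        )
        rec = pd.concat([r["recovery"] for r in used])
        summary["recovery"] = (
            rec.groupby("parameter_set", as_index=False)
            .mean(numeric_only=True)
            .assign(n_replications=len(used))
        )
    else:
        summary["classification"] = pd.DataFrame()
        summary["recovery"] = pd.DataFrame()
    return summary


def run_study(grid: StudyGrid, priors: PriorSpec = None, truth_centered_g_prior: bool = True,
              rhat_threshold: float = ev.RHAT_THRESHOLD, outdir=None, force: bool = False) -> dict:
    """Run every cell of the grid and assemble study-level tables.

    Returns condition summaries, concatenated classification/recovery tables
    keyed by the design factors, and factorial-ANOVA partial eta^2 tables
    for the replication-level recovery outcomes, computed separately per
    number of measurement occasions.
    """
    if outdir is not None:
        outdir = _prepare_outdir(outdir, grid, force)
    conditions = []
    cls_tables, rec_tables, rep_rows = [], [], []
    for idx, cell in enumerate(grid.cells):
        try:
            cond = run_condition(
                cell, grid.replications, base_seed=grid.base_seed, cell_index=idx,
                mcmc=grid.mcmc, priors=priors, truth_centered_g_prior=truth_centered_g_prior,
                rhat_threshold=rhat_threshold,
            )
        except Exception:  # keep going: one bad cell must not sink the study
            logger.exception("cell %d %s failed", idx, cell)
            continue
        conditions.append(cond)
        keys = {col: cell.get(col) for col in _FACTOR_COLUMNS}
        if len(cond["classification"]):
            cls_tables.append(cond["classification"].assign(**keys))
        if len(cond["recovery"]):
            rec_tables.append(cond["recovery"].assign(**keys))
        for r in cond["per_replication"]:
            if not r["converged"]:
                continue
            for _, row in r["recovery"].iterrows():
                rep_rows.append(
                    {**keys, "replication": r["replication"],
                     "parameter_set": row["parameter_set"],
                     "bias": row["bias"], "mse": row["mse"]}
                )
    out = {
        "conditions": conditions,
        "classification": pd.concat(cls_tables, ignore_index=True) if cls_tables else pd.DataFrame(),
        "recovery": pd.concat(rec_tables, ignore_index=True) if rec_tables else pd.DataFrame(),
        "anova": _study_anova(pd.DataFrame(rep_rows)),
    }
    if outdir is not None:
        out["classification"].to_csv(outdir / "classification.csv", index=False)
        out["recovery"].to_csv(outdir / "recovery.csv", index=False)
        out["anova"].to_csv(outdir / "anova.csv", index=False)
        pd.DataFrame(
            [{**c["cell"], "convergence_rate": c["convergence_rate"],
              "n_converged": c["n_converged"]} for c in conditions]
        ).to_csv(outdir / "convergence.csv", index=False)
    return out


def _study_anova(rep_frame: pd.DataFrame) -> pd.DataFrame:
    """Partial eta^2 of design factors on replication-level bias and MSE."""
    if rep_frame.empty:
        return pd.DataFrame()
    factor_names = {"g_design": "G", "growth_pattern": "GP", "n_persons": "SZ"}
    tables = []
    for occ, occ_frame in rep_frame.groupby("n_occasions"):
        factors = [f for f in factor_names if occ_frame[f].nunique() > 1]
        if not factors:
            continue
        for pset, sub in occ_frame.groupby("parameter_set"):
            for outcome in ("bias", "mse"):
                if sub[outcome].nunique() < 2 or len(sub) <= 2 * len(factors) + 1:
                    continue
                try:
                    table = ev.anova_partial_eta2(sub, outcome, factors)
                except (ValueError, KeyError):
                    continue
                table["effect"] = table["effect"].replace(
                    {k: v for k, v in factor_names.items()}
                ).str.replace("g_design", "G").str.replace("growth_pattern", "GP").str.replace(
                    "n_persons", "SZ"
                ).str.replace(":", " x ")
                table.insert(0, "outcome", outcome)
                table.insert(0, "parameter_set", pset)
                table.insert(0, "n_occasions", occ)
                tables.append(table)
    return pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()


def _prepare_outdir(outdir, grid: StudyGrid, force: bool):
    from pathlib import Path

    outdir = Path(outdir)
    manifest = outdir / "manifest.json"
    if manifest.exists() and not force:
        raise FileExistsError(f"{outdir} already holds a study (pass force=True to overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        # only the plain design factors; resolved objects are not serialized
        "cells": [
            {k: v for k, v in cell.items() if isinstance(v, (str, int, float, bool))}
            for cell in grid.cells
        ],
        "replications": grid.replications,
        "base_seed": grid.base_seed,
        "mcmc": {
            "n_chains": grid.mcmc.n_chains,
            "n_iterations": grid.mcmc.n_iterations,
            "n_burnin": grid.mcmc.n_burnin,
            "thin": grid.mcmc.thin,
        },
    }
    manifest.write_text(json.dumps(payload, indent=2))
    return outdir
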