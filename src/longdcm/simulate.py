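"""Synthetic longitudinal diagnostic-assessment data generator.

Generation proceeds in two stages mirroring the model's hierarchy:

1. structural stage — draw person-specific time scores (Normal around the
   occasion means), draw random intercepts/slopes from MVN(0, G), form each
   person-occasion-attribute mastery logit, and draw binary mastery
   indicators from the implied Bernoulli probabilities;
2. measurement stage — map each person-occasion attribute profile through
   the LCDM to per-item correct-response probabilities and draw binary item
   responses.

All randomness flows from the single ``seed`` of the
:class:`SimulationDesign`; repeated calls reproduce bit-identical data.
The generating truth (mastery indicators, probabilities, random effects) is
retained on the returned :class:`LongitudinalResponseSet` so evaluation
never has to re-derive it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import datasets
from .growth import FixedEffects, GMatrix
from .measurement import QMatrix, class_probability_table

__all__ = [
    "SimulationDesign",
    "LongitudinalResponseSet",
    "draw_time_scores",
    "draw_random_effects",
    "simulate_mastery",
    "simulate_responses",
    "generate",
]


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the simulation design, fully resolved.

    Factory :meth:`from_factors` resolves the named growth pattern and G
    design; the ``paper-default`` preset is
    ``from_factors(n_persons=100, growth_pattern="even", g_design="equal")``.
    """

    n_persons: int
    qmatrix: QMatrix
    item_parameters: tuple
    fixed_effects: FixedEffects
    g: GMatrix
    n_occasions: int = 5
    occasion_time_means: tuple = datasets.OCCASION_TIME_MEANS
    occasion_time_sd: float = datasets.OCCASION_TIME_SD
    seed: int = 0
    growth_pattern: str = "custom"
    g_design: str = "custom"

    def __post_init__(self):
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if self.n_occasions < 2:
            raise ValueError("n_occasions must be >= 2")
        if self.occasion_time_sd < 0:
            raise ValueError("occasion_time_sd must be >= 0")
        if len(self.occasion_time_means) < self.n_occasions:
            raise ValueError("not enough occasion time means for n_occasions")
        if len(self.item_parameters) != self.qmatrix.n_items:
            raise ValueError("item_parameters length must match Q-matrix items")
        if self.g.n_attributes != self.qmatrix.n_attributes:
            raise ValueError("G dimension inconsistent with Q-matrix attributes")
        if self.fixed_effects.n_attributes != self.qmatrix.n_attributes:
            raise ValueError("fixed effects inconsistent with Q-matrix attributes")
        object.__setattr__(self, "item_parameters", tuple(self.item_parameters))
        object.__setattr__(
            self, "occasion_time_means", tuple(float(m) for m in self.occasion_time_means)
        )

    @classmethod
    def from_factors(
        cls,
        n_persons: int = 100,
        growth_pattern: str = "even",
        g_design: str = "equal",
        n_occasions: int = 5,
        seed: int = 0,
        **overrides,
    ) -> "SimulationDesign":
        qmatrix = overrides.pop("qmatrix", None) or datasets.paper_qmatrix()
        items = overrides.pop("item_parameters", None) or tuple(
            datasets.build_item_parameters(qmatrix)
        )
        return cls(
            n_persons=n_persons,
            qmatrix=qmatrix,
            item_parameters=items,
            fixed_effects=datasets.fixed_effects(growth_pattern),
            g=datasets.g_matrix(g_design),
            n_occasions=n_occasions,
            seed=seed,
            growth_pattern=growth_pattern,
            g_design=g_design,
            **overrides,
        )

    @property
    def times_mean(self) -> np.ndarray:
        return np.asarray(self.occasion_time_means[: self.n_occasions])

    def with_seed(self, seed: int) -> "SimulationDesign":
        return replace(self, seed=int(seed))

    def manifest(self) -> dict:
        return {
            "n_persons": self.n_persons,
            "n_occasions": self.n_occasions,
            "n_items": self.qmatrix.n_items,
            "n_attributes": self.qmatrix.n_attributes,
            "growth_pattern": self.growth_pattern,
            "g_design": self.g_design,
            "occasion_time_means": list(self.times_mean),
            "occasion_time_sd": self.occasion_time_sd,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class LongitudinalResponseSet:
    """Binary item responses over occasions plus the generating truth.

    ``responses`` is (persons, occasions, items); ``times`` is (persons,
    occasions).  Truth block: ``true_alpha`` (persons, occasions,
    attributes), ``true_mastery_prob`` likewise, and ``true_u`` (persons,
    2K) in G's interleaved effect order.
    """

    responses: np.ndarray
    times: np.ndarray
    true_alpha: np.ndarray = None
    true_mastery_prob: np.ndarray = None
    true_u: np.ndarray = None
    design: SimulationDesign = None

    def __post_init__(self):
        responses = np.asarray(self.responses, dtype=np.int8)
        if responses.ndim != 3:
            raise ValueError("responses must be (persons, occasions, items)")
        if not np.isin(responses, (0, 1)).all():
            raise ValueError("responses must be binary")
        times = np.asarray(self.times, dtype=float)
        if times.shape != responses.shape[:2]:
            raise ValueError("times shape must match (persons, occasions)")
        object.__setattr__(self, "responses", responses)
        object.__setattr__(self, "times", times)
        if self.true_alpha is not None:
            alpha = np.asarray(self.true_alpha, dtype=np.int8)
            if alpha.shape[:2] != responses.shape[:2]:
                raise ValueError("truth block dimensions inconsistent with responses")
            object.__setattr__(self, "true_alpha", alpha)

    @property
    def shape(self):
        return self.responses.shape

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: person_id, occasion, time, item_id, response."""
        n, t, i = self.responses.shape
        item_ids = self.design.qmatrix.item_ids if self.design else range(1, i + 1)
        person, occ, item = np.meshgrid(
            np.arange(1, n + 1), np.arange(1, t + 1), np.asarray(list(item_ids)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "person_id": person.ravel(),
                "occasion": occ.ravel(),
                "time": np.repeat(self.times.ravel(), i),
                "item_id": item.ravel(),
                "response": self.responses.ravel(),
            }
        )

    def write_csv(self, directory) -> None:
        """Write responses plus sidecar truth CSVs into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_long_frame().to_csv(directory / "responses.csv", index=False)
        if self.true_alpha is not None:
            n, t, k = self.true_alpha.shape
            person, occ, attr = np.meshgrid(
                np.arange(1, n + 1), np.arange(1, t + 1), np.arange(1, k + 1), indexing="ij"
            )
            pd.DataFrame(
                {
                    "person_id": person.ravel(),
                    "occasion": occ.ravel(),
                    "attribute": attr.ravel(),
                    "alpha": self.true_alpha.ravel(),
                    "probability": self.true_mastery_prob.ravel(),
                }
            ).to_csv(directory / "truth_mastery.csv", index=False)
        if self.true_u is not None:
            labels = self.design.g.labels if self.design else None
            n, j = self.true_u.shape
            labels = labels or [f"e{idx}" for idx in range(j)]
            pd.DataFrame(
                {
                    "person_id": np.repeat(np.arange(1, n + 1), j),
                    "effect_label": np.tile(labels, n),
                    "value": self.true_u.ravel(),
                }
            ).to_csv(directory / "truth_effects.csv", index=False)

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "LongitudinalResponseSet":
        persons = np.sort(frame["person_id"].unique())
        occasions = np.sort(frame["occasion"].unique())
        items = frame["item_id"].unique()  # preserve file order
        wide = frame.pivot_table(
            index=["person_id", "occasion"], columns="item_id", values="response", sort=True
        )[items]
        responses = wide.to_numpy().reshape(persons.size, occasions.size, items.size)
        times = (
            frame.drop_duplicates(["person_id", "occasion"])
            .sort_values(["person_id", "occasion"])["time"]
            .to_numpy()
            .reshape(persons.size, occasions.size)
        )
        return cls(responses=responses, times=times)

    @classmethod
    def read_csv(cls, directory) -> "LongitudinalResponseSet":
        return cls.from_long_frame(pd.read_csv(Path(directory) / "responses.csv"))


def draw_time_scores(design: SimulationDesign, rng: np.random.Generator) -> np.ndarray:
    """Person-specific time scores ~ Normal(occasion mean, sd^2), (N, T).

    With ``occasion_time_sd=0`` every person gets the balanced design.  Times
    are drawn independently across occasions; with 8-week gaps and SD 1 the
    chance of a person's times crossing is negligible (~1e-8), but a warning
    fires if it happens.
    """
    means = design.times_mean
    times = means[None, :] + design.occasion_time_sd * rng.standard_normal(
        (design.n_persons, design.n_occasions)
    )
    if (np.diff(times, axis=1) <= 0).any():
        warnings.warn("non-monotone time scores drawn for at least one person", stacklevel=2)
    return times


def draw_random_effects(g: GMatrix, n_persons: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. MVN(0, G) person random effects, (N, 2K) in G's effect order."""
    return rng.multivariate_normal(
        np.zeros(g.covariance.shape[0]), g.covariance, size=n_persons, method="eigh"
    )


def simulate_mastery(
    fixed: FixedEffects, u: np.ndarray, times: np.ndarray, rng: np.random.Generator
):
    """Draw mastery indicators; returns (alpha, probability), both (N, T, K)."""
    u = np.asarray(u, dtype=float)
    times = np.asarray(times, dtype=float)
    u0, u1 = u[:, 0::2], u[:, 1::2]
    logit = (fixed.gamma00[None, None, :] + u0[:, None, :]) + (
        fixed.gamma10[None, None, :] + u1[:, None, :]
    ) * times[:, :, None]
    prob = expit(logit)
    alpha = (rng.random(prob.shape) < prob).astype(np.int8)
    return alpha, prob


def simulate_responses(
    alpha: np.ndarray,
    qmatrix: QMatrix,
    item_parameters,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw binary item responses given mastery profiles; (N, T, I)."""
    alpha = np.asarray(alpha, dtype=int)
    if alpha.shape[-1] != qmatrix.n_attributes:
        raise ValueError("alpha attribute dimension inconsistent with Q-matrix")
    # correct-response probability per latent class, then index by profile class
    table = np.stack(
        [
            class_probability_table(item, qmatrix.entries[i])
            for i, item in enumerate(item_parameters)
        ],
        axis=1,
    )  # (2^K, I)
    weights = 2 ** np.arange(qmatrix.n_attributes)
    classes = alpha @ weights  # (N, T)
    prob = table[classes]  # (N, T, I)
    return (rng.random(prob.shape) < prob).astype(np.int8)


def generate(design: SimulationDesign) -> LongitudinalResponseSet:
    """Run the full two-stage generator for one design cell."""
    rng = np.random.default_rng(design.seed)
    times = draw_time_scores(design, rng)
    u = draw_random_effects(design.g, design.n_persons, rng)
    alpha, prob = simulate_mastery(design.fixed_effects, u, times, rng)
    responses = simulate_responses(alpha, design.qmatrix, design.item_parameters, rng)
    return LongitudinalResponseSet(
        responses=responses,
        times=times,
        true_alpha=alpha,
        true_mastery_prob=prob,
        true_u=u,
        design=design,
    )
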