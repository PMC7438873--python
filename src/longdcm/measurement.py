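"""Log-linear cognitive diagnosis model (LCDM) item-response kernel.

The LCDM expresses the log-odds of a correct response to item *i* as an
intercept plus main effects for each attribute the item measures (declared
by the Q-matrix) plus a two-way interaction when the item measures two
attributes::

    logit P(X_i = 1 | alpha) = lambda_i0
        + sum_k lambda_i1k * alpha_k * q_ik
        + sum_{k<k'} lambda_i2kk' * alpha_k * alpha_k' * q_ik * q_ik'

Attribute profiles ``alpha`` are plain binary vectors of length K.  Latent
classes are the 2^K binary profiles enumerated in a fixed canonical order
with attribute 1 as the fastest-varying bit, i.e. class index
``c = sum_k alpha_k * 2**k``; that ordering is used everywhere posterior
output is tabulated so runs are comparable.

Monotonicity (mastery never lowers the success probability) is enforced at
construction: main effects must be nonnegative and each two-way interaction
must be at least minus the smaller of its two main effects.  Pass
``enforce_monotone=False`` to :class:`ItemParameters` for research use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "QMatrix",
    "ItemParameters",
    "enumerate_profiles",
    "response_probability",
    "class_probability_table",
    "reduce_to_dina",
    "read_item_parameters",
    "write_item_parameters",
]

MAX_ATTRIBUTES = 10  # cap for full latent-class enumeration (2^K classes)


@dataclass(frozen=True)
class QMatrix:
    """Items x attributes binary incidence matrix.

    Parameters
    ----------
    entries
        (I, K) array of 0/1; row i declares which attributes item i measures.
    item_ids, attribute_ids
        Optional labels; defaults are ``1..I`` and ``A1..AK``.
    """

    entries: np.ndarray
    item_ids: tuple = field(default=None)
    attribute_ids: tuple = field(default=None)

    def __post_init__(self):
        entries = np.asarray(self.entries, dtype=int)
        if entries.ndim != 2:
            raise ValueError("Q-matrix must be 2-dimensional (items x attributes)")
        if not np.isin(entries, (0, 1)).all():
            raise ValueError("Q-matrix entries must be 0 or 1")
        if (entries.sum(axis=1) < 1).any():
            raise ValueError("every item must measure at least one attribute")
        object.__setattr__(self, "entries", entries)
        if self.item_ids is None:
            object.__setattr__(self, "item_ids", tuple(range(1, entries.shape[0] + 1)))
        else:
            object.__setattr__(self, "item_ids", tuple(self.item_ids))
        if self.attribute_ids is None:
            object.__setattr__(
                self, "attribute_ids", tuple(f"A{k + 1}" for k in range(entries.shape[1]))
            )
        else:
            object.__setattr__(self, "attribute_ids", tuple(self.attribute_ids))
        if len(self.item_ids) != entries.shape[0]:
            raise ValueError("item_ids length mismatch")
        if len(self.attribute_ids) != entries.shape[1]:
            raise ValueError("attribute_ids length mismatch")

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    def measured(self, item: int) -> np.ndarray:
        """Indices of the attributes measured by item ``item`` (0-based)."""
        return np.flatnonzero(self.entries[item])

    @classmethod
    def from_csv(cls, path) -> "QMatrix":
        frame = pd.read_csv(path)
        return cls(
            entries=frame.iloc[:, 1:].to_numpy(dtype=int),
            item_ids=tuple(frame.iloc[:, 0]),
            attribute_ids=tuple(frame.columns[1:]),
        )

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(self.entries, columns=list(self.attribute_ids))
        frame.insert(0, "item", list(self.item_ids))
        frame.to_csv(path, index=False)


@dataclass(frozen=True)
class ItemParameters:
    """LCDM coefficients for one item, keyed by 0-based attribute index.

    ``main_effects`` maps attribute index -> coefficient; ``interactions``
    maps a sorted attribute-index pair -> coefficient.  Parameters may only
    reference attributes the item's Q-matrix row assigns to it (checked by
    :func:`response_probability` and friends against the row supplied).
    """

    intercept: float
    main_effects: dict = field(default_factory=dict)
    interactions: dict = field(default_factory=dict)
    enforce_monotone: bool = True

    def __post_init__(self):
        mains = {int(k): float(v) for k, v in self.main_effects.items()}
        inters = {tuple(sorted(int(a) for a in pair)): float(v)
                  for pair, v in self.interactions.items()}
        object.__setattr__(self, "intercept", float(self.intercept))
        object.__setattr__(self, "main_effects", mains)
        object.__setattr__(self, "interactions", inters)
        for pair in inters:
            if len(pair) != 2 or pair[0] == pair[1]:
                raise ValueError(f"interaction key must be a pair of distinct attributes: {pair}")
            if not set(pair) <= set(mains):
                raise ValueError(f"interaction {pair} references attribute without a main effect")
        if self.enforce_monotone:
            for k, v in mains.items():
                if v < 0:
                    raise ValueError(f"main effect for attribute {k} is negative ({v})")
            for pair, v in inters.items():
                bound = -min(mains[pair[0]], mains[pair[1]])
                if v < bound:
                    raise ValueError(
                        f"interaction {pair}={v} below monotonicity bound {bound}"
                    )

    @property
    def measured_attributes(self) -> tuple:
        return tuple(sorted(self.main_effects))

    def check_qrow(self, qrow: np.ndarray) -> None:
        qrow = np.asarray(qrow, dtype=int)
        measured = set(np.flatnonzero(qrow).tolist())
        if not set(self.main_effects) <= measured:
            extra = set(self.main_effects) - measured
            raise ValueError(f"main effect(s) for attribute(s) {sorted(extra)} not in Q-matrix row")
        for pair in self.interactions:
            if not set(pair) <= measured:
                raise ValueError(f"interaction {pair} references attribute with q=0")


def enumerate_profiles(n_attributes: int) -> np.ndarray:
    """All 2^K binary profiles in canonical order (attribute 1 fastest-varying).

    Row ``c`` holds the profile of latent class ``c``; column ``k`` equals
    bit ``k`` of ``c``.
    """
    if n_attributes > MAX_ATTRIBUTES:
        raise ValueError(f"n_attributes={n_attributes} exceeds cap {MAX_ATTRIBUTES}")
    classes = np.arange(2 ** n_attributes)
    return (classes[:, None] >> np.arange(n_attributes)[None, :]) & 1


def _item_logit(item: ItemParameters, profiles: np.ndarray) -> np.ndarray:
    """Linear predictor for one item over an array of profiles (..., K)."""
    logit = np.full(profiles.shape[:-1], item.intercept, dtype=float)
    for k, lam in item.main_effects.items():
        logit += lam * profiles[..., k]
    for (k, kp), lam in item.interactions.items():
        logit += lam * profiles[..., k] * profiles[..., kp]
    return logit


def response_probability(item: ItemParameters, profile, qrow) -> float:
    """Probability of a correct response given an attribute profile.

    The result depends only on the measured attributes: entries of
    ``profile`` where the Q-matrix row is 0 are ignored by construction.
    """
    profile = np.asarray(profile, dtype=int)
    qrow = np.asarray(qrow, dtype=int)
    if profile.shape != qrow.shape:
        raise ValueError(f"profile length {profile.shape} != Q-matrix row length {qrow.shape}")
    item.check_qrow(qrow)
    return float(expit(_item_logit(item, profile)))


def class_probability_table(item: ItemParameters, qrow, max_attributes: int = MAX_ATTRIBUTES):
    """Correct-response probability for every latent class, canonical order."""
    qrow = np.asarray(qrow, dtype=int)
    if qrow.size > max_attributes:
        raise ValueError(f"K={qrow.size} exceeds cap {max_attributes}")
    item.check_qrow(qrow)
    profiles = enumerate_profiles(qrow.size)
    return expit(_item_logit(item, profiles))


def reduce_to_dina(item: ItemParameters) -> ItemParameters:
    """DINA submodel: zero the main effects so only full mastery helps.

    Only defined for items measuring at least two attributes; for a
    single-attribute item the LCDM has no distinct DINA reduction.
    """
    if len(item.main_effects) < 2:
        raise ValueError("DINA reduction requires an item measuring >= 2 attributes")
    return replace(item, main_effects={k: 0.0 for k in item.main_effects})


# -- CSV interchange ---------------------------------------------------------
# Columns: item, parameter_type (intercept|main|interaction), attributes
# ("" | "2" | "1,3"; 1-based in files), value.

def write_item_parameters(items, path, item_ids=None) -> None:
    rows = []
    ids = item_ids if item_ids is not None else range(1, len(items) + 1)
    for item_id, item in zip(ids, items):
        rows.append((item_id, "intercept", "", item.intercept))
        for k, v in sorted(item.main_effects.items()):
            rows.append((item_id, "main", str(k + 1), v))
        for pair, v in sorted(item.interactions.items()):
            rows.append((item_id, "interaction", f"{pair[0] + 1},{pair[1] + 1}", v))
    pd.DataFrame(rows, columns=["item", "parameter_type", "attributes", "value"]).to_csv(
        path, index=False
    )


def read_item_parameters(path, enforce_monotone: bool = True):
    frame = pd.read_csv(path, dtype={"attributes": str}, keep_default_na=False)
    items = []
    for _, group in frame.groupby("item", sort=False):
        intercept = 0.0
        mains, inters = {}, {}
        for _, row in group.iterrows():
            kind = row["parameter_type"]
            if kind == "intercept":
                intercept = float(row["value"])
            elif kind == "main":
                mains[int(row["attributes"]) - 1] = float(row["value"])
            elif kind == "interaction":
                a, b = (int(s) - 1 for s in str(row["attributes"]).split(","))
                inters[(a, b)] = float(row["value"])
            else:
                raise ValueError(f"unknown parameter_type {kind!r}")
        items.append(ItemParameters(intercept, mains, inters, enforce_monotone=enforce_monotone))
    return items
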