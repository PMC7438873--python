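"""Packaged study-design fixtures: Q-matrix, G matrices, fixed effects, items.

These encode the reference simulation design: 3 attributes measured by 30
binary items (each item measuring one or two attributes, 15 items per
attribute), two growth patterns (``even``: all attributes improve; ``uneven``:
attribute 1 flat), and two random-effect covariance structures
(``equal`` / ``unequal`` correlation).  Intercept variances are 0.15 and
slope variances 0.05 throughout; covariances are built exactly from the
correlation fixtures via :func:`longdcm.growth.corr_to_cov`.

Note on the unequal-correlation structure: the two published renderings of
this matrix disagree in one cell, and only the rendering with the
attribute-1/attribute-3 intercept correlation at 0.90 is positive definite;
that rendering is the one shipped here (a correlation matrix that is not PSD
cannot generate multivariate-normal effects).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .growth import FixedEffects, GMatrix, corr_to_cov
from .measurement import ItemParameters, QMatrix

__all__ = [
    "paper_qmatrix",
    "g_matrix",
    "correlation_matrix",
    "fixed_effects",
    "build_item_parameters",
    "OCCASION_TIME_MEANS",
    "OCCASION_TIME_SD",
]

#: Occasion means of the time variable, in weeks (8-week interim-assessment spacing).
OCCASION_TIME_MEANS = (0.0, 8.0, 16.0, 24.0, 32.0)
#: Person-level scatter of time scores around each occasion mean, in weeks.
OCCASION_TIME_SD = 1.0

_DATA = resources.files("longdcm") / "data"


def _read(name: str) -> pd.DataFrame:
    with (_DATA / name).open() as fh:
        return pd.read_csv(fh)


def paper_qmatrix() -> QMatrix:
    """The 30-item x 3-attribute complex-structure Q-matrix."""
    frame = _read("qmatrix_30x3.csv")
    return QMatrix(
        entries=frame.iloc[:, 1:].to_numpy(dtype=int),
        item_ids=tuple(frame["item"]),
        attribute_ids=tuple(frame.columns[1:]),
    )


def correlation_matrix(design: str) -> np.ndarray:
    """Random-effect correlation matrix for design ``'equal'`` or ``'unequal'``."""
    if design not in ("equal", "unequal"):
        raise ValueError(f"unknown G design {design!r} (expected 'equal' or 'unequal')")
    with (_DATA / f"corr_{design}.csv").open() as fh:
        return pd.read_csv(fh, index_col=0).to_numpy(dtype=float)


def g_matrix(design: str) -> GMatrix:
    """Random-effect covariance matrix G for design ``'equal'`` or ``'unequal'``."""
    corr = correlation_matrix(design)
    variances = _read("variances.csv")["variance"].to_numpy(dtype=float)
    return corr_to_cov(corr, variances)


def fixed_effects(pattern: str) -> FixedEffects:
    """Growth fixed effects for pattern ``'even'`` or ``'uneven'``."""
    if pattern not in ("even", "uneven"):
        raise ValueError(f"unknown growth pattern {pattern!r} (expected 'even' or 'uneven')")
    frame = _read(f"fixed_effects_{pattern}.csv")
    return FixedEffects(
        gamma00=frame["gamma00"].to_numpy(),
        gamma10=frame["gamma10"].to_numpy(),
        attribute_ids=tuple(frame["attribute"]),
    )


def build_item_parameters(
    qmatrix: QMatrix, intercept: float = -1.5, main: float = 1.5, interaction: float = 0.5
):
    """Homogeneous item parameters for every item of a Q-matrix.

    Defaults give correct-response probabilities of 0.18 (no mastery), 0.50
    (one required attribute mastered) and 0.88 (both mastered).
    """
    items = []
    for i in range(qmatrix.n_items):
        measured = qmatrix.measured(i)
        mains = {int(k): main for k in measured}
        inters = {}
        if measured.size == 2:
            inters[(int(measured[0]), int(measured[1]))] = interaction
        elif measured.size > 2:
            raise ValueError("reference design caps items at two attributes")
        items.append(ItemParameters(intercept, mains, inters))
    return items
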