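"""Weighting-scheme calibration by exhaustive grid search scored with the
Matthews correlation coefficient.

Each case carries one binary call per characteristic (aberrant-like vs
allele-specific-like).  Seven characteristics are defined; four apply to
natural sites (1 natural dRi, 4 expression evidence, 5 heterozygosity,
6 tissue expression) and six to cryptic sites (2 cryptic dRi, 3 cryptic Ri
vs the cognate natural site, 4, 5, 6, 7 distance to the natural site).
A weighting scheme assigns each characteristic a weight from the 0.2-step
grid {0, 0.2, ..., 1.0}; the weighted majority of calls predicts the label
and the grid is searched exhaustively for the scheme with maximal MCC
against a labelled truth set.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

ABERRANT_LIKE = "aberrant"
ALLELE_SPECIFIC_LIKE = "allele_specific"

NATURAL_CHARACTERISTICS = (1, 4, 5, 6)
CRYPTIC_CHARACTERISTICS = (2, 3, 4, 5, 6, 7)
WEIGHT_GRID = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

CHARACTERISTIC_NAMES = {
    1: "natural site delta Ri",
    2: "cryptic site delta Ri",
    3: "cryptic Ri vs nearest cognate natural Ri",
    4: "expression evidence (count/p-values)",
    5: "heterozygosity",
    6: "tissue expression level",
    7: "cryptic distance to natural site",
}


@dataclass(frozen=True)
class CharacteristicCall:
    characteristic: int
    call: str  # ABERRANT_LIKE | ALLELE_SPECIFIC_LIKE

    def __post_init__(self) -> None:
        if self.characteristic not in CHARACTERISTIC_NAMES:
            raise ValueError(f"unknown characteristic {self.characteristic}")
        if self.call not in (ABERRANT_LIKE, ALLELE_SPECIFIC_LIKE):
            raise ValueError(f"unknown call {self.call!r}")

    @property
    def sign(self) -> int:
        return 1 if self.call == ABERRANT_LIKE else -1


@dataclass
class WeightScheme:
    weights: Mapping[int, float]
    mcc: float | None = None

    def __post_init__(self) -> None:
        for w in self.weights.values():
            if not any(math.isclose(w, g) for g in WEIGHT_GRID):
                raise ValueError(f"weight {w} not on the 0.2-step grid")
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError("at least one weight must be positive")


def weighted_majority(
    calls: Sequence[CharacteristicCall], scheme: WeightScheme
) -> str:
    """Class with the greater summed weight; ties resolve conservatively to
    the allele-specific-like class."""
    applicable = [c for c in calls if c.characteristic in scheme.weights]
    if not applicable:
        raise ValueError("scheme covers none of the provided characteristics")
    total = sum(scheme.weights[c.characteristic] * c.sign for c in applicable)
    if all(scheme.weights[c.characteristic] == 0 for c in applicable):
        raise ValueError("all applicable weights are zero")
    return ABERRANT_LIKE if total > 0 else ALLELE_SPECIFIC_LIKE


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient with the zero-denominator-is-zero
    convention."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion-matrix counts must be nonnegative")
    if tp + fp + tn + fn == 0:
        raise ValueError("empty confusion matrix")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclass(frozen=True)
class LabeledCase:
    """Per-characteristic calls plus the truth label for one case."""

    calls: Mapping[int, str]  # characteristic id -> call
    label: str  # ABERRANT_LIKE | ALLELE_SPECIFIC_LIKE


def grid_search_weights(
    cases: Sequence[LabeledCase],
    site_type: str,
    characteristics: Sequence[int] | None = None,
) -> WeightScheme:
    """Exhaustive 0.2-step grid search for the MCC-maximal weighting scheme.

    ``site_type`` selects the characteristic set ("natural": 4
    characteristics, 6^4 schemes; "cryptic": 6, 6^6 schemes); the all-zero
    scheme is excluded.  Ties resolve to the scheme with fewest nonzero
    weights (predictions are invariant under scaling all weights, so the
    sparsest representative is canonical), then to the lexicographically
    greatest weight vector, making the result independent of case order.
    """
    if characteristics is None:
        characteristics = (
            NATURAL_CHARACTERISTICS if site_type == "natural" else CRYPTIC_CHARACTERISTICS
        )
    labels = np.array([1 if c.label == ABERRANT_LIKE else -1 for c in cases])
    if len(set(labels.tolist())) < 2:
        raise ValueError("labels must contain both classes")
    call_matrix = np.array(
        [[1 if c.calls[k] == ABERRANT_LIKE else -1 for k in characteristics] for c in cases],
        dtype=float,
    )

    grid = np.array(
        [w for w in itertools.product(WEIGHT_GRID, repeat=len(characteristics)) if any(w)]
    )
    scores = call_matrix @ grid.T  # (n_cases, n_schemes)
    preds = np.where(scores > 0, 1, -1)  # ties -> allele-specific-like

    pos = labels == 1
    tp = (preds[pos] == 1).sum(axis=0)
    fn = (preds[pos] == -1).sum(axis=0)
    fp = (preds[~pos] == 1).sum(axis=0)
    tn = (preds[~pos] == -1).sum(axis=0)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(invalid="ignore", divide="ignore"):
        mccs = np.where(
            denom > 0, (tp * tn - fp * fn) / np.sqrt(denom.astype(float)), 0.0
        )

    best = mccs.max()
    tied = np.flatnonzero(np.isclose(mccs, best))
    # fewest nonzero weights, then lexicographically greatest weight vector
    order = sorted(tied, key=lambda i: ((grid[i] > 0).sum(), tuple(-grid[i])))
    winner = order[0]
    return WeightScheme(
        weights={k: float(w) for k, w in zip(characteristics, grid[winner])},
        mcc=float(mccs[winner]),
    )
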