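"""Baseline coronary flow and its distribution among tree outlets.

Total resting coronary flow is taken as a fixed fraction (default 4.5%) of
cardiac output.  Two distribution criteria are provided: distal Murray
(outlet flow proportional to outlet diameter raised to an exponent,
classically 3) and a vessel-length stem-and-crown rule (outlet flow
proportional to the cumulative length of the crown it feeds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synthetic import CoronaryTree

Q_COR_FRACTION_OF_CO = 0.045  # resting coronary flow as a fraction of CO
L_MIN_TO_ML_S = 1000.0 / 60.0


@dataclass(frozen=True)
class FlowAllocation:
    """Per-outlet baseline flow split.

    ``fractions`` sum to one; ``outlet_flows`` (mL/s) sum to ``q_cor_ml_s``.
    """

    q_cor_ml_s: float
    outlet_ids: tuple[int, ...]
    fractions: np.ndarray
    outlet_flows: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.fractions <= 0) or np.any(self.outlet_flows < 0):
            raise ValueError("allocation entries must be positive")
        if abs(self.fractions.sum() - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1 within 1e-12")
        if self.q_cor_ml_s > 0 and abs(self.outlet_flows.sum() - self.q_cor_ml_s) > 1e-10 * self.q_cor_ml_s:
            raise ValueError("outlet flows must sum to q_cor within 1e-10 relative")


def total_coronary_flow(co_l_min: float, fraction: float = Q_COR_FRACTION_OF_CO) -> float:
    """Resting coronary inflow in mL/s from cardiac output in L/min."""
    if co_l_min < 0:
        raise ValueError("cardiac output cannot be negative")
    return fraction * co_l_min * L_MIN_TO_ML_S


def murray_fractions(outlet_diameters_cm: Sequence[float], exponent: float = 3.0) -> np.ndarray:
    """Flow weights proportional to outlet diameter ** exponent."""
    d = np.asarray(outlet_diameters_cm, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one outlet diameter")
    if np.any(d <= 0):
        raise ValueError("outlet diameters must be positive")
    if not 2.0 <= exponent <= 3.0:
        warnings.warn(f"Murray exponent {exponent} outside the usual [2, 3] range", stacklevel=2)
    w = d**exponent
    return w / w.sum()


def crown_lengths(tree: CoronaryTree) -> dict[int, float]:
    """Crown length of each outlet: summed length of all segments distal to
    and including the outlet's terminal segment.  For a tree with no
    structure beyond its terminals this is the terminal segment length."""
    return {
        sid: _subtree_length(tree, sid) for sid in tree.outlet_ids
    }


def _subtree_length(tree: CoronaryTree, segment_id: int) -> float:
    total = tree.segments[segment_id].length_cm
    for child in tree.children(segment_id):
        total += _subtree_length(tree, child)
    return total


def crown_length_fractions(tree: CoronaryTree) -> np.ndarray:
    """Stem-and-crown flow weights: outlet weight proportional to its crown
    length, ordered by ``tree.outlet_ids``."""
    lengths = crown_lengths(tree)
    w = np.array([lengths[sid] for sid in tree.outlet_ids], dtype=float)
    if w.sum() <= 0:
        raise ValueError("total crown length must be positive")
    return w / w.sum()


def outlet_diameters(tree: CoronaryTree) -> np.ndarray:
    """Healthy lumen diameters of the terminal segments, ordered by id."""
    return np.array([2.0 * tree.segments[sid].radius_cm for sid in tree.outlet_ids])


def distribution_weights(tree: CoronaryTree, method: str = "murray", murray_exponent: float = 3.0) -> np.ndarray:
    """Outlet flow weights for the requested distribution criterion."""
    if method == "murray":
        return murray_fractions(outlet_diameters(tree), exponent=murray_exponent)
    if method == "length_based":
        return crown_length_fractions(tree)
    raise ValueError(f"unknown flow distribution method {method!r}")


def allocate(q_cor_ml_s: float, weights: Sequence[float], outlet_ids: Sequence[int]) -> FlowAllocation:
    """Split total coronary flow among outlets by the given weights.

    Weights off unity by less than 1e-9 are renormalized silently.
    """
    w = np.asarray(weights, dtype=float)
    ids = tuple(outlet_ids)
    if w.size != len(ids):
        raise ValueError(f"{w.size} weights for {len(ids)} outlets")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    s = w.sum()
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {s}, not 1")
    w = w / s
    return FlowAllocation(
        q_cor_ml_s=q_cor_ml_s,
        outlet_ids=ids,
        fractions=w,
        outlet_flows=q_cor_ml_s * w,
    )
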