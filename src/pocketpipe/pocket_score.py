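"""Conservation-enrichment scoring of candidate pockets.

The nomination statistic compares the heavy atoms lining a pocket (P_a) that
belong to residues conserved with respect to a reference ligand-binding
domain (observed conserved atoms, OP_c) against the count expected if
conservation were spread uniformly over the protein:

    EP_c = TC_a * P_a / T_a

where TC_a is the total conserved heavy-atom count of the protein and T_a
its total heavy-atom count. Each pocket is summarized by the enrichment
ratio OP_c/EP_c, the Poisson probability mass at OP_c with mean EP_c,

    p = exp(-EP_c) * EP_c**OP_c / OP_c!

and a Poisson descriptor evaluated at the (generally non-integer) ratio,

    d = lam**r * exp(-lam) / Gamma(r + 1),   r = OP_c/EP_c,

with lam the mean ratio over the candidate set. The pocket with the highest
ratio (ties: lowest p, largest P_a, pocket_id) is nominated as the binding
pocket.

Note the Poisson mass is used as a descriptor exactly as defined above; it is
not a calibrated tail probability. An upper-tail mode P(X >= OP_c) is
available for users who want one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, xlogy

from .conservation import ConservationMap
from .pocket_consensus import PocketPrediction
from .structio import Structure, count_atoms

__all__ = [
    "PocketConservationScore",
    "pocket_atom_count",
    "expected_conservation",
    "poisson_pvalue",
    "poisson_descriptor",
    "score_pockets",
    "select_binding_pocket",
    "score_table",
]


class NoConservationError(ValueError):
    """Every candidate pocket has zero expected conservation."""


@dataclass
class PocketConservationScore:
    pocket: PocketPrediction
    p_a: int
    op_c: int
    ep_c: float
    ratio: float  # nan when ep_c == 0
    poisson_p: float
    descriptor: float
    selected: bool = False

    @property
    def ratio_defined(self) -> bool:
        return math.isfinite(self.ratio)


def pocket_atom_count(pocket: PocketPrediction, s: Structure) -> int:
    """Heavy atoms lining the pocket, P_a.

    When the detector reported explicit lining atoms, those (heavy only) are
    counted; otherwise all heavy atoms of the lining residues.
    """
    if pocket.lining_atoms is not None:
        n = 0
        for chain, num, icode, name in pocket.lining_atoms:
            rid = (chain, num, icode)
            if rid not in s.residue_index:
                raise KeyError(f"residue {rid} not in structure")
            for i in s.residue_index[rid]:
                a = s.atoms[i]
                if a.atom_name == name and not a.is_hydrogen:
                    n += 1
                    break
        return n
    return count_atoms(s, pocket.lining_residues)


def expected_conservation(tc_a: int, p_a: int, t_a: int) -> float:
    """EP_c = TC_a * P_a / T_a."""
    if t_a <= 0:
        raise ValueError("t_a must be positive")
    if not (0 <= tc_a <= t_a) or not (0 <= p_a <= t_a):
        raise ValueError("require 0 <= tc_a, p_a <= t_a")
    return tc_a * p_a / t_a


def poisson_pvalue(op_c: int, ep_c: float, mode: str = "pmf") -> float:
    """Poisson mass (default) or upper tail of OP_c under mean EP_c.

    The pmf is evaluated through log-gamma, so counts up to ~1e6 neither
    overflow nor lose the leading digits.
    """
    if op_c < 0:
        raise ValueError("op_c must be non-negative")
    if not (ep_c > 0) or not math.isfinite(ep_c):
        raise ValueError("ep_c must be positive and finite")
    if mode == "pmf":
        return float(np.exp(xlogy(op_c, ep_c) - ep_c - gammaln(op_c + 1)))
    if mode == "upper_tail":
        return float(stats.poisson.sf(op_c - 1, ep_c))
    raise ValueError(f"unknown mode {mode!r}")


def poisson_descriptor(ratio: float, lam: float) -> float:
    """lam**ratio * exp(-lam) / Gamma(ratio + 1) for non-integer ratios."""
    if not (ratio > 0) or not (lam > 0):
        raise ValueError("ratio and lam must be positive")
    return float(np.exp(ratio * math.log(lam) - lam - gammaln(ratio + 1)))


def _observed_conserved_atoms(pocket: PocketPrediction, s: Structure, cmap: ConservationMap) -> int:
    """OP_c: heavy pocket atoms belonging to conserved/identical residues."""
    if pocket.lining_atoms is not None:
        n = 0
        for chain, num, icode, name in pocket.lining_atoms:
            rid = (chain, num, icode)
            if rid not in cmap.conserved_residues:
                continue
            for i in s.residue_index.get(rid, ()):
                a = s.atoms[i]
                if a.atom_name == name and not a.is_hydrogen:
                    n += 1
                    break
        return n
    conserved_lining = {r for r in pocket.lining_residues if r in cmap.conserved_residues}
    return count_atoms(s, conserved_lining) if conserved_lining else 0


def score_pockets(
    pockets: list[PocketPrediction],
    s: Structure,
    cmap: ConservationMap,
    p_mode: str = "pmf",
    lam: Optional[float] = None,
) -> list[PocketConservationScore]:
    """Score every candidate pocket and flag the nominated one.

    ``lam`` for the descriptor defaults to the mean of the defined
    OP_c/EP_c ratios over this candidate set (the population mean).
    """
    if not pockets:
        raise ValueError("no pockets to score")
    t_a = count_atoms(s)
    scores: list[PocketConservationScore] = []
    for pocket in pockets:
        p_a = pocket_atom_count(pocket, s)
        op_c = _observed_conserved_atoms(pocket, s, cmap)
        ep_c = expected_conservation(cmap.tc_a, p_a, t_a)
        ratio = op_c / ep_c if ep_c > 0 else math.nan
        p = poisson_pvalue(op_c, ep_c, mode=p_mode) if ep_c > 0 else math.nan
        scores.append(
            PocketConservationScore(
                pocket=pocket, p_a=p_a, op_c=op_c, ep_c=ep_c,
                ratio=ratio, poisson_p=p, descriptor=math.nan,
            )
        )

    ratios = [sc.ratio for sc in scores if sc.ratio_defined and sc.ratio > 0]
    if lam is None and ratios:
        lam = float(np.mean(ratios))
    if lam is not None and lam > 0:
        for sc in scores:
            if sc.ratio_defined and sc.ratio > 0:
                sc.descriptor = poisson_descriptor(sc.ratio, lam)

    best = select_binding_pocket(scores, _mark=False)
    for sc in scores:
        sc.selected = sc is best
    return scores


def select_binding_pocket(
    scores: list[PocketConservationScore], _mark: bool = True
) -> PocketConservationScore:
    """Nominate the pocket with the highest OP_c/EP_c ratio.

    Ties are broken by lowest Poisson p, then largest P_a, then pocket_id.
    Raises :class:`NoConservationError` when no pocket has EP_c > 0 (the
    reference domain shares nothing with the target).
    """
    if not scores:
        raise ValueError("empty score list")
    defined = [sc for sc in scores if sc.ratio_defined]
    if not defined:
        raise NoConservationError("all pockets have EP_c = 0; no conservation signal")
    best = min(
        defined,
        key=lambda sc: (-sc.ratio, sc.poisson_p, -sc.p_a, sc.pocket.pocket_id),
    )
    if _mark:
        for sc in scores:
            sc.selected = sc is best
    return best


def score_table(scores: list[PocketConservationScore]) -> pd.DataFrame:
    """Ranked table (best first) of all conservation statistics per pocket."""
    rows = [
        {
            "method": sc.pocket.method,
            "pocket_id": sc.pocket.pocket_id,
            "p_a": sc.p_a,
            "op_c": sc.op_c,
            "ep_c": sc.ep_c,
            "ratio": sc.ratio,
            "poisson_p": sc.poisson_p,
            "descriptor": sc.descriptor,
            "selected": sc.selected,
        }
        for sc in scores
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        by=["ratio", "poisson_p"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
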