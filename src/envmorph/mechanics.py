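"""Outer-membrane mechanics from plasmolysis/lysis and spheroplast data.

The plasmolysis/lysis assay measures each cell's length in three states:
turgid (l1), plasmolyzed after a hyperosmotic shock (l2), and lysed after
detergent removes the outer membrane (l3).  The relative contractions

    eps12 = (l1 - l2) / l2,   eps23 = (l2 - l3) / l3,   eps13 = (l1 - l3) / l3

compose as (1 + eps13) = (1 + eps12)(1 + eps23).  Treating the OM and the
cell wall as springs in series, the OM stiffness relative to the wall is
estimated from population-mean contractions as

    k_OM / k_CW = <eps23> / ( <eps12> * (1 + <eps23>) ).

The OM rest length of a cell is the length the membrane would have if
reshaped into a rod of the cell's width w, obtained from membrane-area
conservation:

    l_OM = l_turgid + (A_OM - A_turgid) / (pi * w),

where A_turgid is the turgid cell's surface of revolution and A_OM the
membrane area of its flattened spheroplast, A_OM = 2a + w*s (two flat
faces of projected area a plus a side wall of height w along perimeter s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .synthetic import PlasmolysisTriplet, SpheroplastShape

__all__ = [
    "StrainSet", "StiffnessEstimate", "RestLengthResult",
    "strains", "stiffness_ratio", "om_surface_area", "om_rest_length",
    "plasmolyzed_ratio", "percent_stiffness_reduction",
]


@dataclass(frozen=True)
class StrainSet:
    """Relative length contractions of one cell; eps23/eps13 None if l3 absent."""

    eps12: float
    eps23: Optional[float]
    eps13: Optional[float]
    #: True when l2 > l1 (negative eps12); kept, not dropped
    flagged: bool = False


@dataclass(frozen=True)
class StiffnessEstimate:
    """Relative OM stiffness k_OM/k_CW from population-mean contractions."""

    k_ratio: float
    mean_eps12: float
    mean_eps23: float
    n_full: int        # cells with all three lengths
    n_eps12_only: int  # cells contributing to <eps12> only


@dataclass(frozen=True)
class RestLengthResult:
    A_OM: float
    A_turgid: float
    l_OM: float
    l_turgid: float
    w: float
    ratio_rest_to_turgid: float


# --------------------------------------------------------------------------

def strains(triplet: PlasmolysisTriplet) -> StrainSet:
    """Contractions eps12, eps23, eps13 of one cell's length triplet."""
    if triplet.l1 <= 0 or triplet.l2 <= 0:
        raise ValueError("lengths must be positive")
    eps12 = (triplet.l1 - triplet.l2) / triplet.l2
    if triplet.l3 is None:
        return StrainSet(eps12=eps12, eps23=None, eps13=None, flagged=eps12 < 0)
    if triplet.l3 <= 0:
        raise ValueError("lengths must be positive")
    eps23 = (triplet.l2 - triplet.l3) / triplet.l3
    eps13 = (triplet.l1 - triplet.l3) / triplet.l3
    return StrainSet(eps12=eps12, eps23=eps23, eps13=eps13, flagged=eps12 < 0)


def stiffness_ratio(triplets: Sequence[PlasmolysisTriplet]) -> StiffnessEstimate:
    """Relative OM stiffness from the mean contractions of a cell population.

    Cells lacking a lysed length contribute to ``<eps12>`` only.  The wall
    stiffness k_CW is the unit of the returned ratio.
    """
    sets = [strains(t) for t in triplets]
    e12 = [s.eps12 for s in sets]
    e23 = [s.eps23 for s in sets if s.eps23 is not None]
    if not e23:
        raise ValueError("need at least one triplet with all three lengths")
    m12 = float(np.mean(e12))
    m23 = float(np.mean(e23))
    if m12 == 0:
        raise ValueError("<eps12> = 0: stiffness ratio undefined")
    k = m23 / (m12 * (1.0 + m23))
    return StiffnessEstimate(k_ratio=k, mean_eps12=m12, mean_eps23=m23,
                             n_full=len(e23), n_eps12_only=len(e12) - len(e23))


def percent_stiffness_reduction(mutant: StiffnessEstimate,
                                reference: StiffnessEstimate) -> float:
    """Percent reduction in relative stiffness vs a reference strain."""
    if reference.k_ratio == 0:
        raise ValueError("reference stiffness is zero")
    return 100.0 * (1.0 - mutant.k_ratio / reference.k_ratio)


def om_surface_area(shape: Union[SpheroplastShape, tuple[float, float, float]]) -> float:
    """Membrane area of a flattened spheroplast: A_OM = 2a + w*s.

    Accepts a :class:`SpheroplastShape` or a raw ``(a, s, w)`` tuple of
    projected area (µm²), perimeter (µm) and height (µm).
    """
    if isinstance(shape, SpheroplastShape):
        a, s, w = shape.a, shape.s, shape.w
    else:
        a, s, w = shape
    if a <= 0 or s <= 0 or w < 0:
        raise ValueError("a and s must be positive, w nonnegative")
    return 2.0 * a + w * s


def om_rest_length(A_OM: float, A_turgid: float, l_turgid: float,
                   w: float) -> RestLengthResult:
    """OM rest length from membrane-area conservation.

    ``l_OM = l_turgid + (A_OM - A_turgid) / (pi * w)``: surplus membrane
    area, spread over the rod's cross-sectional perimeter ``pi*w``, extends
    the rod the membrane could cover at rest.
    """
    if min(A_OM, A_turgid, l_turgid) <= 0 or w <= 0:
        raise ValueError("all inputs must be positive")
    l_om = l_turgid + (A_OM - A_turgid) / (np.pi * w)
    return RestLengthResult(A_OM=A_OM, A_turgid=A_turgid, l_OM=float(l_om),
                            l_turgid=l_turgid, w=w,
                            ratio_rest_to_turgid=float(l_om / l_turgid))


def plasmolyzed_ratio(eps12: float) -> float:
    """Plasmolyzed-to-turgid length ratio l2/l1 = 1/(1 + eps12)."""
    if eps12 <= -1:
        raise ValueError("eps12 must exceed -1")
    return 1.0 / (1.0 + eps12)
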