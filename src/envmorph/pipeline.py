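"""End-to-end pipelines gluing the synthetic generators to the estimators.

These reproduce, on synthetic cells, the measurement chains of the imaging
study: length triplets rendered as cell outlines and re-measured through the
contour -> centerline mesh -> length pipeline before computing contraction
strains and relative OM stiffness; and the rest-length chain that renders a
turgid cell to a mask, extracts its contour, meshes it, computes its surface
of revolution, and combines it with a spheroplast blob's membrane area.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .contours import (CellContour, extract_contour, mesh_contour,
                       render_mask, surface_areas)
from .mechanics import (RestLengthResult, StiffnessEstimate, om_rest_length,
                        om_surface_area, stiffness_ratio, strains)
from .synthetic import (PlasmolysisTriplet, RodSpec, SpheroplastShape,
                        StrainPreset, gen_plasmolysis_triplets,
                        gen_rod_contour, gen_spheroplast_blob)

__all__ = ["measure_length", "measure_triplets", "strain_pipeline",
           "rest_length_pipeline"]


def measure_length(length: float, width: float = 1.0, n_vertices: int = 128,
                   n_stations: int = 50, seed: int = 0) -> float:
    """Render a rod of the given true length and re-measure it via the mesh."""
    contour = gen_rod_contour(RodSpec(length=length, width=width,
                                      n_vertices=n_vertices, seed=seed))
    mesh = mesh_contour(contour, n_stations=n_stations)
    return mesh.cell_length


def measure_triplets(triplets: Sequence[PlasmolysisTriplet],
                     width: float = 1.0, n_vertices: int = 128,
                     n_stations: int = 50) -> list[PlasmolysisTriplet]:
    """Re-measure every state of every triplet through contour -> mesh.

    Each length becomes the centerline length of a rendered spherocylinder
    of that true length, mimicking how lengths are read off segmented
    images rather than taken as given.
    """
    out = []
    for t in triplets:
        out.append(PlasmolysisTriplet(
            l1=measure_length(t.l1, width, n_vertices, n_stations),
            l2=measure_length(t.l2, width, n_vertices, n_stations),
            l3=None if t.l3 is None else measure_length(t.l3, width,
                                                        n_vertices, n_stations),
            cell_id=t.cell_id))
    return out


@dataclass(frozen=True)
class StrainPipelineResult:
    preset: StrainPreset
    triplets_true: tuple[PlasmolysisTriplet, ...]
    triplets_measured: tuple[PlasmolysisTriplet, ...]
    mean_eps12: float
    mean_eps23: float
    stiffness: StiffnessEstimate


def strain_pipeline(preset: StrainPreset, base_length: float = 3.0,
                    width: float = 1.0, seed: int = 0,
                    n_vertices: int = 128,
                    n_stations: int = 50) -> StrainPipelineResult:
    """Generate triplets for a strain preset and recover its contractions.

    Triplet lengths are rendered as spherocylinder contours, meshed, and
    re-measured; strains and the relative stiffness are then computed from
    the measured lengths only.
    """
    true = gen_plasmolysis_triplets(preset, base_length=base_length, seed=seed)
    measured = measure_triplets(true, width=width, n_vertices=n_vertices,
                                n_stations=n_stations)
    sets = [strains(t) for t in measured]
    est = stiffness_ratio(measured)
    return StrainPipelineResult(
        preset=preset, triplets_true=tuple(true),
        triplets_measured=tuple(measured),
        mean_eps12=float(np.mean([s.eps12 for s in sets])),
        mean_eps23=float(np.mean([s.eps23 for s in sets if s.eps23 is not None])),
        stiffness=est)


def rest_length_pipeline(rod: RodSpec, target_A_OM: Optional[float] = None,
                         pixel_size: float = 0.05, irregularity: float = 0.15,
                         seed: int = 0) -> RestLengthResult:
    """Full OM rest-length chain on one synthetic cell.

    The turgid cell is rendered to a binary mask at ``pixel_size`` µm/px,
    its contour extracted at sub-pixel resolution and meshed, and its
    surface of revolution A_turgid measured.  A spheroplast blob is then
    generated with membrane area ``target_A_OM`` (default: the measured
    A_turgid, i.e. matched areas so the rest length equals the turgid
    length), and the rest length follows from area conservation using the
    measured turgid length and width.
    """
    contour_true = gen_rod_contour(rod)
    mask = render_mask(contour_true, pixel_size=pixel_size)
    contour = extract_contour(mask, pixel_size=pixel_size)
    mesh = mesh_contour(contour)
    sa = surface_areas(contour, mesh)
    if target_A_OM is None:
        target_A_OM = sa.area_of_revolution
    blob = gen_spheroplast_blob(target_A_OM, w=mesh.mean_width,
                                irregularity=irregularity, seed=seed)
    A_OM = om_surface_area(blob)
    return om_rest_length(A_OM=A_OM, A_turgid=sa.area_of_revolution,
                          l_turgid=mesh.cell_length, w=mesh.mean_width)
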