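"""Synthetic single-cell and population data with known ground truth.

Every generator is a pure function of its spec and an explicit seed, so
downstream estimators can be tested for exact parameter recovery.  The
generators emulate the observables of a plasmolysis/lysis and time-lapse
imaging study of rod-shaped bacteria:

* spherocylindrical cell contours with tunable local width noise,
* exponential single-cell area growth tracks,
* turgid/plasmolyzed/lysed length triplets with multiplicative noise,
* amorphous flattened-spheroplast blobs of prescribed membrane area,
* two-channel fluorescence traces with compartment-specific loss times,
* plate-reader OD curves with logistic growth and exponential lysis decay.

Noise models: lengths and areas use mean-one multiplicative log-normal
noise (positivity); fluorescence uses additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import Polygon

from .contours import CellContour

__all__ = [
    "RodSpec", "StrainPreset", "GrowthTrackSpec", "TraceSpec",
    "PlasmolysisTriplet", "SpheroplastShape", "FluorTrace", "CellTrack",
    "ODCurve", "PARENT_PRESET", "BAMD_PRESET", "BAMD_SUPPRESSOR_PRESET",
    "gen_rod_contour", "gen_growth_track", "gen_plasmolysis_triplets",
    "gen_spheroplast_blob", "gen_fluor_trace", "gen_od_curve",
]


# --------------------------------------------------------------------------
# specs and result containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RodSpec:
    """Spherocylinder: a cylinder of diameter ``width`` capped by hemispheres.

    ``length`` is pole-to-pole, ``width`` the mean diameter (both µm).
    ``width_noise_cv`` perturbs the local width along the cylindrical body
    with a smooth multiplicative field of that coefficient of variation.
    """

    length: float
    width: float
    width_noise_cv: float = 0.0
    n_vertices: int = 128
    seed: int = 0

    def __post_init__(self):
        if not self.length > self.width > 0:
            raise ValueError("need length > width > 0 (a rod, not a sphere)")
        if self.width_noise_cv < 0:
            raise ValueError("width_noise_cv must be >= 0")
        if self.n_vertices < 16:
            raise ValueError("n_vertices must be >= 16")


@dataclass(frozen=True)
class StrainPreset:
    """Ground-truth contractions of one strain in the plasmolysis/lysis assay.

    ``eps12_true`` is the turgid→plasmolyzed contraction (l1−l2)/l2,
    ``eps23_true`` the plasmolyzed→lysed contraction (l2−l3)/l3.
    """

    name: str
    eps12_true: float
    eps23_true: float
    noise_cv: float = 0.02
    n_cells: int = 20

    def __post_init__(self):
        if self.eps12_true < 0 or self.eps23_true < 0:
            raise ValueError("ground-truth contractions must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


#: Parent strain (bamA E470K background): ~12 % contraction on plasmolysis,
#: ~11 % further on lysis; 17 cells measured.
PARENT_PRESET = StrainPreset("parent", eps12_true=0.12, eps23_true=0.11,
                             noise_cv=0.02, n_cells=17)

#: bamD deletion: ~30 % contraction on plasmolysis and very little further
#: contraction on lysis (0.02 is this package's reading of "very little");
#: 24 cells with full triplets.
BAMD_PRESET = StrainPreset("dbamD", eps12_true=0.30, eps23_true=0.02,
                           noise_cv=0.02, n_cells=24)

#: bamD pldA mlaA triple mutant: contraction pattern like the bamD deletion,
#: with a slightly larger residual lysis contraction; 20 cells.
BAMD_SUPPRESSOR_PRESET = StrainPreset("dbamD_dpldA_dmlaA", eps12_true=0.30,
                                      eps23_true=0.04, noise_cv=0.02,
                                      n_cells=20)


@dataclass(frozen=True)
class GrowthTrackSpec:
    area0: float            # µm²
    rate_true: float        # 1/min
    dt: float = 1.0         # min
    n_frames: int = 60
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.area0 <= 0:
            raise ValueError("area0 must be positive")
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")


@dataclass(frozen=True)
class TraceSpec:
    """Two-channel fluorescence trace with per-compartment loss times (min)."""

    t_loss_periplasm: Optional[float] = None
    t_loss_cytoplasm: Optional[float] = None
    decay_rate: float = 2.0     # 1/min; rupture empties a compartment fast
    noise_sd: float = 0.0       # additive, intensity units
    dt: float = 1.0             # min
    n_frames: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.decay_rate <= 0:
            raise ValueError("decay_rate must be positive")
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")


@dataclass
class PlasmolysisTriplet:
    """Per-cell lengths: turgid l1, plasmolyzed l2, lysed l3 (µm)."""

    l1: float
    l2: float
    l3: Optional[float] = None
    cell_id: str = ""


@dataclass(frozen=True)
class SpheroplastShape:
    """Flattened spheroplast: 2-D blob outline plus an assumed height ``w``.

    ``a`` and ``s`` are the blob's projected area (µm²) and perimeter (µm);
    ``w`` the flow-cell height, taken equal to the pre-plasmolysis cell
    width.  ``A_OM_true`` records the generator's membrane-area target.
    """

    vertices: np.ndarray
    w: float
    A_OM_true: float

    @property
    def a(self) -> float:
        return Polygon(self.vertices).area

    @property
    def s(self) -> float:
        return Polygon(self.vertices).length


@dataclass
class FluorTrace:
    cell_id: str
    times: np.ndarray       # min
    periplasm: np.ndarray   # intensity
    cytoplasm: np.ndarray   # intensity


@dataclass
class CellTrack:
    """Single-cell time series of projected area (biomass proxy)."""

    cell_id: str
    times: np.ndarray   # min, strictly increasing
    areas: np.ndarray   # µm², > 0


@dataclass
class ODCurve:
    times: np.ndarray   # h
    od: np.ndarray      # OD600
    replicate_id: str = ""


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=n)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def gen_rod_contour(spec: RodSpec) -> CellContour:
    """Closed CCW spherocylinder outline, optionally with smooth width noise.

    With ``width_noise_cv = 0`` the polygon is the exact outline (up to
    vertex discretization): two straight sides of length ``length - width``
    at ``y = ±width/2`` joined by semicircular caps of radius ``width/2``.
    Width noise multiplies the local full width along the body by a smooth
    random field that tapers to 1 at the cap junctions, so the caps stay
    circular and the polygon stays simple.
    """
    l, w = spec.length, spec.width
    r = w / 2.0
    body = l - w
    rng = np.random.default_rng(spec.seed)

    # smooth multiplicative width field over the body, pinned to 1 at caps
    if spec.width_noise_cv > 0:
        n_ctrl = 9
        xs = np.linspace(-body / 2, body / 2, n_ctrl)
        amp = rng.normal(0.0, spec.width_noise_cv, n_ctrl)
        amp[0] = amp[-1] = 0.0
        field = CubicSpline(xs, amp, bc_type="clamped")
    else:
        field = None

    def halfwidth(x: np.ndarray) -> np.ndarray:
        if field is None:
            return np.full_like(x, r)
        return r * (1.0 + field(x))

    # vertex budget proportional to arclength of each of the four pieces
    per = 2 * body + np.pi * w
    n_side = max(4, int(round(spec.n_vertices * body / per)))
    n_cap = max(6, (spec.n_vertices - 2 * n_side) // 2)

    xb = np.linspace(-body / 2, body / 2, n_side, endpoint=False)
    # CCW: bottom left->right, right cap, top right->left, left cap
    bottom = np.column_stack([xb, -halfwidth(xb)])
    th_r = np.linspace(-np.pi / 2, np.pi / 2, n_cap, endpoint=False)
    right_cap = np.column_stack([body / 2 + r * np.cos(th_r), r * np.sin(th_r)])
    xt = np.linspace(body / 2, -body / 2, n_side, endpoint=False)
    top = np.column_stack([xt, halfwidth(xt)])
    th_l = np.linspace(np.pi / 2, 3 * np.pi / 2, n_cap, endpoint=False)
    left_cap = np.column_stack([-body / 2 + r * np.cos(th_l), r * np.sin(th_l)])
    return CellContour(np.vstack([bottom, right_cap, top, left_cap]))


def gen_growth_track(spec: GrowthTrackSpec, cell_id: str = "cell") -> CellTrack:
    """Exponential area growth ``A(t) = area0 * exp(rate * t)`` plus noise."""
    t = np.arange(spec.n_frames) * spec.dt
    A = spec.area0 * np.exp(spec.rate_true * t)
    rng = np.random.default_rng(spec.seed)
    A = A * _lognormal_factors(rng, spec.noise_cv, spec.n_frames)
    return CellTrack(cell_id=cell_id, times=t, areas=A)


def gen_plasmolysis_triplets(preset: StrainPreset, base_length: float = 3.0,
                             seed: int = 0) -> list[PlasmolysisTriplet]:
    """Triplets (l1, l2, l3) whose noiseless contractions equal the preset.

    Per cell the lysed length l3 is drawn around ``base_length``; then
    ``l2 = l3 (1 + eps23_true)`` and ``l1 = l2 (1 + eps12_true)``, each
    length carrying independent mean-one log-normal noise of CV
    ``preset.noise_cv``.
    """
    rng = np.random.default_rng(seed)
    n = preset.n_cells
    l3 = base_length * _lognormal_factors(rng, preset.noise_cv, n)
    l2 = l3 * (1.0 + preset.eps23_true) * _lognormal_factors(rng, preset.noise_cv, n)
    l1 = l2 * (1.0 + preset.eps12_true) * _lognormal_factors(rng, preset.noise_cv, n)
    return [PlasmolysisTriplet(l1=float(l1[i]), l2=float(l2[i]), l3=float(l3[i]),
                               cell_id=f"{preset.name}_{i:03d}")
            for i in range(n)]


def gen_spheroplast_blob(target_A_OM: float, w: float,
                         irregularity: float = 0.15,
                         seed: int = 0, n_vertices: int = 256) -> SpheroplastShape:
    """Amorphous flattened-spheroplast blob with prescribed membrane area.

    The outline is a random Fourier perturbation of a circle,
    ``rho(theta) = r0 (1 + sum_{k=2..6} c_k cos(k theta + phi_k))`` with
    ``|c_k| <= irregularity``, uniformly rescaled so that the membrane area
    of the flattened pancake, ``A_OM = 2a + w s`` (two flat faces plus the
    side wall of height ``w``), hits ``target_A_OM`` exactly.
    """
    if target_A_OM <= 0 or w <= 0:
        raise ValueError("target_A_OM and w must be positive")
    if irregularity < 0 or irregularity >= 0.5:
        raise ValueError("irregularity must be in [0, 0.5) to keep the blob simple")
    rng = np.random.default_rng(seed)
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    ck = rng.uniform(-irregularity, irregularity, 5)          # modes k = 2..6
    phik = rng.uniform(0, 2 * np.pi, 5)
    total = np.abs(ck).sum()
    if total > 0.9:  # guarantee rho > 0 (star-convex, simple)
        ck *= 0.9 / total
    rho = np.ones(n_vertices)
    for k, c, phi in zip(range(2, 7), ck, phik):
        rho += c * np.cos(k * theta + phi)
    unit = np.column_stack([rho * np.cos(theta), rho * np.sin(theta)])
    p = Polygon(unit)
    a1, s1 = p.area, p.length
    # 2 a1 c^2 + w s1 c = target  ->  positive quadratic root
    c = (-w * s1 + np.sqrt((w * s1) ** 2 + 8.0 * a1 * target_A_OM)) / (4.0 * a1)
    return SpheroplastShape(vertices=unit * c, w=w, A_OM_true=target_A_OM)


def gen_fluor_trace(spec: TraceSpec, cell_id: str = "cell") -> FluorTrace:
    """Two-channel trace: baseline 1.0, exponential decay after each loss time."""
    t = np.arange(spec.n_frames) * spec.dt
    rng = np.random.default_rng(spec.seed)

    def channel(t_loss: Optional[float]) -> np.ndarray:
        y = np.ones_like(t)
        if t_loss is not None:
            lost = t > t_loss
            y[lost] = np.exp(-spec.decay_rate * (t[lost] - t_loss))
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, len(t))
        return y

    return FluorTrace(cell_id=cell_id, times=t,
                      periplasm=channel(spec.t_loss_periplasm),
                      cytoplasm=channel(spec.t_loss_cytoplasm))


def gen_od_curve(K: float = 1.5, r: float = 1.0, od0: float = 0.05,
                 lysis_start: Optional[float] = None, lysis_rate: float = 0.2,
                 dt: float = 0.25, t_end: float = 18.0,
                 replicate_id: str = "rep") -> ODCurve:
    """Deterministic logistic OD curve, optionally lysing after ``lysis_start``.

    OD follows the logistic solution rising from ``od0`` toward carrying
    capacity ``K`` at rate ``r`` (1/h); if ``lysis_start`` (h) is given the
    curve decays exponentially at ``lysis_rate`` from its value at that time.
    Sampled every ``dt`` h up to ``t_end``.
    """
    if not K >= od0 > 0:
        raise ValueError("need K >= od0 > 0")
    t = np.arange(0.0, t_end + 0.5 * dt, dt)
    if r == 0:
        od = np.full_like(t, od0)
    else:
        od = K * od0 * np.exp(r * t) / (K + od0 * (np.exp(r * t) - 1.0))
    if lysis_start is not None:
        if r == 0:
            od_at = od0
        else:
            od_at = K * od0 * np.exp(r * lysis_start) / (K + od0 * (np.exp(r * lysis_start) - 1.0))
        after = t > lysis_start
        od[after] = od_at * np.exp(-lysis_rate * (t[after] - lysis_start))
    return ODCurve(times=t, od=od, replicate_id=replicate_id)
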