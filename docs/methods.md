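# Methods

## Scope and model

`envmorph` analyzes rod-shaped bacterial cells whose envelope mechanics are
probed three ways: time-lapse morphometrics (growth rate and width
variability), a plasmolysis/lysis assay (length contractions and relative
OM stiffness), and spheroplast shape analysis (OM rest length). The
underlying mechanical picture treats the outer membrane and the
peptidoglycan cell wall as two springs in series along the cell axis. A
turgid cell of length l1 contracts to l2 when turgor is removed
(plasmolysis) and to l3 when the OM is removed (lysis); the contractions
ε12 = (l1−l2)/l2 and ε23 = (l2−l3)/l3 compose exactly as
(1+ε13) = (1+ε12)(1+ε23). Balancing spring forces and assuming the OM rest
length equals the turgid length gives the relative stiffness

    k_OM / k_CW = <ε23> / ( <ε12> · (1 + <ε23>) ),

with ⟨·⟩ arithmetic means over cells, taken over strains (not lengths).
k_CW is an arbitrary reference set to 1; only ratios and percent
reductions between strains are meaningful, reported as
1 − k(mutant)/k(reference). Cells measured without a lysed length
contribute to ⟨ε12⟩ only. Cells with l2 > l1 (negative ε12) are retained
and flagged rather than dropped.

Rod geometry is idealized as a spherocylinder: a cylinder of diameter w
capped by two hemispheres, so the turgid surface area is πwl and the
cross-sectional perimeter πw. The OM rest length converts a membrane-area
surplus into length through that perimeter:

    l_OM = l_turgid + (A_OM − A_turgid) / (π w).

A flattened spheroplast of projected area a, outline length s and height w
(taken equal to the pre-plasmolysis cell width) carries membrane area
A_OM = 2a + ws — two flat faces plus the side wall.

## Contour extraction and centerline meshing

Masks are 0/1 arrays with pixel centers at half-integer physical
coordinates (row 0 at the bottom, y up); the contour is the 0.5-level
iso-contour, which `skimage.measure.find_contours` returns at sub-pixel
resolution. A mask must contain exactly one 4-connected component of at
least 50 px not touching the border; anything else is an error naming the
offense, since a truncated or multi-cell mask silently corrupts widths.

The centerline starts as the principal-axis chord through the centroid
(SVD of the vertices) clipped to the polygon. Each refinement sweep drops
perpendicular ribs at stations equally spaced in arclength, replaces
interior stations by rib midpoints, smooths the midpoint polyline with a
Savitzky–Golay filter (window ≈ 20 % of stations, order 2 — a local
polynomial smoother chosen over a smoothing spline because it has no free
smoothing parameter and is robust to exactly collinear points), re-extends
both ends to the contour along the end tangents, and resamples. Sweeps
stop when the largest station movement falls below 0.1 % of the rough
width, at most 20 sweeps. Local width is the length of the rib chord
through the station; stations within half a mean width of either cell end
are flagged as poles (and the two extreme stations always are), because
the hemispherical caps would otherwise contaminate width statistics. The
default of 50 stations resolves width profiles at ~2 % of cell length.
Cells whose measured aspect ratio is below 1.5 are flagged round and get
no width profile.

A_turgid is the surface of revolution of the half-width profile about the
centerline, computed as a stack of conical frustums
Σ π(r_i + r_{i+1})·slant with the profile resampled at 400 stations and
r = 0 enforced at the poles. The frustum (discrete Pappus) form is used
deliberately: the simpler Σ 2πr·Δ(arclength) underestimates hemispherical
caps by a factor π/4 and would miss the πwl closed form by ~5 %. On a
noiseless 4×1 µm spherocylinder the frustum sum is within 0.03 % of 4π
from the exact contour, and within ~1.5 % after a 0.05 µm/px mask
round-trip.

## Single-cell statistics

Instantaneous growth rate is the slope of a least-squares line of ln A
versus t over a centered window (default 5 frames; ends use the largest
centered window, never fewer than 3 points). The window smooths
measurement noise without masking lysis-scale rate changes. The width CV
is the sample (n−1) standard deviation over non-pole widths divided by
their mean. Shape groups default to quartile bins of the CV distribution;
adjacent groups are compared with `scipy.stats.ks_2samp`.

A fluorescence channel is *lost* at the first sample that falls below
`loss_frac` (default 0.5) of its baseline — the median of the first three
frames — and never recovers above it; the reported loss time interpolates
the threshold crossing between that sample and the previous one, which
removes frame-grid quantization from loss-gap estimates. Rupture order is
OM-first when the periplasmic loss precedes the cytoplasmic loss by more
than a coincidence window (default one frame interval), coincident within
the window, IM-first otherwise, none when neither channel is lost. The
viable fraction is the share of cells with order none (or an unset lysis
flag).

## Population assays

d ln(OD)/dt uses the same windowed fit as the single-cell rate (default 5
points, i.e. 75 min at a 15-min cadence). Lysis curves are divided by the
OD at the sample closest to the transfer time and shifted so transfer is
t = 0 (idempotent on an already-normalized curve). Replicates on different
grids are linearly interpolated onto the union of time points restricted
to the overlapping range — no extrapolation — before the pointwise mean
and sample SD. Relative light units are fluorescence/OD600.

## Synthetic generators

All generators are pure functions of (spec, seed); there is no global
random state. Lengths and areas carry mean-one multiplicative log-normal
noise (positive by construction); fluorescence carries additive Gaussian
noise. The strain presets encode the study conditions the package is
demonstrated under: parent ε12 = 0.12, ε23 = 0.11, n = 17; OMP-depleted
mutant ε12 = 0.30, n = 24; suppressor-background mutant ε12 = 0.30,
n = 20. The mutants' residual lysis contraction is small but never
reported as a number in the source measurements, so the presets use 0.02
and 0.04 ("very little further contraction") as package choices. Length
noise CV defaults to 0.02 and fluorescence noise SD to 0.05 — magnitudes a
sub-pixel segmentation and a typical camera deliver; neither is derived
from a printed value. Triplet base (lysed) length is 3 µm and rendered
rods are 1 µm wide, typical log-phase dimensions.

Spheroplast blobs are star-convex Fourier perturbations of a circle,
ρ(θ) = r0(1 + Σ_{k=2..6} c_k cos(kθ+φ_k)) with |c_k| bounded by the
irregularity parameter (and Σ|c_k| capped at 0.9 so ρ stays positive),
uniformly rescaled so 2a + ws hits the target membrane area exactly — the
scale factor is the positive root of the quadratic 2a·c² + ws·c = target.
Because that map is a bijection onto positive targets, any positive target
is feasible.

Fluorescence traces hold baseline 1.0 until the compartment's loss time,
then decay exponentially at 2/min — a rupture empties a compartment on the
minute scale, which keeps the half-baseline crossing within one frame of
the true loss at the default 1-min cadence. OD curves follow the closed
logistic solution, switching to exponential decay at the lysis start.

What the generators do *not* emulate: microscopy point-spread functions
and shot noise, cell division and lineage branching, curved or branched
cells, multi-cell scenes, or mechanistic coupling between shape defects
and growth rate (group differences are injected, not emergent). Passing
tests therefore validate the estimators' correctness and the pipeline's
geometric accuracy, not robustness to real imaging artifacts.

## Problem sizes and numerical choices

The test suite and acceptance script run the full chains at the study's
own sample sizes (17 and 24 cells × 3 states, 30 traces, 3 OD replicates)
with 128–256-vertex contours, 50 mesh stations and 0.05 µm/px masks;
a strain pipeline run takes about a second. Contour orientation is
normalized to counterclockwise on construction, so meshing a vertex-
reversed contour is exactly invariant. Degenerate inputs fail loudly:
spheres (length ≤ width), empty/multi-component/border-touching masks,
nonpositive lengths, ODs or baselines, ⟨ε12⟩ = 0 in the stiffness ratio,
and w = 0 in the rest-length formula all raise errors rather than
returning NaN.

## Known limitations

The centerline iteration assumes a roughly straight, star-shaped rod; it
is not built for strongly bent or branched cells. The stiffness estimator
reports a ratio only — absolute stiffness in N/m and turgor pressure are
out of scope. Whether shape-grouped growth rates should be per-cell means
or pooled instantaneous values is a judgment call; the package computes
per-cell means (callers can pool frame-level rates themselves, as both
inputs are exposed).
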