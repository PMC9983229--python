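# Methods

This note documents the models, defaults and design choices behind each
stage of the pipeline, and what the synthetic benchmark does and does not
establish about real data.

## The measurement model

A movie is a calibrated stack `I(t, z, y, x, band)` (the `ImageStack`
container). Detection bands are modelled as a linear mixture of
fluorophore abundances:

    I_band(v) = Σ_f  M[band, f] · a_f(v) + shot noise,

where each column of the spectral library `M` is the unit-normalised
emission spectrum of one fluorophore (SHG, tdTomato, EGFP, pHocas-3,
autofluorescence). Unmixing inverts this per voxel by non-negative least
squares; autofluorescence is returned as an explicit channel so the caller
discards it deliberately rather than implicitly. The NNLS solver
enumerates active sets (for each subset of fluorophores a restricted
least-squares solve is vectorised over all voxels; the feasible candidate
with minimal residual is the optimum). This is exact for any
full-column-rank library and is O(2^k) in the fluorophore count k — cheap
for k ≤ 5, and orders of magnitude faster than a per-voxel iterative
solver on 4D stacks. A rank-deficient or underdetermined library raises an
identifiability error naming the collinear columns.

Gamma correction follows the display convention of acquisition software:
min–max normalise to [0, 1], raise to γ, rescale to the original range.
The exponents applied before resorption scoring are γ = 0.9 (tdTomato)
and γ = 2.5 (pHocas-3). The transform is monotone, so segmentation
thresholds computed after correction correspond to unique raw-intensity
thresholds; a constant image is returned unchanged with a log message.

Field drift is modelled as a pure lateral translation per frame (the
calvaria is head-fixed; rotation and scaling are not expected). Each
frame's shift relative to frame 0 is estimated on a reference channel by
maximising the cross-correlation (FFT-based, optional subpixel
refinement; plain rather than phase-normalised correlation, which is less
stable under shot noise). The reference image is the *mean* over z: a
thick structure like bone saturates a maximum projection into a flat,
unregistrable field, while the z-mean preserves its relief. Frames with
no contrast carry the previous estimate and are flagged. Whether drift
correction is applied to the slow (5-min) osteoclast movies is a per-run
choice; the bundled pipeline applies it to precursor movies, where 30-s
sampling makes drift visible in the tracks.

## Segmentation

Otsu's threshold is computed over a 256-bin histogram of the observed
intensity range (the 8-bit display convention), maximising the
between-class variance; ties — including ties at machine precision, which
occur in sparse histograms — break toward the lowest qualifying
threshold, using a relative tolerance of 1e-12 so the choice does not
depend on summation order. Foreground is `image > threshold`. Connected
components use full connectivity by default (8-neighbour in 2D,
26-neighbour in 3D), configurable. Physical measures are exact products:
area = pixel count × pixel area, volume = voxel count × voxel volume.

The precursor-volume filter removes 3D objects ≤ 50 µm³ (read strictly:
survival requires volume > 50 µm³), the published bound below which
EGFP⁺ groupings are unlikely to be cells. It refuses 2D input rather than
silently reinterpreting the bound as an area. The bone mask used for
adhesion is the SHG Otsu mask dilated by 1 voxel — a deterministic proxy
for the manual fitting of bone surfaces to adherent cells that commercial
surface tools require; a manual step cannot live in a tested pipeline.
The 50 µm³ filter is applied to raw labeled volumes (where in the
commercial workflow it sat relative to surface smoothing is unknowable).

## The four indices

**BRI** = mean pH-probe intensity inside the osteoclast mask / mean
outside, computed on gamma-corrected maximum projections. The "outside"
region is the full mask complement by default, with an optional exclusion
ring (default off, 2 px when enabled) to keep PSF bleed out of the noise
term. Empty masks, full masks and a zero noise mean raise rather than
returning infinities. The index is a ratio of means, hence invariant to
positive rescaling of the probe image; absolute values depend strongly on
the background level and only group comparisons are meaningful.

**CDI** = (A + C)/(A + B) ≥ 1, with equality iff the end footprint lies
inside the start footprint. The window defaults to the endpoints of a
10-min span — the stated observation interval; at 5-min frames that is
frames 0 and 2 (the labelling "t = 0 … t = 5" alongside "change over
10 min" is internally inconsistent; the 10-min reading is used and the
span is configurable). Cells are matched across the window by
centroid-nearest optimal assignment within 20 µm — generous, since mature
osteoclasts barely translocate; unmatched objects are skipped and logged.

**TRAP⁺ area** is the summed object area per image divided by the
reference-group mean, matching the "relative to steady state" axis
construction of such figures.

**Adhesion** is reported in both orientations: the precursor/adhesion
ratio as printed in the originating method description (≥ 1, undefined at
zero adhesion — such records are flagged and report fraction 0), and the
bounded adhesion fraction (intersection/precursor ∈ [0, 1]), which is the
primary orientation here because it is bounded and interpretable. Their
product is 1 whenever both are defined; neither is silently corrected to
the other.

## Tracking

Detections (per-frame Otsu centroids in µm, objects < 10 µm² discarded as
noise) are linked frame to frame by minimising summed distances to
predicted positions with the Hungarian algorithm. The "autoregressive"
motion model is constant-velocity prediction (last position + last
velocity), the published equivalent of proprietary autoregressive
trackers; a nearest-position model is available and demonstrably swaps
identities when constant-velocity paths cross. The gate is 6 µm per
frame step and a track survives up to 3 consecutive missing frames
("gap size 3" read as missing frames; a link across a gap of g frames is
gated at 6·g µm, and both the prediction error and the realized
displacement must pass the gate). Mean speed is path length over elapsed
time (gap steps contribute their true duration), converted to µm/min;
single-detection tracks are excluded and counted in the QC record.

## Statistics

Two-group comparisons: Mann-Whitney U (mid-ranks for ties; exact
enumeration for small tie-free samples; large-sample normal approximation
*without* continuity correction — the corrected test is measurably
conservative, rejecting at ≈ 0.026 rather than 0.05 under the null at
n = 30/group) or the unpaired two-tailed t-test. Three or more groups:
Kruskal–Wallis followed by Dunn's pairwise rank z-tests with tie
correction and Holm adjustment (with 2 groups Dunn's z² reduces to the
Kruskal–Wallis H, which the tests exploit as a cross-check), or one-way
ANOVA with Tukey's HSD. The conventional pairing of Kruskal–Wallis with
"Dunnett's post hoc" is internally inconsistent — Dunnett's test is
parametric — so the nonparametric arm uses Dunn; the parametric arm is
one design keyword away. Significance is α = 0.05 throughout. The unit of
observation follows the figure conventions of this field (images, cells
or tracks, not mice); the mouse identifier is retained in every table so
a per-mouse sensitivity analysis is a groupby away.

Relative expression uses the Livak convention 2^(−ΔΔCt) — ΔCt = target −
housekeeping (Gapdh), ΔΔCt relative to the control-group mean — so the
control group averages 1 and a one-cycle excess halves expression.
(The form "2^ΔΔCt" sometimes printed would invert fold-change direction.)
It is invariant under global Ct shifts and monotone decreasing in target
Ct; a missing reference Ct raises.

## The synthetic benchmark

The generator emulates: an undulating bone surface (SHG⁺ below a smooth
height map, mean 4.5 µm, relief 0.8 µm); mature osteoclasts as disks of
radius ~6 ± 1 µm placed without initial overlap on the bone surface —
R-type essentially static (0.05 µm/frame) with one acidification focus
each (radius 3 µm, abundance 3× the reporter level, anchored at the bone
surface slice), N-type translating (2.5 µm/frame) and deforming
(wandering ellipse aspect); precursors as ~3 µm disks doing persistent
random walks with per-track speeds drawn from a configurable normal
distribution (floored at 0.05 µm/min), a Bernoulli(adhesion_probability)
subset dwelling at the bone surface (1 µm above it) and the rest 7 µm
higher; uniform autofluorescence (level 0.1); spectral mixing through the
default library; a Gaussian lateral PSF (σ = 0.4 µm); per-frame field
drift; and Poisson noise at a configurable photon scale (200 detected
photons per abundance unit by default; `None` renders noiselessly).

Acquisition defaults mirror the published geometry: 512 × 512 fields,
3 µm z-steps, 30 s frames for precursor movies, 5 min for osteoclast
movies. The lateral pixel size is not published; 0.62 µm/px (plausible
for a 20× objective at 1.5× zoom over 512 px) is the default and is
explicitly a free parameter — all physical read-outs scale with it.
Cells are 2D footprints extruded over a few z-slices, not full 3D
morphologies; the quantified indices operate on projections and surfaces,
so full 3D realism would add cost without changing what is tested.

The three cohort presets encode the qualitative effect directions of the
study design — versus steady state, LPS (vehicle) raises the R-type
fraction (0.35 → 0.85), osteoclast count (4 → 9), and bone-contact
propensity (0.15 → 0.85) and slows precursors (3.0 → 1.2 µm/min); JAK
inhibition moves each parameter back toward steady state (0.45, 5, 0.25,
2.4). These numbers are the *simulated conditions*, chosen once as
plausible effect sizes; no underlying parameter values are published for
such in vivo effects, so passing the end-to-end test shows that the
pipeline recovers the directions and significance of effects that are
present by construction — not that the original biological effect sizes
are reproduced. Absolute
index values from the simulator are likewise not comparable to published
ones (no access to raw movies, instrument calibrations or real spectral
libraries). Features of real data the generator does not model: optics-
accurate two-photon PSFs, depth-dependent attenuation and scattering,
bone remodelling over the movie, cell fusion/division, and non-uniform
structured autofluorescence.

## Problem sizes and numerics

The bundled cohort-study run uses 3 groups × 5 synthetic mice, each with
three 3-frame osteoclast movies and two 11-frame precursor movies on
128 × 128 px fields — sizes chosen so a complete cohort run finishes in
a few minutes on one CPU while every group comparison retains dozens to
hundreds of observations. Tracking-recovery checks use 200 cells on
320 × 320 px (0.625 µm/px) fields, i.e. 0.005 cells/µm². Determinism is
end-to-end: every stochastic stage draws from `numpy` Generators seeded
from the run seed via `SeedSequence` spawn keys (group, mouse, movie), so
identical configurations produce bit-identical CSVs. Degenerate inputs
fail loudly (constant images for Otsu, empty/full masks for BRI, empty
footprints for CDI, missing reference genes) rather than propagating
NaNs, except where a defined fallback exists (zero-adhesion records,
contrast-free drift frames).

## Known limitations

- Touching osteoclasts are not split (no watershed); fused osteoclasts
  are genuinely multinucleated, but this also merges coincidentally
  touching cells and biases per-cell CDI toward the merged object.
- Detection centroid jitter inflates tracked speeds by a noise floor
  (≈ 0.2–0.5 µm/min at the default photon budget and 30-s frames); group
  comparisons are unaffected because the floor is common to all groups.
- The 6 µm gate bounds measurable speed at 12 µm/min for 30-s frames,
  exactly as in the emulated tracker configuration.
- BRI depends on the background (noise) level; with a near-dark
  background after γ = 2.5 its absolute value is large and only relative
  comparisons are meaningful.
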