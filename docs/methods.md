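# Methods

## The untwisting model

A twisted embryo is modeled from an ordered *lattice* of left/right marker
pairs (seam-cell nuclei, plus nose/tail/bend pairs), index 0 at the nose.
Three cubic splines — through the left points, the right points, and the
pair midpoints — share one chord-length parameter so that corresponding
positions on the three curves stay in register.  Splines use not-a-knot
boundary conditions: with natural (zero second derivative) ends the
endpoint tangent of a curved midline errs by several degrees, which tilts
the first and last sampling planes enough to displace nose/tail markers by
~1 µm axially; not-a-knot removes that bias while still interpolating
every midpoint exactly (to < 1e-6 µm).

The midline is reparameterized by arclength.  Cumulative arclength is
tabulated by per-interval Gauss–Legendre quadrature on a dense grid, the
total length refined by adaptive quadrature (relative tolerance 1e-9), and
the inverse map s→u interpolated monotonically (PCHIP).  On an analytic
semicircular midline the computed length matches πR to ~1e-5 relative.

**Frames and twist.**  At arclength s the plane frame is: tangent = the
normalized midline derivative; left–right axis = the interpolated
(right − left) edge direction with its tangential component projected out;
dorso-ventral axis = tangent × lr.  Carrying the lr axis on the edge
splines — rather than by parallel transport — is what makes helical twist
recoverable from the markers alone: a linear 0→180° twist phantom yields a
180° ± 2° rotation of the lr axis between nose and tail.  A frame is
degenerate (error, with the offending s) if the edge direction is parallel
to the tangent (projection norm < 1e-6).

**Sampling planes and overlap.**  Planes sit at s = 0, step, 2·step, …
(default step: one voxel-equivalent; 0.25 µm for the benchmark runs).
Each plane's half-extent is `margin` × the local body half-width from the
edge splines; the default margin 1.2 covers hypodermis beyond the seam
nuclei.  Overlap is resolved by clipping each plane's in-plane radius to
(i) the bisector plane against either neighbouring plane center, and
(ii) the local radius of curvature of the midline (planes of a circular
arc meet at its center).  The clip is a single symmetric radius per plane:
the bound satisfies the no-double-claim guarantee in all directions, at
the cost of being conservative on the outside of a bend.  Under the
nearest-center claiming rule (ties toward smaller s) every interior point
is then claimed by at most one plane.

**Resampling and point mapping.**  Straightened voxel (i, j, k) is the
trilinear interpolation of the input at
`center_k + (i·step − W)·lr_k + (j·step − W)·dv_k`, zero outside the input
volume or outside the plane's clip radius.  A twisted point maps to
untwisted (x, y, z) via the plane with the nearest center, provided its
in-plane radius is within the clip bound and its axial offset within one
step; at the two end planes the outward axial tolerance widens to the clip
radius so the rounded nose/tail caps are claimed.  z is quantized to the
plane index (k·step), so the twisted→untwisted→twisted round trip errs by
less than one step (measured: ≤ 0.15 µm at step 0.5 on a 360°-twist
phantom).  The inverse map reconstructs on the nearest plane and rejects z
outside [0, total length].

**Lattice sizing.**  For manual lattices the recommended minimum is
2·(seam pairs) + 2 + 2·(bends): 22 points for 10 seam pairs with no bends,
28 with three bends.  Beyond roughly 32 points the model stops improving
(adding 5 pairs to an 11-pair phantom lattice changes total length by
< 1 %).

## Automated lattice building

Seam nuclei are near-uniform in size, so detection is single-scale: local
maxima of the negated, scale-normalized Laplacian-of-Gaussian response at
σ = expected_radius/√3, thresholded at `threshold_rel` × the global
maximum response (default 0.4 — on SNR-10 phantoms the nucleus responses
sit above 0.5× max and body-wall/noise responses below 0.3×), with maxima
closer than one expected radius merged keeping the stronger.

Pairing is the hard step: contralateral partners are *not* reliably each
other's nearest neighbours, because the pair width (the body diameter,
16–22 µm) often exceeds the along-body spacing of neighbouring pairs
(~10–18 µm).  Candidate pairings are therefore generated from several
starts — plain nearest-unused greedy matching seeded at the strongest
detections, greedy matching toward seed-derived pair-width hypotheses, and
seeded random pairings — and each start is refined by score-guided local
search: swapping partners between two pairs, and substituting unused
detections into pairs, whenever the move lowers the lattice score.  Pairs
are then ordered by walking midpoint proximity from an extreme end; the
nose end is chosen by an optional hint point, otherwise both orientations
are emitted.  At most five candidates are returned, ranked by score.

The score is a weighted sum (default weights 1, 1, 1, 0) of: the
coefficient of variation of pair widths; the CV of consecutive midpoint
spacings; a bend penalty (total absolute turning of the midpoint
polyline); and an optional relative length penalty against an expected
body length (unused unless configured).  The dispersion terms are
scale-free, so the score is invariant to uniform rescaling.  On noiseless
phantoms up to 11 pairs and ≤ 180° total twist the top-ranked candidate
reproduces the true pairing; this criterion, not the greedy initializer,
carries the correctness.

## Validation statistics

Morphology preservation compares a metric series (pair distance, contour
length) between frames: per embryo the mean and sample SD (n−1 throughout)
of |twisted − untwisted| across time, then arithmetic means of those
across embryos.  Population σ values average per-embryo SDs rather than
pooling variances, matching the nested ⟨σ⟩ notation.  Differences are
reported as magnitudes.  Inter-embryo positional variability takes the SD
across embryos at each aligned timepoint (timepoints with < 2 embryos are
excluded), averages over time per cell, and averages those over the 20
seam-cell names for the grand means.

## Trajectory pipeline

**Cleaning.**  Missing values, user-marked indices, and automatic flags
are replaced by linear interpolation between the nearest valid neighbours
(endpoint runs extend the nearest valid value).  Automatic flags are
residuals from the centered 5-point rolling median exceeding
`outlier_z` (default 6) × a robust scale — the MAD of the residuals, or
their 90th percentile when the MAD collapses to zero on very smooth
series.  Only full windows are used: truncated edge windows bias the
median and would flag smooth boundary points.  Manual marks always win.

**Growth-curve zoo.**  Ten families: the three-parameter logistic,
Gompertz, von Bertalanffy and exponential; four-parameter Morgan–Mercer–
Flodin and logistic; power (a·t^b + c), linear, quartic polynomial, and
50-point local linear smoothing.  Nonlinear fits use least squares with
data-driven starts (logistic: A = max, C = time at half-max, B = 4·max
slope/A; analogous per family); non-convergence is flagged on the result,
never raised, and flagged fits rank last in model selection.  Goodness of
fit is SSR with the Gaussian-residual criteria AIC = n·ln(SSR/n) + 2k and
SC = n·ln(SSR/n) + k·ln(n) (SSR floored at 1e-30 for the exact-fit case);
ranking is by AIC.  Note von Bertalanffy is a reparameterization of the
exponential family, so on noiseless von Bertalanffy data both reach SSR ≈ 0
and the ranking between them is a numerical tie.  The 50-point smoother is
tricube-weighted local linear regression over a centered span truncated at
the boundaries; straight-line input is reproduced exactly.

**Registration and averaging.**  Each cell's (cleaned) axial series per
embryo is fitted with the three-parameter logistic; the embryo is shifted
by round(C_ref − C_other) reference timepoints (half away from zero —
inflection points 42.6 and 37.7 timepoints give a shift of 5), and the
same integer shift is applied to that cell's X and Y.  The reference grid
is the finest dt present; coarser embryos are resampled onto it by linear
interpolation before averaging.  Averages ignore missing values;
per-timepoint sample SDs are retained.  A cell absent from the reference
embryo takes its embryo's median shift.  Shifts are fitted on cleaned
series (the raw-vs-cleaned choice is not critical at the tested noise
levels, but cleaned is safer against spikes).

**Composite fitting.**  Averaged series are re-fitted by cell type — seam
nuclei: power (X), linear (Y), logistic (Z); CAN: 50-point smoothing (X,
Y) and logistic (Z); AIY: quartic (X), linear (Y), logistic (Z); ALA and
its two neurite points (turn, terminus): linear (X, Y), logistic (Z) —
with the mean and SD of |averaged − fitted| recorded per coordinate.
Axial neighbor differences take the fitted Z of consecutive pairs in
anterior→posterior order (origin→H0 first, the origin fixed at Z = 0) and
report per-pair separation series plus start-to-end changes.

## Synthetic phantoms: what they emulate, and what they do not

Phantom centerlines are chains of straight and circular-arc segments in a
plane (closed form, so arclength, curvature and frames are analytic);
twist is linear in arclength; the body radius tapers linearly
head→tail (the "tadpole" profile).  Default scales echo an elongating
embryo: length ~86→162 µm, diameter ~22→16 µm.  Rendered volumes are
Gaussian blobs (σ = 1 µm) at the 20 seam-nucleus positions plus a soft
body-wall shell (amplitude 0.3 vs. blob 1.0) and Gaussian noise at a
stated peak SNR (default 10).  The pharynx-like control polyline runs from
the nose to one-third body length at ~25 % of the local radius with a slow
azimuthal drift — a body-fixed structure, as a real pharynx is; a rapidly
corkscrewing polyline would conflate its own geometry with the twist being
tested.  Trajectory sets draw each coordinate from the composite-model
families with per-embryo integer time shifts and iid Gaussian noise, with
optional injected spikes and gaps.

Phantoms do **not** emulate: anisotropic PSFs, depth-dependent
attenuation, non-marker fluorescence structure, cell divisions (Q/V5 is a
single track), eggshell confinement, or non-rigid body deformation between
timepoints.  Passing the phantom controls therefore demonstrates the
geometric correctness of the transform and the statistical behaviour of
the pipeline, not robustness to every imaging artifact of real diSPIM
data; real-data quantities (e.g. absolute inter-embryo variability) are
outside what these simulations can certify.

## Numerical choices and benchmark sizes

- Trilinear interpolation with zero fill for resampling (deterministic;
  nearest-neighbour would add half-voxel jitter to the controls).
- Point claiming: nearest plane center, smaller-s tie break, clip-radius
  and one-step axial gates (end planes: clip-radius outward gate).
- Benchmark runs (`scripts/acceptance.py`) use 10 timepoints of the
  elongating phantom at step 0.25 µm with geometry-only phantoms (no
  volume rendering), which keeps a full series under a few seconds while
  exercising the same model/mapping code paths as volume resampling.
- Detection/pairing tests use 60 µm phantoms at 1 µm voxels (volumes of
  ~60×25×45); local search on 10 pairs converges in a few sweeps.
- Stochastic guarantees are tested at fixed seeds: logistic parameter
  recovery (A within 5 %, C within one timepoint) and integer shift
  recovery hold in ≥ 95 % of replicates at noise SD 2 µm; model selection
  prefers the logistic on logistic data in ≥ 90 % of noisy replicates and
  always in the noiseless limit.

## Known limitations

- The sampling-plane z coordinate is quantized to the plane spacing;
  sub-step axial localization requires a smaller step, at linear cost.
- The symmetric clip radius over-clips the outside of sharp bends; an
  asymmetric per-direction clip would retain more voxels there.
- Pairing is a local search over a reconstruction of the published
  workflow's selection criteria; on very dense or highly twisted
  (> 180° between adjacent pairs) marker sets it can require the manual
  fallback, which is also the published tool's behaviour.
- `smooth50` reports AIC/SC with an effective k = 2, a heuristic for a
  nonparametric smoother; its criteria are comparable within smoothers,
  not against parametric families.
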