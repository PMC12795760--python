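# Methods

`axotomo` quantifies cryo-electron tomograms of regenerating axons: it
traces microtubules, detects the particles inside their lumen (MIPs,
microtubule inner proteins), classifies per-filament MIP occupancy,
measures the geometry of spiral tubulin oligomers, analyses microtubule
polarity from segment rotations, measures tubulin-lattice spacing by
rigid monomer fitting, and classifies fluorescence tracks of transported
tubulin clusters. Because the deposited tomograms are not required for
validating the algorithms, every stage is exercised end-to-end on seeded
synthetic scenes with known ground truth; this note documents both the
analysis procedures and the generator that stands in for the microscope.

## Conventions

* Lengths are nanometres everywhere inside the package; Å appears only
  at file boundaries (MRC cell parameters, PDB coordinates) and in the
  lattice-distance report, where the field's convention is Å.
* Volumes are `(z, y, x)` indexed, 0-based, voxel centers on the integer
  grid; the physical position of voxel `(k, j, i)` is
  `origin + voxel_size * (i, j, k)`.
* Contrast is `protein_dark` by default: protein renders as greyscale
  minima, as in unstained tomograms. All minima-based operators honour
  the flag.

## Filament tracing

Tracing is a matched filter with a hollow-cylinder template (100 nm
length, 7 nm lumen radius, 15 nm outer radius, soft 1-voxel edges,
zero-mean). The template is rendered analytically for ~100 directions on
the hemisphere (Fibonacci lattice) — the template is axially symmetric,
so direction is the only orientation parameter — and correlated by FFT.
The per-voxel normalized correlation uses the local mean/variance over
the template bounding box, floored at half the global standard deviation
so structure-free stretches cannot inflate the score. The best score
over orientations is thresholded (default NCC 0.1, roughly midway
between the measured on-axis response ~0.24 and the pure-noise ceiling
~0.013), skeletonized, and each connected component is linked into a
polyline between its two farthest voxels (double breadth-first search).

Because correlation support is partial near a filament's physical ends,
the thresholded tube tapers and overshoots; each path is cut back to
where its smoothed score exceeds 90% of its plateau (90th percentile)
and then by a further fixed 15 nm per end. Path voxels are refined to
the local correlation centroid (sub-voxel axis localization), smoothed
with an 11-point moving average to remove voxel-quantization zig-zag
(which would otherwise inflate arc length and every downstream spacing
by a few percent), and resampled by cubic interpolation at uniform 1 nm
arc length. Known centerlines can be injected instead of tracing
(`--centerline-in`), which is also how large synthetic populations are
processed.

Lumen (d ≤ 7 nm) and shell (7 < d ≤ 15 nm) masks use the exact
point-to-segment distance from every voxel center to the centerline
polyline, so mask voxel counts are brute-force checkable (a straight
axial line through a voxel center gives 149 lumen and 560 shell voxels
per 1 nm slice).

## Luminal particle picking

The picking chain is: Gaussian pre-filter (σ = 0.5 px, reflective
boundaries) → greyscale minima within each region mask (strict
26-connected minima; equal-valued plateaus count once, represented by
their lexicographically smallest voxel; a plateau with no higher
neighbour is not a minimum) → 0-dimensional sublevel-set persistence →
adaptive threshold → flat-kernel mean shift.

Persistence is computed with a union-find sweep over mask voxels sorted
by ascending intensity (ties by lexicographic index): a minimum's
persistence is the intensity at which its basin merges into an older
basin (elder rule: deeper birth wins, ties by birth voxel) minus its own
intensity; the region's global minimum receives (region max − region
min). The sweep is JIT-compiled (numba); a brute-force sublevel-set
flooding oracle cross-checks it property-style on small random volumes.

The persistence threshold is calibrated per filament on the *shell*: the
wall is a regular tubulin polymer, so its minima density is a contrast
invariant, and the threshold is set so that the retained shell density
is 0.006 vertices/nm³ — `k = round(0.006 × shell volume)`, threshold =
persistence of the k-th most persistent shell minimum, ties retained in
full. An under-populated shell yields threshold 0 with a warning. The
achieved density counts retained (post-threshold, pre-clustering)
minima. Shell minima are used only for calibration, never reported as
particles. The same threshold is then applied to the lumen minima.

Retained lumen minima are localized to sub-voxel precision (separable
parabolic fit) and clustered by flat-kernel mean shift with a 5 nm
bandwidth (MIPs are ~6 nm, multi-domain): every minimum seeds a mode,
modes iterate to the centroid of in-bandwidth points until the shift is
below 0.01 nm (max 500 iterations), and converged modes closer than
bandwidth/2 merge; cluster centroids are the means of their converged
seeds.

## MIP occupancy statistics

Particles project to the continuous arc-length position of their nearest
centerline segment; particles farther than the lumen radius from the
trace are excluded with a warning. Per filament, consecutive spacings of
the sorted positions are summarized by their median (robust to a single
missed pick; a max-gap statistic is available via
`FilamentMIPProfile.statistic = "max_gap"`). A filament is **sparse**
when the statistic strictly exceeds 50 nm, **dense** at ≤ 50 nm
(boundary value dense), **empty** with fewer than two particles.
Population summaries report the sparse fraction; MIP-free filaments are
the extreme of sparseness and count as sparse by default
(`empty_counts_as_sparse=False` excludes them and errors if nothing
remains).

## Spiral geometry

Subunit spacing is a line scan: intensity sampled by trilinear
interpolation every 0.1 nm along a polyline through the structure,
low-passed with a 0.4 nm 1D Gaussian (trilinear interpolation is
piecewise linear, and on oblique lines its kinks quantize peak positions
to voxel crossings), peaks (minima under protein-dark) detected with a
prominence of at least max(2 × the MAD-based noise estimate from
successive differences, 20% of the 5–95 percentile dynamic range), and
spacings taken as consecutive peak distances along the arc.

Spiral measurements start from approximate bead positions (supplied by
the generator or a user trace; de novo spiral detection is out of
scope), refined to the darkest voxel within 2 nm and then to sub-voxel
by a parabolic fit. Diameter is twice the radius of a circle fit: total
least-squares plane (SVD), in-plane projection, algebraic Kåsa circle
fit refined by geometric least squares. Collinear points raise an
"extended conformation" error — a legitimate state for string-like
oligomers, reported as such rather than a number. Width is the full
width at half maximum of the averaged in-plane radial cross-profile
through the fitted circle, evaluated at the bead positions against a
baseline taken from the profile tails; the average is measured on the
σ = 0.5 px smoothed volume used by the rest of the pipeline.

## Microtubule polarity

Per image, the reference axis is the axial circular mean of segment
rotations: angles are doubled, averaged as unit vectors, and halved,
which makes the reference insensitive to the 180° flips that encode
opposite polarity (a plain arithmetic mean of {10°, 190°} would be
meaningless). The axis representative (θ vs θ+180°) is chosen so the
mean normalized angle is below 90°, which reproduces plain-average
behaviour on all-parallel data at any absolute rotation and is invariant
to global rotation offsets. Normalized angles are angular distances to
the reference folded into [0°, 180°]; a filament is parallel when its
median normalized angle is below 90°. Folding happens after the axial
reference is computed.

## Lattice spacing

The four-chain model (A/C α-tubulin, B/D β-tubulin of two stacked
dimers) is refined chain-by-chain against the density: the score is the
mean cubic-B-spline-interpolated density at the Cα positions,
sign-adjusted for contrast and normalized by the map σ (an error is
raised if more than 10% of atoms leave the map). Optimization is
deterministic: a coarse translation grid (±1 nm, 0.25 nm step) followed
by Nelder–Mead over the six rigid parameters (rotation vector about the
chain centroid), capped at 10⁴ evaluations.

Distances are medians of corresponding-Cα separations over residues
1–37 ∪ 48–170 (the structurally conserved core; correspondence is by
shared residue number), requiring ≥ 50 shared residues. Three numbers
are reported: A–B (intra-dimer), B–C (dimer interface) and A–C. The A–C
median is the dimer repeat, the quantity whose printed ~83 Å magnitude
is conventionally labelled the "inter-dimer distance"; reporting all
three avoids the ambiguity between the pairing named in text and the
magnitude printed in figures.

## Transport statistics

Tracks are position time-series along the axon axis (µm; injury site at
0, anterograde positive). Net displacement is last minus first position
(endpoints, not path length). Classes: retrograde if net < −0.2 µm (the
dead band keeps jitter-only tracks out of the retrograde class, whose
criterion the source leaves unstated), else anterograde-beyond-5-µm if
net > 5 µm, else within-1-µm if |net| ≤ 1 µm, else intermediate.
Fractions are over tracks. Cluster density is count per 100 µm of axon.

## The synthetic generator

The generator renders protein-dark scenes at 1 nm voxels (round number
close to the 4×-binned experimental 1.068 nm).

**Microtubules.** The wall is a 13-protofilament lattice of Gaussian
blobs (σ 0.85 nm) at the 4.1665 nm monomer repeat (half the 83.3 Å dimer
repeat), in two staggered families at the inner and outer wall radii
(lumen+2.5 / outer−2.5 nm) with the 3-start helical rise between
protofilaments. Two design points matter:

* *Wall depth.* Wall blobs render at ~2× the depth of an isolated
  particle (the wall is a continuous, tightly packed polymer), giving
  the wall texture a peak-to-saddle modulation comparable to a MIP's
  depth. This is what makes the adaptive shell calibration behave as it
  does on real tomograms: the 0.006 nm⁻³ target falls *inside* the
  structural persistence range, so the threshold lands above the noise
  tail and the lumen retains essentially only genuine particles. With a
  texture-free (smooth annulus) wall the threshold would necessarily
  calibrate into the noise floor — a regime in which no
  persistence-based picker can work and which does not correspond to the
  data the procedure was designed for.
* *Noise.* Additive white Gaussian noise parameterized by the
  signal-to-noise **variance** ratio (the cryo-EM convention):
  σ_noise = std(signal over the rendered feature support) / √SNR.
  Microtubule scenes default to SNR 2.

MIPs are Gaussian blobs of 6 nm FWHM and unit depth on the centerline at
arc positions k × spacing (default 18.5 nm, the control-neuron value)
for k = 0 … floor(L/spacing), jittered axially with σ = 1 nm; features
extending outside the box are clipped and flagged in the ground truth.
An optional missing wedge zeroes a hard Fourier wedge about the y tilt
axis (30° half-angle emulates a ±60° tilt range). The splat kernel's
variance (1/6 voxel² per axis, trilinear deposition) is deconvolved from
every blob σ so rendered widths equal their nominal values.

**Spirals and actin.** Spirals are bead circles (diameter 37.8 nm, bead
FWHM 4.2 nm, subunit spacing 4.6 nm) in arbitrarily oriented planes;
closed circles carry round(circumference/spacing) evenly spaced beads,
open arcs floor(arc/spacing)+1; the fully extended string conformation
is available. Actin controls are straight bead filaments at 5.5 nm
periodicity. Spiral/actin scenes default to variance-SNR 5 — these
structures were measured on high-contrast, denoised reconstructions, and
line-scan peak positions degrade qualitatively below that.

**Lattice density.** A fixed pseudo-monomer (170 Cα positions on a
smoothed, confined random walk ~2 nm across) is stacked into chains A–D
at z-offsets {0, f·d, d, d+f·d} for dimer repeat d and intra-dimer
fraction f (default 0.5), smeared with a 2.5 Å Gaussian onto a 1 Å
grid. The unperturbed model is the ground truth.

**Tables.** Rotation tables draw per-filament polarity
(Bernoulli(parallel fraction)), set segment rotations to the per-image
reference plus 0° or 180° plus Gaussian noise, and keep the truth label.
Track tables draw classes from a stated mixture and realize each class's
net displacement exactly at the endpoints (anterograde > 5: U(5.5, 12);
intermediate: U(1.2, 4.8); within 1 µm: U(−0.15, 1.0); retrograde:
U(−8, −0.5) µm), with small mid-track jitter.

All generators are bit-reproducible under a fixed seed.

### What the generator does not emulate

No CTF modulation, dose weighting, membranes, vesicles, cytosolic
crowding, or filament curvature beyond what control points specify; the
wall lattice is geometrically ideal (no seam, no protofilament-number
variation); noise is white rather than reconstruction-correlated. A
passing recovery study therefore shows that the *operators* are correct
and well-calibrated under controlled contrast, not that the pipeline is
robust to every pathology of real tomograms.

## Study conditions of the recovery experiments

The bundled recovery studies (`axotomo.experiments`, also behind
`scripts/acceptance.py`) use desk-scale problem sizes chosen to keep a
single-CPU run in minutes while preserving the populations' statistics:
one 500 nm microtubule for calibration and spacing recovery (tracing run
for real in the spacing study); 300 microtubules of 250 nm for occupancy
recovery, with ground-truth sparse assignment at exactly the stated
fraction (sparse filaments draw spacings U(60, 90) nm) and generator
centerlines supplied through the documented tracing bypass; 100 spirals
and 20 actin filaments for geometry; a two-dimer lattice at 83.3 Å
refined from starts perturbed by ≤ 3 Å and ≤ 5°; 200 tracks at the
axotomy+EpoB mixture (39% anterograde > 5 µm, 9% retrograde, remainder
split 35% within-1-µm / 17% intermediate — the split of the remainder is
not separately constrained). In both population studies the stated
proportion is the condition itself, so the ground-truth assignment
realizes it with exact counts (shuffled by seed); with independent
per-item draws the realized truth would fluctuate by several points at
these population sizes and the recovered fraction would measure that
sampling noise rather than the classifier.

## Numerical choices and degenerate inputs

* Persistence ties (equal birth values) break by lexicographic voxel
  order; threshold ties are retained in full, so calibration is
  order-independent.
* k rounds half-up; an under-populated shell logs a warning instead of
  failing.
* Mean shift stops at 0.01 nm shift or 500 iterations; the flat kernel
  makes fixed points exact centroids.
* Circle fits refuse collinear inputs (second SVD singular value below
  10⁻⁶ of the first) with the extended-conformation error.
* Occupancy threshold is strict (> 50 nm sparse); exactly 50 nm is dense.
* A constant region has no strict minima; a single isolated voxel is a
  minimum with persistence 0.
* MRC i/o is limited to the MRC2014 mode-2 (float32) dialect and fails
  loudly, naming the offending header field.

## Known limitations

* The matched filter loses ~45 nm at each filament end (partial template
  support); end particles may project onto the trace boundary.
  Filaments shorter than ~150 nm are not traceable with the default
  100 nm template; supply centerlines instead.
* Per-filament calibration assumes the shell is mostly intact; heavily
  decorated or broken walls would bias the threshold.
* The polarity reference degrades gracefully but is under-determined on
  images with a near-50/50 polarity split; the axis is then pinned by
  the mean-angle rule, and per-filament calls remain consistent relative
  to it.
* Rigid fitting assumes the start is within ~2 nm / 10° of the optimum;
  it performs local refinement, not a global search.
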