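# Methods

## The phantom model

Each synthetic animal carries two region solids, apoptotic-marker point
sets, and two covariates. The solids are axis-aligned ellipsoids whose long
axis runs along z, the rostrocaudal sectioning direction; DG uses aspect
ratios (0.5, 0.5, 2.5) and CA3 (0.7, 0.7, 2.2) before isotropic scaling, so
both span a few mm rostrocaudally as rat hippocampal subfields do. The
scale factor is chosen so the closed-form volume (4/3·π·abc) equals the
per-animal drawn volume exactly; CA3 is displaced along x by the sum of the
two x semi-axes plus 0.2 mm, which guarantees the solids never overlap. An
extruded-polygon solid (profile area × extent) is also supported for
arbitrary profile shapes.

Apoptotic cells are reduced to a single reference point each (the cell
"top"), seeded as a homogeneous Poisson process: the count is
Poisson(intensity × volume) and locations are uniform inside the solid by
rejection sampling. The single-point particle model means a cell belongs to
exactly one section slab, which makes dissector counting unambiguous and
the conservation identity exact.

Per-arm simulation targets default to the printed group summaries of the
study this package emulates (volumes ~1.58–3.15 mm³, intensities
613–18 055 mm⁻³, blood glucose 101–568 mg/dL, plasma Cu ~7.2–7.3 µg/dL).
The diabetic-arm Cu level was published only graphically; the shipped
default of 8.0 ± 0.5 µg/dL is a synthetic stand-in and is labelled as such
in the fixture file.

The sextuple (V_DG, V_CA3, ND_DG, ND_CA3, BG, Cu) is drawn per animal from
a Gaussian copula with Normal marginals truncated below at 10% of the group
mean (configurable) to exclude non-physical values; at the default SD/mean
ratios the truncation essentially never binds, so marginal means and the
target correlations are preserved. The reported pairwise correlations
(V–BG ≈ −0.9, ND–Cu ≈ 0.99, …) are not jointly positive semi-definite once
assembled into a 6×6 matrix, so the default target is their nearest
correlation matrix (Higham's alternating projections; no entry moves by
more than 0.02). A user-supplied non-PSD matrix is rejected rather than
silently repaired.

Sectioning cuts half-open slabs [z₀+kt, z₀+(k+1)t) tiling the joint
z-extent of both solids, with the section profile taken as the solid's
cross-section at the slab midplane. A marker whose z falls exactly on a
slab boundary belongs to the upper slab. The study design uses 10 µm
sections for volume estimation and 5 µm sections for apoptosis counting;
the generator sections each phantom independently at each thickness.

## Cavalieri estimator

Sections are sampled systematically (every k-th after a uniformly random
start); a square point lattice with uniformly random offset is laid over
each sampled section and V = k·t · u² · Σp. T in the formula is interpreted
as the effective thickness k·t represented by each sampled section —
standard Cavalieri practice when only every k-th section is counted.
Defaults: period 10, spacing u = 0.1 mm; at the study's region sizes this
yields Σp of order 2×10³ per region, so the point-counting contribution to
the error is well below the biological SD. With both randomisations the
estimator is design-unbiased for the Riemann (midplane) volume of the
profile stack, which itself converges to the true solid volume as t → 0;
at 10 µm on ~4.6 mm solids the midplane discretisation error is below
10⁻⁴ relative.

Boundary tie-break: a lattice point exactly on a profile edge is tested
after a +10⁻⁹·u nudge in x and y, so left/bottom edges count as inside and
right/top edges as outside; adjacent tiled profiles can never double-count
a point. The lattice is axis-aligned (rotation not randomised), as is
common practice. A Gundersen–Jensen CE (smoothness class m = 1, no nugget
term) is available as a diagnostic but takes no part in estimation.

## Physical dissector

Pairs (reference, look-up) are formed at a z interval that must be an
integer multiple m of the cutting thickness (default: the 5 µm adjacent
section), stepping 2m·period with a random start, so pairs never share a
section. Counting uses the unbiased counting frame: markers strictly inside
or on the right/top inclusion edges count, markers on the left/bottom
exclusion edges do not. Counting is unidirectional (reference → look-up);
with single-point markers the look-up check can never veto a count, and the
estimator reads N_v = ΣQ / (a·h·ΣP).

Frame placement is a square lattice with uniformly random offset over each
sampled reference profile, the pitch chosen so roughly `n_frames` frames
are applied per animal per region. The default retention rule keeps a frame
only when it lies entirely inside the reference profile: conditional on
retention the count in a frame is exactly Poisson(λ·a·h) for a homogeneous
process, making the estimator exactly unbiased. The alternative rule that
keeps any frame whose lower-left probe point hits the profile is provided
(`retention="probe"`) but carries an O(frame/region) negative edge bias
(≈10% at 100 µm frames on these profiles, measured by simulation), because
partially overhanging frames can only undercount a process that exists
solely inside the region.

Defaults: 100 × 100 µm frames, h = 5 µm, 300 frames per animal per region.
The frame count was set from the expected-count budget: at the lowest
study intensity (945 mm⁻³) a frame-pair samples λ·a·h ≈ 0.05 cells, so
~300 frames yield ≈ 9 counted cells per animal — enough for the group-level
recovery the pipeline reports; 20 frames would yield < 1.

## Indices, curves, critical point

RI = DG quantity / CA3 quantity. Two computation modes exist because
published tables built from per-animal ratios cannot be reproduced exactly
from group means alone: `per_animal` (mean ± SD of each animal's own ratio;
used in the simulated pipeline) and `ratio_of_means` (ratio of group means;
used to reproduce a printed summary table). `reproduce_table1` recomputes
the published index table from the packaged printed means at 2-dp
round-half-even and flags the two volume cells (Ins, VitC) where the
ratio-of-means value is known to differ by 0.01 from the published
per-animal figure.

Index curves are least-squares polynomials (default linear, degree ≤ 2)
over the arm coding Con=1, Ins=2, VitC=3, Dia=4; the published figure's
exact fit form is not recoverable, so the linear default is validated
against closed-form normal equations instead. The critical point solves
the difference polynomial — closed form for two lines, real roots of the
difference otherwise — within a configurable x-range (default [1, 6]),
returning the smallest in-range intersection and verifying both curves
agree there to 1e-9. Parallel distinct lines, identical curves, and
out-of-range crossings raise typed errors. On the published cells the two
fitted lines are y = 0.55 + 0.068x and y = 2.145 − 0.337x, meeting at
x* = 319/81 ≈ 3.94, Y* ≈ 0.82.

## Statistics

One-way ANOVA (F = MS_between/MS_within), Tukey's HSD via the studentized
range (Tukey–Kramer for unbalanced designs), and Pearson correlation with
the two-sided t-transform p value, all delegated to scipy behind a thin
validation layer; unit tests pin F to an exact rational hand computation
and the Tukey adjusted p values to an independent R reference at 6
significant digits. Degenerate inputs (groups of one, all-identical data,
constant correlation inputs) are rejected rather than returning NaN.

## What the phantoms do and do not show

The generator reproduces the study's sampling geometry (serial sectioning,
SURS, frame counting), its group structure and its between-animal
variability, so passing tests demonstrate that the estimators are
implemented without bias and that the pipeline recovers configured group
differences at the study's sample size. The phantoms do not emulate
staining artifacts, tissue shrinkage, lost or folded sections,
inhomogeneous apoptosis (cells cluster in the granular/pyramidal layers in
real tissue), or segmentation error in the region profiles — so agreement
here does not certify those error sources in real material.

## Problem sizes and numerical choices

The shipped validation runs use 500 sampling randomisations for the
Cavalieri check, 100–300 marker realisations per intensity for the
dissector check, and 200 replicated four-arm studies for the ANOVA power
check; these sizes put the Monte-Carlo standard error comfortably below
the tolerances being asserted. Low-count arms use more replicates because
the per-study dissector count at 945 mm⁻³ is only ≈ 9 cells. All random
draws flow through `numpy.random.Generator` seeded explicitly; identical
seeds give bit-identical reports.
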