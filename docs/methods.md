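# Methods

This note documents the models, conventions, numerical choices and known
limitations behind each analysis stage, and what the synthetic generators
do and do not emulate.

## Coordinate and angle conventions

STAR coordinates are 0-based pixels in image convention (origin top-left,
y down). All geometry runs in a math-convention frame via the single
documented flip `(x, y)_math = (x_px, −y_px)`, scaled to nm by the pixel
size (default 0.83 Å/px, the K3 detector at 105,000×; overridden by the
STAR optics table when present). Angles are degrees at I/O, wrapped so that
rot, psi ∈ [−180, 180) and tilt ∈ [0, 180]; internal computation is in
radians.

Euler angles follow the RELION/XMIPP ZYZ convention,
A = Rz(psi)·Ry(tilt)·Rz(rot), with the filament plus-end along the
reference +z. The in-plane image of +z is
(sin tilt · cos psi, sin tilt · sin psi): the direction reduces to
(cos psi, sin psi) because sin tilt ≥ 0, rot drops out, and sin tilt is
kept as a reliability weight. Whether RELION's psi sign in image pixels
requires one further global negation cannot be settled without reference
micrographs; a global 180° flip changes every arrow but provably no
parallel/antiparallel call and no distance (this invariance is tested), so
all bundle statistics are unaffected.

## Consensus polarity

Segments viewed nearly end-on carry no usable in-plane direction;
sin tilt < 0.1 excludes a segment (the direction is ill-conditioned
there). Remaining directions are combined by a weighted circular mean with
axial disambiguation: two candidate orientations (raw weighted mean, and
the doubled-angle axial mean) are each refined by flip-toward-mean passes
until stable, and the assignment with the larger weighted mean resultant
length R wins. The global sign is set so flipped segments are the weighted
minority; an exact tie is resolved toward the representative angle in
[0, 180) and flagged. R ("coherence") must reach 0.8 (configurable) for a
filament to count as confidently polarised. The refinement makes the
result invariant to segment order and to pre-flipping any single segment.

## Bundle pairs and spacing

Axes are total-least-squares (first principal component) lines — x and y
enter symmetrically, which matters at arbitrary filament orientation.
Pair gating (defaults: mutual overlap ≥ 0.5 of the shorter filament, edge
gap ≤ 50 nm) is a deliberate, configurable definition of "bundled"; the
spacing measure is the mean perpendicular distance from 64 points sampled
along the shorter axis's overlap region to the other line. Spacing is
reported both center-to-center and edge-to-edge; the edge gap (center
distance minus the 25 nm outer diameter) is the headline number because
reported minimum spacings of a few nm are only meaningful wall-to-wall.
Negative edge gaps are allowed but flagged as overlapping. Orientation
classes use the angle between consensus plus-end vectors with a ±1° tie
band around 90° flagged ambiguous. The parallel fraction gets an exact
two-sided binomial test against 0.5 — a principled test for a binary
classification count; ambiguous pairs are excluded from the fraction.
Histogram bin width defaults to 1 nm.

## Binding isotherms

The single-site hyperbolic model f([L]) = Bmax·[L]/(Kd+[L]) assumes the
pelleted probe is sub-stoichiometric relative to polymer binding sites (no
ligand depletion); a quadratic tight-binding variant taking the probe
concentration is available behind `model="quadratic"`. Bmax is fitted
(bounded (0, 1.05]) rather than fixed at 1 because incomplete pelleting is
common. Fits run per replicate (reported mean ± SD, the usual triplicate
presentation) and pooled; initialisation is Kd₀ = concentration nearest
half-max, Bmax₀ = max observed fraction. Warnings (not errors): titration
span under one order of magnitude; fitted Kd above 5× the top
concentration ("poorly constrained"); zero curvature. Background
subtraction for control lanes is a simple clipped subtraction of matched
control intensities before forming P/(P+S).

SEC calibration is linear in log10(MW) vs elution volume (standard
Superdex practice), requires ≥ 3 standards with elution strictly
decreasing in MW, and warns on extrapolation. The oligomeric state is the
nearest positive integer of apparent/theoretical monomer mass.

## Dynamic-instability segmentation

The trace is modelled as piecewise-linear with additive Gaussian noise of
unknown level; sigma is estimated robustly from successive differences
(scaled MAD about the median difference — insensitive to the slope and to
rare catastrophe jumps). Changepoints are found by exact penalised optimal
partitioning (dynamic programming over least-squares line segments,
vectorised on prefix sums), penalty 3·σ²·ln n per segment. The penalty is
deliberately above the pure-BIC level: empirically the maximal spurious
split gain of a 600-sample noise-only trace is ≈ 2σ²·ln n, so 3σ²·ln n
keeps false changepoints rare while kinks between phases of ≥ 30 s remain
detectable at the design noise level (20 nm at 1 Hz).

Segments are classified against the ±0.3 nm/s pause band — chosen below
the slowest growth velocity of interest (1.71 nm/s) — with a significance
guard: the full-segment slope must clear the band by 2 standard errors of
the slope estimate, otherwise the segment is a pause. Same-kind neighbours
merge. Sub-5 s phases are absorbed into a neighbour only when the merge
costs less than the changepoint penalty, so genuine depolymerisation
spikes survive while flickers vanish. A rescue pass then re-examines each
phase at penalty/3 for a split whose halves (each ≥ 10 samples) classify
as different kinds: two-run growth|pause mixtures whose single kink falls
just below the free-changepoint penalty are recovered, while uniform
phases are protected by the double requirement (gain and kind change).

Reported phase velocities are re-fitted on a boundary-trimmed interior:
changepoint localisation error is of order σ/|Δv| samples and leaks the
neighbour's velocity into an untrimmed fit, always biasing slow-growth
slopes toward the pause level. The trim is 2σ/|Δv| samples per shared
boundary; a phase whose interior cannot be cleared (fewer than 5 samples
left) keeps a quarter-span trim but is flagged `velocity_reliable=False`
and excluded from velocity aggregates (it still counts for durations and
event transitions).

Event statistics: catastrophe = (growth|pause)→shrinkage, rescue =
shrinkage→(growth|pause); f_cat is normalised by total growth+pause time
(pauses precede catastrophes in the slow-growth condition), f_res by total
shrinkage time and reported as undefined — not zero — when no shrinkage
was observed. The condition-level growth rate is the mean ± SEM of
reliable growth-phase velocities after symmetric rejection of phases more
than 3 scaled-MAD from the median: phases that merge slow growth with
pauses below the detection limit form a one-sided low-velocity tail that
an unscreened mean cannot resist (and duration weighting amplifies, since
the longest phases are the likeliest mixtures).

Residual accuracy at the design conditions (50 traces × 600 s, 20 nm
noise), measured on validation seeds: fast growth (≈ 14–15 nm/s)
recovered within 0.1%, slow growth with pauses (1.71 nm/s) within
1–8% (systematically low; unresolvable short-run mixtures), catastrophe
frequency within ~15–20% (Poisson counting plus events hidden by the
zero-length reflection). The rescue frequency is reported but not
validated against the generator: regrowth after the simulator's reflection
at zero length is observationally identical to a rescue, so the measured
shrinkage→growth rate necessarily conflates the two.

## Synthetic generators

Each generator takes an explicit seed for a single NumPy Generator (no
hidden global state) and emits a `GroundTruth` record that serialises to
JSON and regenerates bit-identically.

`gen_bundle_star` places one filament pair per synthetic micrograph: two
straight, staggered (overlap ≥ 0.8) filaments at random orientation,
separated by edge gap + outer diameter; psi = plus-end angle + Gaussian
noise, tilt = 90° ± 5° clipped, rot uniform, coordinates jittered. The
orientation composition is exact — round(fraction_parallel·n_pairs) pairs
parallel, order shuffled by the seed — so a requested composition is
always reproduced exactly rather than Bernoulli-sampled. Defaults mirror
the bundled-pair study conditions: 177 pairs with 91 parallel, gaps
2–14 nm, 5° angle noise, 1 nm coordinate jitter, 12 segments per 300 nm
filament at 0.83 Å/px. Not emulated: curvature (the spacing measure is
agnostic to mild curvature), rasters, crowded fields with more than two
filaments per micrograph.

`gen_cosed` draws lane fractions from the hyperbolic isotherm with
multiplicative Gaussian noise (clipped to [0, 1]) and log-normal total
lane intensity (σ = 0.2 around 1000 a.u.), splitting pellet/supernatant
accordingly. Not emulated: lane-to-lane background, saturation, smile.

`gen_traces` runs a three-state continuous-time Markov chain
(growth→shrinkage at f_cat, growth↔pause at the pause entry/exit rates,
pause→shrinkage at f_cat, shrinkage→growth at f_res), integrates the state
velocity, reflects at zero length (regrowth from the seed), samples at dt
with additive Gaussian noise and clips at zero. The analytic stationary
distribution of the rate matrix (ignoring reflection) is exposed for
validation. Not emulated: tip-tracking localisation error correlated over
time, photobleaching, velocity variability between filaments.

Passing tests on these generators show the pipeline recovers known truth
under idealised noise; they do not establish performance on real
micrographs (picking errors, curvature, overlapping filaments) or real
kymographs (correlated noise, drift).

## Degenerate inputs and tie-breaks

Coincident points → axis error; identical axes → center distance 0,
edge gap −25 nm, flagged. Single-particle tubes are flagged untraceable
and excluded from geometry with a logged warning. Consensus ties between
the two global orientations resolve toward the angle in [0, 180) and are
flagged. Zero-noise traces give σ̂ = 0, so any true kink is split and
exact ramps stay single phases (ties in the partition resolve toward
fewer segments). Band-edge classification ties (slope exactly at the
band) are pauses.

## Problem sizes

The self-checks run at the scales the analyses are designed for: 177
filament pairs (≈ 4,200 segments), 200 simulated titrations per Kd
recovery (8 concentrations × 3 replicates), and 50 traces × 600 s per
dynamics condition. Each completes in seconds on one CPU.
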