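# Methods

This note documents the models and algorithmic choices behind `spinemech`:
what each stage computes, which parameters matter, what the synthetic data
do and do not emulate, and where the design was genuinely open.

## Coordinate and measurement conventions

Profiles live in the *local sagittal plane* — the plane bisecting a spine
perpendicular to the surface it sits on, which is also the plane of the
serial-angle test rotations. The tip points toward −y at a 0° test angle;
test angles are in-plane rotations in 10° increments. The reference length
of a spine is its **longest axis**: the maximum distance between any two
outline points (caliper length). All spines in the physical protocol are
scaled to a common longest axis before printing, so the normalized tip
radius (tip_roc / longest axis) is the comparable sharpness quantity; the
per-spine table's radius column is treated as length-normalized on that
basis (the raw measurements were recorded in pixels at a common print
scale, which is dimensionally consistent with length normalization but is
an interpretation, not a stated fact).

## Shape metrics (`geometry`)

**Circle fitting.** Algebraic (Kåsa) least squares seeds a
Levenberg–Marquardt refinement of the true radial residuals; `rmse` is the
root-mean-square radial residual. Near-collinear input (second singular
value below 1e−9 of the first) is rejected rather than returning an
unstable fit.

**Centerline.** The midline is traced by tube-following from the apex:
each step advances a short distance (half-perimeter / 160 by default)
along the current axis tangent and recenters on the cross-section chord
through the stepped point. The tangent update is momentum-damped
(0.75 old + 0.25 new) because the raw recentering feedback oscillates; the
chord orientation is refined by minimizing chord length over a ±6° tilt
window, accepted only when tilting shortens the section by more than 2%
(marginal "improvements" arise at taper corners and would bias the
midpoint). The trace ends when the axis exits the base or the chord starts
clipping the base cap (chord length dropping 25% between steps), finishing
with a straight extension to the base surface. Stations are resampled
uniformly and polished by under-relaxed (ω = 0.4) perpendicular-chord
recentering with tangents from a smoothed midline, iterated to
convergence; under-relaxation is required because the plain recentering
iteration has feedback gain above one in steeply tapering regions.
The result is ordered base → tip with per-station half-widths. On
generated test shapes the stations sit on the generative arc to ~1e−3 of
the length mid-body, and a straight cone's centerline is collinear to
1e−6 of the length. This tube-following formulation replaces a
perpendicular-to-one-axis scan, which cannot parameterize hooks curved
beyond ~90°.

**Tip angle.** Total-least-squares lines are fit to the two flank point
sets near the apex; the angle between them is the tip angle. Each flank
window starts just beyond the rounded cap — by default the cap extent is
detected by the adaptive cap fit (`cap_exclusion="auto"`); a numeric
`cap_exclusion` gives a fixed exclusion instead — and grows away from the
apex only while the points stay on the fitted line (residual tolerance
2e−3 of the length), bounded by `flank_window` (default 0.15 of length).
The growth rule matters for blunt spines: a fixed window would average the
parallel-sided shank into the flanks of a short, wide wedge and
underestimate angles near 90° by over 15°. Recovered tip angles on
noiseless generated profiles are within 0.6° across tip angles 15–90° and
curvatures 0–110°; the value is stable within ±3° across flank windows
0.10–0.20 on hooked spines.

**Tip radius of curvature.** The default is an adaptive grow-from-apex
fit: the innermost boundary vertices (≥7) seed a circle, and vertices
further from the apex are admitted while they stay within 2% of the fitted
radius, bounded by `cap_window` (default 0.05 of length). This handles the
full observed range of normalized radii (0.025–0.60) with one default — a
fixed window is contaminated by flank points for fine tips and truncates
large caps. `adaptive=False` fits all points in the window (the classical
fixed-window measurement). A fit whose rmse exceeds 5% of the radius — a
sharp wedge with no real cap — is flagged with a warning.

**Structural curvature.** The bisecting-circle construction: find the
largest tip-anchored prefix of centerline stations whose best-fit circle
stays within `deviation_tol` (default 0.25) of the local half-width at
every included station — "the circle still bisects the spine" — and
return the arc angle accumulated around that circle between the tip and
the last included station. Half-widths are floored at 2% of length for
the tolerance so the near-apex stations (half-width → 0) do not veto
every fit. Prefix search runs from the full centerline downward, so a
constant-curvature spine is fit in one step; near-straight spines (fit
radius above 10³ × length, or collinear stations) return 0°. Noiseless
recovery is within 3.7° over the factorial sweep below, against a ±5°
design tolerance.

**Volume and morphotype.** Volume is the signed divergence-theorem sum
over triangles of a watertight mesh (via trimesh); non-watertight input is
rejected with the open-edge count. Morphotype flags: elongate ⇔ aspect
ratio (max width / longest axis) < 0.5; hooked ⇔ structural curvature
≥ 60°; wavy ⇔ the centerline turning direction flips ≥ 2 times (turns
below 0.75°/station are noise); conical ⇔ out-of-plane / in-plane width
ratio ≥ 0.8. All thresholds are fields of `MorphotypeThresholds`.

**Apex identification.** Generated profiles carry their exact tip vertex.
Profiles read from CSV use an `is_tip` marker column when present;
otherwise the vertex farthest from the polygon's area centroid is used
(deterministic, ties to the smallest index), which can mis-pick on
strongly hooked outlines — annotate the tip when possible.

## Puncture events and performance (`puncture`)

**Detection.** The force series is moving-median smoothed (window 5
samples). A candidate event is a smoothed local maximum followed within
`max_drop_width` (0.2 mm) by a decrease of at least
max(`min_drop_abs` = 0.5 N, `min_drop_fraction` = 0.10 × peak). A
**persistence** requirement — the smoothed force must stay below
peak − drop/2 for one further drop-width beyond the trough — separates
true punctures (loading resumes from the dropped level) from transient
noise excursions; without it, ~5σ noise ranges in the low-force head of a
trace occasionally clear the 0.5 N absolute threshold and the
false-positive rate cannot reach zero at 0.2 N noise. The reported
`peak_force` is the unsmoothed maximum just before the steepest force step
of the drop (median smoothing erodes sharp peaks, so the smoothed argmax
sits a few samples early and would bias the peak low). At 0.2 N noise and
40% drops the detector attains 100% sensitivity, 0% false positives on
matched no-drop traces, and peak-force error ≤ 3σ in ≥ 99% of events
(1000 seeded traces).

**Summaries.** A trial succeeds iff at least one event is detected; its
force is the first event's peak (first-event convention — later, larger
peaks are re-punctures of deeper layers). An angle succeeds if any of its
replicates did (`rule="majority"` is available; replicate disagreement is
flagged in the output). Per spine: puncture range = max − min successful
angle (0 when at most one angle succeeded — this convention reproduces the
published pattern in which a never-puncturing spine prints range 0 with
missing forces); lowest force = minimum over all successful replicate
forces; average force = mean over successful angles of the per-angle
replicate means (the per-angle means are computed first, matching the
protocol's description; whether the published per-angle averages included
failed replicates is unstated — successful-only is used and flagged).
Broken spines are retained in the table with `broken`/`excluded` flags so
downstream statistics can drop them while keeping the audit trail.

## Shape space (`morpho`)

GPA centers each configuration, scales to unit centroid size, and
iteratively rotates to the consensus (mean, renormalized) until the
consensus rms change is below 1e−10 (max 100 iterations). Rotations are
proper by default — spine chirality is biologically meaningful (left and
right hemipenes are mirror images) — with `allow_reflection=True`
available. PCA is the SVD of the centered vectorized aligned coordinates;
each axis is oriented so its largest-magnitude loading is positive
(deterministic signs across platforms); variance fractions sum to 1.

The permutation linear model regresses vectorized aligned shapes on a
covariate (numeric, or dummy-coded factor) and forms
F = (SS_eff/df_eff)/(SS_res/df_res) from Procrustes sums of squares. The
null distribution permutes the rows of the intercept-only-model residuals
(residual randomization); the observed arrangement counts toward the null,
so min p = 1/(n_permutations + 1). Defaults: 999 permutations, seeded.
Under a simulated null the rejection rate at α = 0.05 sits inside the
exact binomial 95% interval (200 datasets × 999 permutations).

Phylomorphospace: internal-node scores minimize Σ_edges (Δscore)²/length —
branch-length-weighted squared-change parsimony, equal to the ML Brownian
ancestral states — solved as one sparse linear system per score axis.
Zero or missing branch lengths get ε = 1e−8 × tree height. Tips without
scores are pruned; scored labels missing from the tree are an error.
States match a brute-force numeric minimizer to 1e−6 on all tested trees
up to 6 tips.

Reproducing the published morphospace percentages (e.g. PC1 variance of
the real 41-spine dataset) requires the deposited landmark data, which is
outside the package's scope; the morphospace machinery is validated on
synthetic landmark sets with known latent structure instead.

## Regressions and reference tables (`stats`)

`ols` is ordinary least squares with intercept after listwise deletion;
the p-value is the two-sided t test on the slope with n − 2 df (via
`scipy.stats.linregress`; cross-checked against statsmodels in the test
suite). The screen fits one model per predictor and logs the exact cohort:
by default broken spines are excluded everywhere and never-puncturing
spines keep their 0° range in range models while dropping out of force
models via their missing force fields. No multiple-testing correction is
applied to the primary p-values (matching the marginal presentation of the
source analysis); a Benjamini–Hochberg column is emitted alongside. On
the packaged per-spine table, average force on tip angle gives
p = 0.05204 with the default cohort (n = 11: broken spine and
never-puncturing spine excluded); including the broken spine gives
p = 0.014 — the cohort is printed with every result row so the choice is
auditable.

The two reference tables ship as CSVs with sha256 checksums verified at
load; the 13-row per-spine table carries the broken flag and the
missing-force row exactly as printed.

## Synthetic data (`synth`)

**Profiles.** A generated spine is a tapering outline around a
circular-arc centerline whose arc angle *is* the structural curvature.
Near the apex the outline is a wedge of the requested tip angle closed by
an *exactly circular* cap of the requested tip radius, centered on the
centerline point one radius from the apex — exact even on curved
centerlines, so the ground truth for the tip radius is exact. The body
tapers to the base width, then runs as a constant-width shank to a flat
base. The centerline arclength is solved by Brent's method so the
emitted outline's longest axis equals the requested length to 1e−10,
keeping all other dimensions exact in mm. Waviness (lateral sinusoid,
2.5 periods) exists to exercise the wavy morphotype flag; with it the
structural-curvature ground truth is approximate. The cap-tangency
feasibility condition is tip_roc·cos(tip_angle/2) < base_width/2; blunt
domes with normalized tip radius up to 0.6 (the largest observed value)
are generatable with wide tip angles.

**Meshes.** Sweeping elliptical cross-sections (in-plane semi-axis = local
half-width; out-of-plane = half-width × lateral_compression) along the
measured centerline, closed by apex and base-center fans. Volume matches
an independent column-parity voxelization oracle within 2% and scales
exactly linearly in lateral_compression.

**Traces.** F(d) = F_p·(d/d_p)^p with exponent p = 1.5 (Hertz-like;
any convex ramp suffices for drop detection and the exponent is exposed),
a drop of `drop_fraction` (default 0.4) completed in one sample step at
the puncture displacement, resumed loading, additive seeded Gaussian
noise, truncation at the travel limit (5–15 mm; compression rate 10
mm·min⁻¹ carried as metadata). A trace embeds an event iff
drop_fraction > 0, so matched event/no-event pairs share every other
parameter and seed.

**Experiments.** Trial success is deterministic: angle a succeeds iff
|a| ≤ max_puncture_angle = base_max_angle + curvature_to_angle ×
structural_curvature, making success contiguous in |a| (whether the
physical protocol stopped at the first failure or probed past gaps is
unstated; no gap mode is exposed). Required force is
F(a) = force_at_zero + force_angle_slope·|a| with force_at_zero =
base_force + tip_angle_to_force × tip_angle. Defaults — grid ±30° in 10°
steps, 3 replicates, base_max_angle 5°, curvature_to_angle 0.25°/°,
base_force 5 N, tip_angle_to_force 0.4 N/°, force_angle_slope 0.1 N/°,
noise 0.2 N — keep simulated forces within the observed 3–50 N envelope
and ranges within the observed 0–60°, and encode the observed effect
*directions* (curvature widens the puncture envelope; blunter tips need
more force); the published study reports directions, not functional
forms, so the linear links are a modeling choice. Substrate and print
material moduli (silicone ≈ 1 MPa, resin 2.8 GPa) are metadata only — no
contact mechanics is simulated, because the physical study measures
rather than models the contact.

**Landmarks.** A template configuration deformed along one latent
direction per specimen plus isotropic noise and a random similarity
transform; PC1 of the aligned data recovers the latent scores
(|r| > 0.99 at default noise), giving a known answer for the morphospace
and permutation-model validation.

**What the synthetic data do not emulate.** Real µCT segmentation
artifacts, surface texture, asymmetric taper, out-of-plane curvature,
material failure (one physical spine broke during testing; breakage is a
manual flag here, not a simulated event), viscoelastic substrate
behavior, and landmark correspondence error from automated alignment.
Passing tests therefore demonstrate the correctness of the measurement
and inference machinery under controlled conditions, not the field
accuracy of the metrics on noisy scan data.

## Validation problem sizes

The self-validation run by the test suite and `scripts/acceptance.py`
uses: a 6 × 7 factorial of tip angle {15…90} × structural curvature
{0…110} at 512 outline points with slender study proportions (length
3.22, base width 0.64, tip radius 0.08 — aspect ≈ 0.2, the needle-like
end of the observed range; the tip-radius ladder {0.025, 0.08, 0.60}
uses matched tip angles and base widths since a 0.6-length cap radius
only exists on wide blunt domes); 1000 seeded trace pairs for detector
calibration; 200 datasets × 999 permutations for type-I calibration of
the shape model; and 200 simulated 20-spine experiments for effect-sign
recovery. These sizes give stable estimates at desk scale.

## Known limitations

- The centerline is a planar construction; spines with strong
  out-of-plane curvature need a 3D medial axis the package does not
  provide.
- The structural-curvature stopping rule operationalizes a visual
  judgement ("no longer bisects") as a half-width-relative tolerance;
  different tolerances shift values by a few degrees on wavy shapes.
- The apex heuristic for unannotated CSV profiles can mis-identify the
  tip of strongly hooked outlines.
- `performance_table` assumes the trial grid is the tested grid: angles
  never tested are indistinguishable from angles not provided.
- The permutation model fits a single covariate (or factor) at a time;
  there is no multi-term or phylogenetically corrected model, matching
  the scope of the source analysis.
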