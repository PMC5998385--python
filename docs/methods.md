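# Methods

This note documents the models, numerical schemes, parameter choices and
known limitations of `atriafit`, the way a simulation package should be
read before its results are trusted.

## The cell model

Local electrophysiology is a modified Mitchell–Schaeffer (mMS) two-variable
model: a dimensionless transmembrane potential `vm` (rest 0, plateau ≈ 1)
and a recovery gate `h ∈ [0, 1]`,

    dvm/dt = h·vm·(vm − v_gate)·(1 − vm)/τ_in − vm/τ_out + I_app
    dh/dt  = (1 − h)/τ_open   if vm < v_gate
           = −h/τ_close       otherwise

with `v_gate = 0.1` fixed. The cubic inward current vanishes at `vm = 0`,
so the resting state is a genuine stable equilibrium: the model cannot
self-depolarise for any admissible parameter combination, which removes
the need for pacemaker screening during fitting. Calcium handling and
memory are deliberately absent — the clinical protocol does not constrain
them.

### Physiological markers and their inversion

A parameter set `(τ_in, τ_out, τ_open, τ_close, D)` maps to markers
`(CV_max, APD_max, h_min, τ_in, τ_open)`:

* `h_min = 4 τ_in / (τ_out (1 − v_gate)²)` — the minimum of the gate
  null-cline `h(v) = τ_in / (τ_out (v − v_gate)(1 − v))`; this is exact,
  not leading-order (the extremum is attained at `v = (1 + v_gate)/2`).
* `APD_max = τ_close · ln(1/h_min)` — leading-order plateau duration.
* `CV_max = γ(h_min, v_gate) · sqrt(D / (2 τ_in))` with

      γ = [3 (1 − v_gate) sqrt(1 − h_min) − (1 + v_gate)] / 2.

  `γ` is the exact bistable-front speed coefficient of the full mMS
  reaction with the gate pinned at 1: the outward current `−vm/τ_out`
  shifts the upper roots of the cubic, and the frequently quoted
  `(1 − 2 v_gate) sqrt(D/(2 τ_in))` (the `h_min → 0` limit) overestimates
  the propagating speed by ~27% at `h_min = 0.3` and ~2× at `h_min = 0.5`.
  We validated `γ` against cable simulations over the marker grid:
  resolved rows propagate a rested beat within a few percent of
  `CV_max` (the physiology checks allow 20%, absorbing discretisation
  effects). Propagation requires `γ > 0`, i.e.
  `h_min < 1 − ((1+v_gate)/(3(1−v_gate)))² ≈ 0.834` at `v_gate = 0.1`;
  the grid maximum is 0.5.

All three relations are algebraically invertible, which is what makes the
marker grid a practical database coordinate system. "Plateau CV" checks
use a single beat into fully rested tissue: the premature-beat CVs of a
restitution curve are systematically slower because the gate has not
recovered at clinical coupling intervals — that slowing is the signal the
fit uses, not an error.

## 1D cable and the restitution database

The database solves the monodomain cable `∂t vm = D ∂xx vm + I_ion + I_app`
with the clinical S1S2 protocol: 2 drive beats at s1 = 470 ms, one
premature beat at s2 descending in 2% steps from 343 ms to 200 ms
(27 rungs). Two bipolar pairs (2 mm pole spacing, 7 mm between pair
barycentres) record the wave; the beat LAT is the first trace extremum
above a capture threshold, CV = 0.7 cm / ΔLAT, and the electrode-level ERP
is the largest non-capturing s2. The extracellular potential uses the
closed form `φ_e = (mean(vm) − vm)/2` (the unique zero-mean solution of
`d²(vm + 2 φ_e)/dx² = 0` with sealed ends), so the bipolar trace is half
the pole-wise vm difference.

Numerics: Godunov splitting; forward-Euler reaction sub-steps; a
Crank–Nicolson step for diffusion (tridiagonal solve, Neumann ends).
Reference resolution is L = 10 cm, dx = 200 μm, dt = 10/100 μs. The desk
preset used by the test suite and the acceptance script is L = 9 cm,
dx = 250 μm, dt = 10/200 μs, with the electrode pairs centred at 4.5 cm —
deliberately equal to the typical catheter-to-pacing-site distance of the
synthetic cases, so that local-coupling (A1A2) prolongation affects the
database and the measurement alike and largely cancels in the fit. The
post-premature observation window (400 ms) equals the surface window for
the same reason: a crawling near-refractory beat must be classified as
capture or block consistently on both sides of the comparison.

The full published grid (580,800 rows) is enumerated exactly but is a
cluster-scale build; `build_database` accepts strides/sub-grids, and rows
whose leading-order front width `sqrt(8 D τ_in)` spans fewer than 4 cells
are flagged `resolved = False` (their discrete CV is lattice-limited).
Physiology checks sample resolved rows only; this is a statement about the
numerical validity domain of a given grid spacing, not about the model.

## Electrogram processing

LAT = time of the first peak or valley of the bipolar trace above a
capture threshold of 40% of that electrode's drive-beat deflection. The
threshold is deliberately high: at short coupling intervals the preceding
beat's repolarisation wave falls inside the premature search window and
deflects at ~20% of the drive amplitude, while genuine depolarisation
fronts — even crawling ones, whose spatial width shrinks with speed —
stay above ~80%.

Local CV: electrode positions are projected onto their least-squares
plane, Delaunay-triangulated, the constant per-triangle LAT gradient is
inverted (`CV = 1/|∇LAT|`), and each electrode takes the median of the
triangle CVs whose centroid lies within 2.5 cm (twice a spline length).
The estimator is exact on affine LAT fields by construction, and the
median bounds the influence of a single corrupted electrode. CVs above
200 cm/s are discarded as non-physiological (the clinical rule: pooled
mean + 2 SD, rounded).

## Fitting

Each electrode's measured CV restitution and ERP are matched against every
database row by normalised least squares:

    Σ_rungs ((CV_meas − CV_row)/200)² + 0.25·((ERP_meas − ERP_row)/span)²
    + λ Σ_k ((marker_k − median_k)/range_k)²

* CV residuals run over rungs where **both** sides captured. A candidate
  that blocks where a CV was measured is penalised through the ERP
  residual only: the block boundary carries a one-rung (≈5 ms)
  quantisation uncertainty, and an explicit per-rung capture penalty made
  the fit hypersensitive to it.
* `erp_weight = 0.25` for the same reason: one quantised residual should
  complement, not override, ~10–15 CV residuals.
* Censored ERPs (capture never lost within the ladder) are represented by
  one rung below the smallest tested s2 on both sides.
* Two passes: an unregularised argmin per electrode, then a refit with a
  quadratic penalty toward the per-marker medians of the first pass
  (`λ = 0.1` on grid-range-normalised differences — strong enough to flip
  near-ties only). Ties break to the lowest row index; the result is
  invariant under electrode permutations.

## Surface model

The atrium (here: a tissue sheet) is an isotropic monodomain shell:
linear FEM on triangles embedded in 3D (cotangent stiffness, lumped
mass, zero-flux boundary), element-wise conductivity binned into 200
equal-width sets with bin-mean representatives (per-element binning error
≤ range/200). Vertices and elements inherit parameters from their
Euclidean-nearest fitted electrode (ties to the lowest electrode id).
Splitting and Crank–Nicolson as in 1D; the diffusion system is
LU-factorised once per model. Reference time steps are 5/50 μs with
≈215 μm edges; the desk preset is 20/200 μs with 0.6 mm edges.
Simulated LAT is the first upward `v_gate` crossing during the premature
window; vertices that never cross are functionally blocked.

At matched spatial resolution, plane waves on the sheet propagate within
5% of the 1D cable (tested). A curved front is additionally slowed by
≈ D/r; at the ≥3 cm catheter stand-off of the synthetic cases this
curvature bias stays below half a database bin for CV_max ≤ ~100 cm/s,
which bounds the regime where exact bin recovery can be expected.

## Stimulus localisation (graph eikonal)

The effective entry point of a remote pacing wave is found by: (1)
extrapolating electrode CVs at s2 = 343 ms over the mesh
(nearest-neighbour); (2) solving a first-arrival model on the mesh graph
(Dijkstra; edge time = length / harmonic mean of endpoint speeds; each
adjacent-triangle pair contributes a virtual opposite-vertex chord to cut
metrication error — on the near-equilateral lattice the worst-case error
is ~3.5%, and ≤8% is asserted generally); (3) scoring every candidate
vertex by the MAE between measured and predicted electrode LATs after a
mean-offset correction; (4) taking the argmin. By reciprocity of the
symmetric metric this needs one solve per electrode, not per candidate;
the equivalence with the brute-force loop is tested. The offset absorbs
the unknown conduction delay from the true (off-mesh) pacing catheter as
well as the convention lag between trace-extremum and threshold-crossing
LATs (≈ half a bipole length over the front speed; uniform across
electrodes, as tested).

## Validation indices

For each pacing site, measured and simulated LATs at the electrodes are
pooled over all tested s2 (one global offset per site), yielding: the OLS
regression `y = m·x + q` of computed on measured, Pearson r, the
covariance slender ratio (minor/major principal component; 0 = perfectly
collinear) and the functional-block error
`100·Σ N_blocked / Σ N_measured` (electrodes blocked in simulation are
excluded from the paired indices and counted here).

## The synthetic generator

Clinical recordings are not public, so the pipeline is validated on
generated cases whose truth is known:

* **Tissue**: a flat near-equilateral triangulated sheet (default
  7×7 cm, 0.6 mm edges) with `n_regions` Voronoi patches; each patch
  draws CV_max from {50…90} cm/s and APD_max from {150…210} ms (grid
  values inside the clinical left-atrial ranges: population CV
  ≈ 88 ± 35 cm/s, ERP 200–322 ms); τ_in = 0.28 ms, h_min = 0.3,
  τ_open = 105 ms are held at mid-grid values. The CV pool's upper end
  respects the curvature-bias bound above.
* **Pacing**: two disk stimuli (radius 1 cm, 4 ms⁻¹, 0.6 ms) at opposite
  sheet corners emulate the two remote clinical entries (fitting site
  and held-out site). Snapshot centres keep ≥3 cm from both.
* **Recordings**: a five-spline catheter (poles at 2/6/10/14 mm on each
  spline, 72° apart; distal and proximal bipole per spline = 10 bipoles)
  is placed at each region seed. Bipolar traces are the pole-wise vm
  difference halved — the 1D extracellular identity used as a surrogate;
  a genuine 2D extracellular solve would change amplitudes, not the LAT
  timing that the pipeline consumes. Gaussian LAT jitter and
  whole-electrode dropout model measurement noise; everything is
  reproducible from the case seed.
* **Economy**: recording a case simulates one S1S2 train per tested rung;
  the suites use 9 of the 27 rungs (the three longest coupling intervals
  plus a dense band across the expected ERP range 200–270 ms), which
  keeps ERP identifiable at a fraction of the cost.

What passing synthetic tests does **not** show: robustness to fibrotic
texture, anisotropy, curved anatomy with holes, fractionated electrograms,
catheter-contact noise or registration error — none of which the
generator emulates.

## Numerical and design notes

* Forward-Euler reaction sub-steps are stable for
  `dt_ode ≤ min(τ)/2`; the grid's fastest depolarisation
  (τ_in = 0.01 ms) is marginal at 10 μs and such rows are usually also
  spatially unresolved — they are flagged, not silently trusted.
* Blow-up (`|vm| > 10`) raises an error naming the offending step sizes;
  database builds record such rows as `unstable` and continue.
* The s2 ladder stops at the last rung ≥ 200 ms (no clamp to exactly
  200); configurable.
* Non-monotone capture across the ladder applies the literal ERP
  definition and emits a warning.
* Electrode-level CV restitutions are monotone away from the block
  boundary; at the one or two rungs just above it the apparent CV can
  rise again as the crawling wave re-accelerates over the electrode pair
  (its local coupling interval prolongs with distance). Monotonicity
  checks therefore exclude those boundary rungs.
* Problem sizes in the test and acceptance runs (desk presets, 7 cm
  sheets, 9-rung subsets, ~50-row databases, 20-row physiology samples)
  are the package's documented desk-scale defaults; the reference-scale
  settings are one config object away.

## Known limitations

* Exact marker-bin recovery degrades above CV_max ≈ 100 cm/s (front
  curvature) and near block boundaries (±1 rung ERP quantisation →
  occasionally ±1 APD bin). These are properties of the measurement
  physics, not solver bugs; they mirror the regularised, approximate
  agreement reported for clinical data.
* The eikonal speed field ignores restitution (it uses the longest
  coupling interval only), so onset localisation inherits a small bias at
  short s2.
* Single-onset search: two simultaneous breakthrough sites would be
  mis-localised.
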