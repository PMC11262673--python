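# Methods

## Scope and model overview

`mtrsim` models the feasibility of monitored tomographic acquisition —
reconstruct-while-scanning with early stopping — on realistic
instruments, and implements the reconstruction primitive that makes it
affordable (the O(1) incremental partial-FBP update). It deliberately
models rather than executes the heavy parts: GPU kernels, cone-beam
volumes at full detector scale, and scanner control are represented by
calibrated cost expressions, while the 2D parallel-beam core is executed
for real so the reconstruction claims are testable end to end.

## Angle grids and acquisition orders

A grid is half-open: `angle(j) = a_min + j/N_p·(a_max − a_min)`,
`j = 0..N_p−1`, so a full-circle grid never duplicates 0°/360°. An
acquisition order is a permutation of grid indices.

The logarithmic order acquires `N_prescan` equidistant angles in
rotation 0, then doubles the acquired count each rotation by inserting
midpoints, visited in ascending angle within a rotation (the intra-
rotation sweep direction is a free choice; a single ascending sweep
minimizes travel and makes the order deterministic). `N_p/N_prescan`
must be a power of two — other ratios cannot halve the spacing exactly
and are rejected rather than approximated. After every completed
rotation the acquired set is equidistant, which is the property that
keeps filtered back projection artifact-free on partial data.

### Stage travel

Per-step angular distances support three conventions:

- `unidirectional` — forward arc, wrap allowed (a stage that always
  rotates one way);
- `bidirectional` — shortest arc (mean step for a random order → 90°);
- `bounded` — straight travel between absolute angles, no wrap (a stage
  whose cabling/hard stops forbid crossing the range ends; mean step for
  a random order → one third of the range, 120° on a full circle).

One movement term is charged per acquired projection; the initial
positioning move carries the fixed overhead `C_move` but zero distance.
`order_metrics` defaults to `bidirectional` (pure order
characterization). The *time model* defaults to `"auto"`: consecutive
and logarithmic orders are executed as forward rotation programs —
consistent with the closed form `d_total = 360·(1+log₂(N_p/N_prescan))`
— while arbitrary (random) orders are driven as direct moves on a
bounded stage. This mixed default reflects how the two programs are
realized mechanically (a monotone sweep schedule vs. arbitrary
repositioning) and reproduces both reference behaviours: the
logarithmic validation-stand total and the ~10× random-order slowdown
on the micro preset. Any mode can be forced explicitly.

## Time and dose model

Per projection: `T_exp = T_frame + C_det`, `T_move = C_move +
dist·(time_per_rotation/360)`, `T_gate = gate·C_gate_move`. Dose is
object-exposition time: `D_exp = T_exp`; `D_move = (1−gate)·T_move`
(gating blocks the beam while the stage moves — this is what makes the
gated dose independent of acquisition order); `D_gate = gate·C_gate_dose`.

Quasi-stationary instruments sum all terms. Continuous-movement
instruments (medical, cargo) expose while rotating: each projection
costs `max(T_exp + T_gate, T_move)` in time and only `T_exp + D_gate`
in dose. Partial sums follow the acquisition prefix, not sorted angles,
giving the monitored-protocol time/dose-vs-n curves.

Preset notes (units: seconds, degrees):

- `C_gate_move` defaults to 0 — gating can be synchronized with the
  stage so it costs no wall time; it is configurable.
- Rotation speed is `360°/time_per_rotation` even when the scan range
  is narrower (cargo: 256°).
- EBCT has no gantry: angle changeover is a distance-independent
  constant (`C_move = 10 µs`, zero rotation-time term). Its modeled
  total is 400·(70+10) µs = 0.032 s; reference tables quoting 0.03 s
  agree at their one-significant-figure precision.
- The nano preset's commonly quoted total (~4.9×10⁴ s) is inconsistent
  with its per-projection parameters (180 s frames × 800 projections
  alone exceed it ~3×); the preset is shipped parameter-faithful and its
  modeled total (~1.45×10⁵ s) should be read accordingly.

## Reconstruction-cost model

`proj_size = N_x·N_z·N_a`, `vol_size = N_x²·N_z`;
`T_load = proj_size·bpp/s_load` (charged only on request — in a
monitored run data are shipped to the device once, so per-cycle costs
exclude it), `T_memory = proj_size·bpp/s_memory`,
`T_prep = proj_size·P_pixel/s_rec`,
`T_rec = it_count·vol_size·N_a·P_voxel/s_rec`.

Choices: `bytes_per_pixel` defaults to 4 (single precision). SIRT
multiplies the kernel term by `iteration_ops_multiplier` (default 3:
forward + back projection + update per iteration); with that factor the
model lands within a few percent of independently quoted SIRT cycle
times, but the factor is an empirical knob, not a derived constant. The
model is an order-of-magnitude instrument: medical-CT cycle times
evaluate ~1.7× above some published figures with the same inputs.
A warning (not an error) is raised when volume + projections exceed
device RAM, since the model assumes resident data.

`reconstructions_per_acquisition` floors `T_acq/T_cycle`; a count below
one flags real-time reconstruction as infeasible. The protocol needs
`N_rec > 3` to function at all (baseline, difference, compared
difference).

## Tomography core

Primary geometry is 2D parallel-beam — it has an independent oracle
(inverse radon) and exposes every property that matters for acquisition-
order analysis; fan-beam weighting is out of scope. Forward projection
is `skimage.transform.radon`; the filter, backprojector, FBP and SIRT
are implemented in-package.

Numerical choices:

- Ramp filter built from the band-limited real-space kernel
  (`h[0]=1/4`, `h[odd n] = −1/(πn)²`) rather than a naive `|f|` ramp,
  zero-padded to the next power of two ≥ 2·bins; optional Hann window.
  A constant profile filters to ≈0 away from finite-window edge
  transients.
- Backprojection: image center at `N//2`, detector coordinate
  `t = y′cosθ − x′sinθ`, linear interpolation, zero outside the
  detector; reconstruction grid = detector column count.
- The accumulator is the plain average of filtered backprojections —
  scale-free, so the incremental identity
  `v_{n+1} = (n·v_n + BP(p̃_{n+1}))/(n+1)` holds to machine precision
  (float64) regardless of calibration. The physical read-out scale π/2
  (exact for uniform coverage of either a half or full turn) and the
  outside-circle mask are applied at read-out only.
- SIRT uses row/column-sum normalization (`x += λ·C·BPᵀ(R·(b−Ax))`),
  relaxation 1.0, support-masked; residual norms are recorded before
  each update. Warm starts accept any previous reconstruction.

The phantom is a deterministic piecewise-constant ellipse image in
[0, 1] with moderately high contrast. Full-data FBP error against it is
discretization-dominated: ~12% relative RMSE at 128², ~8.7% at 256²,
~6% at 512². Agreement with the independent inverse-radon oracle is
~0.5% relative RMSE.

One geometry caveat: on a 360° parallel-beam grid, a consecutive prefix
of `N_p/2` projections spans 180° — *complete* data — so "equidistant
beats wedge" comparisons at half scan are run on a 180° grid, where a
half prefix is a genuine 90° limited-angle wedge. This is the
parallel-beam analogue of the fan-beam setting in which such
comparisons are usually illustrated.

## Monitored-protocol engine

Discrete-event simulation, not threads: acquisition events fire at the
cumulative model times, a single worker drains the whole FIFO queue each
cycle, cycle duration comes from a pluggable cost model (default: fixed
overhead + per-new-projection cost, matching the observation that real
cycle times are dominated by volume transfer and only weakly depend on
batch size). One decision point per completed cycle. The default
stopping rule stops when the relative change of the quality signal stays
below `epsilon` for `patience` consecutive points, never before 3
points. The quality signal is task-specific by design; the engine takes
any `quality_fn` (default: the projection count, a convenient monotone
proxy for demos — real deployments should plug in an image- or
task-based signal such as the relative L2 change between decision-point
reconstructions, which `convergence_report` computes).

Guarantees by construction: acquisition never blocks on reconstruction
(worst-case realized time/dose equal the standard protocol exactly);
every projection is consumed by exactly one cycle; `N_rec` counts cycles
finishing before acquisition ends, so the instant-reconstruction limit
gives `N_rec = N_p` and an oversized cycle gives `N_rec = 0` with an
infeasibility flag. A zero cycle cost is accepted as the instant limit;
negative costs are errors. On an early stop, projections already in
flight up to the decision time are counted as acquired.

## What the synthetic setup does and does not show

The phantom/sinogram pipeline is noise-free, monochromatic, perfectly
aligned parallel-beam 2D. Passing tests therefore demonstrate the
*algorithmic* properties — order-dependent artifact structure, the exact
batch/incremental equivalence, convergence of the partial average, and
the protocol-level time/dose accounting — not robustness to detector
noise, beam hardening, misalignment, or 3D cone-beam effects. The
acquisition and cost models are calibrated to published instrument and
GPU parameters and are order-of-magnitude tools; they ignore
acceleration ramps, detector readout overlap, and multi-GPU scheduling.

## Problem sizes used in the test suite

Unit tests run at 64–256² with 48–256 projections; the end-to-end
quality checks use the validation-stand scale (512², 512 projections,
checkpoints 8–512). These sizes were chosen as the smallest at which the
discretization-dominated error plateaus enough for the stated bounds to
be meaningful; the whole suite runs in well under a minute on one CPU.
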