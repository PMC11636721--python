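# Methods

## Model and iteration

The solver targets the saddle-point problem
`min_x max_y Σᵢ ⟨Aᵢx, yᵢ⟩ − fᵢ*(yᵢ) + g(x)` with proper sampling
probabilities `pᵢ > 0, Σpᵢ = 1`.  One pass performs, in order:

1. the step controller proposes the ratio factor γᵏ from quantities
   observed up to the previous pass only, and the pass step sizes are
   formed as `τ ← τ/γ`, `σᵢ ← γσᵢ`;
2. primal proximal step `x⁺ = prox_{τg}(x − τ z)` against the maintained
   extrapolated dual transform `z = A*ȳ`;
3. one block `i` is sampled with probability `pᵢ` (inverse-CDF draw from a
   dedicated stream);
4. dual proximal step `yᵢ⁺ = prox_{σᵢ fᵢ*}(yᵢ + σᵢ Aᵢ x⁺)`;
5. bookkeeping: with `Δ = Aᵢ*(yᵢ⁺ − yᵢ)`, update `h ← h + Δ` (so
   `h = A*y`) and `z ← h + Δ/pᵢ` (so `z = A*ȳ` with
   `ȳᵢ = yᵢ⁺ + (yᵢ⁺ − yᵢ)/pᵢ`).  The extrapolated dual is never stored;
   memory and FLOPs match a standard SPDHG implementation.

Sampling is serial (one block per pass) — the regime the convergence
theory analyzes.  Dual variables start at zero, making `h = z = 0` exact
at the first pass; the primal start is the zero image by default.  A guard
aborts with a named iteration if any iterate goes non-finite or
`‖x‖ > 10¹²`.

Convergence of the adaptive scheme requires (i) step sizes for pass k+1
measurable with respect to history up to pass k — enforced structurally,
because controllers propose before the primal step from the stored
previous-pass observables; (ii) `τᵏσᵢᵏ‖Aᵢ‖²/pᵢ ≤ β < 1` at every pass —
guaranteed at initialization and preserved exactly by the ratio-only
update, and audited every pass anyway; (iii) quasi-increasing step-size
sequences — supplied by the amplitude schedule (paper mode) or the
deterministic envelope (certified mode, below).

## Step-size initialization

`init_step_sizes(problem, ratio, beta, mode)` with `β ∈ (0,1)`
(default 0.99):

* `shared` (default; the residual-balancing rule assumes one dual step
  size): `σ = minᵢ √(β pᵢ/ratio)/‖Aᵢ‖`, `τ = ratio·σ`;
* `per_block`: `τ = minᵢ √(β·ratio·pᵢ)/‖Aᵢ‖`, `σᵢ = β pᵢ/(τ‖Aᵢ‖²)`
  (saturates the bound on every block).

Block norms are power-iteration estimates (seeded, deterministic,
relative tolerance 1e-7); the margin 1−β absorbs estimation error.

## Adaptation rules

**Residual balancing (rule a).**  After the pass on block `i`, with
`Δx = xᵏ − xᵏ⁺¹`, `Δyᵢ = yᵢᵏ − yᵢᵏ⁺¹`:

```
v = ‖Δx/τ − (1/pᵢ) Aᵢ*Δyᵢ‖₁      d = (1/pᵢ)‖Δyᵢ/σ − AᵢΔx‖₁
```

`Aᵢ*Δyᵢ` reuses the bookkeeping adjoint; the only extra cost is `AᵢΔx`,
at most a 50 % overhead, reduced to ~5 % by estimating `d` on a uniform
10 % row subsample without replacement, each absolute entry reweighted by
the inverse inclusion fraction (unbiased by construction; an exhaustive
subset enumeration and a Monte-Carlo check in the tests verify this).
Only flat-range blocks are subsampled; the image-gradient block, whose
application is cheap, gets the exact `d`.  Decision, with scaled dual
residual `d′ = s·d`: `v > δ·d′` → `γ = 1 − α` (boost τ); `d′ > δ·v` →
`γ = 1/(1 − α)`; otherwise no change.  α shrinks to `ηα` on every change.

Defaults: `α₀ = 0.5`, `δ = 1.5` (values in the tradition of the adaptive
deterministic scheme this extends; sensitivity is weak), `η = 0.995`,
`s = ‖A‖` of the full stacked operator (estimated once per run),
subsample fraction `q = 0.1`.  The `s` factor compensates the unit
mismatch between the primal residual (scale x/τ) and the dual residual
(scale Ax); placing it on the dual side before comparison reproduces the
full-batch deterministic scheme at `n = 1`.

**Angle alignment (rule b).**  `q = Δx/τ − (1/pᵢ)Aᵢ*Δyᵢ` estimates the
primal subgradient; `w = ⟨Δx, q⟩/(‖Δx‖₂‖q‖₂)` (flagged undefined when
either vector vanishes).  `w ≥ c` → boost τ; `w < c_low` → shrink;
otherwise no change.  Defaults `c = 0.999` (must be close to 1 in high
dimension), `c_low = 0.9` (chosen; weak sensitivity), same α/η schedule.

**Modes.**  `certified` (library default) clips every proposed γ into
`[1−εᵏ, 1/(1−εᵏ)]` with `εᵏ = α₀ηᵏ`, a deterministic schedule with
`Σεᵏ = α₀/(1−η) < ∞`; the step-size sequences are then quasi-increasing
with a deterministic control and the convergence theorem applies verbatim.
`paper` mode applies the raw rule (the experiment-replication setting);
its control is random but the per-change amplitude shrink keeps total
adaptation finite.

## Operators

All operators implement exact adjoints.  The parallel-beam projector is
built by Siddon exact ray/pixel intersection (unit pixels, image centered
at the origin, detector bins uniformly spaced over the image diagonal,
rays perpendicular to the detector) as an explicit sparse matrix —
adjoint = transpose, and row restriction is exact matrix slicing, which
for sparse storage is bit-identical to select-after-apply.  The grid is
capped at side 512: beyond that the package declines rather than trade
away adjoint exactness.  Fanbeam geometry is not implemented: the
acquisition geometry is orthogonal to the step-size adaptation being
studied, and parallel-beam with an explicit matrix gives the exact
adjoint and cheap row subsetting the stochastic residual estimates need.
The TV operator is the forward-difference gradient with replicate
boundary (zero difference at the last row/column), `‖D‖² ≤ 8`.

## Synthetic CT test-bed

The phantom is an additive ellipse superposition (head-like default:
skull rim, interior, two low-contrast cavities, two small lesions);
a pixel's value is the sum of intensities of ellipses containing its
center.  Desk-scale geometries: 64×64 grid; sparse-view 12 angles over
[0°, 180°); limited-angle 50 angles over [0°, 150°); low-dose 90 angles
with Beer–Lambert photon counts `Poisson(N₀ e^{−μ})`, `N₀ = 10⁴`, line
integrals rescaled so the peak optical depth is 4, counts clamped at 1
before the log transform.  Measurements are interleave-partitioned into
`n = 10` minibatches (block i owns every 10th row), so each minibatch
sees all angles; the TV term enters as one additional dual block, and
sampling is uniform over the 11 blocks.  TV weights default to
`λ = 0.02` for the noise-free geometries and `λ = 0.2` for low-dose,
where the regularizer must actually denoise.  TV is anisotropic
(`λ‖Dx‖₁`) by default; isotropic is available as a flag.

What the generator does *not* emulate: fanbeam/helical geometry, detector
blur, scatter and beam hardening, real anatomy.  Passing tests therefore
demonstrate correctness of the optimization machinery and the qualitative
step-size phenomenology at desk scale, not clinical image quality.

## Study protocol and tuned ratios

The replication study runs constant vs adaptive controllers for 50 epochs
from a zero image over starting ratios spanning four orders of magnitude,
with 5 seeds and median final objectives.  A *well-tuned* fixed ratio is
defined operationally as one in the range to which the adaptive scheme is
observed to converge; at desk scale these are `10⁻²` (sparse-view),
`5·10⁻⁴` (limited-angle) and `2·10⁻⁴` (low-dose), and the badly chosen
ratio is four orders of magnitude below.  On these problems the
residual-balancing rule recovers the badly chosen start to within a few
percent of the well-tuned run, a two-to-three-order-of-magnitude
improvement over constant SPDHG at the same budget.

The λ=0 convergence verification (16×16 grid, 24 angles, 2 minibatches,
20000 iterations, certified mode) checks every controller against the
dense least-squares solution at 10⁻⁴ relative error.  The 2-block
partition is deliberate: with many tiny blocks the adaptive rules settle
at their balanced ratio, whose *asymptotic* linear rate on this toy
problem would need more iterations to reach 10⁻⁴ — a property of the
balanced operating point, not a convergence failure.

## Numerical choices and degenerate cases

* Residual comparison dead zone: `v = d′ = 0` (stationary pass) proposes
  `γ = 1`; an undefined cosine (zero update or zero subgradient estimate)
  likewise.
* The product `τσᵢ` is preserved exactly (one division, one
  multiplication per pass); the pass audit allows 1e-9 relative slack for
  accumulated floating-point error.
* Maintained transforms `h, z` are exact up to floating-point
  accumulation; tests bound drift against from-scratch recomputation at
  1e-8 relative over hundreds of passes.
* Power iteration is seeded; non-convergence is reported via a flag on
  the returned estimate, not an exception.

## Known limitations

* **Rule (b) full-batch runaway.**  On smooth problems with `n = 1` (and
  occasionally small `n`) in raw paper mode, a frozen dual
  (σ collapsed) makes the cosine identically 1, which keeps boosting τ —
  a positive feedback that ends in numerical overflow, cleanly aborted by
  the divergence guard.  The certified envelope prevents it in the
  settings used here; rule (a) is the recommended controller, and rule (b)
  is retained as the weaker alternative it is known to be.
* Serial sampling only; no minibatch-of-blocks sampling, no
  strong-convexity acceleration, no line search.
* The balanced ratio the residual rule finds optimizes a fixed-horizon
  objective well but is not guaranteed to be the asymptotically fastest
  ratio on every problem (see the λ=0 note above).
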