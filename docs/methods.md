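# Methods

## The model

`osmocell` models a mass-action reaction network enclosed in a unilamellar
lipid vesicle whose aqueous volume is governed by osmosis. The state is the
vector of internal solute concentrations `s` (molar). Three physical
assumptions shape the equations:

1. **Isotonic condition.** Water crosses the bilayer orders of magnitude
   faster than any solute, so the total internal concentration — reacting
   solutes plus `B_T` trapped, impermeable, non-reacting buffer molecules —
   always equals the total external concentration
   `C_ε = b_ε + Σ_j s_jε`. The scaled volume (Avogadro's number times the
   litre volume) is therefore an algebraic function of the state,

       Ω = B_T / (C_ε − Σ_j s_j),

   and diverges as the solute total approaches `C_ε` (osmotic blow-up, which
   the package treats as an error, never a clamp).

2. **Spherical surface kinetics.** The membrane area instantaneously follows
   the volume as a sphere: `S_µ = (36π V²)^(1/3)` with `V = Ω/N_A` in dm³.
   The reduced surface `Φ = S_µ / (36π V²)^(1/3)` is exactly 1 under this
   rule; `Φ < 1` is osmotic tension (burst near 0.9), `Φ > 1` a deflated,
   filament-prone vesicle.

3. **Fickian membrane exchange.** Each solute permeates with a constant
   `D_i = D_i^× · D_ref / λ`, where the dimensionless multiplier `D_i^×`
   scales the permeability of ribose through an oleic-acid bilayer
   (`D_ref = 2.65×10⁸ dm² s⁻¹ mol⁻¹`, bilayer thickness `λ = 4×10⁻⁸ dm`).

The full concentration ODE combines mass-action chemistry `r_i(s)`, membrane
exchange and the dilution correction for the changing solvent volume:

    ds_i/dt = g_i − (s_i/C_ε) Σ_j g_j,
    g_i = r_i(s) + (S_µ D_i / B_T)(C_ε − Σ_j s_j)(s_iε − s_i).

The second term is algebraically identical to the textbook dilution term
`−(s_i/Ω) dΩ/dt` after substituting the isotonic volume; the identity is
unit-tested symbolically. Two classical bulk reactors are provided as limit
cases: reservoir conditions (resource/waste species clamped) and the CSTR,
which the high-buffer vesicle reproduces exactly under
`θ = B_T/(S_µ∅ D b_ε)` when all species share one permeability.

### Dual formulation

The same dynamics expressed in molecule numbers `n_i = s_i Ω` need no
dilution term, because numbers are extensive:

    dn_i/dt = Ω r_i + S_µ D_i (s_iε − s_i),   Ω = (B_T + Σ_j n_j)/C_ε.

The trajectory integrator works in number space (stiff LSODA, default
rtol 1e-8, atol 1e-12 M converted to molecules), which also makes syringe
injections exact: an injection adds its rate directly to `dn_i/dt`, with
event start/end times used as integration breakpoints. The two formulations
are cross-checked against each other on random reactors in the test suite —
they are genuinely independent code paths joined only by the exact inversion
of the volume relation.

## Steady states: the surface-sweep construction

The spherical surface law makes the full model non-polynomial, so fixed
points are found indirectly. At an *imposed* constant surface `S_µ∅` the
steady-state conditions are square polynomial systems,

    r_i(s) + (S_µ∅ D_i / B_T)(C_ε − Σ_j s_j)(s_iε − s_i) = 0,

(the dilution term vanishes at any steady state). These are solved
*completely* — every isolated complex root — and the real, non-negative roots
with positive volume below a 2000-nm-diameter cap are kept. Sweeping `S_µ∅`
and linking roots across adjacent grid values (nearest neighbour in
normalised concentration space, cap 0.2 per step; concentrations determine
the state completely and stay well scaled where log-volume does not) yields
the bifurcation curve through vesicle morphology space. Fixed points of the
full model are exactly the branch crossings of the spherical line
`S_µ∅ = sphere_surface(Ω*)`; each detected sign change is refined by
bisection on the imposed surface with a local Newton re-solve until
`|Φ − 1| < 10⁻⁶`.

Stability computed from the fixed-surface Jacobian is reported as
**quasi-stability**: it ignores both the dilution term and the surface's
dependence on the state. The package treats it as a predictor only. For
large-vesicle states the distinction matters — the solute total sits just
below `C_ε`, so the osmotic feedback terms are first-order — and the
verification pipeline therefore confirms stable crossings by integrating the
full model from perturbed starts (see below).

## The homotopy continuation solver

All-roots solving uses a total-degree homotopy written for this package
(`osmocell.homotopy`): the target system `f` is deformed from the decoupled
start system `g_i = x_i^{d_i} − 1` along `H = (1−t)γ g + t f` with a random
complex phase `γ`, tracking every Bézout-count path with an Euler predictor,
a three-step Newton corrector, per-path adaptive steps, and a guard that
rejects steps whose corrector pull is large compared with the predicted move
(the signature of a path jumping into a neighbouring root's basin). Paths are
tracked to `t = 0.995` and then walked to `t = 1` through twelve
geometrically shrinking steps before a final Newton polish — a cheap endgame
that keeps steep final approaches inside the right basin. Variables are
rescaled by `C_ε` and every equation normalised to unit maximum coefficient
before tracking.

Robustness choices, all of which were driven by cross-checks against an
independent dense multi-start damped-Newton oracle (1000+ random starts,
deduplicated):

* two full passes with independent `γ` per solve, root sets unioned — a
  single random deformation very occasionally loses a path near
  ill-conditioned geometry;
* batched execution: all paths of *many* systems (a Monte-Carlo census, or a
  whole surface grid, or both) are tracked simultaneously in flat arrays,
  with singular members of batched linear solves falling back to per-path
  least squares rather than poisoning the batch;
* roots with `|imag| < 10⁻⁸(1+|real|)` count as real; duplicates merge within
  `10⁻⁷` relative distance.

Residual systems on the excluded manifold `Σs = C_ε` (where the volume
diverges) attract some paths to singular roots; these polish out or are
dropped by the validity filters and are not counted as solver failures.
Parameter draws that sit numerically on a fold (two valid roots closer than
the merge tolerance) are intrinsically ambiguous to count; they are rare
(≲0.5% of census draws) and fall well inside the census error budget.

## Monte-Carlo censuses

The Case-Study censuses encapsulate the classic bulk bistable regimes of the
Schlögl switch (`X + 2Y ⇌ 3Y`, `Y ⇌ Z`) and the Wilhelm switch (four
irreversible reactions) and ask how often the fixed-surface system retains
multiple fixed points. Sampling ranges (the study conditions, shipped as the
presets `schlogl_cs1` / `wilhelm_cs1`):

| parameter | range |
|---|---|
| permeability multipliers `D_i^×` | uniform (1/5, 50) |
| non-reservoir externals `s_iε` | uniform (0, 0.002) M |
| external buffer `b_ε` | 0.002 M ± 40% |
| trapped buffer count `B_T` | uniform (2, 2000) |
| rate constants | pinned to the bulk regimes |
| reservoir externals | pinned (`x_ε, z_ε` Schlögl; `x_ε` Wilhelm) |

The Wilhelm waste `W` diffuses with a sampled external concentration (the
bulk regime places no constraint on it). The imposed surface is a 400-nm
sphere. One detail deserves emphasis: the printed Schlögl reverse
trimolecular constant is used as `k1r = 2.85×10³ M⁻² s⁻¹`; only this value
makes the classic regime's three steady states satisfy the cubic's Vieta
relations (root sum `k1·x/k1r`, product `k2r·z/k1r`, both to three
significant figures), and it is exposed as a parameter throughout.

The generic wide-area ranges (rates in (0,10), reverse rates capped at a
tenth of the forward, externals in (0, 0.2) M, `b_ε = 0.2 M ± 40%`,
`B_T = 63064 ± 40%`) drive the emergent-bistability search.

## The bistability search pipeline

`find_bistable_regimes` mechanises the two-phase strategy:

1. **Wide area.** `budget` uniform draws are censused at the 400-nm surface;
   draws with ≥3 valid fixed points become bases (typically 0.1–0.5%).
   A hot-spot stage then resamples ±20% around each basis (250 draws) and
   keeps its ≥3-fixed-point variants, multiplying the candidate pool with
   diverse curve geometries.
2. **Steering.** The exact transformation `D_i → D_i·a·c`, `B_T → B_T·b·c`
   leaves every `K_i = S_µ D_i/B_T` — hence every fixed-point concentration —
   unchanged while mapping morphologies `{Ω, S_µ} → {Ω·b·c, S_µ·b/a}`. In
   log-log morphology space this is a *rigid translation*, so which branch
   portions can be made to cross the spherical line together depends only on
   the scalar shift `w = log₁₀(b/a) − (2/3)log₁₀(bc)` and on the curve's
   intrinsic shape. Every candidate is swept over a deliberately huge
   surface range (2 nm – 200 µm equivalent spheres, no volume cap — the
   transformation can translate any region into the viable window
   afterwards) and scored by a staged objective: curves with no admissible
   three-crossing shift window score by how far their stable/unstable/stable
   segment f-intervals are from overlapping; curves with a window score by
   the interpolated quasi-eigenvalue violation of the
   stable/unstable/stable requirement at the three crossings (continuous in
   the parameters, unlike the binary labels) plus any spread excess. The
   most promising candidates are hill-climbed on this objective with a mix
   of isotropic hot-spot proposals (size tracking the objective) and
   coordinate line-search moves (each free parameter alone ×0.6 / ×1.7),
   which travel much further per evaluation when one knob dominates. This
   replaces the manual "trial-and-error adjustment" step with a reproducible
   optimisation.
3. **Verification.** Steering windows are admissible when their three
   crossings are pairwise separated by ≥0.15 decades of volume (anything
   closer is a fold grazing the line — a tangency, not distinct states) and
   the triple spans 1.0–5.9 decades (narrower triples are fold-local
   structure, where coarse sweeps also produce phantom crossings; wider ones
   leave the physically sensible size range). Windows are relocated on a
   320-point sweep (they can be only millidecades wide), realised with
   `a = 10^(−w)·b^(1/3)`, `c = 1` and `b` centring the triple near a 320-nm
   geometric-mean diameter (recentring *along* the spherical line needs the
   coordinated `b^(1/3)` factor — the line has slope 2/3, not 1), and
   re-swept on a fine grid covering the predicted crossings. The refined
   triple is accepted only if the two outer crossings are confirmed as
   attractors of the **full** variable-volume dynamics, by integrating from
   three perturbed starts each: volume ±2% at fixed composition, and a
   compositional jitter at fixed solute total. Per-species concentration
   kicks are deliberately *not* used: at large-vesicle states they translate
   into enormous volume excursions that can jump the saddle while saying
   nothing about local stability. The quasi-stability labels are recorded
   but are not the acceptance criterion — near folds they routinely disagree
   with the integration verdict, in both directions.

## Osmotic coupling response curves

For chemically disjoint reaction sets sharing a vesicle, each set sees the
other's molecules as extra trapped buffer. `coupling_response_curve` solves
one sub-network's fixed-surface system with effective buffer `B_T + B_extra`
(numerically — no closed form is assumed) and returns the particle number the
set holds at each steady state; sub-networks are routinely two-branched (a
small-volume and a large-volume state), so the curve is reported per rank-
linked branch, with grid values lacking any steady state recorded as gaps.
Joint steady states are the intersections of the two curves (the cyclic
consistency condition), located by segment-pair crossing and verified by
Newton-polishing on the joint system's own equations.

## What the synthetic study conditions do and do not show

All inputs are parameter sets — printed bulk regimes and seeded uniform
draws; there is no external data. Passing tests therefore demonstrate
internal consistency of the model and reproducibility of the census and
search statistics under the stated ranges, not agreement with measured
vesicle chemistry. Real membranes have state-dependent permeabilities,
finite water permeability, non-spherical shape dynamics and lipid-exchange
kinetics, all outside this model by construction.

## Numerical choices and degenerate inputs

* Concentrations are bare numbers in the molar convention; the rescaling
  rules (first-order rates unchanged, second-order ×n, third-order ×n²,
  `B_T`/externals ÷n) move a regime between concentration scales with
  identical morphology and an unchanged Jacobian spectrum.
* Eigenvalue classification uses a band of 10⁻⁹ times the spectral radius;
  inside it a point is 'marginal'.
* Osmotic blow-up (`Σs ≥ C_ε`) raises everywhere; negative concentrations
  are clipped only below the integrator's absolute tolerance.
* Reaction-free reactors with several species make the fixed-surface system
  positive-dimensional on the excluded manifold; the package handles the
  physical (single-solute or reacting) cases and the tests exercise the
  reaction-free limit with one species.
* Census problem sizes: the shipped acceptance script uses 2000 draws per
  census (binomial standard error under one percentage point); the original
  tables used 5000. Test-suite censuses use 1000.

## Known limitations

* Quasi-stability can disagree with full-model stability at large-vesicle
  states; only integration-confirmed crossings should be called stable.
* The homotopy tracker can mis-count fixed points for draws lying numerically
  on a fold (measure-zero in parameter space, ≲0.5% at census tolerances).
* The search pipeline's hill climb is stochastic; budgets are seeded and
  documented, but success within a given budget varies by reaction scheme.
* Systems beyond four species slow the all-roots solve considerably (the
  Bézout count grows multiplicatively) and are out of scope.
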