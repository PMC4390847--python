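# osmocell

Chemistry inside a vesicle is not chemistry in a beaker. A lipid vesicle's
membrane passes solutes slowly and water quickly, so any osmotic imbalance
created by ongoing reactions changes the aqueous volume — and hence every
concentration — almost instantly. `osmocell` models this coupling for
mass-action reaction networks encapsulated in a semi-permeable,
variable-volume vesicle ("protocell") reactor, and provides the machinery to
find and classify its steady states:

* the **isotonic volume law** `Ω = B_T / (C_ε − Σ_j s_j)` (scaled volume from
  trapped buffer count and the concentration gap to the environment), with
  spherical surface kinetics and Fickian membrane exchange;
* concentration ODEs with the **dilution term** for the changing solvent
  volume, plus an exactly equivalent molecule-number formulation used for
  stiff integration and syringe-injection protocols;
* a complete-root **polynomial homotopy continuation** solver for the
  fixed-surface steady-state systems, batched so that thousands of systems
  (Monte-Carlo censuses, surface sweeps) are tracked in one vectorised run;
* the **bifurcation-curve construction**: sweep the imposed surface, link
  roots into branches through vesicle morphology space, and read off the
  full model's steady states where branches cross the spherical `Φ = 1` line;
* **Monte-Carlo parameter-space search** for emergent bistability — vesicles
  with two stable sizes — including the exact `(a, b, c)` transformation that
  steers a bifurcation curve through morphology space without changing any
  fixed-point concentration, and concentration-regime rescaling;
* **osmotic coupling** analysis: response curves describing how chemically
  independent reaction sets sharing one vesicle act as effective buffer for
  each other, and the cyclic-consistency construction of their joint steady
  states.

The audience is researchers in systems chemistry, origin-of-life modelling
and encapsulated-reactor design who want a reproducible implementation of
variable-volume reactor analysis beyond fixed-volume CSTR/reservoir
idealisations (both of which are included as exact limit cases).

## Worked example

The Schlögl switch `X + 2Y ⇌ 3Y`, `Y ⇌ Z` is the classic one-variable
bistable scheme. Under reservoir conditions (X, Z clamped) its steady states
are the roots of a cubic:

```python
>>> from osmocell import schlogl_reservoir_fixed_points
>>> schlogl_reservoir_fixed_points(x=6.47e-4, z=6.32e-4)
array([5.03218848e-05, 4.00923624e-03, 7.85886293e-03])
```

— the low stable, unstable, and high stable states of Y (in M). Note the
reverse trimolecular constant defaults to `2.85e3 M⁻² s⁻¹`, the value
consistent with this classic regime's Vieta relations (see
`docs/methods.md`).

Encapsulate the same chemistry in a vesicle and the picture changes. The
census below draws 1000 random membrane/environment parameter sets around
the switch (permeabilities between one fifth and fifty times that of ribose
through an oleic-acid bilayer, millimolar externals, trapped buffer counts
from 2 to 2000), solves *all* fixed points of each vesicle at a fixed
400-nm-diameter surface, and tabulates how many survive the physical
validity filters:

```python
>>> from osmocell import preset_ranges, sample_wide, census
>>> from osmocell.reactor import sphere_surface_from_diameter
>>> net, ranges = preset_ranges("schlogl_cs1")
>>> draws = sample_wide(net, ranges, 1000, seed=1)
>>> result = census(draws, sphere_surface_from_diameter(400.0), seed=1)
>>> {k: round(v, 3) for k, v in result.summary().items()}
{'0': 0.002, '1': 0.852, '2': 0.146, '3': 0.0, '4+': 0.0}
```

Most draws keep a single fixed point: encapsulation usually *degenerates*
the bulk bistability. The converse — very simple chemistry gaining
bistability from the variable volume — is what `find_bistable_regimes`
searches for:

```python
>>> from osmocell import parse_network, find_bistable_regimes, SamplingRanges
>>> net = parse_network("2 X -> Z (k=1); Z -> 2 Y (k=1)")
>>> regimes = find_bistable_regimes(net, SamplingRanges(), budget=3000, seed=3)
>>> [round(fp.diameter_nm, 1) for fp in regimes[0].crossings]
[41.7, 369.7, 2119.1]
>>> regimes[0].confirmed_by_integration
True
```

A two-step irreversible sequence — utterly monostable in any bulk reactor —
supports two stable vesicle states here: a ~42-nm and a ~2.1-µm sphere,
separated by an unstable intermediate size, each outer state confirmed by
integrating the full variable-volume dynamics back onto it from perturbed
starts (the fixed-surface stability labels are predictors only; the
integration is the decisive check). The vesicle's *size* is the switch.

## Command line

`osmocell simulate|steady|sweep|census|search|transform|rescale|demo`, each a
thin wrapper over the library; run configurations are YAML/JSON documents
(`osmocell demo --out DIR --seed 0` writes ready-to-run examples). Outputs are
CSV tables (trajectories, fixed points, bifurcation curves) and JSON
summaries, canonically sorted so reruns diff cleanly.

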