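# thermoweb

Temperature-driven biomechanical feasibility networks for consumer–resource
communities.

Warming shrinks ectotherm body sizes; body size sets biomechanical
capacity; biomechanical capacity decides which trophic interactions are
physically possible. `thermoweb` turns that chain into a quantitative
pipeline for ecologists studying climate-change impacts on interaction
networks: it propagates temperature-driven body-size change through
allometric trait scaling, builds one bipartite consumer–resource
*feasibility network* per temperature, and measures how the trophic niche
contracts and rewires across the temperature layers.

The motivating system is leaf-cutter ant colonies and the plants available
to them: an ant colony can harvest a plant only if its maximum bite force
exceeds the force required to cut the leaf.

## The model

* Allometric scaling: trait `F = a·m^x` (bite force in mN, body mass `m`
  in mg; `x = 2/3` for muscle cross-section scaling).
* Temperature–size rule: `m(ΔT) = m₀·α^ΔT`, with `α` the per-°C body-mass
  factor. The induced per-degree performance penalty is `α^x`; for
  `α = 0.9` it spans 3.45 % (`x = 1/3`) to 10 % (`x = 1`).
* Q10 thermal performance of rate traits:
  `P(T) = P_ref·Q10^((min(T, T_plateau) − T_ref)/10)`, with `Q10 ≈ 2`
  equivalent to +10 %/°C in the linearised reading.
* Feasibility: edge (consumer `i`, resource `j`) at temperature `T` iff
  `F_bite,i(T) ≥ F_cut,j`; the edge weight is the force surplus.
* Metrics per temperature layer: consumer degree, guild generality (mean
  degree), connectance, robustness `R` (area under the secondary-extinction
  attack-tolerance curve), and Jaccard link turnover between layers.
* Three directional hypotheses evaluated on each sweep: warming decreases
  guild generality (H1), decreases individual consumer degrees (H2), and
  affects consumers unequally depending on their baseline bite force (H3).

See `docs/methods.md` for assumptions, parameter defaults, and numerical
conventions.

## Worked example

```python
import thermoweb as tw

cfg = tw.SyntheticConfig(seed=42)            # 3 colonies, 100 plants
consumers, resources = tw.generate_community(cfg)
rule = tw.TemperatureSizeRule(alpha=cfg.alpha, reference_temperature=20.0)
sweep = tw.temperature_sweep(consumers, resources, tw.parse_t_grid("20:30:0.5"), rule)

for c in consumers:
    print(f"{c.id}: mass {c.reference_mass:.2f} mg, baseline bite {c.baseline_bite_force:.1f} mN")
print(f"generality at 20 C: {sweep.generality_series.iloc[0]:.2f}")
print(f"generality at 30 C: {sweep.generality_series.iloc[-1]:.2f}")
for name, v in tw.evaluate_hypotheses(sweep).items():
    print(f"{name}: supported={v['supported']} statistic={v['statistic']:.3f}")
r = tw.robustness(sweep.networks[0], "random", n_replicates=1000, seed=0)
print(f"robustness R at 20 C (random removal): {r.robustness_r:.3f}")
```

prints

```
colony_1: mass 10.96 mg, baseline bite 49.3 mN
colony_2: mass 7.32 mg, baseline bite 37.7 mN
colony_3: mass 12.52 mg, baseline bite 53.9 mN
generality at 20 C: 61.33
generality at 30 C: 52.00
H1_generality_declines: supported=True statistic=-0.996
H2_individual_degrees_decline: supported=True statistic=1.000
H3_degree_loss_differs_by_baseline_bite_force: supported=True statistic=4.000
robustness R at 20 C (random removal): 0.988
```

Reading: at 20 °C each colony can, on average, cut 61 of the 100 plants;
a 2 %-per-°C body-size decline over 10 °C of warming removes about nine
plants from the average niche. Every colony's accessible plant set shrinks
monotonically (the hotter networks are nested inside the colder ones), the
smallest-jawed colony loses the most plants (H3 statistic: the spread in
per-colony losses is 4 plants), and the baseline network is highly robust
to random plant loss (R = 0.99, reflecting its high connectance).

## Command line

```sh
thermoweb simulate --config examples/demo.yaml --out out/      # trait tables
thermoweb sweep --config examples/demo.yaml --out out/         # full analysis
thermoweb robustness out/edges_T20.tsv --strategy random --n-replicates 1000
thermoweb report --manifest out/manifest.json --out replay/    # reproduce a run
```

`sweep` writes `metrics.csv`, per-layer edge lists (`edges_T<t>.tsv`),
`turnover.csv`, `hypotheses.json`, robustness curves, a niche-contraction
plot, and a `manifest.json` that `report` can replay byte-identically.

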