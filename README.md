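# coptdrake

How rare are planets that keep **C**ontinents, **O**ceans and **P**late
**T**ectonics coexisting for hundreds of millions of years — and what does
that scarcity do to the expected number of communicating civilizations in
the galaxy?

`coptdrake` is a modelling toolkit for astrobiologists and planetary
scientists who want to evaluate Drake-equation scenarios in which the
intelligent-life factor is split into two geophysical bottlenecks:

```
ACCs  = R* · f_p · n_e · f_l · (f_oc · f_pt) · f_c · L
COPTs = R* · f_p · n_e · f_l ·  f_oc · f_pt        · L_COPT
```

- **f_oc** — the fraction of habitable exoplanets whose surface-water
  inventory permits *both* significant continents and oceans. Isostasy makes
  planetary topography nearly size-independent, so the permitted water mass
  fraction window scales inversely with radius: on an Earth-radius planet it
  is 0.007–0.027 % of planet mass (0.3–1.2 Earth oceans; 1 Earth ocean ≡
  0.0224 % of an Earth mass). Comparing the window widths across 0.5–2.35
  Earth radii (0.009–0.04 %) with the expected spread of delivered water
  (up to 3.8–55 %) brackets f_oc between 0.00016 and 0.011.
- **f_pt** — the fraction of those planets sustaining plate tectonics for at
  least 0.5 Gyr: at most 0.33 from stellar compositions able to host
  density-driven tectonics, further cut by ~50 % of terrestrial planets
  being too small for vigorous convection, giving f_pt < 0.17 (an upper
  bound — additional unquantified reductions only lower it).

Their product f_i = f_oc·f_pt < 0.00003–0.002 shrinks the classic 1961 ACC
range of 200–50,000,000 down to < 0.006 – < 100,000 — a resolution of the
Fermi paradox by geophysics. Supporting modules compute how long a
single-lid planet needs to assemble a global plate mosaic (55,000 km of
convergent margin at 100–600 km/Myr trench lengthening: 92–550 Myr;
event-bracketed estimates on Earth: 241 and 140 Myr), and how many species a
sequential birth–death speciation chain can generate in a tectonic era
(rates ≤ 1 per lineage per Myr over 500–1000 Myr: at most a few hundred).

A seeded synthetic exoplanet-population generator (radius 0.5–2.35 Earth
radii, water fraction 0–56 % as a dry / planetesimal-delivered / ocean-world
mixture) supports end-to-end parameter-recovery checks of the f_oc
estimator, with an exact analytic companion for its in-window probability.

## Worked example

```python
>>> import coptdrake as cd
>>> w = cd.permitted_window(cd.PlanetSpec(2.35))       # largest known super-Earth
>>> (round(w.fmin, 4), round(w.fmax, 4))                # percent of planet mass
(0.003, 0.0115)
>>> (round(w.oceans_min, 2), round(w.oceans_max, 2))    # Earth oceans
(1.73, 6.66)
>>> cd.foc_ratio_bounds(0.009, 0.04)                    # window width / delivery spread
(0.00016363636363636363, 0.010526315789473686)
>>> cd.fpt_estimate().value                             # 0.33 stellar x 0.5 size cut
0.165
>>> cd.scale_acc_range((200, 5e7), (3e-5, 2e-3))        # rescaled 1961 ACC range
(0.006, 100000.0)
```

The super-Earth window reads: a 2.35-Earth-radius planet can host continents
plus oceans plus plate tectonics only if it carries between roughly 2 and 7
Earth oceans of surface water (0.003–0.012 % of its mass) — a narrow target
compared with the orders-of-magnitude spread of delivered water, which is
why f_oc is of order 10⁻⁴–10⁻².

The same chains are scriptable as scenarios:

```
$ coptdrake run paper_headline --out results
scenario,stage,key,value,display,upper_bound
paper_headline,drake,acc_scaled_high,100000,100000,1
paper_headline,drake,acc_scaled_low,0.006,0.006,1
paper_headline,drake,fi_high,0.00173684,0.002,1
paper_headline,drake,fi_low,2.7e-05,3e-05,1
...
paper_headline,foc,foc_high,0.0105263,0.011,0
paper_headline,foc,foc_low,0.000163636,0.00016,0
paper_headline,fpt,fpt_upper,0.165,0.17,1
```

Every rounded `display` value sits next to the raw `value` it came from;
`upper_bound = 1` marks quantities inheriting the one-sided f_pt limit.
`coptdrake list-scenarios` shows the bundled scenarios (`drake1961`,
`modified_acc`, `copt`, `paper_headline`, `speciation`, `tectonic`);
`coptdrake generate-population --n 100000 --seed 1 --out pop.tsv` writes a
synthetic population table.

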