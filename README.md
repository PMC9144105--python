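# coromorph

Morphometry of microdissected coronary resistance-artery networks.

Video-microscopy of a pressure-perfused left anterior descending (LAD)
coronary tree yields a digitized planar network: node coordinates in
µm, per-segment centreline polylines, and outer/inner diameters
measured at three points per segment, resolved down to the ~80 µm
visibility cutoff. `coromorph` turns that geometry into the
morphometric quantities used to compare experimental groups (for
example vitamin-D-deficient vs. supplemented animals):

* **Segments** — branch order, flow (arc) length vs. direct (chord)
  length, tortuosity `T(%) = 100 − direct·100/flow`, mean diameters,
  wall thickness, lumen cross-section area `A = π r_i²`.
* **Bifurcations** — dichotomic / lateral / multiplex categories,
  branch and deviation angles, asymmetry index
  `A_i = D_od1/D_od2 ≥ 1`, compliance with Murray's law
  `D_om³ = D_od1³ + D_od2³`, and estimation of the branching exponent
  *k* with a bootstrap CI.
* **Ring units** — decomposition of every vessel into 50 µm
  cylindrical units located by flow and direct distance from the
  orifice, with diameter and diameter × distance histograms.
* **Anomalies** — counts of hemodynamically disadvantageous
  deformities: parallel-running branches, broken courses, multiple
  (≥3-daughter) branching, and segments with `T > 8`.
* **Group statistics** — χ² probes on pooled counts normalized to 8
  networks per group, an r×2 contingency χ² on binned ring-unit
  frequencies, Shapiro–Wilk-gated t / Mann–Whitney location tests,
  and Pearson correlation of branch angle on asymmetry.
* **Synthetic cohorts** — a seeded generator of Murray-compliant
  planar trees with group presets (`VDminus`, `VDplus`) that program
  the direction of the vitamin-D contrasts, so the whole pipeline is
  testable without laboratory data.

Input formats: standard 7-column SWC (plus an automatic companion
`*.segments.csv` carrying the three-point diameters) or a documented
CSV pair (`*.nodes.csv` + `*.segments.csv`).

## Worked example

```python
import coromorph as cm

# two synthetic cohorts, 8 networks each, with programmed contrasts
vdm = cm.analyze_cohort(cm.generate_cohort("VDminus", 1), "VD-")
vdp = cm.analyze_cohort(cm.generate_cohort("VDplus", 2), "VD+")

print(int(vdm.ring_total()), int(vdp.ring_total()))
report = cm.compare_cohorts(vdm, vdp)
row = report.row("ring_unit_total")
print(round(row.p, 4), report.row("first_order_lumen_area").direction)
print(round(cm.chi2_equal_counts(6365, 6602).p, 4))
```

prints

```
6601 6840
0.0393 B>A
0.0374
```

— the two pooled, normalized 50 µm ring-unit totals (the supplemented
preset is programmed to be ~4% richer; here the surplus is flagged by
the equal-expectation χ² probe at p = 0.0393, and the first-order
lumen surplus in group B (VD+) has the programmed direction), and the
same probe applied to the published pooled totals (6365 vs. 6602),
which reproduces the published significance level p = 0.0374.

The same workflow is available from a shell:

```sh
coromorph simulate VDminus -o vdm --seed 1
coromorph simulate VDplus  -o vdp --seed 2
coromorph analyze vdm/*.swc -o out_vdm
coromorph compare -a vdm/*.swc -b vdp/*.swc -o cmp
```

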