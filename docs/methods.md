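# Methods

This note records the models, conventions and numerical choices
behind `coromorph`, and what its synthetic cohorts do and do not
emulate.

## Geometry and coordinate frame

The network is treated as planar: micropreparations are stretched
flat for imaging, and the analysis operates on the resulting 2-D
coordinates (SWC `z` is read and ignored, with a warning when
non-zero). The frame is anchored at the orifice — the origin of the
LAD network at the aorta — with +X toward the cardiac apex and +Y
toward the left ventricle. `to_coordinate_frame` applies the rigid
(optionally Y-mirroring) transform that realizes this; all pairwise
distances are preserved and the transform is idempotent. How the
apex direction is fixed when the trunk curves is not derivable from
the geometry alone, so it is an explicit input (an apex-direction
point), as is the left-ventricle side.

Segment axes are polylines; arc ("flow") quantities use the summed
chord lengths of consecutive vertices, and positions along a segment
are linear interpolations in arc length. The three diameter
measurements per segment are placed at arc fractions 0, ½ and 1 and
interpolated linearly between them.

## Per-segment metrics

* Tortuosity `T(%) = 100 − direct·100/flow`; 0 for a straight
  vessel, invariant under rigid motions and uniform scaling.
* Three-point diameters are aggregated by the arithmetic mean
  (configurable to median); the measurement protocol records three
  points but no aggregate, and the mean is the least surprising
  choice for a quantity that "generally does not change along the
  segment".
* Wall thickness is per side: `(outer − inner)/2`.
* Lumen area is `π r_i²` from the mean inner radius.
* Branch ordering defaults to the *generation* scheme (root = 1,
  every daughter increments); first-order statistics then describe
  the main trunk, which matches how "first-order branches" carry the
  largest lumen. A *trunk-following* scheme (the daughter continuing
  the trunk keeps its mother's order) is provided for analyses that
  want topological trunks.
* The direct distance of a segment from the orifice is measured to
  the segment's arc midpoint by default (configurable to the
  endpoint); the anchor is not fixed by the measurement protocol.

## Bifurcations

A branch point with ≥3 daughters is *multiplex*; with two daughters
it is *lateral* when one dominant daughter continues the mother axis
(deviation < 30° **and** `A_i > 2`), else *dichotomic*. The two
thresholds are config keys: the field names the categories without
numeric criteria, so reproducibility requires declared ones.

Axis directions at a node use 100 µm chords (two ring units) rather
than single polyline edges, which is robust to digitization jitter;
the chord length is configurable. Branch angles are unsigned planar
angles in [0°, 180°].

Murray's law is assessed on outer diameters. The per-bifurcation
relative residual is `(D_om^k − ΣD_od^k)/D_om^k` with k = 3 by
default. The exponent estimate is the root of the *summed* log-scale
residual `Σ_j [k·log D_m,j − log(D_d1,j^k + D_d2,j^k)]`, which is
strictly increasing in k. A least-squares minimization of the squared
residuals is attenuated when diameters carry multiplicative
measurement noise (an errors-in-variables effect of roughly
−0.26 at 2% noise for strongly asymmetric trees), while the
balanced-residual root is first-order unbiased because symmetric
noise enters each residual with mean ≈ 0 (measured bias ≈ −0.008 at
2% noise, n = 200). Multiplex bifurcations are excluded from Murray
and asymmetry statistics by default (the law is stated for two
daughters); a generalized ΣD³ mode exists. Confidence intervals are
percentile bootstrap over bifurcations (1000 resamples by default,
seeded).

Identifiability note: near-symmetric bifurcations (A_i ≈ 1) carry
far more information about k than strongly asymmetric ones; exponent
recovery at a given noise level is therefore sensitive to the
asymmetry spread of the data.

## Ring units

Every segment is cut into consecutive 50 µm units along its arc; the
unit centre is the axis point at the arc midpoint, diameters are
interpolated at the centre, the local axis angle (vs +X, mod 180°)
comes from the unit's chord, and the flow distance is the upstream
path length plus `(i + ½)·50`. Terminal fragments shorter than one
unit are dropped by default (a ring unit is a fixed-length base
element); a `keep` policy (retain fragments ≥ 25 µm as a final unit)
exists because pooled historical counts cannot reveal which policy
produced them. Conservation under `drop`: per segment,
`0 ≤ flow − 50·n_units < 50`.

Diameter histograms use half-open bins `[c−25, c+25)` centred on
multiples of 50 µm (so a 225 µm unit falls in the 250 bin), matching
the 50…650 µm axis labelling of the density plots. The 2-D
diameter × flow-distance histogram uses 1 mm distance pitch, which
supports both the 6–9 mm and the 10–15 mm windows discussed for the
group contrast. Pooled counts are normalized to a reference cohort
size (8 networks) as `counts · 8/n_networks`; normalized counts stay
real-valued internally and are rounded half-up only for reporting,
because the χ² probes operate on the normalized values.

## Anomaly detectors

Four deformity classes are counted; the two that the field names
without criteria get explicit, documented defaults:

* *Multiple branching*: one instance per node with ≥3 daughters
  (arity recorded).
* *Tortuosity > 8*: per-segment, strict inequality on `T(%)`.
* *Broken course*: a direction change exceeding 60° between
  consecutive 50 µm chords **within** one segment; turns at
  bifurcation nodes are branching, never kinks.
* *Parallel running*: an unordered pair of segments whose ring units
  stay within 200 µm of each other with local axis directions
  differing by < 15° (mod 180°) over ≥ 250 µm of arc. Mother–daughter
  pairs are excluded (a daughter necessarily starts on its mother);
  sibling daughters are eligible, which is exactly how a
  parallel-running deformity arises at a bifurcation.

Detectors are deterministic and invariant to segment relabeling.

## Group statistics

* Total-count probes (segments, ring units, each anomaly class, sum
  of deformities) are df = 1 goodness-of-fit χ² of the pair (a, b)
  against equal expectation `(a+b)/2`, two-sided, **without**
  continuity correction. This reading reproduces the published
  significance levels of the historical count pairs exactly —
  (6365, 6602) → 0.0374, (2, 3) → 0.65, (11, 8) → 0.49,
  (7, 5) → 0.56, (27, 22) → 0.48 — which is why it, and no corrected
  variant, is implemented. (The published broken-course level 0.74
  is not reproduced by any standard χ² reading of (7, 6), which
  gives 0.78; it is treated as a typographical error.)
* Binned frequency profiles are compared with an r×2 contingency χ²
  (df = r−1) after merging adjacent bins until every expected cell
  reaches 1.0 (merge map reported).
* Continuous per-network variables use a Shapiro–Wilk gate at
  α = 0.05 per group: both normal → two-tailed unpaired t-test,
  otherwise Mann–Whitney; the chosen test is recorded. Note the gate
  itself consumes type-I error: truly normal fixtures route to the
  t-branch ~90% of the time (0.95²), not 100%.
* Asymmetry–angle coupling is Pearson correlation (plus OLS slope)
  of branch angle on A_i, pooled across a cohort's bifurcations
  (per-network mode available through the per-network analyses).
* Significance criterion p < 0.05 throughout; no multiple-testing
  correction is applied (none is part of the emulated battery); a
  hook exists but defaults off.

## Synthetic cohorts

The generator grows rooted planar trees by recursive bifurcation:

* Diameters: the root outer diameter (550 µm default) splits at each
  node by Murray's law at a drawn asymmetry index; recursion stops
  when a daughter would fall below the 80 µm visibility cutoff
  (`terminal_diameter`), or at `max_order` 12. Measured diameters
  get multiplicative log-normal noise (`murray_noise_sd`, default
  2%) plus a per-network scale jitter (2%); inner diameters follow a
  wall fraction (10% of outer per side; 7.5% on the first-order
  trunk in the `VDplus` preset).
* Asymmetry: a fixed per-order pattern (2.8, 1.9, 3.2, 2.3, 3.4)
  with small log-normal jitter (2%). The strongly asymmetric rungs
  produce the long-trunk, quickly-terminating side branches typical
  of these networks (~31 segments, ~810 ring units, ~15 mm maximal
  flow distance per network; pooled 8-network totals land in the
  6000–7000 range of the emulated study).
* **Near-replicate design**: termination decisions are taken on a
  noise-free *template* diameter lineage (pattern asymmetry only),
  so every network of a preset shares one branching skeleton;
  between-network variability comes from segment-length jitter (3%),
  diameter noise and angle jitter. This is deliberate: the pooled
  χ² probes treat the pooled count as the only randomness, and a
  programmed few-percent count contrast is recoverable at n = 8 per
  group only in this regime. Real inter-animal variability is much
  larger (segment counts and totals vary tens of percent), so
  passing recovery tests here demonstrates pipeline correctness and
  calibration, **not** statistical power on real cohorts.
* Angles: total branch angle = 35° + 25°·(A_i − 1) + N(0, 4°), the
  larger daughter deviating less (weight 1/(1 + A_i²)), side chosen
  to fan subtrees away from the trunk axis (keeps the planar layout
  collision-free). This builds in the positive asymmetry–angle
  coupling the supplemented group shows.
* Axes: single-arch sinusoidal lateral excursion (3% of length), a
  mild baseline tortuosity far below the 8% anomaly threshold.
* Defect injection: preset counts per network for each anomaly
  class, constructed to be detector-exact (verified): parallel pairs
  straighten one bifurcation's daughters ~100 µm apart (leaf
  daughters preferred), kinks are single 65° grid-aligned turns at
  88% of the arc (which keeps the kinked segment's tortuosity below
  8%), tortuous segments become deep sine arches (T ≈ 10%) bending
  away from siblings, and multiple branching adds a third small
  daughter in the angular gap left by the existing two. Injected
  ground truth is recorded in `network.meta["injected"]`.
* Presets: `VDminus` scales orders 1–4 lengths by 1.12 (lengthier
  proximal branches); `VDplus` thins the first-order wall (larger
  first-order lumen) and scales orders ≥ 5 lengths by 1.175, fixed
  once from the template tree's low-order length share so the pooled
  ring-unit surplus over `VDminus` is the programmed ~4%. Both
  presets inject one deformity of each class per network (groups do
  not differ in anomalies). Seeds: one master seed; per-network
  seeds derive from it by a fixed splitting rule, so a cohort can be
  extended without reshuffling existing networks. The within-network
  spatial density profile along flow distance is an emergent
  property of the length/decay parameters, not a fitted quantity.

What the generator does **not** emulate: 3-D course and
foreshortening, digitization jitter correlated along an axis,
inter-animal topological variability, vessel taper within a segment
(default 0 so that exact Murray compliance is well-defined on
segment-mean diameters), and any biophysical growth mechanism.

## Numerical choices and degenerate inputs

* Parent-end/daughter-start coincidence tolerance 1 µm
  (digitization jitter); exceeding it is a validation error.
* Canonical serialization order: depth-first, daughters by
  descending mean outer diameter, ties by departure angle — writing
  the same network twice is byte-identical.
* SWC carries one radius; without the companion table, inner
  diameters are reconstructed as outer − 2×(default wall 15 µm) and
  the network is flagged.
* Closed-loop axes (direct length 0) warn and yield T = 100 −
  0 = 100-capped behaviour upstream; zero flow length is an error.
* Exponent search bounded to [0.5, 8]; root-finding tolerance 1e-12.
* χ² with zero counts in both groups of a class is reported as
  p = 1 rather than an error in cohort reports.
* All simulation problem sizes used by the tests and the acceptance
  script (8-network cohorts, 50-replicate recovery runs, 500-replicate
  calibration, n = 200 bifurcation samples) were chosen as the
  smallest sizes at which the binomial/bootstrap noise of the checked
  rates is comfortably inside the asserted bands.

## Known limitations

* The planar model cannot represent vessels crossing in depth;
  apparent crossings in projected data may trigger the
  parallel-running detector on real material.
* The lateral/dichotomic boundary and all four anomaly criteria are
  declared conventions, not measured properties; conclusions that
  hinge on them should report sensitivity to the config keys.
* Normalized (non-integer) counts entering χ² formulas follow the
  emulated battery; it slightly miscalibrates the probe when
  normalization factors are far from 1.
* The near-replicate cohort design deliberately understates
  biological variance (see above).
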