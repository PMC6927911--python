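# Methods

## Data reduction

A nanoSIMS screen of this kind counts four secondary-ion species per cell
(ROI): ¹²C₂⁻, ¹²C¹³C⁻, ¹²C¹⁴N⁻ and ¹²C¹⁵N⁻. Nitrogen is reduced directly:
at.% ¹⁵N = 100 · CN¹⁵/(CN¹⁵ + CN¹⁴). Carbon is collected as a dimer;
assuming random pairing of carbon atoms at ¹³C atom fraction a, the dimer
species probabilities are (1−a)² for ¹²C₂ and 2a(1−a) for ¹²C¹³C, so the
measured dimer ratio r_d equals twice the monomer atomic ratio R = a/(1−a).
We therefore take R = r_d/2 and convert to atom percent. An additional
multiplicative correction on R (instrument calibration against isotopic
standards; values near 1–1.5 are typical) is exposed as
`correction_factor` in the experiment configuration, defaults to 1.0, and
is echoed into all outputs; it is deliberately not baked into the dimer
algebra because calibration practice varies between facilities.

Degenerate counts: a zero denominator (¹²C₂⁻ or ¹²C¹⁴N⁻ of zero) raises a
measurement-invalid error; the table reader flags and excludes such rows
with their line numbers rather than dropping them silently.

## The two-pool mixing model

A cell's final biomass for element X is modeled as a linear mix, in
atom-fraction space, of original biomass at the initial composition
a_init and newly synthesized biomass at the labeled-substrate composition
a_sub:

    F_s = (a_meas − a_init) / (a_sub − a_init)      F_i = 1 − F_s
    X_net% = 100 · F_s / (F_s + F_i) = 100 · F_s

X_net% is the percent of the *final* biomass synthesized during the
incubation. The companion quantity relative to *initial* biomass,
Fx_net% = 100 · F_s/F_i, satisfies X = 100·Fx/(Fx + 100); the conversion
is implemented on the percent scale throughout so that both quantities are
percents (the fraction-scale form of this conversion that sometimes
appears in print is dimensionally inconsistent and is not used). Fx_net%
diverges for a cell whose biomass is entirely new (X = 100); it is then
reported as undefined.

Assumptions worth keeping in mind:

- a_init is the mean of a representative unlabeled control population per
  site, not the composition of the particular cell (isotopic analysis is
  destructive, so the same cell cannot be measured twice). Canonical
  natural-abundance values (1.11 at.% ¹³C, 0.366 at.% ¹⁵N) are defaults
  for synthetic data only.
- Newly synthesized biomass is assumed to have the same C:N ratio as
  existing biomass; beyond that the classification is independent of the
  cell's C:N ratio, which is therefore not simulated.
- Measurement noise can push a_meas below a_init. F_s is clamped to [0, 1]
  for classification — noise must not become negative biomass — while the
  raw value is preserved in the per-cell output (`f_s_c_raw`,
  `f_s_n_raw`) for QC.

## Thresholds and detection limits

A cell is isotopically enriched — anabolically active — when its at.%
strictly exceeds the control mean plus three control standard deviations
(sample SD, n−1: the control cells are a sample of the unlabeled
population). A value exactly at the threshold is not enrichment; this
tie-break is deterministic and one-sided. Controls are fit per site and
per isotope, never pooled across sites. No control outliers are excluded.

The net-assimilation detection limit is the mixing model evaluated at the
threshold: DL = 100 · 3σ/(a_sub − a_init). It is zero iff σ = 0,
increases with control scatter and decreases with pool enrichment —
which is why a 98 at.% amino-acid pool yields a far lower detection limit
(~0.07% of biomass for SPOT-like control scatter) than a 13.1 at.%
bicarbonate pool (~0.38%): the assay is inherently more sensitive to
activity than to autotrophy.

## Metabolic classification

Active cells are assigned by fixed first-match rules on (C_net%, N_net%):

1. **I, exclusively heterotrophic** — C_net% < DL_C and N_net% > DL_N
   (no detectable bicarbonate-derived carbon);
2. **II, exclusively autotrophic** — C_net% ≥ N_net% (all new carbon from
   bicarbonate; includes cells enriched in ¹³C only);
3. **III, primarily heterotrophic** — N_net% ≥ 2·C_net% (<50% of new
   carbon from bicarbonate);
4. **IV, primarily autotrophic** — C_net% < N_net% < 2·C_net%.

Rules 2–4 partition the plane, so every active cell receives exactly one
zone. Boundary behavior is explicit: the 1:1 line belongs to zone II (the
"≥" in rule 2) and the 2:1 line to zone III (written "≥" here: with a
strict ">" in rule 3 and a strict "<" in rule 4, points exactly on the
2:1 line would match neither; assigning the line to the heterotrophic
zone is the conservative choice for autotrophy claims). Chemoautotrophs
are II + IV, heterotrophs I + III. Mixotrophy is deliberately not a
category: minor ¹³C uptake by heterotrophs is better explained by
anaplerotic reactions, and cells are classified by primary carbon source
only.

Because the enrichment flag and the detection limit are the same linear
transform of the same measurement, a cell cannot have both nets below
their detection limits while an at.% sits above its threshold; this
consistency is asserted in the test suite.

Formatted (human-readable) percentages round half away from zero to the
nearest integer; machine outputs keep full double precision.

## The synthetic-data generator

`simulate_community` emulates the study conditions of a dark-bottle
coastal-seawater incubation screened at high throughput:

| parameter | default | why |
|---|---|---|
| class fractions (inactive/auto/hetero) | 0.09 / 0.10 / 0.81 | a mostly active community (~91%) with a ~10% chemoautotroph share, typical of such screens |
| activity distribution | lognormal, median 1%, σ_log 1.8, clipped at 95% | single-cell activity spans several orders of magnitude (~0.01–50%) |
| heterotroph C_net | U[0.01, 0.03] × N_net | anaplerotic inorganic-carbon fixation is ~1–3% in heterotrophs; exercises the I/III boundary |
| autotroph N_net | U[0.3, 1.0] × C_net | autotrophs are always ¹⁵N-labeled to some degree (amino-acid-derived N is recycled community-wide) |
| pools | C: 13.1 at.%; N: 98 at.% | spiked-bicarbonate and amino-acid pool enrichments of the emulated setup |
| control | n = 262 per element at 1.11 / 0.366 at.% | natural-abundance unlabeled population of realistic size |
| counting | Poisson, 10⁶ expected ions per species pair | realistic ROI-integrated count totals; control at.% scatter then follows √(a(1−a)/N) counting statistics |
| excess Gaussian scatter | 0 | counting-limited by default; instrument/biological excess variance is opt-in |

Cells are drawn classwise, the forward mixing model gives the expected
at.% (a = a_init + (X_net/100)(a_sub − a_init)), and counts are Poisson
around the random-pairing dimer expectations (carbon) and monomer
expectations (nitrogen). With `counting=None` the generator emits exact
at.% values, and the pipeline recovers true nets to machine precision —
the forward model is the exact inverse of the analysis.

Class assignment is iid by default (`rng.choice` with the class
probabilities). `exact_class_counts=True` switches to largest-remainder
apportionment with shuffling, so the realized composition equals the
configured fractions exactly; parameter-recovery tests use this mode so
that a binomial interval around the recovered fraction measures pipeline
error rather than the generator's own sampling noise.

`simulate_dual_label_experiment` emulates a dual-labeled
(¹³C,¹⁵N)-amino-acid incubation with two active archetypes — "N-only
assimilators" (enriched in ¹⁵N but not in the carbon from the same
molecule) and "intact-uptake" cells (enriched in both) — to exercise the
co-enrichment summary used to quantify intact amino-acid uptake in
archaea.

What the generator does **not** emulate: spatial images or ROI
segmentation (the pipeline starts at ROI-level counts), substrate
recycling and cross-feeding kinetics, population dynamics over the
incubation, detector dead time or quasi-simultaneous-arrival effects
beyond the scalar correction factor, and any taxon-dependent activity
structure beyond the labels the caller assigns. Passing tests on
synthetic data therefore validate the arithmetic, thresholds, and
classification logic — not the biological realism of any particular
field sample.

## Numerical choices

- All percent quantities are carried on the 0–100 scale; fractions appear
  only inside the mixing algebra.
- Conversions (ratio↔at.%, X_net↔Fx_net) round-trip to ≤1e-12 and are
  covered by derandomized property tests.
- Per-cell CSVs are written at full double precision and re-read with
  round-trip float parsing, so numeric columns survive a write/read cycle
  bit-exactly. Rounding is presentation-only.
- Classification requires strictly positive detection limits; a
  zero-scatter control (DL = 0) is rejected as a configuration error
  rather than silently classifying every cell as enriched.
- The simulator redraws any zero Poisson denominator count so stored raw
  counts always reduce to the emitted at.% via the declared conversions
  (vanishing probability at realistic count totals).

## Known limitations

- The detection limit assumes Gaussian-like control scatter; heavy-tailed
  control populations would make the 3σ threshold's false-positive rate
  deviate from the nominal one-sided Normal tail (~0.135%).
- Aggregated screens report exact counts and full-precision fractions per
  group; summary statements combining groups with different denominators
  (e.g. "most active cells of taxon T across experiments") should be made
  from the counts, since rounded per-group percentages need not average
  to the pooled value.
- Only C and N isotope systems are implemented; no dead-time or drift
  corrections are applied.
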