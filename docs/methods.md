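# Methods

## Model

The vertebral column is idealised as a structural system of 24 articulating
sections (C1–C7, T1–T12, L1–L5), each pairing a vertebra with the
intervertebral disc below it (L5 has none in the default topology; the fused
sacral/coccygeal block is the fixed support and is not load-rated, though a
flag counts it in the series length as a zero-failure member). Per tissue —
cortical, cancellous, annulus, nucleus — and per loading mode — tension,
compression — a strength limit state g = R − Q compares a normal yield
stress R against a normal applied stress Q, both in MPa.

Component reliability uses the first-order closed form
β = (μ_R − μ_Q)/√(σ_R² + σ_Q²), P_f = Φ(−β), valid for independent normal
R and Q with a linear limit state. Monte Carlo counting of R < Q over paired
draws is the independent verification route; it samples both distributions
truncated below at zero (strengths and stresses are non-negative), so it is
also the reference when truncation matters.

System aggregation follows the load-path structure: the two tissues within
a vertebra (or disc) carry the load in parallel, so the component fails only
if both tissues fail, P_F = Π P_Fi; disc and vertebra within a section, and
the sections along the column, are series links, P_F = 1 − Π(1 − P_Fi).
Independence of component failures is an explicit assumption — it is what
makes the products exact — and correlated extensions are out of scope. The
system reliability index is β_sys = −Φ⁻¹(P_f,sys); this generalized
definition round-trips every packaged reference (P_f, β) pair at two printed
decimals, which is the evidence for adopting it.

One printed source formula labels the vertebra-level product with the disc's
symbol; it is read as the vertebra equation (cancellous × cortical). The
accompanying prose also calls the within-disc combination a "series" system
while printing a product; the product (parallel) reading is implemented as
the default and a `disc_combination: parallel|series` switch exposes the
alternative.

## Demand synthesis

The demand side emulates, not reproduces, a finite-element stress analysis:

- **Load model.** The spine carries `trunk_fraction` (default 0.55, bounded
  0.50–0.60) of body weight, divided into equal per-vertebra shares that
  accumulate cranial→caudal over the 24 articulating vertebrae (static
  equilibrium: section k of 24 carries k shares), plus a `head_mass`
  (default 5.0 kg, bounded 4.5–5.5) load entering at C2. A non-cumulative
  variant (every section below C1 carries one share) sits behind a config
  switch; whether the even division was meant cumulatively is genuinely
  open, and cumulative is the default because it is what equilibrium
  implies.
- **Areas.** Stress = force / effective area. The packaged area table is
  synthetic: anatomically plausible endplate areas rising from ~200 mm²
  (C1) to ~1000 mm² (L5), a cortical shell at 20 % of the vertebral area,
  disc areas equal to the mean of the adjacent vertebrae split 60 %
  annulus / 40 % nucleus. The same sectional force loads both parallel
  tissues through their own areas. Areas shape only the *relative* stress
  profile — the absolute level is calibrated away (below) — and the table
  is fully user-replaceable.
- **Tension demands.** Pure axial compression would never exercise the two
  tension limit states, yet tension-governed sites exist in the reference
  vulnerable-zone tables. A baseline tension demand equal to
  `tension_fraction` (default 0.2) of the local compression demand stands
  in for bending/eccentricity effects.
- **Scatter.** A per-(section, tissue, mode) multiplicative log-normal
  jitter with sigma `jitter_sigma` (default 0.05) emulates the spread of
  stress results across random-property models. It is drawn from the master
  seed in a fixed order independent of condition and load, so equal seeds
  give draw-for-draw comparable tables; dispersion enters as
  `std = cov × mean` with `cov` default 0.10 (no demand coefficient of
  variation is published; calibration absorbs the choice and the parameter
  is exposed).
- **Scoliosis.** Reference results place maximum stresses near the
  inflection points of the scoliosis curvature. Demand means are multiplied
  by 1 + (κ − 1)·w(d), d the section distance to the nearest inflection,
  w a triangular kernel with w(0) = 1 vanishing at `decay_width` (default 3)
  sections; κ (`amplification`) defaults to 2 and the default inflections
  are T7 and T12, a typical thoracolumbar double-curve pattern. The normal
  profile is exactly the identity.

What the generator does **not** emulate: real geometry, bending moments and
eccentric load paths, inter-section stress correlation, viscoelastic
time-dependence, and patient-specific curvature. Passing tests therefore
demonstrate the reliability machinery and the qualitative structure
(accumulating load, inflection-concentrated amplification, the orderings),
not validated patient-level stress predictions.

## Calibration

A single multiplier s on all demand means and stds is the bridge between the
synthetic generator and published system-level targets. β_sys(s) is
continuous and strictly decreasing (every component margin shrinks as s
grows), so the s matching a target β is found by bisection — geometric
midpoints, since s spans decades — on a bracket that expands up to 10¹²
either way, to a default tolerance of 10⁻³ on β. As s → 0, β_sys approaches
a finite ceiling (each component β tends to μ_R/σ_R, so the system retains a
floor failure probability ≈ 1.3 × 10⁻⁵, β ≈ 4.2 under the default
generator); targets above the ceiling raise a bracket error rather than
silently clipping. All twelve packaged reference cells (β from 2.73 to 4.10)
lie below the ceiling and are recovered within 10⁻³.

The normal-vs-scoliosis comparison sweeps body mass at one *shared* scale,
calibrated on the normal column at 30 kg: the two conditions then differ
only in the curvature profile, so the scoliosis β deficit at every mass
isolates the effect of the deformity.

## Numerical choices

- Series complement-products are computed as −expm1(Σ log1p(−pf)), so a
  33-term chain of pf ≈ 10⁻⁶ loses nothing to cancellation; an exact
  enumeration oracle over ≤ 20-component series/parallel trees provides the
  ground truth in tests (agreement to 10⁻¹² relative).
- Truncated-normal sampling uses the inverse-CDF transform of a seeded
  uniform stream; Monte Carlo consumes one uniform *pair* per (R, Q) draw,
  making estimates independent of the batch size used for streaming.
- The closed form ignores truncation; a warning fires whenever a
  distribution with mean/std < 3 enters it (cancellous and nucleus are the
  affected tissues). When one side is degenerate (std = 0) the exact
  truncated-normal CDF is used instead, so zero demand yields pf = 0
  exactly; when both are degenerate the deterministic indicator
  μ_R ≤ μ_Q is reported through a separate code path.
- pf = 0 and pf = 1 map to ±∞ β sentinels; an MC estimate with zero
  observed failures additionally carries the one-sided 95 % rule-of-three
  bound 3/n.
- Per-component mode combination defaults to the governing mode
  (max of the tension and compression pfs), matching how a
  principal-stress check reports the governing state; a series policy is
  available and the choice is recorded in all outputs.
- All randomness derives from one master integer seed; derived streams use
  fixed spawn keys, never hash-dependent values, so runs are bit-reproducible
  across processes.

## Problem sizes

Default test and reporting sizes: Monte Carlo verification at n = 10⁵–10⁶
per limit state (binomial standard error ~10⁻⁵ at pf ~10⁻⁴), 100 random
trees for the enumeration cross-check, 20 random limit states for the
MC-vs-closed-form agreement suite, and the 12-cell calibration recovery
suite; the full default run completes in seconds on one core. MC sample
counts are configurable up to 10⁸ via streamed batches when tighter
rare-event verification is wanted.

## Limitations

Failure here means first yield of any tissue under the axial-load strength
limit state: no fatigue, no time-variant or service limit states, no
correlated failures, no FORM/SORM with non-normal marginals, and no
patient-specific geometry. The packaged yield-stress, elastic and
viscoelastic tables are fixed transcriptions; the elastic and Prony-series
tables are carried as validated metadata only. Scoliosis severity enters
solely through the amplification profile, not through a curvature-angle
measure, so comparisons across severities require the user to map severity
onto (κ, inflection set) themselves.
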