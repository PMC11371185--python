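# Methods

## The problem

During meiosis I, each pair of homologous chromosomes (a *bivalent*) must
obtain at least one crossover (CO) to segregate correctly, and most COs —
the class I, HEI10-marked kind — are subject to *interference*: a CO
suppresses further COs nearby, so per-bivalent CO counts are
under-dispersed relative to a Poisson law and adjacent COs are more evenly
spaced than uniform. Cytologists read this out from chromosome spreads:
diakinesis configurations (ring / rod / pair of univalents) give a
conservative chiasma count, HEI10 immunofluorescence gives class I focus
counts and positions, and unlabelled chiasmata are booked as
interference-insensitive class II COs. `meioscope` implements that
read-out and the statistics around it, plus a generative simulator used to
validate the inference by parameter recovery and test calibration.

## Scoring rules

* **Minimum chiasmata.** A ring bivalent is scored 2, a rod 1, a univalent
  pair 0; the cell score is the sum over its 19 pairs. This undercounts
  whenever a bivalent carries more than two COs or several COs confined to
  one arm (a rod with two chiasmata still scores 1); the simulator-backed
  tests assert exactly this conservatism. The expected per-cell score for
  configuration proportions (p_ring, p_rod) is `n_pairs · (2·p_ring + p_rod)`.
* **Crossover partition.** Per diakinesis cell:
  class I = Σ HEI10-labelled chiasmata, class II = Σ unlabelled chiasmata,
  total = class I + class II (an enforced identity).
* **Distributions and spacings.** Foci-per-bivalent counts are tabulated
  over categories 0..K. Univalent pairs are excluded by default (the
  distribution describes *bivalents*); `count_univalents_as_zero` includes
  them, which shifts category-0 mass — the choice is surfaced because the
  source convention is ambiguous. Focus positions are fractions of bivalent
  length; adjacent-focus spacings are consecutive differences of the sorted
  positions, with 0- and 1-focus bivalents contributing an empty spacing
  set (not zeros).
* **Intensity normalization.** value = (raw − background) / mean of
  (raw − background) over the reference genotype; the reference mean is 1
  by construction and the output is invariant to uniform rescaling.
  Percent decrease = 1 − normalized mean.

## The Poisson null and its two chi-square conventions

Interference is tested by goodness of fit of foci-per-bivalent counts to
Poisson(λ̂), λ̂ = sample mean (maximum likelihood), no continuity
correction. Because published chi-square values of this kind are often
produced in spreadsheets whose binning/df convention cannot be recovered,
two explicit policies are provided and reported side by side:

* `excel_k_minus_1`: categories 0..max observed plus one extra empty
  category; expected counts `n·pmf` (not renormalized); df = categories − 1.
* `folded_k_minus_2`: the right tail is folded until every expected count
  is ≥ 5 (the last category carries the Poisson tail mass, so expectations
  sum to n); df = categories − 2, charging one df for the estimated rate.

The pipeline emits a verdict only when both configured policies agree,
otherwise it flags the result as policy-sensitive. Exact published
p-magnitudes of this family are not reproduction targets — only the
sign/threshold conclusions are. Calibration of the folded policy is
checked empirically (rejection rate 5% ± 2% on truly Poisson data at
n = 551); the classical caveat that the true null law lies between
χ²(K−2) and χ²(K−1) when λ is estimated from ungrouped data is covered by
that tolerance.

Group-vs-group distribution differences use the standard 2×K homogeneity
chi-square with combined-expected < 5 columns folded into the tail.

## Interference strength from spacings

The spacing coefficient of variation (SD/mean of pooled adjacent
spacings) is the usual summary: a gamma-renewal process with shape ν has
gap CV = 1/√ν, so CV ≈ 1 means no interference and small CV strong
interference. `estimate_nu` fits the gamma shape to pooled spacings by
maximum likelihood (method-of-moments start, Newton iteration on
log k − ψ(k) = log x̄ − mean(log x), tolerance 1e-8, ≤100 iterations) with
a seeded percentile bootstrap interval (default 1000 resamples). On finite
bivalents long gaps are censored by the ends, so ν̂ is biased; at the
spacing densities used in validation (rate 5 per unit length) the bias is
small and the estimate stays within 25% of truth at 1000 bivalents — a
bound established empirically and pinned as a regression test. Spacings
are pooled across bivalents by default (per-bivalent averaging first is
not implemented as a separate mode; pooling is the documented convention).

## Games–Howell comparisons

For each pair of groups: Welch SE = √(s₁²/n₁ + s₂²/n₂),
Welch–Satterthwaite df, statistic q = |mean diff|/(SE/√2), and p from the
studentized-range distribution with k groups at that df
(`scipy.stats.studentized_range`). Adjustment is within one family (one
measured quantity across genotypes); no cross-family correction. Under
equal sample variances and equal n the procedure reduces to Tukey's HSD up
to the df convention, which the tests exploit as an independent oracle;
family-wise error under the global null is calibrated to α ± 2%.

## The simulator

Per bivalent of relative length L with centromere fraction c:

* class I positions: stationary gamma-renewal process, shape ν, event rate
  λ₁ per unit length. The first event is drawn from the equilibrium
  (integrated-tail) law so E[count] = λ₁·L exactly for every ν. Integer ν
  uses the exact thinning construction (Poisson process at rate ν·λ₁, keep
  every ν-th point from a uniformly random phase — gaps are then Erlang(ν)
  and the first arrival the exact Erlang equilibrium mixture); non-integer
  ν uses sequential sampling, inverting the closed-form equilibrium CDF
  F_e(x) = F_{ν+1}(x) + (βx/ν)·S_ν(x) (β = ν·λ₁) for the first arrival.
* class II positions: independent homogeneous Poisson overlay at λ₂.
  Interference acts within bivalents only and on class I only, matching
  the observation that class II formation is dosage-insensitive.
* obligate-CO mechanism on the union: `none`, `resample_until_nonempty`
  (redraw the pair until ≥ 1 CO), or `forced_extra` (add one uniform
  rescue CO when the pair is empty, booked as class II). `forced_extra` is
  the preset default for non-null genotypes: because the rescue CO is
  class II, the class I per-bivalent marginal remains exactly the renewal
  count law (in particular exactly Poisson at ν = 1), whereas conditioning
  the whole pair on non-emptiness depletes the class I zero category and
  would make nominally interference-free genotypes reject the Poisson
  null. Biologically this treats CO assurance as a non-interfering backup
  pathway.
* observation: configuration from *all* COs arm-wise around the centromere
  (both arms hit → ring, one arm → rod, none → univalent pair);
  n_chiasmata = all COs; each class I CO becomes a focus independently
  with probability `detection_prob` (default 1), and foci positions are
  the detected class I positions as fractions of L. With full detection,
  foci + unlabelled chiasmata = chiasmata on every record.

Default genome: 19 pairs, equal relative lengths 1.0, centromere fraction
0.45 everywhere (no karyotype metrics are assumed); overridable via YAML.

### Genotype presets

The six presets encode the ASY3 dosage series. Class I rates are set so
that the expected foci per diakinesis cell (19·λ₁) equals the observed
genotype means; class II rates additionally absorb the expected
forced-extra contribution λ₂ + P(no class I)·e^(−λ₂) so unlabelled
chiasmata per cell match the observed class II means (P(no class I) from
the closed-form equilibrium survival). Interference is strong (ν = 8) in
wild type and the two-functional-allele genotypes — strong enough that
n ≈ 550 bivalents reject the Poisson null essentially always, as observed —
and absent (ν = 1) in the one-allele genotypes, whose published
distributions fit Poisson. The null genotype has a strongly reduced class
I rate, a near-zero class II rate and no CO assurance, which reproduces
~71% of pairs as univalents without further tuning (e^(−0.318) ≈ 0.73).

| preset | ν | λ₁/pair | λ₂/pair | obligate | target foci/cell |
|--------|---|---------|---------|----------|------------------|
| AACC_wt | 8 | 1.4147 | 0.3232 | forced_extra | 26.88 |
| aaCC    | 8 | 1.5663 | 0.3336 | forced_extra | 29.76 |
| AAcc    | 8 | 1.5474 | 0.3326 | forced_extra | 29.40 |
| aaCc    | 1 | 1.9953 | 0.2050 | forced_extra | 37.91 |
| Aacc    | 1 | 1.9300 | 0.2264 | forced_extra | 36.67 |
| aacc    | 1 | 0.2884 | 0.0295 | none         | 5.48  |

### What the simulator does and does not emulate

It reproduces count means, count dispersion, configuration mixes,
assurance behavior and spacing statistics. It does not model chromosome-
specific CO landscapes (telomere/centromere bias), cross-bivalent
interference, synaptonemal-complex spatial dynamics, HEI10 coarsening, or
stage-dependent focus consolidation (stages other than diakinesis are
annotations, not distinct generative regimes). Passing tests therefore
validate the inference machinery under the stated renewal model, not those
spatial features of real meiocytes.

## Numerical choices and problem sizes

* Positions serialize to 6 decimal places; round trips are exact for text
  and within 1e-6 for fractions.
* Percent changes round half away from zero to the nearest integer.
* brentq inversion tolerance 1e-12 for the equilibrium first arrival;
  Newton tolerance 1e-8 for the gamma-shape MLE.
* COs exactly at the centromere coordinate count as the proximal arm
  (measure-zero event).
* Validation experiments use 200–1000 replicates at 29–1000 bivalents and
  500-cell calibration runs — sizes at which Monte-Carlo error is well
  inside the stated tolerances while the whole suite stays fast.
* Per-genotype RNG streams in the pipeline are spawned as
  `default_rng([run_seed, genotype_index])`, making outputs byte-identical
  per seed.

## Known limitations

* The configuration-based chiasma count is a lower bound by design.
* ν̂ from pooled spacings is censoring-biased (low at low focus density);
  no bias correction is applied.
* The homogeneity and GOF tests assume independent bivalents; within-cell
  correlation (e.g. cell-level rate variation) is not modelled.
* Exact spreadsheet p-magnitudes for the GOF family are unknowable without
  the original binning convention; only directional conclusions are
  reproduced.
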