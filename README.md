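# meioscope

Crossover-patterning analysis for meiotic cytology tables, built around
the *Brassica napus* ASY3 dosage series: chiasma scoring from diakinesis
bivalent configurations, class I/II crossover partitioning from
HEI10-labelled chiasmata, Poisson-null interference tests on
foci-per-bivalent counts, normalized inter-focus spacing statistics,
Games–Howell group comparisons — and a gamma-renewal meiocyte simulator
that validates the whole inference chain by parameter recovery and test
calibration.

It is written for cytogeneticists who already have per-cell measurement
tables (configurations, focus counts, focus positions, intensities) and
want reproducible, convention-explicit statistics on top of them.

## The science in brief

Each of the 19 chromosome pairs of a *B. napus* meiocyte must gain at
least one crossover (CO); a ring bivalent carries ≥ 2 chiasmata, a rod 1,
a univalent pair 0, so a cell's configurations give a conservative
chiasma count `2·n_ring + n_rod`. Class I COs (HEI10 foci) are subject to
interference: modelling their placement as a stationary gamma-renewal
process with shape ν, inter-CO distances are gamma(ν) with CV = 1/√ν, and
ν = 1 (no interference) makes per-bivalent counts Poisson. Interference is
therefore read out two ways: a chi-square goodness-of-fit of
foci-per-bivalent counts against Poisson(λ̂ = sample mean), and the
spacing CV / maximum-likelihood ν̂ from pooled adjacent-focus distances.
Chiasmata without a HEI10 label are booked as interference-insensitive
class II COs, so per cell: total = class I + class II.

## Worked example

```python
from meioscope import (distribution_from_counts, expected_min_chiasmata,
                       poisson_gof, percent_change)

# Wild-type diakinesis: 65.95% ring / 34.05% rod bivalents over 19 pairs
print("expected minimum chiasmata:",
      round(expected_min_chiasmata(0.6595, 0.3405, 0.0, 19), 2))

# Foci per bivalent over 551 wild-type bivalents (9.80/43.19/39.93/7.08%)
dist = distribution_from_counts([54, 238, 220, 39], genotype_label="WT")
for policy in ("excel_k_minus_1", "folded_k_minus_2"):
    fit = poisson_gof(dist, policy)
    print(f"{policy}: lambda={fit.lambda_hat:.3f} chi2={fit.chi2:.2f} "
          f"df={fit.df} p={fit.p_value:.2e}")

# Focus-count gain of a one-functional-allele mutant vs wild type
print("diakinesis increase:", percent_change(37.91, 26.88).rounded, "%")
```

prints

```
expected minimum chiasmata: 31.53
excel_k_minus_1: lambda=1.443 chi2=144.69 df=4 p=2.79e-30
folded_k_minus_2: lambda=1.443 chi2=145.77 df=2 p=2.22e-32
diakinesis increase: 41 %
```

Reading: the observed wild-type configuration mix implies 31.53 chiasmata
per cell; the focus-count distribution rejects the Poisson null
overwhelmingly under both chi-square conventions (strong interference);
and the single-functional-allele mutant carries 41% more class I COs than
wild type.

## Command-line pipeline

```
cat > run.yaml <<EOF
seed: 7
n_cells: 30
genotypes: [AACC_wt, aaCc]
output_dir: out
EOF
meioscope simulate --config run.yaml
meioscope analyze --data out/bivalents.csv --config run.yaml
```

`out/report.txt` then contains, per genotype: foci/cell and minimum
chiasmata (mean ± SD), class II and total CO means, Poisson GOF verdicts
under both binning policies (flagged policy-sensitive if they disagree),
distribution homogeneity versus the reference genotype, spacing summaries
and Games–Howell comparisons. With the config above the wild-type-like
genotype rejects the Poisson null (p ≈ 6e-64, excel policy) while the
interference-free mutant-like genotype fits it (p ≈ 0.85), their spacing
means are 0.54 vs 0.24, and the simulated caveat of configuration-based
counting is visible: the mutant gains ~11 foci per cell while its minimum
chiasma score barely moves.

Everything is seed-deterministic: rerunning a config reproduces every
output byte-for-byte (`simulate` refuses to overwrite without `--force`).

Input/output schemas (`bivalents.csv`, `intensity.csv`, YAML presets,
JSON/CSV result twins) are documented in `meioscope/io.py`; the model and
all statistical conventions are described in `docs/methods.md`.

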