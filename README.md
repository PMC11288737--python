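# chiascan

Statistical toolkit for dissecting meiotic-sterility phenotypes from
cytology counts, phenotype ratios and bulked-segregant sequencing —
built around the soybean case of losing interference-sensitive (Class I)
crossovers, and usable for any organism where the same questions arise.

It answers four questions a meiosis geneticist asks of a sterile mutant:

1. **Is the residual crossover activity interference-free?**
   Per-meiocyte chiasma counts are summarised (mean, SD, dispersion
   index = variance/mean) and tested against a Poisson distribution with
   a one-sample Kolmogorov–Smirnov statistic on the integer support,
   D = max_k |F_n(k) − F_λ(k)|. Interference makes counts under-dispersed
   and rejects Poisson; a pure Class II residuum does not. The default
   p-value is a parametric bootstrap (B = 2000, λ re-estimated per
   resample), which is correctly calibrated on a discrete null with an
   estimated rate; the classical asymptotic p is available as a mode.
2. **Does sterility segregate as a single recessive locus?**
   Two-class chi-square against a Mendelian ratio (default 3:1, df = 1,
   α = 0.05 critical value 3.84).
3. **How infertile should random univalent segregation make the plant?**
   Each achiasmate pair segregates balanced with probability 1/2, so u
   univalent pairs leave a balanced-set chance of (1/2)^u — with u taken
   either as a plug-in mean (n_pairs − mean bivalents) or as the exact
   per-cell expectation E[2^−u] (≥ the plug-in value, by Jensen).
4. **Where is the causal locus?** A QTL-seq-style scan of a sterile-bulk
   VCF: per-variant SNP index ad_alt/(ad_ref+ad_alt), 200-kb windows
   stepped by 50 kb, candidate regions where the window mean exceeds 0.9,
   written as BED.

A forward meiosis simulator (obligate + under-dispersed Class I counts,
Poisson Class II, coin-flip univalent segregation) and synthetic-data
generators (cytology tables, F2 counts, bulk VCFs with a planted locus
linked through Haldane's map function) make every stage testable offline;
the simulator is also the Monte-Carlo oracle for the (1/2)^u algebra.
See `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate 158 meiocytes in the Class-I-null regime (residual crossovers
Poisson with mean 8.41), then test the counts:

```sh
$ chiascan simulate-meiosis --preset mlh1_mutant --n-cells 158 --seed 7 --out cyt.csv
mean_chiasmata  8.3608
sd      2.8199
mean_bivalents  6.8924

$ chiascan chiasma-test cyt.csv --seed 1
n_cells 158
mean_chiasmata  8.3608
sd      2.8199
dispersion_index        0.9511
ks_D    0.040123
p_value 0.4063
method  bootstrap
reject_poisson_at_0.01  False
```

The dispersion index sits at ≈ 0.95 (Poisson-like; the wild-type preset
gives ≈ 0.05) and the bootstrap KS test does not reject the Poisson fit —
the signature of interference-insensitive residual crossovers. The same
dataset's Poisson verdict flips to rejection on wild-type-like counts.

Segregation and fertility arithmetic:

```sh
$ chiascan segregation-test --counts 142,39
chi2    1.15
df      1
critical_value  3.84
p_value 0.2833
expected        135.75,45.25
verdict consistent

$ chiascan fertility-predict --mean-bivalents 6.4
u_effective     13.6000
p_balanced      8.053637e-05
p_balanced_percent      0.008
```

142 fertile : 39 sterile is consistent with 3:1 (single recessive locus),
and a mean of 6.4 bivalents out of 20 pairs leaves 13.6 univalent pairs —
a balanced-gamete chance of 0.008%, i.e. near-complete sterility.

BSA end to end on synthetic data:

```sh
chiascan simulate-bsa --seed 7 --out bulk.vcf
chiascan bsa-scan bulk.vcf --windows-out windows.tsv --regions-out regions.bed
```

prints the candidate regions (chrom, start, end, peak index); the region
containing the planted locus at Chr04:20,000,000 carries a peak index
near 1.0, while windows on the unlinked chromosome hover around 0.5.

The library mirrors the CLI: `chiascan.ks_goodness_of_fit`,
`chiascan.chi_square_ratio_test`, `chiascan.expected_balanced_from_bivalents`,
`chiascan.window_scan` / `call_candidate_regions`, `chiascan.simulate_dataset`
and the generators in `chiascan.synthetic`.

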