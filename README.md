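# adnauth — authenticity testing for low-coverage ancient-DNA read sets

Ancient DNA carries a chemical signature of age: cytosine deamination in
single-stranded overhangs produces an excess of C→T substitutions at the 5′
end of sequenced fragments, highest at the first base and decaying roughly
exponentially towards the read centre. Modern contamination lacks this
pattern. Standard damage-profile inspection needs many reads; studies that
rest on a **handful of taxonomically assigned reads** (e.g. metagenomic /
sedimentary ancient DNA) cannot authenticate them by eye.

`adnauth` implements a resampling test that works at that scale. For any set
of aligned reads it:

1. computes the 5′ C→T frequency profile *y₁…y₂₀* (position 1 = first
   aligned 5′ base, reverse-strand reads complemented);
2. fits the decay model **y = N·exp(−rate·x)** by nonlinear least squares
   and summarises the profile by a *goodness-of-fit p-value* — the one-sided
   t-test p for H₁: rate > 0 (t = rate/SE(rate), df = points − 2). Small p
   ⇒ significant decay ⇒ ancient-like;
3. locates that p-value within an empirical distribution obtained by
   subsampling a *bona fide* ancient (or modern) library with replacement
   (default 10,000 subsamples, size matched to the test set), yielding an
   **empirical p-value**:
   - *ancient mode*: fraction of subsample p-values ≥ the test value
     (H₀: the test set is at least as damaged as the reference aDNA);
   - *modern mode*: fraction ≤ the test value (H₀: the test set matches
     undamaged modern DNA). Both counts include ties.

The package also ships a read simulator with a parameterised deamination
model (per-position C→T probability `a·exp(−r·i) + baseline` plus uniform
sequencing error), which provides ground truth for every statistical claim
in the test suite, and the filtering stack used for real alignments
(MAPQ ≥ 30, length ≥ 30, coordinate duplicate removal, trinucleotide
entropy > 50).

Intended users: ancient-DNA and sedaDNA practitioners who need *positive*
evidence of authenticity for small read sets aligned in SAM/BAM.

## Worked example

Simulate a damaged (ancient-like) and an undamaged (modern-like) library,
profile the damaged one, and test the undamaged reads against it:

```sh
adnauth simulate --ref-length 200000 --n-reads 20000 --seed 7 \
    --fasta-out ref.fa --sam-out ancient.sam
adnauth simulate --ref-length 200000 --n-reads 20000 --seed 8 \
    --damage-amplitude 0 --fasta-out ref2.fa --sam-out modern.sam

adnauth profile ancient.sam --out ancient_profile.tsv
adnauth fit ancient_profile.tsv
```

```
{
  "rate": 0.2691505680133442,
  "rate_se": 0.010372671433094014,
  "t_value": 25.94804720745508,
  "df": 18,
  "gof_p": 5.162287728724603e-16,
  "n_points": 20,
  "converged": true,
  "amplitude_N": 0.1587056593460179
}
```

The fitted decay (≈15.9% amplitude, rate ≈ 0.27) recovers the simulated
damage (a = 0.15, r = 0.3, baseline 0.005), and gof_p ≈ 5·10⁻¹⁶ says the
decay is highly significant — this library looks ancient.

```sh
adnauth test modern.sam ancient.sam --mode ancient -n 152 -M 10000 --seed 7
```

```
authenticity test (ancient mode): gof p = 0.3074, empirical p = 0.0072 (72/10000)
```

The undamaged reads have a non-significant decay (gof p = 0.31); only 72 of
10,000 size-152 subsamples of the ancient reference fit as poorly, so the
hypothesis that these reads are as ancient as the reference is rejected
(empirical p = 0.0072).

Other subcommands: `adnauth dist` (write a subsample p-value distribution),
`adnauth power` (empirical p-value vs number of reads tested, long-format
TSV). Every command logs its resolved parameters and seed to stderr, so any
output can be regenerated.

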