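# Methods

## The damage model and the statistic

Postmortem cytosine deamination converts C to U in the single-stranded
overhangs of ancient DNA fragments; after amplification and sequencing this
is read as T. Because overhang probability decays from the fragment end, the
per-position C→T mismatch frequency at the 5′ end of aligned reads decays
approximately exponentially, while modern DNA shows a flat, near-zero
profile. `adnauth` scores that contrast.

For a read set, position i ∈ {1..20} (1 = first *aligned* 5′ base; soft
clips skipped) accumulates `ref_c_counts[i]` = reads whose reference base at
i is C in read orientation, and `ct_counts[i]` = the subset reading T there.
Reverse-strand reads are walked from the right-hand alignment edge with both
bases complemented, so the minus-strand mirror image (reference G, read A)
counts identically. Non-C→T mismatches under a reference C enter only the
denominator; columns with N on either side, insertions and deletions are not
counted. Reads shorter than i simply contribute nothing at i.

The profile y_i = ct/ref_c is fitted with y = N·exp(−rate·x) by
Levenberg–Marquardt least squares (scipy `curve_fit`; start values
N₀ = max y, rate₀ = 0.5, restarts at rate₀ ∈ {0.01, 0.1, 1.0}). The
goodness-of-fit p-value is the upper tail of Student's t at
t = rate/SE(rate) with df = n_points − 2, SE from the Jacobian-based
covariance scaled by residual variance. One-sidedness matters: decay
(rate > 0) gives small p, growth gives p > 0.5, so small p is specific to
the ancient signature.

Degenerate cases are resolved conservatively toward modernity: a fit that
fails all restarts, or whose rate SE is not a positive finite number,
reports p = 1 with `converged = false`; a numerically perfect fit
(residual sum ≤ 10⁻¹⁶ relative) reports p = 0 if rate > 0 and 1 otherwise,
since SE = 0 makes t undefined. Positions with an empty denominator are
dropped from the sum and from df rather than imputed.

Using x = 1..20 (not 0..19) is a declared convention; shifting x rescales
the fitted amplitude by exp(rate) but leaves the rate, its t-statistic and
the p-value unchanged, so the test is insensitive to the choice.

## The empirical test

A reference library of known provenance is subsampled with replacement
M times (default 10,000) at the size of the test set; each subsample yields
a goodness-of-fit p-value; the test set's own p-value is located in that
distribution. Ancient mode counts subsample values ≥ the test value, modern
mode counts ≤; both inclusive, divided by M. The resolution is 1/M; a zero
count is reported as 0 annotated "< 1/M", with no pseudo-count. Failed fits
inside the distribution contribute p = 1 and are counted in
`n_failed_fits` so their influence can be audited.

All resampling uses one named numpy generator per run, seeded explicitly;
identical seeds give bit-identical distributions and results.

`power_curve` traces the empirical p-value against the number of reads
tested. For each size it builds **one** size-matched reference distribution
and scores all repeats against it, rather than rebuilding the distribution
per repeat: the distribution is independent of the test draws either way,
and this keeps 1000-repeat curves to seconds. Default problem sizes
(50,000-read libraries, M = 1000 per size, 200 repeats) keep the full
power/specificity analysis under a minute on one CPU.

## Filtering stack

`load_alignments` keeps primary mapped records with MAPQ ≥ 30 and aligned
length ≥ 30 (both inclusive), reconstructing reference bases from the MD tag
or a reference FASTA. Duplicates are removed on the
(reference, start, end, strand) coordinate key, keeping the highest MAPQ
(ties: smallest read id) — a deliberate simplification of consensus-based
duplicate collapsing, which does not materially change a substitution
frequency. Low-complexity reads are removed when their entropy score is
≤ 50: the score is 100·H/log₂(min(K, 64)) with H the Shannon entropy of the
overlapping-3-mer distribution and K the number of counted 3-mers
(N-containing 3-mers ignored). This trinucleotide dialect is a declared
convention for the PRINSEQ-style filter, whose exact formula variant is not
pinned down by its users; the boundary ("≤ removed") follows common usage.
Filters are idempotent and log removals so that retained + removed always
equals the input count.

## The simulator

`simulate` draws reads uniformly from an i.i.d. random reference
(P(G or C) = gc_content), with truncated-normal lengths (mean 60, sd 15,
hard minimum 30 bp to respect the length filter), uniform strands, MAPQ 60
and full-match CIGARs with correct MD/NM tags. In read orientation each
reference C at position i becomes T with probability a·exp(−r·i) + baseline;
independently every base is substituted uniformly with probability
`seq_error` (default 0.001, Q30-grade). Canonical regimes: ancient-like
a = 0.15, r = 0.3, baseline = 0.005 (a strongly damaged, well-preserved
sample, ~12% C→T at base 1); modern-like a = 0 (flat baseline). The
baseline absorbs residual library artefacts and keeps flat profiles off the
boundary of the parameter space.

What the simulator deliberately omits: 3′ G→A damage (library-protocol
dependent; the test uses the 5′ end only), fragment-end biophysics
(overhang-length/nick models), indels, base-quality strings, mapping error
and reference misassignment. Passing tests therefore demonstrate the
statistical machinery under a correctly specified damage decay with
realistic sampling noise — not robustness to alignment artefacts or
taxonomic misassignment in real data.

## Numerical and design notes

* **Baseline misspecification.** The fitted single exponential has no
  constant term, so a nonzero baseline biases the fitted rate downward
  (about −15% at a = 0.15, r = 0.3, baseline = 0.005, already without
  noise). Parameter-recovery checks therefore use baseline = 0, where the
  model is correctly specified (mean fitted rate within 10% of truth at
  50,000 reads); at baseline 0.005 amplitude and rate are still recovered
  within 20%. The *test statistic* is unaffected by this bias: a biased but
  strongly positive rate still gives a tiny p-value, and flat profiles
  stay calibrated (type-I rate 5% ± 2% in 2,000 flat replicates).
* **Self-consistency is exactly nominal.** When a library is tested against
  its own subsample distribution, exchangeability makes the rejection
  probability exactly the nominal 5%, so specificity checks over 100
  repeats sit at their binomial boundary by construction.
* **No base-quality threshold** is applied in counting (flag available but
  off by default); CpG context is not treated specially.
* Base cases: `max_pos` < 2 is a parameter error; a profile with fewer than
  two defined points cannot be fitted; an empty filtered set is returned
  with a warning, not an error.

## Limitations

The empirical p-value inherits the reference library's damage level: a test
set can be "rejected as ancient" against a heavily damaged reference yet
compatible with a mildly damaged one, so reference choice is part of the
hypothesis being tested, not a nuisance parameter. With very few reads the
test loses power gradually (undamaged sets of ≤300 reads are often not
rejected); raw empirical p-values are reported without multiple-testing
correction across references.
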