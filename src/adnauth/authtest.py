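"""The authenticity test: empirical p-values from resampled reference libraries.

A test read set is summarised by one number, the goodness-of-fit p-value of
its 5' C->T decay. To decide whether that number is what a genuinely ancient
(or genuinely modern) library of the same size would produce, a reference
library is subsampled with replacement many times (default 10,000), the
goodness-of-fit p-value computed for each subsample, and the test value is
located within this empirical distribution.

Two one-sided modes correspond to two null hypotheses:

* ``ancient`` — H0: the test set carries a damage signal at least as
  pronounced as the reference aDNA library. The empirical p-value is the
  fraction of subsample p-values greater than or equal to the test value;
  rejecting it says the test set is *less* damaged than real aDNA.
* ``modern`` — H0: the test set matches the absence of damage seen in modern
  DNA. The empirical p-value is the fraction of subsample p-values smaller
  than or equal to the test value.

Both counts are inclusive of ties. The resolution is 1/M; a count of zero is
reported as 0 with a "< 1/M" annotation rather than with a pseudo-count.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import damage as _damage
from .damage import DEFAULT_MAX_POS, damage_matrices, profile_from_matrices
from .expfit import fit_exponential
from .sam_io import AlignmentSet

MODE_ANCIENT = "ancient"
MODE_MODERN = "modern"
DEFAULT_N_SUBSAMPLES = 10_000


@dataclass
class PValueDistribution:
    """Empirical distribution of goodness-of-fit p-values from subsampling."""

    values: np.ndarray
    subsample_size: int
    n_subsamples: int
    seed: int
    source_label: str = ""
    n_failed_fits: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.n_subsamples:
            raise ValueError("values length differs from n_subsamples")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("p-values must lie in [0, 1]")


@dataclass
class AuthTestResult:
    mode: str
    p_test: float
    empirical_p: float
    count_extreme: int
    n_subsamples: int
    subsample_size: int = 0
    seed: int | None = None
    test_label: str = ""
    reference_label: str = ""

    def __str__(self) -> str:
        p = self.empirical_p
        shown = f"< {1.0 / self.n_subsamples:g}" if p == 0 else f"{p:g}"
        return (f"authenticity test ({self.mode} mode): gof p = "
                f"{self.p_test:.4g}, empirical p = {shown} "
                f"({self.count_extreme}/{self.n_subsamples})")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _subsample_pvalues(refc: np.ndarray, ct: np.ndarray, n: int, m: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Goodness-of-fit p-values of ``m`` with-replacement subsamples of size
    ``n`` drawn from the read rows of the damage matrices."""
    n_reads = refc.shape[0]
    pvals = np.empty(m)
    failed = 0
    for j in range(m):
        idx = rng.integers(0, n_reads, size=n)
        prof = profile_from_matrices(
            refc[idx].sum(axis=0, dtype=np.int64),
            ct[idx].sum(axis=0, dtype=np.int64), n_reads=n)
        fit = fit_exponential(prof)
        pvals[j] = fit.gof_p
        failed += not fit.converged
    return pvals, failed


def build_distribution(reference: AlignmentSet, n: int,
                       m: int = DEFAULT_N_SUBSAMPLES, seed: int = 0,
                       max_pos: int = DEFAULT_MAX_POS) -> PValueDistribution:
    """Subsample ``reference`` M times (size n, with replacement) and collect
    the goodness-of-fit p-value of each subsample's damage profile."""
    if len(reference.reads) == 0:
        raise ValueError("reference alignment set is empty")
    if n < 1:
        raise ValueError("subsample size must be at least 1")
    if m < 1:
        raise ValueError("number of subsamples must be at least 1")
    rng = np.random.default_rng(seed)
    refc, ct = damage_matrices(reference, max_pos)
    values, failed = _subsample_pvalues(refc, ct, n, m, rng)
    return PValueDistribution(values=values, subsample_size=n,
                              n_subsamples=m, seed=seed,
                              source_label=reference.source_label,
                              n_failed_fits=failed)


def empirical_pvalue(p_test: float, dist: PValueDistribution,
                     mode: str) -> AuthTestResult:
    """Locate ``p_test`` in the empirical distribution (inclusive counts)."""
    if not 0 <= p_test <= 1:
        raise ValueError("p_test must lie in [0, 1]")
    if mode == MODE_ANCIENT:
        count = int(np.sum(dist.values >= p_test))
    elif mode == MODE_MODERN:
        count = int(np.sum(dist.values <= p_test))
    else:
        raise ValueError(f"mode must be '{MODE_ANCIENT}' or '{MODE_MODERN}',"
                         f" got {mode!r}")
    return AuthTestResult(mode=mode, p_test=float(p_test),
                          empirical_p=count / dist.n_subsamples,
                          count_extreme=count,
                          n_subsamples=dist.n_subsamples,
                          subsample_size=dist.subsample_size,
                          seed=dist.seed,
                          reference_label=dist.source_label)


def run_test(test_set: AlignmentSet, reference: AlignmentSet, mode: str,
             n: int | None = None, m: int = DEFAULT_N_SUBSAMPLES,
             seed: int = 0,
             max_pos: int = DEFAULT_MAX_POS) -> AuthTestResult:
    """Full test: gof p-value of the whole test set against a distribution
    of reference subsamples whose size matches the test set (or ``n``)."""
    if len(test_set.reads) == 0 or len(reference.reads) == 0:
        raise ValueError("test and reference sets must be non-empty")
    if n is None:
        n = len(test_set.reads)
    dist = build_distribution(reference, n=n, m=m, seed=seed, max_pos=max_pos)
    p_test = fit_exponential(
        _damage.substitution_profile(test_set, max_pos)).gof_p
    result = empirical_pvalue(p_test, dist, mode)
    result.test_label = test_set.source_label
    return result


def power_curve(test_library: AlignmentSet, reference: AlignmentSet,
                sizes: list[int], repeats: int, mode: str = MODE_ANCIENT,
                seed: int = 0, m: int = 1000,
                max_pos: int = DEFAULT_MAX_POS) -> pd.DataFrame:
    """Empirical p-value as a function of the number of reads tested.

    For each size s a single size-matched reference distribution is built
    (M = ``m`` subsamples); then ``repeats`` times, s reads are drawn with
    replacement from ``test_library``, their profile fitted, and the
    empirical p-value recorded. Long-format output: size, repeat,
    empirical_p.
    """
    if not sizes:
        raise ValueError("sizes must be non-empty")
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    rng = np.random.default_rng(seed)
    t_refc, t_ct = damage_matrices(test_library, max_pos)
    n_test = t_refc.shape[0]
    rows = []
    for size in sizes:
        dist = build_distribution(reference, n=size, m=m,
                                  seed=int(rng.integers(2**31)),
                                  max_pos=max_pos)
        for rep in range(repeats):
            idx = rng.integers(0, n_test, size=size)
            prof = profile_from_matrices(
                t_refc[idx].sum(axis=0, dtype=np.int64),
                t_ct[idx].sum(axis=0, dtype=np.int64), n_reads=size)
            p_test = fit_exponential(prof).gof_p
            res = empirical_pvalue(p_test, dist, mode)
            rows.append((size, rep, res.empirical_p))
    return pd.DataFrame(rows, columns=["size", "repeat", "empirical_p"])


def summarize_power(curve: pd.DataFrame) -> pd.DataFrame:
    """Per-size mean/median/quartiles of the empirical p-value."""
    g = curve.groupby("size")["empirical_p"]
    out = g.agg(mean="mean", median="median",
                q25=lambda s: s.quantile(0.25),
                q75=lambda s: s.quantile(0.75))
    return out.reset_index()


def write_distribution(dist: PValueDistribution, path: str) -> None:
    """One p-value per line, preceded by a JSON header comment."""
    header = {"subsample_size": dist.subsample_size,
              "n_subsamples": dist.n_subsamples, "seed": dist.seed,
              "source": dist.source_label,
              "n_failed_fits": dist.n_failed_fits}
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("gof_p\n")
        for v in dist.values:
            fh.write(f"{v:.10g}\n")


def read_distribution(path: str) -> PValueDistribution:
    with open(path) as fh:
        header = json.loads(fh.readline().lstrip("# "))
        fh.readline()  # column name
        values = np.array([float(line) for line in fh if line.strip()])
    return PValueDistribution(values=values,
                              subsample_size=header["subsample_size"],
                              n_subsamples=header["n_subsamples"],
                              seed=header["seed"],
                              source_label=header.get("source", ""),
                              n_failed_fits=header.get("n_failed_fits", 0))
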