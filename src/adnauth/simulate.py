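"""Synthetic references and aligned reads with a tunable 5' deamination model.

Reads are drawn uniformly from a random reference; in read orientation each
reference C at position i (1-based from the 5' end) is converted to T with
probability

    a * exp(-r * i) + baseline

mimicking the exponentially decaying excess of C->T substitutions left by
cytosine deamination in single-stranded overhangs. A modern-like library is
the a = 0 special case (flat, baseline-only profile). On top of the damage
channel every base is substituted uniformly at random with probability
``seq_error``, the simplest position-independent sequencing-error confounder.

Ground truth (the full configuration) is echoed in the SAM header as a @CO
line and optionally in a sidecar JSON, so every downstream estimate can be
checked against the generating parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .sam_io import FORWARD, REVERSE, AlignedRead, AlignmentSet, write_alignments

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3
MIN_READ_LENGTH = 30


@dataclass
class SimConfig:
    """Generation parameters; defaults give a strongly damaged ancient-like
    library comparable to a well-preserved permafrost-grade sample (about
    15% C->T at the first base, decaying with rate 0.3 per position)."""

    ref_length: int = 1_000_000
    gc_content: float = 0.5
    n_reads: int = 50_000
    read_length_mean: float = 60.0
    read_length_sd: float = 15.0
    damage_amplitude: float = 0.15
    damage_rate: float = 0.3
    baseline: float = 0.005
    seq_error: float = 0.001
    strand_fraction_forward: float = 0.5
    seed: int = 0
    reference_name: str = "ref1"

    def __post_init__(self) -> None:
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must lie in [0, 1]")
        if self.n_reads < 1:
            raise ValueError("n_reads must be at least 1")
        if self.ref_length < MIN_READ_LENGTH:
            raise ValueError("reference shorter than the minimum read length")
        if not 0 <= self.damage_amplitude < 1:
            raise ValueError("damage_amplitude must lie in [0, 1)")
        if self.damage_rate < 0:
            raise ValueError("damage_rate must be non-negative")
        if not 0 <= self.baseline <= 0.05:
            raise ValueError("baseline must lie in [0, 0.05]")
        if not 0 <= self.seq_error <= 0.02:
            raise ValueError("seq_error must lie in [0, 0.02]")
        if not 0 <= self.strand_fraction_forward <= 1:
            raise ValueError("strand_fraction_forward must lie in [0, 1]")
        peak = (self.damage_amplitude * np.exp(-self.damage_rate)
                + self.baseline + self.seq_error)
        if peak > 1:
            raise ValueError("total substitution probability at position 1 "
                             "exceeds 1")


def make_reference(config: SimConfig, fasta_path: str | None = None) -> str:
    """I.i.d. random reference with P(G or C) = gc_content."""
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=config.ref_length, p=p).astype(np.uint8)
    seq = _BASES[codes].tobytes().decode()
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            fh.write(f">{config.reference_name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    return seq


def _to_strings(codes: np.ndarray, lengths: np.ndarray) -> list[str]:
    chars = _BASES[codes]
    return [chars[i, :lengths[i]].tobytes().decode()
            for i in range(codes.shape[0])]


def simulate_reads(reference: str, config: SimConfig,
                   sam_path: str | None = None,
                   source_label: str = "simulated") -> AlignmentSet:
    """Draw ungapped aligned reads from ``reference`` under the damage model.

    Returns an AlignmentSet; when ``sam_path`` is given, the same reads are
    written as SAM records (MAPQ 60, full-length match CIGAR, MD/NM tags)
    with the configuration in a @CO header line.
    """
    rng = np.random.default_rng(config.seed + 1)  # reference used seed itself
    n = config.n_reads
    ref_len = len(reference)

    lengths = np.rint(rng.normal(config.read_length_mean,
                                 config.read_length_sd, size=n)).astype(int)
    lengths = np.clip(lengths, MIN_READ_LENGTH, ref_len)
    starts = rng.integers(0, ref_len - lengths + 1)
    is_rev = rng.random(n) >= config.strand_fraction_forward

    lmax = int(lengths.max())
    ref_codes = np.frombuffer(reference.encode(), dtype=np.uint8)
    code = np.full(256, 255, dtype=np.uint8)
    code[_BASES] = np.arange(4)
    ref_codes = code[ref_codes]

    offs = np.arange(lmax)
    valid = offs < lengths[:, None]
    idx = np.minimum(starts[:, None] + offs, ref_len - 1)
    refmat = ref_codes[idx]  # reference orientation, padded

    # read-orientation reference bases: reverse+complement the minus rows
    rev_idx = np.clip(lengths[:, None] - 1 - offs, 0, None)
    revcomp = 3 - np.take_along_axis(refmat, rev_idx, axis=1)
    oriented_ref = np.where(is_rev[:, None], revcomp, refmat)

    # deamination channel: C -> T with exponentially decaying probability
    p_ct = (config.damage_amplitude * np.exp(-config.damage_rate * (offs + 1))
            + config.baseline)
    hit = (oriented_ref == _C) & (rng.random((n, lmax)) < p_ct) & valid
    read = np.where(hit, _T, oriented_ref)

    # uniform sequencing error on every base
    err = (rng.random((n, lmax)) < config.seq_error) & valid
    shift = rng.integers(1, 4, size=(n, lmax), dtype=np.uint8)
    read = np.where(err, (read + shift) % 4, read).astype(np.uint8)

    # store reads in reference orientation, as SAM does
    stored = np.where(is_rev[:, None],
                      3 - np.take_along_axis(read, rev_idx, axis=1), read)

    seqs = _to_strings(stored, lengths)
    refs = _to_strings(refmat, lengths)
    reads = [
        AlignedRead(
            read_id=f"sim_{i}",
            query_sequence=seqs[i],
            strand=REVERSE if is_rev[i] else FORWARD,
            reference_name=config.reference_name,
            reference_start=int(starts[i]),
            reference_end=int(starts[i] + lengths[i]),
            mapq=60,
            query_aligned=seqs[i],
            ref_aligned=refs[i],
        )
        for i in range(n)
    ]
    aset = AlignmentSet(reads=reads, source_label=source_label)
    if sam_path is not None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": config.reference_name, "LN": ref_len}],
            "CO": ["ground_truth " + json.dumps(asdict(config))],
        }
        write_alignments(aset, sam_path, header)
    return aset


def simulate_library(config: SimConfig, sam_path: str | None = None,
                     source_label: str = "simulated") -> AlignmentSet:
    """Reference + reads in one call (the reference is not kept)."""
    reference = make_reference(config)
    return simulate_reads(reference, config, sam_path=sam_path,
                          source_label=source_label)


def ancient_config(seed: int = 0, **overrides) -> SimConfig:
    """Canonical ancient-like regime: a = 0.15, rate = 0.3, baseline 0.005."""
    return SimConfig(seed=seed, **overrides)


def modern_config(seed: int = 1, **overrides) -> SimConfig:
    """Canonical modern-like regime: no deamination, baseline only."""
    overrides.setdefault("damage_amplitude", 0.0)
    return SimConfig(seed=seed, **overrides)


def simulate_library_pair(ancient: SimConfig | None = None,
                          modern: SimConfig | None = None,
                          ancient_sam: str | None = None,
                          modern_sam: str | None = None,
                          seed: int = 0) -> tuple[AlignmentSet, AlignmentSet]:
    """The canonical ancient-like / modern-like fixture pair.

    The two libraries always use distinct seeds (modern = ancient seed + 1
    unless overridden)."""
    if ancient is None:
        ancient = ancient_config(seed=seed)
    if modern is None:
        modern = modern_config(seed=ancient.seed + 1)
    aset = simulate_library(ancient, sam_path=ancient_sam,
                            source_label="ancient-like")
    mset = simulate_library(modern, sam_path=modern_sam,
                            source_label="modern-like")
    return aset, mset


def write_ground_truth(config: SimConfig, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=2)
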