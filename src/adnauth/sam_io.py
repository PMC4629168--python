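"""Reading, filtering and deduplicating aligned reads.

Alignments come from SAM/BAM files. For every retained read the reference
base at each aligned column is reconstructed, either from the MD tag or from
a user-supplied reference FASTA, so that downstream substitution counting
never needs the original reference again.

The filter stack mirrors standard ancient-DNA practice: mapping quality,
aligned length, coordinate-based duplicate removal and a trinucleotide
entropy filter against low-complexity reads.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import pysam

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")

FORWARD = "+"
REVERSE = "-"


class InputError(ValueError):
    """Raised for unreadable or malformed input files."""


class RecordError(ValueError):
    """Raised when a single alignment record cannot be interpreted."""


@dataclass(frozen=True)
class AlignedRead:
    """One aligned read with its reconstructed reference bases.

    ``query_aligned`` and ``ref_aligned`` are equal-length strings over
    ``ACGTN-`` giving, column by column, the query base and the reference
    base of the alignment ('-' marks a gap on that side).  Both are stored
    in reference orientation, exactly as SAM stores the query sequence;
    ``strand`` records whether the read's 5' end is on the left (forward)
    or the right (reverse) of the alignment.
    """

    read_id: str
    query_sequence: str
    strand: str  # FORWARD or REVERSE
    reference_name: str
    reference_start: int  # 0-based
    reference_end: int  # half-open
    mapq: int
    query_aligned: str
    ref_aligned: str
    query_offset: int = 0  # index in query_sequence of first aligned base

    def __post_init__(self) -> None:
        if len(self.query_aligned) != len(self.ref_aligned):
            raise ValueError("query_aligned and ref_aligned differ in length")
        if len(self.query_sequence) < 1:
            raise ValueError("empty query sequence")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def aligned_pairs(self) -> list[tuple[int | None, str | None]]:
        """(query_position, reference_base) per column; None marks a gap."""
        pairs: list[tuple[int | None, str | None]] = []
        qpos = self.query_offset
        for qc, rc in zip(self.query_aligned, self.ref_aligned):
            if qc == "-":
                pairs.append((None, rc))
            else:
                pairs.append((qpos, None if rc == "-" else rc))
                qpos += 1
        return pairs

    def oriented_columns(self) -> tuple[str, str]:
        """Query and reference bases of match columns, 5'-to-3' in read
        orientation (reverse-strand reads are reverse-complemented)."""
        q = []
        r = []
        for qc, rc in zip(self.query_aligned, self.ref_aligned):
            if qc != "-" and rc != "-":
                q.append(qc)
                r.append(rc)
        qs, rs = "".join(q), "".join(r)
        if self.strand == REVERSE:
            qs = qs.translate(_COMPLEMENT)[::-1]
            rs = rs.translate(_COMPLEMENT)[::-1]
        return qs, rs


@dataclass
class AlignmentSet:
    """A filtered collection of aligned reads plus a log of removals."""

    reads: list[AlignedRead]
    source_label: str = ""
    filter_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def with_reads(self, reads: list[AlignedRead], filter_name: str,
                   removed: int) -> "AlignmentSet":
        log = dict(self.filter_log)
        log[filter_name] = log.get(filter_name, 0) + removed
        return AlignmentSet(reads=reads, source_label=self.source_label,
                            filter_log=log)


def _columns_from_record(rec: pysam.AlignedSegment,
                         fasta: pysam.FastaFile | None) -> tuple[str, str]:
    """Reconstruct per-column query/reference bases for one record."""
    seq = rec.query_sequence
    try:
        pairs = rec.get_aligned_pairs(with_seq=True)
        have_md = True
    except ValueError:
        have_md = False
    if not have_md:
        if fasta is None:
            raise RecordError(
                f"read {rec.query_name!r} has no MD tag and no reference "
                "FASTA was supplied")
        ref = fasta.fetch(rec.reference_name, rec.reference_start,
                          rec.reference_end).upper()
        pairs = [
            (qpos, rpos,
             ref[rpos - rec.reference_start] if rpos is not None else None)
            for qpos, rpos in rec.get_aligned_pairs()
        ]
    qcols = []
    rcols = []
    for qpos, rpos, refb in pairs:
        if qpos is None and rpos is None:  # pragma: no cover - padded
            continue
        qcols.append(seq[qpos] if qpos is not None else "-")
        rcols.append(refb.upper() if refb is not None else "-")
    return "".join(qcols), "".join(rcols)


def load_alignments(path: str, reference: str | None = None,
                    min_mapq: int = 30, min_length: int = 30,
                    source_label: str | None = None) -> AlignmentSet:
    """Load a SAM/BAM file, keeping primary mapped reads that pass the
    mapping-quality and aligned-length thresholds (both inclusive).

    Reference bases are taken from the MD tag when present, otherwise from
    ``reference`` (a FASTA path). Unmapped, secondary and supplementary
    records are always dropped.
    """
    try:
        af = pysam.AlignmentFile(path, check_sq=False)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read alignments from {path!r}: {exc}") from exc
    fasta = pysam.FastaFile(reference) if reference is not None else None
    reads: list[AlignedRead] = []
    log = Counter()
    total = 0
    with af:
        for rec in af:
            total += 1
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                log["unmapped_or_nonprimary"] += 1
                continue
            if rec.mapping_quality < min_mapq:
                log["mapq"] += 1
                continue
            if rec.query_alignment_length < min_length:
                log["length"] += 1
                continue
            if rec.query_sequence is None:
                raise RecordError(f"read {rec.query_name!r} has no sequence")
            qcols, rcols = _columns_from_record(rec, fasta)
            reads.append(AlignedRead(
                read_id=rec.query_name,
                query_sequence=rec.query_sequence,
                strand=REVERSE if rec.is_reverse else FORWARD,
                reference_name=rec.reference_name,
                reference_start=rec.reference_start,
                reference_end=rec.reference_end,
                mapq=rec.mapping_quality,
                query_aligned=qcols,
                ref_aligned=rcols,
                query_offset=rec.query_alignment_start,
            ))
    if fasta is not None:
        fasta.close()
    if not reads:
        warnings.warn(f"no reads retained from {path!r}", stacklevel=2)
    label = source_label if source_label is not None else path
    return AlignmentSet(reads=reads, source_label=label,
                        filter_log=dict(log))


def sequence_entropy(seq: str) -> float:
    """Low-complexity score in [0, 100] from overlapping trinucleotides.

    Shannon entropy (base 2) of the 3-mer frequency distribution, normalised
    by log2(min(K, 64)) where K is the number of counted 3-mers, and scaled
    by 100. 3-mers containing N are ignored. A homopolymer scores 0.
    """
    if len(seq) < 3:
        raise ValueError("entropy is undefined for sequences shorter than 3")
    counts = Counter(
        seq[i:i + 3] for i in range(len(seq) - 2) if "N" not in seq[i:i + 3]
    )
    k = sum(counts.values())
    if k == 0:
        raise ValueError("entropy is undefined: every 3-mer contains N")
    if len(counts) == 1:
        return 0.0
    h = -sum((c / k) * math.log2(c / k) for c in counts.values())
    return min(100.0, 100.0 * h / math.log2(min(k, 64)))


def filter_entropy(aset: AlignmentSet, threshold: float = 50.0) -> AlignmentSet:
    """Drop reads whose sequence entropy is <= threshold (low complexity)."""
    if not 0 <= threshold <= 100:
        raise ValueError("entropy threshold must lie in [0, 100]")
    kept = [r for r in aset.reads
            if sequence_entropy(r.query_sequence) > threshold]
    return aset.with_reads(kept, "entropy", len(aset.reads) - len(kept))


def deduplicate(aset: AlignmentSet) -> AlignmentSet:
    """Keep one read per (reference, start, end, strand) coordinate key.

    Within a key the highest-MAPQ read wins; MAPQ ties go to the
    lexicographically smallest read id, so the output is deterministic.
    """
    best: dict[tuple, AlignedRead] = {}
    order: list[tuple] = []
    for r in aset.reads:
        key = (r.reference_name, r.reference_start, r.reference_end, r.strand)
        cur = best.get(key)
        if cur is None:
            best[key] = r
            order.append(key)
        elif (r.mapq, ) > (cur.mapq, ) or (r.mapq == cur.mapq
                                           and r.read_id < cur.read_id):
            best[key] = r
    kept = [best[k] for k in order]
    return aset.with_reads(kept, "duplicate", len(aset.reads) - len(kept))


def write_filter_report(aset: AlignmentSet, path: str) -> None:
    """TSV report: filter_name, reads_removed, reads_remaining."""
    removed_total = sum(aset.filter_log.values())
    n_in = len(aset.reads) + removed_total
    lines = ["filter_name\treads_removed\treads_remaining"]
    remaining = n_in
    for name, removed in aset.filter_log.items():
        remaining -= removed
        lines.append(f"{name}\t{removed}\t{remaining}")
    lines.append(f"total\t{removed_total}\t{len(aset.reads)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_alignments(aset: AlignmentSet, path: str,
                     header: pysam.AlignmentHeader | dict) -> None:
    """Write the set back out as SAM/BAM (ungapped records only)."""
    mode = "wb" if str(path).endswith(".bam") else "w"
    if isinstance(header, dict):
        header = pysam.AlignmentHeader.from_dict(header)
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for r in aset.reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = r.read_id
            rec.query_sequence = r.query_sequence
            rec.flag = 16 if r.strand == REVERSE else 0
            rec.reference_id = out.header.get_tid(r.reference_name)
            rec.reference_start = r.reference_start
            rec.mapping_quality = r.mapq
            rec.cigarstring = f"{len(r.query_sequence)}M"
            rec.set_tag("MD", _md_tag(r.query_aligned, r.ref_aligned))
            rec.set_tag("NM", sum(q != rr for q, rr in
                                  zip(r.query_aligned, r.ref_aligned)))
            out.write(rec)


def _md_tag(query: str, ref: str) -> str:
    """MD string for an ungapped alignment."""
    out = []
    run = 0
    for q, r in zip(query, ref):
        if q == r:
            run += 1
        else:
            out.append(str(run))
            out.append(r)
            run = 0
    out.append(str(run))
    return "".join(out)
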