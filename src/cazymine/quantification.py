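"""Fragment counting and FPKM for unigenes, plus read quality metrics.

The aligner of the original workflow is replaced by an exact k-mer
pseudo-mapper: a read is assigned to a unigene iff every k-mer of the
read occurs in that unigene and in no other. FPKM then normalises the
fragment count by transcript length (kb) and library size (millions of
mapped fragments):

    FPKM = fragments / ((length / 1000) · (library / 1e6))

Single-end synthetic reads count one fragment each. By default the
library size is the total of assigned fragments in the sample (the
RSEM convention); it can be overridden with the total input fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

DEFAULT_K = 31


class FastqParseError(ValueError):
    """Malformed FASTQ, reported with the offending line number."""


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    length: int
    fragments: int
    fpkm: float


@dataclass
class MappingResult:
    """Per-gene fragment counts plus assignment accounting."""

    fragments: dict[str, int]
    n_reads: int
    n_assigned: int

    @property
    def mapping_rate(self) -> float:
        """Percent of reads assigned to exactly one unigene."""
        return 100.0 * self.n_assigned / self.n_reads if self.n_reads else 0.0

    @property
    def unassigned_rate(self) -> float:
        return 100.0 - self.mapping_rate if self.n_reads else 0.0


def _kmers(seq: str, k: int) -> Iterator[str]:
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def build_kmer_index(unigenes: Mapping[str, str], k: int) -> dict[str, str | None]:
    """k-mer → gene id, or None where the k-mer occurs in several genes."""
    if not unigenes:
        raise ValueError("cannot index an empty unigene set")
    index: dict[str, str | None] = {}
    for gid, seq in unigenes.items():
        for kmer in _kmers(seq.upper(), k):
            if kmer in index and index[kmer] != gid:
                index[kmer] = None
            else:
                index[kmer] = gid
    return index


def pseudo_map(
    reads: Iterable[str | tuple[str, str]],
    unigenes: Mapping[str, str],
    k: int = DEFAULT_K,
) -> MappingResult:
    """Assign reads to unigenes by unanimous unique k-mer vote.

    A read counts for gene g iff all of its k-mers occur in the index
    and every one of them is unique to g. Reads shorter than k, reads
    with any unindexed k-mer and reads whose k-mers disagree (or hit
    multi-gene k-mers) are unassigned.
    """
    index = build_kmer_index(unigenes, k)
    fragments = {gid: 0 for gid in unigenes}
    n_reads = 0
    n_assigned = 0
    for read in reads:
        seq = read[1] if isinstance(read, tuple) else read
        seq = seq.upper()
        n_reads += 1
        if len(seq) < k:
            continue
        target: str | None = None
        ok = True
        for kmer in _kmers(seq, k):
            gid = index.get(kmer)
            if gid is None or (target is not None and gid != target):
                ok = False
                break
            target = gid
        if ok and target is not None:
            fragments[target] += 1
            n_assigned += 1
    return MappingResult(fragments=fragments, n_reads=n_reads, n_assigned=n_assigned)


def compute_fpkm(
    counts: Mapping[str, int],
    lengths: Mapping[str, int],
    library: float | None = None,
) -> list[ExpressionRecord]:
    """FPKM per gene from fragment counts and transcript lengths.

    ``library`` defaults to the total of ``counts`` (per-sample mapped
    fragments). A zero or negative library is an error.
    """
    if library is None:
        library = float(sum(counts.values()))
    if library <= 0:
        raise ValueError("library size must be positive")
    records = []
    for gid in counts:
        length = lengths[gid]
        if length <= 0:
            raise ValueError(f"gene {gid}: non-positive length {length}")
        frags = int(counts[gid])
        fpkm = frags / ((length / 1000.0) * (library / 1e6))
        records.append(ExpressionRecord(gid, length, frags, fpkm))
    return records


def expression_table(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.length, r.fragments, r.fpkm) for r in records],
        columns=["gene_id", "length", "fragments", "fpkm"],
    )


# ---------------------------------------------------------------------------
# Read QC


@dataclass(frozen=True)
class ReadQC:
    q20_pct: float
    q30_pct: float
    gc_pct: float
    n_reads: int
    n_bases: int


def parse_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a 4-line FASTQ file.

    Raises :class:`FastqParseError` carrying the 1-based line number of
    the first malformed line.
    """
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise FastqParseError(f"line {lineno}: expected '@' header, got {header[:20]!r}")
            seq = fh.readline().rstrip("\n")
            lineno += 1
            if not seq:
                raise FastqParseError(f"line {lineno}: missing sequence")
            plus = fh.readline()
            lineno += 1
            if not plus.startswith("+"):
                raise FastqParseError(f"line {lineno}: expected '+' separator")
            qual = fh.readline().rstrip("\n")
            lineno += 1
            if len(qual) != len(seq):
                raise FastqParseError(
                    f"line {lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            yield header[1:].strip().split()[0], seq, qual


def read_qc(
    reads: Iterable[tuple[str, str]] | str | Path,
    phred_offset: int = 33,
) -> ReadQC:
    """Q20/Q30/GC percentages over a read set.

    ``reads`` is either a FASTQ path or an iterable of (sequence,
    quality-string) pairs with Phred+33 qualities. Q20/Q30 are the
    percentage of bases called at quality ≥ 20 / ≥ 30; GC is the
    percentage of G or C bases.
    """
    if isinstance(reads, (str, Path)):
        pairs: Iterable[tuple[str, str]] = ((s, q) for _, s, q in parse_fastq(reads))
    else:
        pairs = reads
    n_reads = n_bases = n_q20 = n_q30 = n_gc = 0
    for seq, qual in pairs:
        n_reads += 1
        n_bases += len(seq)
        for ch in qual:
            q = ord(ch) - phred_offset
            if q >= 20:
                n_q20 += 1
                if q >= 30:
                    n_q30 += 1
        n_gc += sum(1 for b in seq.upper() if b in "GC")
    if n_bases == 0:
        return ReadQC(0.0, 0.0, 0.0, 0, 0)
    return ReadQC(
        q20_pct=100.0 * n_q20 / n_bases,
        q30_pct=100.0 * n_q30 / n_bases,
        gc_pct=100.0 * n_gc / n_bases,
        n_reads=n_reads,
        n_bases=n_bases,
    )


__all__ = [
    "ExpressionRecord", "MappingResult", "ReadQC", "FastqParseError",
    "build_kmer_index", "pseudo_map", "compute_fpkm", "expression_table",
    "parse_fastq", "read_qc",
]
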