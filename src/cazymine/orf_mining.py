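"""Six-frame ORF prediction and catalytic-domain / CBM screening.

ORFs are maximal stop-free codon stretches of at least 600 nt, reported
in all six reading frames (the getorf-style stop-to-stop definition; a
Met-anchored mode is available behind ``require_start``). Coordinates
are 0-based half-open on the forward strand throughout; frames 1–3 are
the forward offsets 0–2 and frames 4–6 the reverse-strand offsets.

Translations use the standard (NCBI table 1) or bacterial (table 11)
genetic code according to the taxonomic origin of the unigene. The two
tables share stop codons and differ, for our purposes, in the set of
permitted start codons, which matters only in Met-anchored mode.

Domain screening supports two routes: an external HMMER ``domtblout``
table (hmmsearch against Pfam), or the built-in motif models below.
Either way a hit is retained when its bit score is at least the model's
Gathering Threshold (GA), and overlapping hits of the same model on the
same protein are merged into the higher-scoring one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 600

GENETIC_CODES = {"standard": 1, "bacterial": 11}

_STOPS = {"TAA", "TAG", "TGA"}  # identical in tables 1 and 11


class DomtbloutParseError(ValueError):
    """Malformed domtblout line, reported with its line number."""


@dataclass(frozen=True)
class OrfRecord:
    """A predicted open reading frame on a unigene.

    ``start``/``end`` are forward-strand nt coordinates (0-based,
    half-open) of the stop-free stretch itself (flanking stop codons
    excluded). Frames 4–6 mean the codons are read from the reverse
    complement.
    """

    unigene_id: str
    frame: int
    start: int
    end: int
    nt_seq: str
    protein: str
    genetic_code: str = "standard"

    @property
    def nt_length(self) -> int:
        return self.end - self.start

    @property
    def orf_id(self) -> str:
        return f"{self.unigene_id}|F{self.frame}|{self.start}-{self.end}"

    @property
    def is_reverse(self) -> bool:
        return self.frame >= 4


@dataclass(frozen=True)
class DomainHit:
    orf_id: str
    model: str
    pfam_id: str
    family: str
    kind: str  # "CD" or "CBM"
    aa_start: int  # 0-based half-open on the protein
    aa_end: int
    score: float
    ga_threshold: float


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _codon_map(genetic_code: str) -> tuple[dict[str, str], set[str]]:
    table_id = GENETIC_CODES[genetic_code]
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), set(table.start_codons)


def translate(nt_seq: str, genetic_code: str = "standard") -> str:
    """Translate an in-frame nucleotide sequence to protein.

    Codons containing N or any non-ACGT letter are emitted as 'X' with a
    warning; stop codons are emitted as '*'.
    """
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"sequence length {len(nt_seq)} not a multiple of 3")
    forward, _ = _codon_map(genetic_code)
    out = []
    seq = nt_seq.upper()
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in _STOPS:
            out.append("*")
        elif codon in forward:
            out.append(forward[codon])
        else:
            logger.warning("ambiguous codon %r at position %d -> X", codon, i)
            out.append("X")
    return "".join(out)


def find_orfs(
    unigene_id: str,
    sequence: str,
    min_len: int = DEFAULT_MIN_LEN,
    genetic_code: str = "standard",
    require_start: bool = False,
) -> list[OrfRecord]:
    """Report stop-free codon stretches of ≥ ``min_len`` nt in six frames.

    The default mode reports every maximal stop-free stretch per frame,
    trimmed to codon boundaries, including stretches truncated by the
    sequence ends; ``min_len`` counts neither flanking stop. With
    ``require_start`` each stretch is trimmed to its first start codon
    of the chosen genetic code and kept only if still long enough.
    """
    if min_len % 3 != 0:
        raise ValueError("min_len must be a multiple of 3")
    if genetic_code not in GENETIC_CODES:
        raise ValueError(f"unknown genetic code {genetic_code!r}")
    seq = sequence.upper()
    length = len(seq)
    _, start_codons = _codon_map(genetic_code)
    records: list[OrfRecord] = []
    for strand, strand_seq in (("+", seq), ("-", reverse_complement(seq))):
        for offset in range(3):
            frame = offset + 1 if strand == "+" else offset + 4
            n_codons = (length - offset) // 3
            run_start = None  # codon index where current stop-free run began
            for ci in range(n_codons + 1):
                codon = (
                    strand_seq[offset + 3 * ci : offset + 3 * ci + 3]
                    if ci < n_codons
                    else None  # sentinel terminates the final run
                )
                if codon is None or codon in _STOPS:
                    if run_start is not None:
                        records.extend(
                            _emit_run(
                                unigene_id, strand_seq, strand, frame, offset,
                                run_start, ci, length, min_len,
                                genetic_code, require_start, start_codons,
                            )
                        )
                    run_start = None
                elif run_start is None:
                    run_start = ci
    records.sort(key=lambda r: (r.frame, r.start))
    return records


def _emit_run(
    unigene_id: str,
    strand_seq: str,
    strand: str,
    frame: int,
    offset: int,
    ci_start: int,
    ci_end: int,
    length: int,
    min_len: int,
    genetic_code: str,
    require_start: bool,
    start_codons: set[str],
) -> list[OrfRecord]:
    if require_start:
        ci = ci_start
        while ci < ci_end:
            codon = strand_seq[offset + 3 * ci : offset + 3 * ci + 3]
            if codon in start_codons:
                break
            ci += 1
        ci_start = ci
    nt_len = 3 * (ci_end - ci_start)
    if nt_len < min_len:
        return []
    s = offset + 3 * ci_start
    e = offset + 3 * ci_end
    nt_seq = strand_seq[s:e]
    if strand == "-":
        start, end = length - e, length - s
    else:
        start, end = s, e
    return [
        OrfRecord(
            unigene_id=unigene_id,
            frame=frame,
            start=start,
            end=end,
            nt_seq=nt_seq,
            protein=translate(nt_seq, genetic_code),
            genetic_code=genetic_code,
        )
    ]


# ---------------------------------------------------------------------------
# Domain screening


@dataclass(frozen=True)
class MotifModel:
    """Synthetic position-specific motif standing in for a Pfam HMM.

    These are NOT Pfam profiles: they are fixed consensus peptides with
    a match/mismatch score (match +2, mismatch −1) and a curated-style
    gathering threshold, built for planted-truth testing and for runs
    where real HMMER output is unavailable. Real Pfam screening should
    go through the ``domtblout`` route of :func:`screen_domains`.
    """

    name: str
    pfam_id: str
    family: str
    kind: str  # "CD" or "CBM"
    consensus: str

    MATCH = 2.0
    MISMATCH = -1.0

    @property
    def ga_threshold(self) -> float:
        # tolerates ~25% mismatches against the consensus
        return round(1.25 * len(self.consensus), 1)

    def score_window(self, window: str) -> float:
        return sum(
            self.MATCH if a == b else self.MISMATCH
            for a, b in zip(window, self.consensus)
        )


#: Synthetic stand-in motifs for the Pfam families of the cellulase screen.
BUILTIN_MODELS: tuple[MotifModel, ...] = (
    MotifModel("Glyco_hydro_1", "PF00232", "GH1", "CD", "WDTFTHTPGKVANGDTGDVACDSYHR"),
    MotifModel("Glyco_hydro_3", "PF00933", "GH3", "CD", "GVMYTDWSPIDQRGEAMNAGLDMEMP"),
    MotifModel("Cellulase", "PF00150", "GH5", "CD", "HEYLDHIGNGNPWNCGKEAMDYIRSK"),
    MotifModel("Glyco_hydro_6", "PF01341", "GH6", "CD", "NPYRELAQCSKDPMLRTWAEQYVKGD"),
    MotifModel("Glyco_hydro_8", "PF01270", "GH8", "CD", "QDGFRWTADHMKRELGNWEVYSACPD"),
    MotifModel("Glyco_hydro_9", "PF00759", "GH9", "CD", "DAGDHVKFGWPMAYSLTNERCYTQID"),
    MotifModel("CBM_2", "PF00553", "CBM2", "CBM", "ASWNVQGNTYDIRCPA"),
    MotifModel("CBM_3", "PF00942", "CBM3", "CBM", "GNLKVQYNCSDTWGAP"),
    MotifModel("CBM_4_9", "PF02018", "CBM4, CBM9", "CBM", "TYEWSDGAVNKQCRIP"),
    MotifModel("CBM_6", "PF03422", "CBM6", "CBM", "RPCAYDQWTGSNIVEK"),
)

MODELS_BY_NAME: dict[str, MotifModel] = {m.name: m for m in BUILTIN_MODELS}
MODELS_BY_FAMILY: dict[str, MotifModel] = {m.family: m for m in BUILTIN_MODELS}


def _merge_overlaps(hits: list[DomainHit]) -> list[DomainHit]:
    """Collapse overlapping same-model hits on one protein to the best one."""
    merged: list[DomainHit] = []
    by_key: dict[tuple[str, str], list[DomainHit]] = {}
    for h in hits:
        by_key.setdefault((h.orf_id, h.model), []).append(h)
    for group in by_key.values():
        group.sort(key=lambda h: (h.aa_start, h.aa_end))
        kept: list[DomainHit] = []
        for h in group:
            if kept and h.aa_start < kept[-1].aa_end:
                if h.score > kept[-1].score:
                    kept[-1] = h
            else:
                kept.append(h)
        merged.extend(kept)
    merged.sort(key=lambda h: (h.orf_id, h.model, h.aa_start))
    return merged


def scan_motifs(
    proteins: Mapping[str, str],
    models: Sequence[MotifModel] = BUILTIN_MODELS,
) -> list[DomainHit]:
    """Slide every motif model along every protein; keep scores ≥ GA."""
    hits: list[DomainHit] = []
    for orf_id, protein in proteins.items():
        for model in models:
            w = len(model.consensus)
            for i in range(len(protein) - w + 1):
                score = model.score_window(protein[i : i + w])
                if score >= model.ga_threshold:
                    hits.append(
                        DomainHit(
                            orf_id=orf_id,
                            model=model.name,
                            pfam_id=model.pfam_id,
                            family=model.family,
                            kind=model.kind,
                            aa_start=i,
                            aa_end=i + w,
                            score=score,
                            ga_threshold=model.ga_threshold,
                        )
                    )
    return _merge_overlaps(hits)


@dataclass(frozen=True)
class ModelInfo:
    """Metadata needed to interpret a domtblout row for one Pfam model."""

    pfam_id: str
    family: str
    kind: str
    ga_threshold: float


def builtin_model_info() -> dict[str, ModelInfo]:
    return {
        m.name: ModelInfo(m.pfam_id, m.family, m.kind, m.ga_threshold)
        for m in BUILTIN_MODELS
    }


def parse_domtblout(
    path: str | Path,
    model_info: Mapping[str, ModelInfo],
) -> list[DomainHit]:
    """Read HMMER3 hmmsearch ``--domtblout`` output.

    The target column is the protein (ORF) id and the query column the
    Pfam model; the per-domain bit score (column 14) and alignment
    coordinates (1-based inclusive, columns 18–19) are used. Models
    absent from ``model_info`` are skipped with a warning; hits below
    the model's gathering threshold are dropped.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise DomtbloutParseError(
                    f"line {lineno}: expected ≥22 whitespace-delimited fields, "
                    f"got {len(fields)}"
                )
            try:
                orf_id = fields[0]
                model = fields[3]
                score = float(fields[13])
                ali_from = int(fields[17])
                ali_to = int(fields[18])
            except ValueError as exc:
                raise DomtbloutParseError(f"line {lineno}: {exc}") from exc
            info = model_info.get(model)
            if info is None:
                logger.warning("line %d: unknown model %r, skipped", lineno, model)
                continue
            if score < info.ga_threshold:
                continue
            hits.append(
                DomainHit(
                    orf_id=orf_id,
                    model=model,
                    pfam_id=info.pfam_id,
                    family=info.family,
                    kind=info.kind,
                    aa_start=ali_from - 1,
                    aa_end=ali_to,
                    score=score,
                    ga_threshold=info.ga_threshold,
                )
            )
    return _merge_overlaps(hits)


def screen_domains(
    proteins: Mapping[str, str] | None = None,
    models: Sequence[MotifModel] = BUILTIN_MODELS,
    domtblout_path: str | Path | None = None,
    model_info: Mapping[str, ModelInfo] | None = None,
) -> list[DomainHit]:
    """Screen proteins for catalytic domains and CBMs.

    Either scan ``proteins`` with built-in motif models, or parse an
    external HMMER ``domtblout_path`` (then ``model_info`` supplies each
    model's family, kind and gathering threshold; defaults to the
    built-in set). Retention is score ≥ GA, inclusive.
    """
    if domtblout_path is not None:
        return parse_domtblout(domtblout_path, model_info or builtin_model_info())
    if proteins is None:
        raise ValueError("either proteins or domtblout_path is required")
    return scan_motifs(proteins, models)


def tabulate_domains(domain_hits: Iterable[DomainHit]) -> pd.DataFrame:
    """Per-family ORF and domain counts, Table-1 style.

    ``orf_count`` is the number of distinct ORFs with at least one
    retained hit of the family; ``domain_count`` the total retained
    hits. CBM families that share one Pfam model arrive pre-pooled under
    a combined label (e.g. "CBM4, CBM9").
    """
    orfs: dict[str, set[str]] = {}
    doms: dict[str, int] = {}
    kinds: dict[str, str] = {}
    for h in domain_hits:
        orfs.setdefault(h.family, set()).add(h.orf_id)
        doms[h.family] = doms.get(h.family, 0) + 1
        kinds[h.family] = h.kind
    rows = [
        {
            "family": fam,
            "kind": kinds[fam],
            "orf_count": len(orfs[fam]),
            "domain_count": doms[fam],
        }
        for fam in sorted(orfs)
    ]
    return pd.DataFrame(rows, columns=["family", "kind", "orf_count", "domain_count"])


__all__ = [
    "OrfRecord", "DomainHit", "MotifModel", "ModelInfo", "BUILTIN_MODELS",
    "MODELS_BY_NAME", "MODELS_BY_FAMILY", "DomtbloutParseError",
    "reverse_complement", "translate", "find_orfs", "scan_motifs",
    "parse_domtblout", "screen_domains", "tabulate_domains",
    "builtin_model_info", "GENETIC_CODES", "DEFAULT_MIN_LEN",
]
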