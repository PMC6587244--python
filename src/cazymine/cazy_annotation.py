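"""CAZy family annotation of unigenes from tabular homology hits.

Hits arrive in an outfmt-6-style tab-separated table extended with query
and subject lengths plus the subject's CAZy family and taxonomic lineage.
Each hit is screened on three criteria before it may contribute to an
annotation:

* e-value ≤ 1e-5,
* HSP bit score strictly greater than 60,
* BLAST coverage ratio (BCR) of at least 40% on BOTH the reference and
  the query, where BCR_Ref = 100·Align_length/Ref_length and
  BCR_Que = 100·Align_length/Que_length.

A unigene keeps, per CAZy family, its single best retained hit, and may
legitimately carry several families (multi-domain transcripts).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: GH families that contain at least one characterised cellulase.
CELLULASE_GH_FAMILIES = frozenset(
    {
        "GH1", "GH3", "GH5", "GH6", "GH8", "GH9", "GH12", "GH30",
        "GH44", "GH45", "GH48", "GH51", "GH74", "GH116", "GH124",
    }
)

#: Recognised CAZyme class prefixes, longest first so "GT" wins over "G".
CAZY_CLASSES = ("CBM", "GH", "GT", "CE", "PL", "AA")

DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_BITS_MIN = 60.0
DEFAULT_BCR_MIN = 40.0

#: Column order of the extended tabular hit format (outfmt 6 + extras).
HIT_TABLE_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "align_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "evalue", "bits", "que_length", "ref_length",
    "subject_family", "subject_lineage",
]

LINEAGE_SEP = ";"


class InvalidHitError(ValueError):
    """A hit record whose fields cannot yield a coverage ratio."""


@dataclass(frozen=True)
class HitRecord:
    """One query↔reference alignment from the tabular hit file.

    ``subject_lineage`` is a rank-ordered tuple of taxon names from
    superkingdom downwards. ``query_is_nt``/``subject_is_nt`` declare the
    length units of the dialect: when the query is nucleotide and the
    subject is protein (blastx-style), the query length is divided by 3
    before BCR_Que so both ratios are in amino-acid units.
    """

    query_id: str
    subject_id: str
    align_length: int
    que_length: int
    ref_length: int
    bits: float
    evalue: float
    pct_identity: float = 100.0
    subject_family: str | None = None
    subject_lineage: tuple[str, ...] = ()
    query_is_nt: bool = True
    subject_is_nt: bool = True


@dataclass
class CazyAnnotation:
    """CAZy families assigned to one query, with per-family best hits."""

    query_id: str
    best_hits: dict[str, HitRecord] = field(default_factory=dict)

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(sorted(self.best_hits))


def compute_bcr(hit: HitRecord) -> tuple[float, float]:
    """Return (BCR_Ref, BCR_Que) in percent for one hit.

    An alignment length exceeding either sequence length (possible with
    gapped columns in tabular output) is clamped to that length so the
    ratio never exceeds 100%.

    Raises
    ------
    InvalidHitError
        If either sequence length is non-positive.
    """
    if hit.ref_length <= 0 or hit.que_length <= 0:
        raise InvalidHitError(
            f"hit {hit.query_id}->{hit.subject_id}: non-positive length "
            f"(que={hit.que_length}, ref={hit.ref_length})"
        )
    que_length = hit.que_length
    if hit.query_is_nt and not hit.subject_is_nt:
        # blastx-style mixed units: express the query in codons.
        que_length = que_length / 3.0
    align_ref = hit.align_length
    align_que = hit.align_length
    if align_ref > hit.ref_length:
        logger.warning(
            "hit %s->%s: align_length %d > ref_length %d, clamping",
            hit.query_id, hit.subject_id, hit.align_length, hit.ref_length,
        )
        align_ref = hit.ref_length
    if align_que > que_length:
        logger.warning(
            "hit %s->%s: align_length %d > que_length %s, clamping",
            hit.query_id, hit.subject_id, hit.align_length, que_length,
        )
        align_que = que_length
    return 100.0 * align_ref / hit.ref_length, 100.0 * align_que / que_length


def filter_hits(
    hits: Iterable[HitRecord],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    bits_min: float = DEFAULT_BITS_MIN,
    bcr_min: float = DEFAULT_BCR_MIN,
) -> list[HitRecord]:
    """Retain hits passing the e-value, bit-score and coverage criteria.

    Boundary semantics follow the published wording: exclusion on
    coverage is strictly "< 40%" (so exactly 40.0 is retained) while
    retention on score is strictly "> 60 bits" (so exactly 60.0 is
    excluded). Records with invalid lengths are skipped with a warning.
    Retention is per-record, hence order-independent and idempotent.
    """
    for t in (evalue_max, bits_min, bcr_min):
        if not math.isfinite(t):
            raise ValueError("filter thresholds must be finite")
    kept: list[HitRecord] = []
    for hit in hits:
        try:
            bcr_ref, bcr_que = compute_bcr(hit)
        except InvalidHitError as exc:
            logger.warning("skipping invalid hit: %s", exc)
            continue
        if (
            hit.evalue <= evalue_max
            and hit.bits > bits_min
            and bcr_ref >= bcr_min
            and bcr_que >= bcr_min
        ):
            kept.append(hit)
    return kept


def _hit_rank_key(hit: HitRecord) -> tuple[float, float, str]:
    # Best hit first: highest bits, then lowest e-value, then smallest id.
    return (-hit.bits, hit.evalue, hit.subject_id)


def assign_families(hits: Iterable[HitRecord]) -> dict[str, CazyAnnotation]:
    """Group filtered hits by query and keep the best hit per CAZy family.

    Ties on bit score fall back to lower e-value, then lexicographically
    smallest subject id. Queries with no hits simply do not appear (they
    are counted as unannotated). Hits without a subject family are
    ignored.
    """
    annotations: dict[str, CazyAnnotation] = {}
    for hit in hits:
        if not hit.subject_family:
            continue
        ann = annotations.setdefault(hit.query_id, CazyAnnotation(hit.query_id))
        incumbent = ann.best_hits.get(hit.subject_family)
        if incumbent is None or _hit_rank_key(hit) < _hit_rank_key(incumbent):
            ann.best_hits[hit.subject_family] = hit
    return annotations


def cazy_class_of(family: str) -> str:
    """Map a family label (GH5, CBM3, ...) to its CAZyme class."""
    for cls in CAZY_CLASSES:
        if family.startswith(cls):
            return cls
    return "unclassified"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, matching printed-table convention."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def tabulate_families(
    annotations: Mapping[str, CazyAnnotation] | Iterable[CazyAnnotation],
) -> pd.DataFrame:
    """Tabulate unigene counts per CAZyme class and family.

    Returns a DataFrame with one row per family: ``family``,
    ``cazy_class``, ``n_unigenes``, ``pct`` (share of family-level
    annotations, half-up to 1 decimal) and ``cellulase_subset`` flagging
    the 15 cellulase-containing GH families. A query annotated to several
    families contributes once to each; families whose class prefix is not
    recognised are pooled under class "unclassified" with a warning.
    """
    if isinstance(annotations, Mapping):
        anns: Iterable[CazyAnnotation] = annotations.values()
    else:
        anns = annotations
    counts: dict[str, int] = {}
    for ann in anns:
        for fam in set(ann.families):
            counts[fam] = counts.get(fam, 0) + 1
    rows = []
    total = sum(counts.values())
    for fam in sorted(counts):
        cls = cazy_class_of(fam)
        if cls == "unclassified":
            logger.warning("unknown CAZy family label %r", fam)
        rows.append(
            {
                "family": fam,
                "cazy_class": cls,
                "n_unigenes": counts[fam],
                "pct": round_half_up(100.0 * counts[fam] / total) if total else 0.0,
                "cellulase_subset": fam in CELLULASE_GH_FAMILIES,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["family", "cazy_class", "n_unigenes", "pct", "cellulase_subset"],
    )


def class_totals(family_table: pd.DataFrame) -> pd.DataFrame:
    """Sum the family table up to CAZyme classes (GH/GT/CE/PL/AA/CBM)."""
    if family_table.empty:
        return pd.DataFrame(columns=["cazy_class", "n_unigenes"])
    out = (
        family_table.groupby("cazy_class", as_index=False)["n_unigenes"]
        .sum()
        .sort_values("cazy_class", ignore_index=True)
    )
    return out


# ---------------------------------------------------------------------------
# Tabular I/O


def read_hit_table(
    path: str | Path,
    query_is_nt: bool = True,
    subject_is_nt: bool = True,
) -> list[HitRecord]:
    """Read the extended outfmt-6 hit table (tab-separated, with header)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table {path} missing columns: {sorted(missing)}")
    hits = []
    for row in df.itertuples(index=False):
        lineage = row.subject_lineage
        lineage_t = (
            tuple(str(lineage).split(LINEAGE_SEP))
            if isinstance(lineage, str) and lineage
            else ()
        )
        family = row.subject_family if isinstance(row.subject_family, str) else None
        hits.append(
            HitRecord(
                query_id=str(row.query_id),
                subject_id=str(row.subject_id),
                align_length=int(row.align_length),
                que_length=int(row.que_length),
                ref_length=int(row.ref_length),
                bits=float(row.bits),
                evalue=float(row.evalue),
                pct_identity=float(row.pct_identity),
                subject_family=family,
                subject_lineage=lineage_t,
                query_is_nt=query_is_nt,
                subject_is_nt=subject_is_nt,
            )
        )
    return hits


def write_hit_table(hits: Sequence[HitRecord], path: str | Path) -> None:
    """Write hits in the extended outfmt-6 dialect read by read_hit_table."""
    rows = []
    for h in hits:
        rows.append(
            {
                "query_id": h.query_id,
                "subject_id": h.subject_id,
                "pct_identity": h.pct_identity,
                "align_length": h.align_length,
                "mismatches": 0,
                "gap_opens": 0,
                "q_start": 1,
                "q_end": h.align_length,
                "s_start": 1,
                "s_end": h.align_length,
                "evalue": h.evalue,
                "bits": h.bits,
                "que_length": h.que_length,
                "ref_length": h.ref_length,
                "subject_family": h.subject_family or "",
                "subject_lineage": LINEAGE_SEP.join(h.subject_lineage),
            }
        )
    pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def annotations_to_frame(
    annotations: Mapping[str, CazyAnnotation]
) -> pd.DataFrame:
    """Flatten annotations to one row per (query, family) with BCRs."""
    rows = []
    for qid in sorted(annotations):
        ann = annotations[qid]
        for fam in ann.families:
            hit = ann.best_hits[fam]
            bcr_ref, bcr_que = compute_bcr(hit)
            rows.append(
                {
                    "query_id": qid,
                    "family": fam,
                    "cazy_class": cazy_class_of(fam),
                    "subject_id": hit.subject_id,
                    "bits": hit.bits,
                    "evalue": hit.evalue,
                    "bcr_ref": round_half_up(bcr_ref, 2),
                    "bcr_que": round_half_up(bcr_que, 2),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "query_id", "family", "cazy_class", "subject_id",
            "bits", "evalue", "bcr_ref", "bcr_que",
        ],
    )


def annotate(
    hits: Iterable[HitRecord],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    bits_min: float = DEFAULT_BITS_MIN,
    bcr_min: float = DEFAULT_BCR_MIN,
) -> dict[str, CazyAnnotation]:
    """Filter hits and assign families in one step."""
    return assign_families(filter_hits(hits, evalue_max, bits_min, bcr_min))


__all__ = [
    "HitRecord", "CazyAnnotation", "InvalidHitError",
    "CELLULASE_GH_FAMILIES", "compute_bcr", "filter_hits",
    "assign_families", "tabulate_families", "class_totals",
    "cazy_class_of", "round_half_up", "read_hit_table", "write_hit_table",
    "annotations_to_frame", "annotate",
]
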