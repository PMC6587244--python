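"""Ground-truthed synthetic inputs for the cellulase-mining pipeline.

The generator emulates the statistical shape of a rumen
metatranscriptome study at desk scale: a small multi-taxon community
with full lineages, unigenes carrying planted cellulase ORFs (a
controllable fraction truncated below the 600-nt ORF filter), tabular
homology-hit files with controlled alignment lengths, bit scores and
identities (plus decoys built to fail exactly one named filter each),
negative-binomial per-sample fragment counts, single-end reads with
quality strings, and assay plates with linear standard curves plus
Gaussian noise. Every generator is deterministic for a fixed seed, and
every planted feature is recorded in a truth table so downstream
recovery is exactly checkable.

Distributional choices (log-normal expression, Gaussian identity and
absorbance noise, negative-binomial counts) are conventions — the kind
of structure such data is usually modelled with — not estimates from
any particular dataset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .cazy_annotation import HitRecord
from .orf_mining import MODELS_BY_FAMILY, MotifModel
from .taxonomy import TaxonomyTree

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
STOP = "TAA"

#: Rumen-flavoured lineage pool (superkingdom→genus).
LINEAGE_POOL: tuple[tuple[str, ...], ...] = (
    ("Bacteria", "Firmicutes", "Clostridia", "Eubacteriales", "Oscillospiraceae", "Ruminococcus"),
    ("Bacteria", "Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae", "Butyrivibrio"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae", "Rikenella"),
    ("Bacteria", "Fibrobacteres", "Fibrobacteria", "Fibrobacterales", "Fibrobacteraceae", "Fibrobacter"),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    ("Bacteria", "Spirochaetes", "Spirochaetia", "Spirochaetales", "Treponemataceae", "Treponema"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Succinivibrionaceae", "Succinivibrio"),
    ("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", "Methanobrevibacter"),
    ("Eukaryota", "Neocallimastigomycota", "Neocallimastigomycetes", "Neocallimastigales", "Neocallimastigaceae", "Neocallimastix"),
)

DEFAULT_FAMILY_MIX: dict[str, float] = {
    "GH3": 0.35, "GH5": 0.30, "GH9": 0.15, "GH1": 0.08, "GH6": 0.06, "GH8": 0.06,
}

_CD_MARGIN = 20  # keep the CD motif away from both protein termini


@dataclass(frozen=True)
class PlantedGene:
    """Truth record for one planted gene."""

    gene_id: str
    taxon_index: int
    cazy_family: str | None
    cd_intervals: tuple[tuple[int, int], ...]  # aa, 0-based half-open
    cbm_family: str | None
    cbm_intervals: tuple[tuple[int, int], ...]
    orf_nt_length: int
    strand: str  # '+' or '-'
    expression_rate: float  # expected fragments per kilobase (relative)


@dataclass
class CommunityTruth:
    """A synthetic community with lineages, genes and abundances."""

    taxa: list[tuple[str, ...]]
    abundance: np.ndarray
    genes: list[PlantedGene]
    seed: int

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.abundance)) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        for g in self.genes:
            if not 0 <= g.taxon_index < len(self.taxa):
                raise ValueError(f"gene {g.gene_id}: taxon index out of range")
            if g.orf_nt_length % 3:
                raise ValueError(f"gene {g.gene_id}: ORF length not a codon multiple")

    def taxonomy_tree(self) -> TaxonomyTree:
        return TaxonomyTree.from_lineages(self.taxa)

    def lineage_of(self, gene: PlantedGene) -> tuple[str, ...]:
        return self.taxa[gene.taxon_index]


def _lineages(n_taxa: int) -> list[tuple[str, ...]]:
    out = []
    for i in range(n_taxa):
        base = LINEAGE_POOL[i % len(LINEAGE_POOL)]
        if i < len(LINEAGE_POOL):
            out.append(base)
        else:
            # extra genera under the same family, uniquely named
            out.append(base[:-1] + (f"{base[-1]}_{i // len(LINEAGE_POOL) + 1}",))
    return out


def generate_community(
    n_taxa: int = 8,
    n_genes: int = 60,
    family_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    non_cazyme_rate: float = 0.15,
    cbm_rate: float = 0.25,
) -> CommunityTruth:
    """Sample a community: taxa with lineages, abundances, planted genes.

    ``family_mix`` gives relative weights over cellulase families with a
    built-in domain model; the CAZyme label of each gene is multinomial
    in those weights. ``non_cazyme_rate`` genes carry no family at all
    (background transcripts), and ``cbm_rate`` of CAZyme genes also get
    a carbohydrate-binding module.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if n_genes < 1:
        raise ValueError("need at least 1 gene")
    mix = dict(family_mix) if family_mix is not None else dict(DEFAULT_FAMILY_MIX)
    if not mix or any(w < 0 for w in mix.values()) or sum(mix.values()) <= 0:
        raise ValueError("family_mix weights must be nonnegative and not all zero")
    unknown = [f for f in mix if f not in MODELS_BY_FAMILY or MODELS_BY_FAMILY[f].kind != "CD"]
    if unknown:
        raise ValueError(f"no built-in catalytic-domain model for families: {unknown}")
    rng = np.random.default_rng(seed)
    taxa = _lineages(n_taxa)
    abundance = rng.dirichlet(np.ones(n_taxa))
    fam_labels = sorted(mix)
    fam_w = np.array([mix[f] for f in fam_labels], dtype=float)
    fam_w /= fam_w.sum()
    cbm_families = sorted(f for f, m in MODELS_BY_FAMILY.items() if m.kind == "CBM")

    genes: list[PlantedGene] = []
    for i in range(n_genes):
        taxon_index = int(rng.choice(n_taxa, p=abundance))
        is_cazyme = rng.random() >= non_cazyme_rate
        family = str(rng.choice(fam_labels, p=fam_w)) if is_cazyme else None
        orf_nt = 3 * int(rng.integers(220, 500))
        plen = orf_nt // 3
        cd_intervals: tuple[tuple[int, int], ...] = ()
        cbm_family = None
        cbm_intervals: tuple[tuple[int, int], ...] = ()
        if family is not None:
            w = len(MODELS_BY_FAMILY[family].consensus)
            cd_start = int(rng.integers(_CD_MARGIN, plen - w - 2 * _CD_MARGIN))
            cd_intervals = ((cd_start, cd_start + w),)
            if rng.random() < cbm_rate:
                cbm_family = str(rng.choice(cbm_families))
                cw = len(MODELS_BY_FAMILY[cbm_family].consensus)
                cbm_start = plen - cw - 2
                cbm_intervals = ((cbm_start, cbm_start + cw),)
        strand = "+" if rng.random() < 0.5 else "-"
        expression_rate = float(rng.lognormal(mean=0.0, sigma=1.2))
        genes.append(
            PlantedGene(
                gene_id=f"G{i:06d}",
                taxon_index=taxon_index,
                cazy_family=family,
                cd_intervals=cd_intervals,
                cbm_family=cbm_family,
                cbm_intervals=cbm_intervals,
                orf_nt_length=orf_nt,
                strand=strand,
                expression_rate=expression_rate,
            )
        )
    return CommunityTruth(taxa=taxa, abundance=abundance, genes=genes, seed=seed)


# ---------------------------------------------------------------------------
# Unigene synthesis

_BACK_TABLE: dict[str, list[str]] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _BACK_TABLE.setdefault(_aa, []).append(_codon)
for _aa in _BACK_TABLE:
    _BACK_TABLE[_aa].sort()


def _random_protein(rng: np.random.Generator, gene: PlantedGene) -> str:
    plen = gene.orf_nt_length // 3
    aa = rng.choice(list(AA_ALPHABET), size=plen)
    aa[0] = "M"
    protein = list("".join(aa))
    def splice(interval: tuple[int, int], model: MotifModel) -> None:
        s, e = interval
        protein[s:e] = list(model.consensus)
    if gene.cazy_family:
        for iv in gene.cd_intervals:
            splice(iv, MODELS_BY_FAMILY[gene.cazy_family])
    if gene.cbm_family:
        for iv in gene.cbm_intervals:
            splice(iv, MODELS_BY_FAMILY[gene.cbm_family])
    return "".join(protein)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = []
    for aa in protein:
        options = _BACK_TABLE[aa]
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n > 0 else ""


def generate_unigenes(
    truth: CommunityTruth,
    flank_len: int = 120,
    frag_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Embed each planted ORF in a unigene; return sequences + truth table.

    Each ORF is back-translated from its planted protein, bracketed by
    in-frame stop codons and random flanks, and placed on its planted
    strand. The flanking stop codon counts as the innermost 3 nt of each
    flank, so ``flank_len=0`` yields a unigene that is exactly the ORF
    (recovered as a boundary-truncated stop-free stretch); flank lengths
    of 1–2 nt are rejected since they can neither hold a stop nor leave
    the reading frame clean. A ``frag_fraction`` share of genes is
    instead truncated so that fewer than 600 nt of the ORF survive,
    exercising the length filter downstream. The truth table records
    realized coordinates (0-based half-open, forward strand), frame
    (1–6) and truncation.
    """
    if flank_len < 0 or flank_len in (1, 2):
        raise ValueError("flank_len must be 0 or ≥ 3")
    if not 0.0 <= frag_fraction <= 1.0:
        raise ValueError("frag_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(truth.genes)
    truncate = np.zeros(n, dtype=bool)
    n_trunc = int(round(frag_fraction * n))
    if n_trunc:
        truncate[rng.choice(n, size=n_trunc, replace=False)] = True

    unigenes: dict[str, str] = {}
    rows = []
    for i, gene in enumerate(truth.genes):
        unigene_id = f"UG{i:06d}"
        protein = _random_protein(rng, gene)
        orf_nt = _back_translate(rng, protein)
        left = _random_nt(rng, flank_len - 3) + STOP if flank_len else ""
        right = STOP + _random_nt(rng, flank_len - 3) if flank_len else ""
        if truncate[i]:
            kept = 3 * int(rng.integers(60, 199))  # 180..594 nt < filter
            cassette = left + orf_nt[:kept]
        else:
            kept = len(orf_nt)
            cassette = left + orf_nt + right
        orf_start = flank_len
        orf_end = orf_start + kept
        if gene.strand == "-":
            seq = _revcomp(cassette)
            start = len(seq) - orf_end
            end = len(seq) - orf_start
            frame = 4 + (orf_start % 3)
        else:
            seq = cassette
            start, end = orf_start, orf_end
            frame = 1 + (orf_start % 3)
        unigenes[unigene_id] = seq
        lineage = truth.lineage_of(gene)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "unigene_id": unigene_id,
                "family": gene.cazy_family or "",
                "cbm_family": gene.cbm_family or "",
                "lineage": ";".join(lineage),
                "superkingdom": lineage[0],
                "phylum": lineage[1],
                "strand": gene.strand,
                "frame": frame,
                "orf_start": start,
                "orf_end": end,
                "orf_nt_length": gene.orf_nt_length,
                "kept_nt": kept,
                "truncated": bool(truncate[i]),
                "unigene_length": len(seq),
                "expression_rate": gene.expression_rate,
                "protein": protein,
            }
        )
    return unigenes, pd.DataFrame(rows)


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Hit tables

DECOY_KINDS = ("BCR", "BITS", "EVALUE")


def generate_hit_table(
    truth: CommunityTruth,
    truth_table: pd.DataFrame,
    identity_noise: float = 2.0,
    decoy_rate: float = 0.1,
    seed: int = 0,
) -> list[HitRecord]:
    """Homology hits for every CAZyme unigene, plus filter-failing decoys.

    True hits carry the gene's own family and lineage, pass every filter
    (e ≤ 1e-5, bits > 60, both BCRs ≥ 40%), and have bit scores monotone
    in alignment length at fixed identity. Each decoy query (id prefix
    ``DECOY_<kind>``) fails exactly the one named filter — BCR_Ref < 40%,
    bits ≤ 60, or e-value > 1e-5 — so per-filter sensitivity is
    attributable downstream.
    """
    if not 0.0 <= decoy_rate <= 1.0:
        raise ValueError("decoy_rate must be in [0, 1]")
    if identity_noise < 0:
        raise ValueError("identity_noise must be ≥ 0")
    rng = np.random.default_rng(seed)
    hits: list[HitRecord] = []
    by_gene = truth_table.set_index("gene_id")
    n_cazyme = 0
    for gene in truth.genes:
        if gene.cazy_family is None:
            continue
        n_cazyme += 1
        row = by_gene.loc[gene.gene_id]
        que_len = int(row["unigene_length"])
        lineage = truth.lineage_of(gene)
        for j in range(int(rng.integers(2, 5))):
            ref_len = int(que_len * rng.uniform(0.8, 1.2))
            align = int(0.9 * min(que_len, ref_len))
            identity = float(np.clip(rng.normal(88.0, identity_noise), 60.0, 100.0))
            bits = round(0.5 * align * identity / 100.0, 1)
            evalue = max(1e-180, que_len * ref_len * 2.0 ** -min(bits, 500.0))
            hits.append(
                HitRecord(
                    query_id=str(row["unigene_id"]),
                    subject_id=f"ref|{gene.cazy_family}|{gene.gene_id}|{j}",
                    align_length=align,
                    que_length=que_len,
                    ref_length=ref_len,
                    bits=bits,
                    evalue=evalue,
                    pct_identity=round(identity, 2),
                    subject_family=gene.cazy_family,
                    subject_lineage=lineage,
                )
            )
    n_decoys = int(round(decoy_rate * n_cazyme))
    for d in range(n_decoys):
        kind = DECOY_KINDS[d % len(DECOY_KINDS)]
        que_len = int(rng.integers(700, 1600))
        identity = float(np.clip(rng.normal(88.0, identity_noise), 60.0, 100.0))
        ref_len = int(que_len * rng.uniform(0.9, 1.1))
        align = int(0.9 * min(que_len, ref_len))
        bits = round(0.5 * align * identity / 100.0, 1)
        evalue = 1e-30
        if kind == "BCR":
            ref_len = 5 * align  # BCR_Ref = 20%
        elif kind == "BITS":
            bits = round(float(rng.uniform(30.0, 60.0)), 1)
        else:
            evalue = 1e-4
        lineage = truth.taxa[int(rng.integers(len(truth.taxa)))]
        family = str(rng.choice(sorted({g.cazy_family for g in truth.genes if g.cazy_family})))
        hits.append(
            HitRecord(
                query_id=f"DECOY_{kind}_{d:04d}",
                subject_id=f"ref|{family}|decoy|{d}",
                align_length=align,
                que_length=que_len,
                ref_length=ref_len,
                bits=bits,
                evalue=evalue,
                pct_identity=round(identity, 2),
                subject_family=family,
                subject_lineage=lineage,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Fragment counts


def generate_counts(
    truth_table: pd.DataFrame,
    n_samples: int = 6,
    library_size: int = 200_000,
    dispersion: float | None = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial fragment counts, genes × samples.

    The expected count of gene g is library_size · w_g / Σw with
    w_g = expression_rate · length_kb, so counts scale with both
    expression and transcript length and column sums concentrate on the
    library size. ``dispersion`` is the NB size parameter r in
    Var = µ + µ²/r; ``None`` gives the Poisson limit (r → ∞).
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be ≥ 1")
    if dispersion is not None and dispersion <= 0:
        raise ValueError("dispersion must be positive (or None for Poisson)")
    rng = np.random.default_rng(seed)
    lengths_kb = truth_table["unigene_length"].to_numpy(dtype=float) / 1000.0
    w = truth_table["expression_rate"].to_numpy(dtype=float) * lengths_kb
    if w.sum() <= 0:
        raise ValueError("all expression rates are zero")
    mu = library_size * w / w.sum()
    counts = np.zeros((len(mu), n_samples), dtype=int)
    for s in range(n_samples):
        if dispersion is None:
            counts[:, s] = rng.poisson(mu)
        else:
            r = dispersion
            p = r / (r + mu)
            counts[:, s] = np.where(mu > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)
    return pd.DataFrame(
        counts,
        index=pd.Index(truth_table["unigene_id"], name="unigene_id"),
        columns=[f"S{s + 1}" for s in range(n_samples)],
    )


# ---------------------------------------------------------------------------
# Reads


def generate_reads(
    unigenes: Mapping[str, str],
    truth_table: pd.DataFrame,
    n_reads: int = 2000,
    read_len: int = 100,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Single-end reads with known origins and Phred+33 qualities.

    Reads are drawn from the forward strand of unigenes with probability
    proportional to expression_rate · length, positions uniform; the
    origin unigene id is encoded in the read id after the last ':'.
    Per-base qualities are sampled from a high-quality profile.
    """
    rng = np.random.default_rng(seed)
    ids = list(truth_table["unigene_id"])
    lengths = truth_table["unigene_length"].to_numpy(dtype=float)
    w = truth_table["expression_rate"].to_numpy(dtype=float) * lengths
    w = np.where(lengths >= read_len, w, 0.0)
    if w.sum() <= 0:
        raise ValueError("no unigene long enough for the requested read length")
    p = w / w.sum()
    quals = np.array([40, 38, 36, 33, 30, 25, 20, 14])
    qp = np.array([0.30, 0.25, 0.15, 0.10, 0.08, 0.06, 0.04, 0.02])
    qp = qp / qp.sum()
    reads = []
    for i in range(n_reads):
        gi = int(rng.choice(len(ids), p=p))
        gid = ids[gi]
        seq = unigenes[gid]
        pos = int(rng.integers(0, len(seq) - read_len + 1))
        q = rng.choice(quals, size=read_len, p=qp)
        qual = "".join(chr(int(x) + 33) for x in q)
        reads.append((f"read{i:06d}:{gid}", seq[pos : pos + read_len], qual))
    return reads


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid in sequences:
            fh.write(f">{sid}\n")
            seq = sequences[sid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Assay plates


@dataclass(frozen=True)
class AssayConfig:
    """Reaction geometry needed to convert absorbance to U/mg.

    Defaults mirror a 250 µl + 250 µl, 10-minute microplate reaction;
    ``protein_mg`` is the purified protein per reaction.
    """

    reaction_minutes: float = 10.0
    reaction_volume_ml: float = 0.5
    protein_mg: float = 2e-4
    replicates: int = 2
    standards: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0)  # µmol/ml


def generate_assay_plate(
    enzymes: Sequence[tuple[str, float, str]],
    curve_slope: float = 0.5,
    curve_intercept: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
    config: AssayConfig = AssayConfig(),
) -> pd.DataFrame:
    """Simulate a plate: standards, blanks, negative controls, samples.

    ``enzymes`` is a list of (enzyme_id, true specific activity in U/mg,
    substrate). Product concentration of a sample well is
    U/mg · protein_mg · minutes / volume; absorbance is intercept +
    slope · concentration + N(0, noise_sd). Controls carry zero true
    activity. Columns: well, role, enzyme_id, substrate, condition,
    replicate, concentration, absorbance.
    """
    if curve_slope <= 0:
        raise ValueError("standard-curve slope must be positive")
    if config.replicates < 2:
        raise ValueError("need at least duplicate wells")
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    rng = np.random.default_rng(seed)
    rows = []
    well = 0

    def add(role: str, enzyme_id: str, substrate: str, replicate: int,
            concentration: float) -> None:
        nonlocal well
        well += 1
        absorbance = curve_intercept + curve_slope * concentration
        if noise_sd > 0:
            absorbance += float(rng.normal(0.0, noise_sd))
        rows.append(
            {
                "well": f"W{well:03d}",
                "role": role,
                "enzyme_id": enzyme_id,
                "substrate": substrate,
                "condition": "",
                "replicate": replicate,
                "concentration": concentration,
                "absorbance": round(absorbance, 6),
            }
        )

    for conc in config.standards:
        for rep in range(1, config.replicates + 1):
            add("standard", "", "", rep, conc)
    for rep in range(1, config.replicates + 1):
        add("blank", "", "", rep, 0.0)
    for rep in range(1, config.replicates + 1):
        add("control", "empty_vector", "", rep, 0.0)
    for enzyme_id, activity, substrate in enzymes:
        if activity < 0:
            raise ValueError(f"negative activity for {enzyme_id}")
        conc = (
            activity * config.protein_mg * config.reaction_minutes
            / config.reaction_volume_ml
        )
        for rep in range(1, config.replicates + 1):
            add("sample", enzyme_id, substrate, rep, conc)
    return pd.DataFrame(rows)


def generate_activity_profile(
    conditions: Sequence[float],
    optimum: float,
    width: float,
    peak: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[float, float]:
    """Unimodal (Gaussian-bump) activity profile over a condition grid."""
    rng = np.random.default_rng(seed)
    out = {}
    for c in conditions:
        a = peak * float(np.exp(-((c - optimum) ** 2) / (2.0 * width**2)))
        if noise_sd > 0:
            a += float(rng.normal(0.0, noise_sd))
        out[float(c)] = max(a, 0.0)
    return out


def generate_protein_clusters(
    n_clusters: int = 8,
    per_cluster: int = 4,
    n_singletons: int = 3,
    length: int = 60,
    within_mutations: int = 2,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Planted protein family structure for tree-clustering tests.

    Each cluster descends from its own random ancestor; members carry
    ``within_mutations`` point substitutions, so within-cluster identity
    is high while unrelated ancestors are ~5% identical. Singletons are
    independent random sequences. Returns (sequences, truth) with truth
    mapping each label to its cluster name or "unclustered".
    """
    if n_clusters < 1 or per_cluster < 2:
        raise ValueError("need ≥1 cluster of ≥2 members")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    truth: dict[str, str] = {}

    def mutate(base: str, n_mut: int) -> str:
        s = list(base)
        for pos in rng.choice(len(s), size=n_mut, replace=False):
            choices = [a for a in AA_ALPHABET if a != s[pos]]
            s[pos] = choices[int(rng.integers(len(choices)))]
        return "".join(s)

    for c in range(n_clusters):
        ancestor = "".join(rng.choice(list(AA_ALPHABET), size=length))
        for m in range(per_cluster):
            label = f"c{c + 1}_m{m + 1}"
            seqs[label] = mutate(ancestor, within_mutations)
            truth[label] = f"cluster_{c + 1}"
    for s in range(n_singletons):
        label = f"single_{s + 1}"
        seqs[label] = "".join(rng.choice(list(AA_ALPHABET), size=length))
        truth[label] = "unclustered"
    return seqs, truth


def generate_decay_timecourse(
    times: Sequence[float],
    baseline: float,
    half_life: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[float, float]:
    """Exponential-decay residual activity at the given timepoints."""
    rng = np.random.default_rng(seed)
    out = {}
    for t in times:
        a = baseline * 0.5 ** (t / half_life)
        if noise_sd > 0:
            a += float(rng.normal(0.0, noise_sd))
        out[float(t)] = max(a, 0.0)
    return out


# ---------------------------------------------------------------------------
# One-stop configuration


@dataclass
class SimulationConfig:
    """All generator rates and seeds in one (JSON-serialisable) place."""

    seed: int = 0
    n_taxa: int = 8
    n_genes: int = 60
    family_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FAMILY_MIX))
    non_cazyme_rate: float = 0.15
    cbm_rate: float = 0.25
    flank_len: int = 120
    frag_fraction: float = 0.0
    identity_noise: float = 2.0
    decoy_rate: float = 0.1
    n_samples: int = 6
    library_size: int = 200_000
    dispersion: float | None = 0.3
    n_reads: int = 2000
    read_len: int = 100

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls(**json.loads(Path(path).read_text()))


__all__ = [
    "PlantedGene", "CommunityTruth", "AssayConfig", "SimulationConfig",
    "LINEAGE_POOL", "DEFAULT_FAMILY_MIX", "DECOY_KINDS",
    "generate_community", "generate_unigenes", "generate_hit_table",
    "generate_counts", "generate_reads", "generate_assay_plate",
    "generate_activity_profile", "generate_decay_timecourse",
    "generate_protein_clusters",
    "write_fasta", "write_fastq",
]
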