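"""Genomic context of miRNA loci: intergenic/intronic/exonic, host genes, 10-kb clusters.

miRNA loci are intersected with gene models: a locus overlapping any annotated
exon is exonic (exon takes precedence over intron), a locus inside a gene body
but no exon is intronic, and a locus touching no gene is intergenic. The host
gene is the overlapped gene (longest overlap wins ties) and orientation is
sense iff the miRNA and host strands agree. Neighboring loci whose inter-locus
gap is at most 10 kb are chained into clusters (single linkage, strand
ignored). Intronic miRNAs are additionally compared with their host gene's
expression profile, since co-transcription predicts concordant profiles.

Internally all intervals are 0-based half-open; GFF3 input (1-based closed)
is converted on read and back on write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gffutils
from intervaltree import IntervalTree

from .correlation import spearman_rho


@dataclass(frozen=True)
class MirnaLocus:
    """A miRNA genomic interval, optionally annotated with its context."""

    mirna: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    context: str | None = None  # intergenic | intronic | exonic
    host_gene: str | None = None
    orientation: str | None = None  # sense | antisense | n/a

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.mirna}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.mirna}: strand must be + or -")


@dataclass
class MirnaCluster:
    """Neighboring miRNA loci chained within the maximum gap, ordered by start."""

    chrom: str
    members: list[MirnaLocus] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.members[0].start, max(m.end for m in self.members)


@dataclass(frozen=True)
class HostRelation:
    mirna: str
    host_gene: str
    rho: float
    category: str  # correlated | poor | negative
    flagged: bool = False  # rho undefined (constant profile)


def gff_to_internal(start1: int, end1: int) -> tuple[int, int]:
    """GFF3 1-based closed -> 0-based half-open."""
    return start1 - 1, end1


def internal_to_gff(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> GFF3 1-based closed."""
    return start0 + 1, end0


class GeneModels:
    """Per-chromosome interval indexes of gene bodies and exons from GFF3."""

    def __init__(self) -> None:
        self.gene_trees: dict[str, IntervalTree] = {}
        self.exon_trees: dict[str, IntervalTree] = {}
        self.gene_strand: dict[str, str] = {}

    def add_gene(self, gene_id: str, chrom: str, start: int, end: int, strand: str) -> None:
        self.gene_trees.setdefault(chrom, IntervalTree())[start:end] = gene_id
        self.gene_strand[gene_id] = strand

    def add_exon(self, gene_id: str, chrom: str, start: int, end: int) -> None:
        self.exon_trees.setdefault(chrom, IntervalTree())[start:end] = gene_id

    @property
    def chroms(self) -> set[str]:
        return set(self.gene_trees)


def read_gene_models_gff3(path) -> GeneModels:
    """Load gene bodies and exons from GFF3; exon parents are resolved to genes."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    models = GeneModels()
    for gene in db.features_of_type("gene"):
        start, end = gff_to_internal(gene.start, gene.end)
        models.add_gene(gene.id, gene.seqid, start, end, gene.strand)
    for exon in db.features_of_type("exon"):
        parents = list(db.parents(exon, featuretype="gene"))
        if not parents:  # exon -> transcript -> gene, or orphan exon
            for mid in db.parents(exon):
                parents.extend(db.parents(mid, featuretype="gene"))
        gene_id = parents[0].id if parents else exon.attributes.get("Parent", [exon.id])[0]
        start, end = gff_to_internal(exon.start, exon.end)
        models.add_exon(gene_id, exon.seqid, start, end)
    return models


def read_mirna_loci_gff3(path, featuretype: str = "miRNA") -> list[MirnaLocus]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    loci = []
    for feat in db.features_of_type(featuretype):
        start, end = gff_to_internal(feat.start, feat.end)
        loci.append(MirnaLocus(feat.id, feat.seqid, start, end, feat.strand))
    return loci


def read_mirna_loci_bed(path) -> list[MirnaLocus]:
    """BED6 alternative input (already 0-based half-open)."""
    loci = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: BED6 requires 6 columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            loci.append(MirnaLocus(name, chrom, int(start), int(end), strand))
    return loci


def _overlap_by_gene(tree: IntervalTree | None, start: int, end: int) -> dict[str, int]:
    """Total overlapped bases per gene id within [start, end)."""
    if tree is None:
        return {}
    totals: dict[str, int] = {}
    for iv in tree.overlap(start, end):
        bases = min(end, iv.end) - max(start, iv.begin)
        if bases > 0:
            totals[iv.data] = totals.get(iv.data, 0) + bases
    return totals


def classify_locus(locus: MirnaLocus, models: GeneModels) -> MirnaLocus:
    """Assign context, host gene (longest overlap) and strand orientation.

    Precedence: any exon overlap -> exonic; else gene-body overlap -> intronic;
    else intergenic. A chromosome absent from the gene models classifies as
    intergenic with a warning.
    """
    if locus.chrom not in models.chroms:
        warnings.warn(
            f"{locus.mirna}: chromosome {locus.chrom!r} absent from gene models; "
            "classified intergenic",
            stacklevel=2,
        )
        return replace(locus, context="intergenic", host_gene=None, orientation="n/a")
    exonic = _overlap_by_gene(models.exon_trees.get(locus.chrom), locus.start, locus.end)
    genic = _overlap_by_gene(models.gene_trees.get(locus.chrom), locus.start, locus.end)
    if exonic:
        context, pool = "exonic", exonic
    elif genic:
        context, pool = "intronic", genic
    else:
        return replace(locus, context="intergenic", host_gene=None, orientation="n/a")
    # longest overlap wins; ties broken by gene id for determinism
    host = max(sorted(pool), key=lambda g: pool[g])
    orientation = "sense" if models.gene_strand.get(host) == locus.strand else "antisense"
    return replace(locus, context=context, host_gene=host, orientation=orientation)


def classify_loci(loci, models: GeneModels) -> list[MirnaLocus]:
    return [classify_locus(locus, models) for locus in loci]


def cluster_mirnas(
    loci, max_gap: int = 10_000
) -> tuple[list[MirnaCluster], list[MirnaLocus]]:
    """Single-linkage chaining of loci per chromosome.

    Loci are sorted by start; the open cluster extends while the gap from its
    rightmost end to the next start is at most ``max_gap``. Strand is ignored.
    Returns (clusters of size >= 2, singletons).
    """
    by_chrom: dict[str, list[MirnaLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    clusters: list[MirnaCluster] = []
    singletons: list[MirnaLocus] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda m: (m.start, m.end, m.mirna))
        open_members = [ordered[0]]
        open_end = ordered[0].end
        for locus in ordered[1:]:
            if locus.start - open_end <= max_gap:
                open_members.append(locus)
                open_end = max(open_end, locus.end)
            else:
                if len(open_members) >= 2:
                    clusters.append(MirnaCluster(chrom, open_members))
                else:
                    singletons.append(open_members[0])
                open_members = [locus]
                open_end = locus.end
        if len(open_members) >= 2:
            clusters.append(MirnaCluster(chrom, open_members))
        else:
            singletons.append(open_members[0])
    return clusters, singletons


def host_gene_relation(
    mirna_id: str,
    host_gene: str,
    mirna_profile,
    host_profile,
    cut_hi: float = 0.5,
    cut_neg: float = -0.3,
) -> HostRelation:
    """Spearman concordance category between an intronic miRNA and its host gene.

    rho >= cut_hi -> correlated; rho <= cut_neg -> negative; else poor. An
    undefined rho (constant profile) is reported as poor with a flag. The
    cutoffs are package defaults, exposed in configuration.
    """
    rho = spearman_rho(mirna_profile, host_profile)
    if rho != rho:  # nan
        return HostRelation(mirna_id, host_gene, float("nan"), "poor", flagged=True)
    if rho >= cut_hi:
        category = "correlated"
    elif rho <= cut_neg:
        category = "negative"
    else:
        category = "poor"
    return HostRelation(mirna_id, host_gene, rho, category)
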