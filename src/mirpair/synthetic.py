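"""Synthetic study generator with planted regulatory structure and a truth ledger.

Emulates the reference design — six ordered cellular states profiled in
triplicate on two channels (miRNA probes and mRNA transcripts) — together with
every side input the pipeline consumes: mature miRNA and 3'UTR FASTA, gene
models and miRNA loci in GFF3, external prediction and validated-interaction
tables, and GMT gene sets. The statistical structure the analysis assumes is
planted explicitly:

* repressor miRNAs follow a strictly monotone geometric ladder across the six
  states and their planted targets follow the reversed ladder (population
  rho = -1), with a seed site of a declared type embedded in the target UTR;
* a "weak" repressive class swaps one adjacent pair of states in the target
  profile (population rho = 1 - 12/210 ≈ 0.943), exercising the |rho| > 0.8
  cutoff's discrete behavior at n = 6;
* intronic miRNAs share one template with their host gene (population
  rho = +1) and sit inside that gene's intron in the gene models;
* null transcripts carry independently permuted ladders;
* replicate noise is multiplicative log-normal; a configured fraction of
  transcripts is rescaled below the intensity filter threshold;
* decoy predictions (pairs without strong negative correlation), decoy
  validated entries and random gene sets exercise every integration branch.

Replicates are ``template * exp(Normal(0, noise_sd))``; all randomness flows
through one seeded generator, so outputs are byte-identical per (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .correlation import spearman_rho
from .design import StudyDesign
from .enrichment import write_gmt
from .expression import ExpressionMatrix
from .genome_context import MirnaLocus, internal_to_gff
from .targets import _COMPLEMENT, _revcomp, find_seed_sites

_SITE_CYCLE = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_DNA = "ACGT"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale knobs; defaults reflect the emulated design (6 states x 3 replicates)."""

    n_conditions: int = 6
    replicates: int = 3
    n_repressor_pairs: int = 20
    n_weak_pairs: int = 5
    n_cotranscribed_pairs: int = 10
    n_null_mrnas: int = 50
    n_null_mirnas: int = 10
    frac_subthreshold: float = 0.1
    noise_sd: float = 0.1
    baseline_range: tuple[float, float] = (50.0, 400.0)
    fold_step: float = 1.6
    n_decoy_predictions: int = 8
    n_decoy_validated: int = 2
    n_random_terms: int = 8
    utr_length: int = 200
    seed: int = 0

    @property
    def n_mirnas(self) -> int:
        return (
            self.n_repressor_pairs
            + self.n_weak_pairs
            + self.n_cotranscribed_pairs
            + self.n_null_mirnas
        )

    @property
    def n_mrnas(self) -> int:
        return (
            self.n_repressor_pairs
            + self.n_weak_pairs
            + self.n_cotranscribed_pairs
            + self.n_null_mrnas
        )

    def validate(self) -> None:
        if self.n_conditions != 6:
            raise ValueError("the emulated design has exactly six conditions")
        if self.replicates < 2:
            raise ValueError("need at least two replicates per condition")
        for name in (
            "n_repressor_pairs",
            "n_weak_pairs",
            "n_cotranscribed_pairs",
            "n_null_mrnas",
            "n_null_mirnas",
            "n_decoy_predictions",
            "n_decoy_validated",
            "n_random_terms",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.frac_subthreshold < 1:
            raise ValueError("frac_subthreshold must be in [0, 1)")
        if self.fold_step <= 1:
            raise ValueError("fold_step must exceed 1")
        if self.utr_length < 40:
            raise ValueError("utr_length too short to embed sites")
        if self._n_sub_mirnas() > self.n_null_mirnas:
            raise ValueError("frac_subthreshold exceeds the null miRNA pool")
        if self._n_sub_mrnas() > self.n_null_mrnas:
            raise ValueError("frac_subthreshold exceeds the null mRNA pool")

    def _n_sub_mirnas(self) -> int:
        return int(round(self.frac_subthreshold * self.n_mirnas))

    def _n_sub_mrnas(self) -> int:
        return int(round(self.frac_subthreshold * self.n_mrnas))


@dataclass
class TruthLedger:
    """Ground truth of everything planted; ids refer to the generated matrices."""

    repressor_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    weak_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    cotranscribed: list[tuple[str, str]] = field(default_factory=list)
    subthreshold_mirnas: list[str] = field(default_factory=list)
    subthreshold_mrnas: list[str] = field(default_factory=list)
    differential: dict[str, dict[str, str]] = field(default_factory=dict)
    contexts: dict[str, dict[str, str | None]] = field(default_factory=dict)
    clusters: list[list[str]] = field(default_factory=list)
    decoy_predictions: list[tuple[str, str]] = field(default_factory=list)
    validated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def repressive_pairs(self) -> set[tuple[str, str]]:
        """All planted repressive (miRNA, mRNA) pairs, strong and weak."""
        return {(m, g) for m, g, _ in self.repressor_pairs} | {
            (m, g) for m, g, _ in self.weak_pairs
        }

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthLedger":
        raw = json.loads(text)
        out = cls(**raw)
        out.repressor_pairs = [tuple(t) for t in out.repressor_pairs]
        out.weak_pairs = [tuple(t) for t in out.weak_pairs]
        out.cotranscribed = [tuple(t) for t in out.cotranscribed]
        out.decoy_predictions = [tuple(t) for t in out.decoy_predictions]
        out.validated_pairs = [tuple(t) for t in out.validated_pairs]
        return out


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    design: StudyDesign
    mirna_matrix: ExpressionMatrix
    mrna_matrix: ExpressionMatrix
    mirna_seqs: dict[str, str]
    utr_seqs: dict[str, str]
    gene_models_gff: str
    mirna_loci: list[MirnaLocus]
    predictions_a: pd.DataFrame
    predictions_b: pd.DataFrame
    validated: pd.DataFrame
    gene_sets: dict[str, set[str]]
    truth: TruthLedger

    @property
    def mirna_loci_gff(self) -> str:
        lines = ["##gff-version 3"]
        for locus in self.mirna_loci:
            start1, end1 = internal_to_gff(locus.start, locus.end)
            lines.append(
                f"{locus.chrom}\tsynth\tmiRNA\t{start1}\t{end1}\t.\t{locus.strand}\t.\tID={locus.mirna}"
            )
        return "\n".join(lines) + "\n"

    def write(self, outdir) -> dict[str, Path]:
        """Emit every file dialect the pipeline consumes; byte-stable per config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mirna_matrix": outdir / "mirna_matrix.tsv",
            "mrna_matrix": outdir / "mrna_matrix.tsv",
            "design": outdir / "design.tsv",
            "mirna_fasta": outdir / "mirna.fa",
            "utr_fasta": outdir / "utr.fa",
            "gene_models": outdir / "genes.gff3",
            "mirna_loci": outdir / "mirna_loci.gff3",
            "predictions_a": outdir / "predictions_a.tsv",
            "predictions_b": outdir / "predictions_b.tsv",
            "validated": outdir / "validated.tsv",
            "gene_sets": outdir / "gene_sets.gmt",
            "truth": outdir / "truth.json",
        }
        self.mirna_matrix.write(paths["mirna_matrix"])
        self.mrna_matrix.write(paths["mrna_matrix"])
        self.design.write(paths["design"])
        _write_fasta(self.mirna_seqs, paths["mirna_fasta"])
        _write_fasta(self.utr_seqs, paths["utr_fasta"])
        paths["gene_models"].write_text(self.gene_models_gff)
        paths["mirna_loci"].write_text(self.mirna_loci_gff)
        self.predictions_a.to_csv(paths["predictions_a"], sep="\t", index=False)
        self.predictions_b.to_csv(paths["predictions_b"], sep="\t", index=False)
        self.validated.to_csv(paths["validated"], sep="\t", index=False)
        write_gmt(self.gene_sets, paths["gene_sets"])
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


def _write_fasta(seqs: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# sequence planting


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = _DNA) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def _embed_site(utr: list[str], mirna_seq: str, site_type: str, pos: int) -> None:
    """Write a seed site of exactly ``site_type`` into ``utr`` at match start ``pos``."""
    mirna = mirna_seq.upper().replace("U", "T")
    core = _revcomp(mirna[1:7])
    c8 = _COMPLEMENT[mirna[7]]
    utr[pos : pos + 6] = list(core)
    not_c8 = next(c for c in "CGT" if c != c8)  # 5' flank that cannot pair position 8
    if site_type == "8mer":
        utr[pos - 1], utr[pos + 6] = c8, "A"
    elif site_type == "7mer-m8":
        utr[pos - 1], utr[pos + 6] = c8, "C"  # any non-A 3' flank
    elif site_type == "7mer-A1":
        utr[pos - 1], utr[pos + 6] = not_c8, "A"
    elif site_type == "6mer":
        utr[pos - 1], utr[pos + 6] = not_c8, "C"
    else:
        raise ValueError(f"unknown site type {site_type!r}")


def _scrub_utr(
    rng: np.random.Generator,
    utr: list[str],
    patterns: dict[str, str],
    protected: tuple[int, int] | None,
    keep: tuple[str, int] | None,
) -> bool:
    """Mutate away every seed-match occurrence except the planted one.

    ``protected`` is a [start, end) window that must not be touched; ``keep``
    is (mirna id, match start) of the planted occurrence. Returns False when a
    stray occurrence cannot be removed without touching the protected window.
    """
    for _round in range(60):
        text = "".join(utr)
        dirty = False
        for mirna_id, pattern in patterns.items():
            start = text.find(pattern)
            while start != -1:
                if keep is not None and (mirna_id, start) == keep:
                    start = text.find(pattern, start + 1)
                    continue
                # mutate one base of this occurrence outside the protected window
                positions = [
                    i
                    for i in range(start, start + 6)
                    if protected is None or not (protected[0] <= i < protected[1])
                ]
                if not positions:
                    return False
                i = positions[int(rng.integers(0, len(positions)))]
                choices = [c for c in _DNA if c != utr[i]]
                utr[i] = choices[int(rng.integers(0, len(choices)))]
                dirty = True
                break  # re-scan from scratch after each mutation
            if dirty:
                break
        if not dirty:
            return True
    return False


def _planted_utr(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    mirna_id: str,
    mirna_seq: str,
    site_type: str,
    patterns: dict[str, str],
) -> str:
    """A UTR containing exactly one site (of the declared type) for ``mirna_id``
    and no seed match for any other miRNA."""
    for _attempt in range(200):
        utr = list(_random_seq(rng, cfg.utr_length))
        pos = int(rng.integers(4, cfg.utr_length - 10))
        _embed_site(utr, mirna_seq, site_type, pos)
        protected = (pos - 1, pos + 7)
        if not _scrub_utr(rng, utr, patterns, protected, keep=(mirna_id, pos)):
            continue
        text = "".join(utr)
        own = find_seed_sites(mirna_seq, text, mirna_id, "utr")
        if len(own) == 1 and own[0].site_type == site_type:
            return text
    raise RuntimeError(f"could not plant a clean {site_type} site for {mirna_id}")


def _clean_utr(rng: np.random.Generator, cfg: SyntheticConfig, patterns: dict[str, str]) -> str:
    for _attempt in range(200):
        utr = list(_random_seq(rng, cfg.utr_length))
        if _scrub_utr(rng, utr, patterns, protected=None, keep=None):
            return "".join(utr)
    raise RuntimeError("could not scrub a null UTR")


# ---------------------------------------------------------------------------
# study generation


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Build the full synthetic study. Deterministic for a given config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = StudyDesign()
    asc = config.fold_step ** np.arange(6, dtype=float)
    lo, hi = config.baseline_range
    truth = TruthLedger()

    def baseline() -> float:
        return float(rng.uniform(lo, hi))

    mirna_templates: dict[str, np.ndarray] = {}
    mrna_templates: dict[str, np.ndarray] = {}

    # strong repressive pairs: miRNA monotone, target reversed (rho = -1)
    for i in range(config.n_repressor_pairs):
        mid, gid = f"mir-rep-{i + 1:03d}", f"gene-tgt-{i + 1:03d}"
        up = bool(rng.random() < 0.5)
        mirna_templates[mid] = baseline() * (asc if up else asc[::-1])
        mrna_templates[gid] = baseline() * (asc[::-1] if up else asc)
        site = _SITE_CYCLE[i % len(_SITE_CYCLE)]
        truth.repressor_pairs.append((mid, gid, site))

    # weak repressive pairs: one adjacent state swap in the target (rho ~ 0.943)
    for i in range(config.n_weak_pairs):
        mid, gid = f"mir-weak-{i + 1:03d}", f"gene-wtgt-{i + 1:03d}"
        up = bool(rng.random() < 0.5)
        mirna_templates[mid] = baseline() * (asc if up else asc[::-1])
        target = baseline() * (asc[::-1] if up else asc)
        target[[2, 3]] = target[[3, 2]]
        mrna_templates[gid] = target
        site = _SITE_CYCLE[i % len(_SITE_CYCLE)]
        truth.weak_pairs.append((mid, gid, site))

    # co-transcribed intronic miRNA / host-gene pairs share one template (rho = +1)
    for i in range(config.n_cotranscribed_pairs):
        mid, gid = f"mir-cotx-{i + 1:03d}", f"gene-host-{i + 1:03d}"
        shape = rng.permutation(asc)
        mirna_templates[mid] = baseline() * shape
        mrna_templates[gid] = baseline() * shape
        truth.cotranscribed.append((mid, gid))

    # null transcripts: independently permuted ladders
    null_mirnas = [f"mir-null-{i + 1:03d}" for i in range(config.n_null_mirnas)]
    for mid in null_mirnas:
        mirna_templates[mid] = baseline() * rng.permutation(asc)
    null_mrnas = [f"gene-null-{i + 1:03d}" for i in range(config.n_null_mrnas)]
    for gid in null_mrnas:
        mrna_templates[gid] = baseline() * rng.permutation(asc)

    # planted differential directions (treatment course, last state vs receptor-positive)
    truth.differential = {"mirna": {}, "mrna": {}}
    for mid, t in mirna_templates.items():
        if not mid.startswith("mir-null"):
            truth.differential["mirna"][mid] = "up" if t[5] > t[1] else "down"
    for gid, t in mrna_templates.items():
        if not gid.startswith("gene-null"):
            truth.differential["mrna"][gid] = "up" if t[5] > t[1] else "down"

    # replicate matrices (condition-major column order, log-normal noise)
    def build_matrix(templates: dict[str, np.ndarray], channel: str) -> ExpressionMatrix:
        columns = design.samples
        reps = design.replicates_per_condition
        rows = {}
        for tid, template in templates.items():
            per_sample = np.repeat(template, reps)
            if config.noise_sd > 0:
                per_sample = per_sample * np.exp(
                    rng.normal(0.0, config.noise_sd, size=per_sample.size)
                )
            rows[tid] = per_sample
        values = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
        return ExpressionMatrix(values=values, channel=channel)

    mirna_matrix = build_matrix(mirna_templates, "mirna")
    mrna_matrix = build_matrix(mrna_templates, "mrna")

    # sub-threshold slice: rescale trailing null transcripts so max intensity < 10
    def push_subthreshold(matrix: ExpressionMatrix, pool: list[str], count: int) -> list[str]:
        chosen = pool[-count:] if count else []
        for tid in chosen:
            row = matrix.values.loc[tid]
            matrix.values.loc[tid] = row * (float(rng.uniform(3.0, 8.0)) / row.max())
        return chosen

    truth.subthreshold_mirnas = push_subthreshold(
        mirna_matrix, null_mirnas, config._n_sub_mirnas()
    )
    truth.subthreshold_mrnas = push_subthreshold(
        mrna_matrix, null_mrnas, config._n_sub_mrnas()
    )

    # mature miRNA sequences with unique, shift-compatible seeds: no match
    # pattern may be a one-base shift of another (or of itself), otherwise a
    # planted site's fixed flanks could harbour an unscrubbable foreign match
    mirna_seqs: dict[str, str] = {}
    patterns_seen: list[str] = []

    def _shift_clash(q: str) -> bool:
        if q[0:5] == q[1:6]:
            return True
        for p in patterns_seen:
            if p == q or p[1:6] == q[0:5] or p[0:5] == q[1:6]:
                return True
        return False

    for mid in mirna_templates:
        while True:
            seq = _random_seq(rng, 22, "ACGU")
            pattern = _revcomp(seq.upper().replace("U", "T")[1:7])
            if not _shift_clash(pattern):
                patterns_seen.append(pattern)
                mirna_seqs[mid] = seq
                break
    patterns = {
        mid: _revcomp(seq.upper().replace("U", "T")[1:7]) for mid, seq in mirna_seqs.items()
    }

    # 3'UTRs: planted sites for repressive targets, scrubbed elsewhere
    utr_seqs: dict[str, str] = {}
    for mid, gid, site in truth.repressor_pairs + truth.weak_pairs:
        utr_seqs[gid] = _planted_utr(rng, config, mid, mirna_seqs[mid], site, patterns)
    for gid in [g for _, g in truth.cotranscribed] + null_mrnas:
        utr_seqs[gid] = _clean_utr(rng, config, patterns)
    utr_seqs = {gid: utr_seqs[gid] for gid in mrna_templates}  # stable order

    # genome: host genes with intronic miRNAs, one exonic miRNA, intergenic rest
    gff_lines = ["##gff-version 3"]
    loci: list[MirnaLocus] = []
    chrom = "chr1"
    decoy_gene_id = "gene-decoy-model"
    gff_lines.append(f"{chrom}\tsynth\tgene\t10001\t19000\t.\t+\t.\tID={decoy_gene_id}")
    for j, (rel_s, rel_e) in enumerate(((0, 1500), (4500, 6000), (7500, 9000)), start=1):
        gff_lines.append(
            f"{chrom}\tsynth\texon\t{10001 + rel_s}\t{10000 + rel_e}\t.\t+\t.\t"
            f"ID={decoy_gene_id}.e{j};Parent={decoy_gene_id}"
        )

    host_starts: dict[str, tuple[int, str]] = {}
    for i, (mid, gid) in enumerate(truth.cotranscribed):
        gstart = 100_000 * (i + 1)
        strand = "+" if i % 2 == 0 else "-"
        host_starts[gid] = (gstart, strand)
        g1, g2 = internal_to_gff(gstart, gstart + 9000)
        gff_lines.append(f"{chrom}\tsynth\tgene\t{g1}\t{g2}\t.\t{strand}\t.\tID={gid}")
        for j, (rel_s, rel_e) in enumerate(((0, 1500), (4500, 6000), (7500, 9000)), start=1):
            e1, e2 = internal_to_gff(gstart + rel_s, gstart + rel_e)
            gff_lines.append(
                f"{chrom}\tsynth\texon\t{e1}\t{e2}\t.\t{strand}\t.\tID={gid}.e{j};Parent={gid}"
            )
        antisense = bool(rng.random() < 0.3)
        mstrand = ("-" if strand == "+" else "+") if antisense else strand
        loci.append(MirnaLocus(mid, chrom, gstart + 2000, gstart + 2080, mstrand))
        truth.contexts[mid] = {
            "context": "intronic",
            "host_gene": gid,
            "orientation": "antisense" if antisense else "sense",
        }

    remaining_nulls = list(null_mirnas)
    if truth.cotranscribed and remaining_nulls:
        # one exonic locus inside the first host gene's middle exon
        mid = remaining_nulls.pop(0)
        gid = truth.cotranscribed[0][1]
        gstart, strand = host_starts[gid]
        antisense = bool(rng.random() < 0.3)
        mstrand = ("-" if strand == "+" else "+") if antisense else strand
        loci.append(MirnaLocus(mid, chrom, gstart + 4700, gstart + 4780, mstrand))
        truth.contexts[mid] = {
            "context": "exonic",
            "host_gene": gid,
            "orientation": "antisense" if antisense else "sense",
        }
        # the exonic locus sits within 10 kb of that gene's intronic miRNA
        truth.clusters.append([truth.cotranscribed[0][0], mid])

    intergenic = (
        [m for m, _, _ in truth.repressor_pairs]
        + [m for m, _, _ in truth.weak_pairs]
        + remaining_nulls
    )
    base = 100_000 * (len(truth.cotranscribed) + 2)
    placed = 0

    def place(mid: str, start: int) -> None:
        strand = "+" if rng.random() < 0.5 else "-"
        loci.append(MirnaLocus(mid, chrom, start, start + 80, strand))
        truth.contexts[mid] = {"context": "intergenic", "host_gene": None, "orientation": "n/a"}

    if len(intergenic) >= 2:  # planted cluster of two, 5 kb apart
        pair = intergenic[:2]
        place(pair[0], base)
        place(pair[1], base + 80 + 5000)
        truth.clusters.append(pair)
        placed = 2
    if len(intergenic) >= 5:  # planted chain of three at 8 kb gaps
        trio = intergenic[2:5]
        start = base + 40_000
        for k, mid in enumerate(trio):
            place(mid, start + k * (80 + 8000))
        truth.clusters.append(trio)
        placed = 5
    for k, mid in enumerate(intergenic[placed:]):
        place(mid, base + 120_000 + k * 50_000)

    gene_models_gff = "\n".join(gff_lines) + "\n"

    # prediction tables: planted pairs + weakly-correlated decoys, two sources
    planted_pred = [(m, g) for m, g, _ in truth.repressor_pairs + truth.weak_pairs]
    decoys: list[tuple[str, str]] = []
    decoy_sources = [m for m, _, _ in truth.repressor_pairs] or list(mirna_templates)
    if null_mrnas:
        for d in range(config.n_decoy_predictions):
            mid = decoy_sources[d % len(decoy_sources)]
            for _try in range(100):
                gid = null_mrnas[int(rng.integers(0, len(null_mrnas)))]
                rho = spearman_rho(mirna_templates[mid], mrna_templates[gid])
                if (mid, gid) not in decoys and abs(rho) <= 0.6:
                    decoys.append((mid, gid))
                    break
    truth.decoy_predictions = decoys
    shared = planted_pred + decoys

    def extras(offset: int) -> list[tuple[str, str]]:
        out = []
        if truth.cotranscribed and len(null_mrnas) > offset + 1:
            mid = truth.cotranscribed[offset % len(truth.cotranscribed)][0]
            gid = null_mrnas[offset]
            if (mid, gid) not in shared:
                out.append((mid, gid))
        return out

    table_a = pd.DataFrame(shared + extras(0), columns=["mirna", "gene"])
    table_b = pd.DataFrame(shared + extras(1), columns=["mirna", "gene"])

    # validated interactions: some planted, one decoy (curated-database-style table)
    validated_pairs = planted_pred[: config.n_decoy_validated]
    if decoys:
        validated_pairs = validated_pairs + decoys[:1]
    truth.validated_pairs = list(validated_pairs)
    validated = pd.DataFrame(
        [(m, g, "synthetic-validation-db") for m, g in validated_pairs],
        columns=["mirna", "gene", "source"],
    )

    # gene sets: one module collecting all planted targets, plus random terms
    gene_sets: dict[str, set[str]] = {}
    planted_targets = {g for _, g in planted_pred}
    if planted_targets:
        gene_sets["planted_repression_module"] = planted_targets
    all_genes = list(mrna_templates)
    for t in range(config.n_random_terms):
        size = int(rng.integers(8, min(25, max(9, len(all_genes)))))
        members = rng.choice(len(all_genes), size=min(size, len(all_genes)), replace=False)
        gene_sets[f"random_term_{t + 1:02d}"] = {all_genes[i] for i in members}

    return SyntheticStudy(
        config=config,
        design=design,
        mirna_matrix=mirna_matrix,
        mrna_matrix=mrna_matrix,
        mirna_seqs=mirna_seqs,
        utr_seqs=utr_seqs,
        gene_models_gff=gene_models_gff,
        mirna_loci=loci,
        predictions_a=table_a,
        predictions_b=table_b,
        validated=validated,
        gene_sets=gene_sets,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# recovery evaluation


@dataclass
class RecoveryReport:
    precision: float | None  # None when nothing was reported
    recall: float
    per_class_recall: dict[str, float]
    n_reported: int
    n_planted: int
    false_positives: list[tuple[str, str]]


def evaluate_recovery(reported, truth: TruthLedger) -> RecoveryReport:
    """Precision/recall of reported high-confidence pairs against the planted truth.

    ``reported`` is either the integrated pair table (rows with a ``tier``
    column; only high-confidence rows count) or an iterable of (miRNA, mRNA)
    pairs. The positive class is the union of strong and weak planted
    repressive pairs; recall is additionally broken down per class.
    """
    if isinstance(reported, pd.DataFrame):
        mask = reported["tier"] == "high-confidence"
        reported_pairs = set(zip(reported.loc[mask, "mirna"], reported.loc[mask, "mrna"]))
    else:
        reported_pairs = {(m, g) for m, g in reported}
    planted = truth.repressive_pairs()
    hits = reported_pairs & planted

    def class_recall(pairs: list[tuple[str, str, str]]) -> float:
        keys = {(m, g) for m, g, _ in pairs}
        return len(keys & reported_pairs) / len(keys) if keys else float("nan")

    return RecoveryReport(
        precision=(len(hits) / len(reported_pairs)) if reported_pairs else None,
        recall=(len(hits) / len(planted)) if planted else float("nan"),
        per_class_recall={
            "repressor": class_recall(truth.repressor_pairs),
            "weak": class_recall(truth.weak_pairs),
        },
        n_reported=len(reported_pairs),
        n_planted=len(planted),
        false_positives=sorted(reported_pairs - planted),
    )
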