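"""End-to-end orchestration: normalize -> filter -> summarize -> differential ->
correlate -> integrate -> genome context -> enrichment.

Each stage is a pure function from files to files inside one run directory, so
any stage can be re-run from cached upstream outputs and reproduces its output
bit-identically. ``run_pipeline`` chains the stages and writes a manifest
recording parameters, input checksums and per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .correlation import correlate_all
from .design import read_design
from .differential import call_differential, differential_transcripts
from .enrichment import enrich_per_mirna, read_gmt
from .expression import (
    ExpressionMatrix,
    condition_geometric_means,
    filter_low_intensity,
    normalize_pm_only,
    read_expression_table,
)
from .genome_context import (
    classify_loci,
    cluster_mirnas,
    host_gene_relation,
    read_gene_models_gff3,
    read_mirna_loci_bed,
    read_mirna_loci_gff3,
)
from .targets import (
    integrate_high_confidence,
    load_external_predictions,
    load_validated_pairs,
    predict_all_seed_sites,
)

logger = logging.getLogger("mirpair")


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 in the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3 in the CLI)."""


@dataclass
class RunConfig:
    """All inputs and stage parameters of one pipeline run."""

    # inputs
    mirna_matrix: str = ""
    mrna_matrix: str = ""
    design: str = ""
    mirna_fasta: str | None = None
    utr_fasta: str | None = None
    gene_models: str | None = None
    mirna_loci: str | None = None
    predictions: list[str] = field(default_factory=list)
    validated: str | None = None
    gene_sets: str | None = None
    outdir: str = "mirpair_run"
    # parameters
    normalize: bool = True
    norm_target: float = 100.0
    trim_fraction: float = 0.02
    intensity_threshold: float = 10.0
    floor: float = 0.5
    fc_threshold: float = 1.5
    alpha: float = 0.05
    gate: str = "either"
    adjust_method: str = "fdr_bh"
    rho_cut: float = 0.8
    correlation_universe: str = "differential"  # or "all"
    prediction_mode: str = "intersection"
    max_gap: int = 10_000
    host_cut_hi: float = 0.5
    host_cut_neg: float = -0.3
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ConfigError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.fc_threshold < 1:
            raise ConfigError("fc_threshold must be >= 1")
        if not (0 <= self.rho_cut < 1):
            raise ConfigError("rho_cut must lie in [0, 1)")
        if self.max_gap < 0:
            raise ConfigError("max_gap must be non-negative")
        if self.intensity_threshold < 0:
            raise ConfigError("intensity_threshold must be non-negative")
        if not (0 <= self.trim_fraction < 0.5):
            raise ConfigError("trim_fraction must lie in [0, 0.5)")
        if self.floor <= 0:
            raise ConfigError("floor must be positive")
        if self.correlation_universe not in ("differential", "all"):
            raise ConfigError("correlation_universe must be 'differential' or 'all'")
        if self.prediction_mode not in ("intersection", "union"):
            raise ConfigError("prediction_mode must be 'intersection' or 'union'")
        if self.gate not in ("either", "both", "anova", "mw"):
            raise ConfigError("gate must be one of either/both/anova/mw")
        for name in ("mirna_matrix", "mrna_matrix", "design"):
            path = getattr(self, name)
            if not path:
                raise ConfigError(f"{name} input is required")
            if not Path(path).exists():
                raise ConfigError(f"{name}: no such file {path}")
        optional = [self.mirna_fasta, self.utr_fasta, self.gene_models, self.mirna_loci,
                    self.validated, self.gene_sets, *self.predictions]
        for path in optional:
            if path and not Path(path).exists():
                raise ConfigError(f"no such file: {path}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        flat: dict = {}
        for key, value in data.items():
            if key in ("inputs", "params") and isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        unknown = set(flat) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)


def config_for_study(paths: dict, outdir, seed: int = 0, normalize: bool = False, **overrides) -> RunConfig:
    """RunConfig wired to a written synthetic study (see SyntheticStudy.write).

    Normalization defaults off here because the generator emits intensities on
    one coherent scale already.
    """
    cfg = RunConfig(
        mirna_matrix=str(paths["mirna_matrix"]),
        mrna_matrix=str(paths["mrna_matrix"]),
        design=str(paths["design"]),
        mirna_fasta=str(paths["mirna_fasta"]),
        utr_fasta=str(paths["utr_fasta"]),
        gene_models=str(paths["gene_models"]),
        mirna_loci=str(paths["mirna_loci"]),
        predictions=[str(paths["predictions_a"]), str(paths["predictions_b"])],
        validated=str(paths["validated"]),
        gene_sets=str(paths["gene_sets"]),
        outdir=str(outdir),
        normalize=normalize,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def _read_ids(path) -> set[str]:
    text = Path(path).read_text()
    return {line for line in text.splitlines() if line}


def _write_ids(ids, path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in sorted(ids)))


# ---------------------------------------------------------------------------
# stages


def stage_preprocess(cfg: RunConfig) -> dict:
    out = _outdir(cfg)
    design = read_design(cfg.design)
    counts: dict = {}
    for channel, path in (("mirna", cfg.mirna_matrix), ("mrna", cfg.mrna_matrix)):
        matrix = read_expression_table(path, design, channel)
        if cfg.normalize:
            matrix = normalize_pm_only(matrix, cfg.norm_target, cfg.trim_fraction)
        filtered, removed = filter_low_intensity(matrix, cfg.intensity_threshold)
        profiles = condition_geometric_means(filtered, design, cfg.floor)
        filtered.write(out / f"{channel}_filtered.tsv")
        profiles.to_csv(out / f"{channel}_profiles.tsv", sep="\t", index_label="transcript")
        _write_ids(removed, out / f"{channel}_removed.txt")
        counts[f"n_{channel}_input"] = int(matrix.values.shape[0])
        counts[f"n_{channel}_removed_low_intensity"] = len(removed)
        counts[f"n_{channel}_retained"] = int(filtered.values.shape[0])
    logger.info("preprocess: %s", counts)
    return counts


def stage_differential(cfg: RunConfig) -> dict:
    out = _outdir(cfg)
    design = read_design(cfg.design)
    counts: dict = {}
    for channel in ("mirna", "mrna"):
        matrix = ExpressionMatrix(
            pd.read_csv(out / f"{channel}_filtered.tsv", sep="\t", index_col=0), channel
        )
        profiles = _read_profiles(out / f"{channel}_profiles.tsv")
        calls = call_differential(
            profiles,
            matrix,
            design,
            fc_threshold=cfg.fc_threshold,
            alpha=cfg.alpha,
            gate=cfg.gate,
            adjust_method=cfg.adjust_method,
        )
        calls.to_csv(out / f"{channel}_differential.tsv", sep="\t", index=False)
        diff_ids = differential_transcripts(calls)
        _write_ids(diff_ids, out / f"{channel}_differential_ids.txt")
        counts[f"n_{channel}_differential"] = len(diff_ids)
        baseline = design.baseline_contrast()[0]
        counts[f"n_{channel}_differential_baseline"] = len(
            differential_transcripts(calls, [baseline])
        )
        counts[f"n_{channel}_treatment_responsive"] = len(
            differential_transcripts(
                calls, [name for name, _, _ in design.treatment_contrasts()]
            )
        )
    logger.info("differential: %s", counts)
    return counts


def stage_correlate(cfg: RunConfig) -> dict:
    out = _outdir(cfg)
    mirna_profiles = _read_profiles(out / "mirna_profiles.tsv")
    mrna_profiles = _read_profiles(out / "mrna_profiles.tsv")
    diff_mirnas = _read_ids(out / "mirna_differential_ids.txt")
    mirna_profiles = mirna_profiles.loc[sorted(set(mirna_profiles.index) & diff_mirnas)]
    if cfg.correlation_universe == "differential":
        diff_mrnas = _read_ids(out / "mrna_differential_ids.txt")
        mrna_profiles = mrna_profiles.loc[sorted(set(mrna_profiles.index) & diff_mrnas)]
    pairs, summary = correlate_all(
        mirna_profiles, mrna_profiles, rho_cut=cfg.rho_cut, alpha=cfg.alpha
    )
    pairs.to_csv(out / "correlation_pairs.tsv", sep="\t", index=False)
    (out / "correlation_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("correlate: %s", summary)
    return summary


def stage_integrate(cfg: RunConfig) -> dict:
    out = _outdir(cfg)
    pairs = pd.read_csv(out / "correlation_pairs.tsv", sep="\t")
    diff_mrnas = _read_ids(out / "mrna_differential_ids.txt")
    imported = (
        load_external_predictions(cfg.predictions, mode=cfg.prediction_mode)
        if cfg.predictions
        else set()
    )
    seed_pred: set[tuple[str, str]] = set()
    if cfg.mirna_fasta and cfg.utr_fasta:
        mirna_seqs = {r.id: str(r.seq) for r in SeqIO.parse(cfg.mirna_fasta, "fasta")}
        utr_seqs = {r.id: str(r.seq) for r in SeqIO.parse(cfg.utr_fasta, "fasta")}
        seed_pred, _sites = predict_all_seed_sites(mirna_seqs, utr_seqs)
    validated = load_validated_pairs(cfg.validated) if cfg.validated else set()
    regulatory, n_high_genes = integrate_high_confidence(
        pairs,
        differential_mrnas=diff_mrnas,
        predictions_imported=imported,
        predictions_seed=seed_pred,
        validated=validated,
        rho_cut=cfg.rho_cut,
        alpha=cfg.alpha,
    )
    regulatory.to_csv(out / "regulatory_pairs.tsv", sep="\t", index=False)
    counts = {
        "n_predicted_imported": len(imported),
        "n_predicted_seed": len(seed_pred),
        "n_pairs_integrated": int(regulatory.shape[0]),
        "n_high_confidence_pairs": int((regulatory["tier"] == "high-confidence").sum()),
        "n_high_confidence_genes": n_high_genes,
        "n_validated_flagged": int(regulatory["validated"].sum()),
    }
    logger.info("integrate: %s", counts)
    return counts


def stage_context(cfg: RunConfig) -> dict:
    out = _outdir(cfg)
    if not (cfg.gene_models and cfg.mirna_loci):
        logger.info("context: skipped (no gene models / loci)")
        return {"skipped": True}
    models = read_gene_models_gff3(cfg.gene_models)
    if str(cfg.mirna_loci).endswith(".bed"):
        loci = read_mirna_loci_bed(cfg.mirna_loci)
    else:
        loci = read_mirna_loci_gff3(cfg.mirna_loci)
    classified = classify_loci(loci, models)
    pd.DataFrame(
        [
            {
                "mirna": l.mirna,
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "strand": l.strand,
                "context": l.context,
                "host_gene": l.host_gene if l.host_gene else "",
                "orientation": l.orientation,
            }
            for l in classified
        ]
    ).to_csv(out / "locus_classification.tsv", sep="\t", index=False)
    clusters, singletons = cluster_mirnas(classified, max_gap=cfg.max_gap)
    pd.DataFrame(
        [
            {
                "cluster": f"cluster-{i + 1:02d}",
                "chrom": c.chrom,
                "start": c.span[0],
                "end": c.span[1],
                "n_members": len(c.members),
                "members": ",".join(m.mirna for m in c.members),
            }
            for i, c in enumerate(clusters)
        ]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)

    mirna_profiles = _read_profiles(out / "mirna_profiles.tsv")
    mrna_profiles = _read_profiles(out / "mrna_profiles.tsv")
    relations = []
    for locus in classified:
        if locus.context == "intronic" and locus.host_gene in mrna_profiles.index and locus.mirna in mirna_profiles.index:
            rel = host_gene_relation(
                locus.mirna,
                locus.host_gene,
                mirna_profiles.loc[locus.mirna].to_numpy(),
                mrna_profiles.loc[locus.host_gene].to_numpy(),
                cut_hi=cfg.host_cut_hi,
                cut_neg=cfg.host_cut_neg,
            )
            relations.append(
                {
                    "mirna": rel.mirna,
                    "host_gene": rel.host_gene,
                    "rho": rel.rho,
                    "category": rel.category,
                    "flagged": rel.flagged,
                    "cut_hi": cfg.host_cut_hi,
                    "cut_neg": cfg.host_cut_neg,
                }
            )
    pd.DataFrame(
        relations, columns=["mirna", "host_gene", "rho", "category", "flagged", "cut_hi", "cut_neg"]
    ).to_csv(out / "host_relations.tsv", sep="\t", index=False)
    counts = {
        "n_intergenic": sum(l.context == "intergenic" for l in classified),
        "n_intronic": sum(l.context == "intronic" for l in classified),
        "n_exonic": sum(l.context == "exonic" for l in classified),
        "n_reverse_strand": sum(l.strand == "-" for l in classified),
        "n_clusters": len(clusters),
        "n_singletons": len(singletons),
        "n_host_correlated": sum(r["category"] == "correlated" for r in relations),
        "n_host_poor": sum(r["category"] == "poor" for r in relations),
        "n_host_negative": sum(r["category"] == "negative" for r in relations),
    }
    logger.info("context: %s", counts)
    return counts


def stage_enrich(cfg: RunConfig) -> dict:
    out = _outdir(cfg)
    if not cfg.gene_sets:
        logger.info("enrich: skipped (no gene sets)")
        return {"skipped": True}
    regulatory = pd.read_csv(out / "regulatory_pairs.tsv", sep="\t")
    high = regulatory[regulatory["tier"] == "high-confidence"]
    targets_by_mirna = {
        mirna: set(group["mrna"]) for mirna, group in high.groupby("mirna")
    }
    universe = set(_read_profiles(out / "mrna_profiles.tsv").index)
    gene_sets = read_gmt(cfg.gene_sets)
    results = enrich_per_mirna(targets_by_mirna, gene_sets, universe, cfg.adjust_method)
    frames = []
    for mirna, frame in results.items():
        frame = frame.copy()
        frame.insert(0, "mirna", mirna)
        frames.append(frame)
    combined = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["mirna", "term", "k", "K", "n", "N", "p_hyper", "p_adj"])
    )
    combined.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    counts = {
        "n_mirnas_enriched": len(targets_by_mirna),
        "n_enrichment_rows": int(combined.shape[0]),
        "n_terms_significant": int((combined["p_adj"] <= cfg.alpha).sum())
        if not combined.empty
        else 0,
    }
    logger.info("enrich: %s", counts)
    return counts


_STAGES = (
    ("preprocess", stage_preprocess),
    ("differential", stage_differential),
    ("correlate", stage_correlate),
    ("integrate", stage_integrate),
    ("context", stage_context),
    ("enrich", stage_enrich),
)


def run_pipeline(cfg: RunConfig) -> dict:
    """Validate, run all stages in order, and write ``manifest.json``.

    Returns the manifest. Any stage failure raises :class:`StageError` naming
    the stage; outputs of completed stages remain on disk and the manifest is
    flagged partial.
    """
    cfg.validate()
    out = _outdir(cfg)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        inputs = {}
        for name in (
            "mirna_matrix", "mrna_matrix", "design", "mirna_fasta", "utr_fasta",
            "gene_models", "mirna_loci", "validated", "gene_sets",
        ):
            path = getattr(cfg, name)
            if path:
                inputs[name] = {"path": str(path), "sha256": _sha256(path)}
        for i, path in enumerate(cfg.predictions):
            inputs[f"predictions_{i}"] = {"path": str(path), "sha256": _sha256(path)}
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "parameters": asdict(cfg),
            "inputs": inputs,
            "stages": {},
            "complete": False,
        }
        for name, stage in _STAGES:
            try:
                manifest["stages"][name] = stage(cfg)
            except Exception as exc:
                manifest["stages"][name] = {"error": str(exc)}
                (out / "manifest.json").write_text(
                    json.dumps(manifest, indent=2, sort_keys=True)
                )
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["complete"] = True
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()
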