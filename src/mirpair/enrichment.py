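"""Hypergeometric over-representation of miRNA target sets in annotation gene sets.

For each miRNA the genes it is inferred to repress are tested against every
annotation term: with N universe genes, K of them in the term, and n genes in
the target set, the upper-tail probability P(X >= k) of drawing k or more term
genes measures over-representation. The default universe is the expressed
genes (those surviving the intensity filter) rather than the whole genome, to
avoid expression-bias inflation. Adjustment is Benjamini-Hochberg across terms
within each miRNA.
"""

from __future__ import annotations

import warnings

import pandas as pd
from gseapy import read_gmt as _gseapy_read_gmt
from scipy import stats

from .differential import adjust_pvalues


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT gene sets as {term: set of genes}."""
    return {term: set(genes) for term, genes in _gseapy_read_gmt(str(path)).items()}


def write_gmt(gene_sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as handle:
        for term in gene_sets:
            genes = "\t".join(sorted(gene_sets[term]))
            handle.write(f"{term}\t{description}\t{genes}\n")


def hypergeometric_enrichment(
    target_set,
    gene_sets: dict[str, set[str]],
    universe,
    adjust_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Score every term for over-representation of the target set.

    Targets outside the universe are dropped with a warning; terms are
    intersected with the universe and empty intersections are not scored.
    Returns rows (term, k, K, n, N, p_hyper, p_adj) sorted by ascending p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    target_set = set(target_set)
    outside = target_set - universe
    if outside:
        warnings.warn(
            f"{len(outside)} target genes outside the universe were dropped",
            stacklevel=2,
        )
    targets = target_set & universe
    if not targets:
        warnings.warn("empty target set; no enrichment computed", stacklevel=2)
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p_hyper", "p_adj"])

    big_n = len(universe)
    n = len(targets)
    records = []
    for term in sorted(gene_sets):
        term_genes = gene_sets[term] & universe
        if not term_genes:
            continue
        big_k = len(term_genes)
        k = len(targets & term_genes)
        # upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        records.append({"term": term, "k": k, "K": big_k, "n": n, "N": big_n, "p_hyper": p})
    out = pd.DataFrame.from_records(
        records, columns=["term", "k", "K", "n", "N", "p_hyper"]
    )
    if out.empty:
        out["p_adj"] = []
        return out
    out["p_adj"] = adjust_pvalues(out["p_hyper"].to_numpy(), method=adjust_method)
    return out.sort_values(["p_hyper", "term"]).reset_index(drop=True)


def enrich_per_mirna(
    targets_by_mirna: dict[str, set[str]],
    gene_sets: dict[str, set[str]],
    universe,
    adjust_method: str = "fdr_bh",
) -> dict[str, pd.DataFrame]:
    """Per-miRNA enrichment; BH adjustment is applied within each miRNA's terms."""
    return {
        mirna: hypergeometric_enrichment(targets, gene_sets, universe, adjust_method)
        for mirna, targets in sorted(targets_by_mirna.items())
    }
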