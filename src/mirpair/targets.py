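"""Target prediction (seed matching), imported prediction tables, and integration.

The internal predictor is a canonical seed matcher: it scans a 3'UTR for the
reverse complement of miRNA nucleotides 2-7 and classifies each hit as 6mer,
7mer-A1 (adenosine opposite miRNA position 1), 7mer-m8 (complement of miRNA
position 8), or 8mer (both). It deliberately implements only this sequence
primitive — no free-energy or conservation scoring — and shares its schema
with predictions imported from external tools so both routes can be combined.

Integration assigns each (miRNA, mRNA) pair a confidence tier: a pair is
high-confidence iff it is predicted (by any route), negatively correlated
beyond the configured cutoffs, and its mRNA is differentially expressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_VALID_UTR = set("ACGTN")
_VALID_MIRNA = set("ACGT")


@dataclass(frozen=True)
class TargetSite:
    """One seed-match site on a UTR (0-based, half-open coordinates)."""

    mirna: str
    transcript: str
    start: int
    end: int
    site_type: str


def _normalize_nucleotides(seq: str, name: str, allow_n: bool = False) -> str:
    """Uppercase, RNA->DNA (U->T); fail with position on an invalid character."""
    out = seq.upper().replace("U", "T")
    valid = _VALID_UTR if allow_n else _VALID_MIRNA
    for pos, ch in enumerate(out):
        if ch not in valid:
            raise ValueError(f"{name}: invalid character {seq[pos]!r} at position {pos}")
    return out


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def find_seed_sites(
    mirna_seq: str,
    utr_seq: str,
    mirna_id: str = "mirna",
    transcript_id: str = "utr",
) -> list[TargetSite]:
    """Scan a 3'UTR (5'->3') for canonical seed sites of a mature miRNA (5'->3').

    The seed is miRNA nucleotides 2-7; a site is an exact match of its reverse
    complement on the UTR. Classification follows the canonical convention:
    the 5' flank of the match pairing miRNA position 8 upgrades to 7mer-m8,
    an adenosine on the 3' flank (opposite miRNA position 1) upgrades to
    7mer-A1, and both together give an 8mer. One site is reported per distinct
    match start. Both sequences may be given as DNA or RNA.
    """
    mirna = _normalize_nucleotides(mirna_seq, f"miRNA {mirna_id}")
    if len(mirna) < 8:
        raise ValueError(f"miRNA {mirna_id}: need at least 8 nucleotides")
    utr = _normalize_nucleotides(utr_seq, f"UTR {transcript_id}", allow_n=True)
    if not utr:
        raise ValueError(f"UTR {transcript_id}: empty sequence")

    seed_match = _revcomp(mirna[1:7])
    m8_complement = _COMPLEMENT[mirna[7]]
    sites: list[TargetSite] = []
    start = utr.find(seed_match)
    while start != -1:
        m8 = start > 0 and utr[start - 1] == m8_complement
        a1 = start + 6 < len(utr) and utr[start + 6] == "A"
        if m8 and a1:
            site_type, s, e = "8mer", start - 1, start + 7
        elif m8:
            site_type, s, e = "7mer-m8", start - 1, start + 6
        elif a1:
            site_type, s, e = "7mer-A1", start, start + 7
        else:
            site_type, s, e = "6mer", start, start + 6
        sites.append(TargetSite(mirna_id, transcript_id, s, e, site_type))
        start = utr.find(seed_match, start + 1)
    return sites


def predict_all_seed_sites(
    mirna_seqs: dict[str, str], utr_seqs: dict[str, str]
) -> tuple[set[tuple[str, str]], list[TargetSite]]:
    """Run the seed matcher over every miRNA x UTR combination.

    Returns the predicted (mirna, gene) pair set (any-site-hit collapses to
    gene level) together with the full site list.
    """
    sites: list[TargetSite] = []
    for mirna_id, mseq in mirna_seqs.items():
        for gene_id, useq in utr_seqs.items():
            sites.extend(find_seed_sites(mseq, useq, mirna_id, gene_id))
    return {(s.mirna, s.transcript) for s in sites}, sites


def load_external_predictions(paths, mode: str = "intersection") -> set[tuple[str, str]]:
    """Load one or more predicted-target tables (TSV with columns mirna, gene).

    Multiple tables are combined by set ``intersection`` (default — a pair must
    be supported by every source) or ``union``. Rows are deduplicated.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown combination mode {mode!r}")
    sets = []
    for path in paths:
        table = pd.read_csv(path, sep="\t")
        missing = {"mirna", "gene"} - set(table.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        sets.append(set(zip(table["mirna"].astype(str), table["gene"].astype(str))))
    if not sets:
        return set()
    out = sets[0]
    for s in sets[1:]:
        out = (out & s) if mode == "intersection" else (out | s)
    return out


def load_validated_pairs(path) -> set[tuple[str, str]]:
    """Load an experimentally-validated interaction table (columns mirna, gene[, source])."""
    table = pd.read_csv(path, sep="\t")
    missing = {"mirna", "gene"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return set(zip(table["mirna"].astype(str), table["gene"].astype(str)))


def annotate_validated(pairs: pd.DataFrame, validated: set[tuple[str, str]]) -> pd.DataFrame:
    """Add/overwrite a boolean ``validated`` column; duplicate table rows are harmless."""
    out = pairs.copy()
    out["validated"] = [
        (m, g) in validated for m, g in zip(out["mirna"], out["mrna"])
    ]
    return out


def integrate_high_confidence(
    correlations: pd.DataFrame,
    differential_mrnas: set[str],
    predictions_imported: set[tuple[str, str]] | None = None,
    predictions_seed: set[tuple[str, str]] | None = None,
    validated: set[tuple[str, str]] | None = None,
    rho_cut: float = 0.8,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Combine correlations, predictions and differential calls into tiers.

    The pair universe is (passing correlations) ∪ (predicted pairs). Tier
    assignment:

    * ``high-confidence`` — predicted (any route) AND negatively correlated
      with |rho| > rho_cut, p <= alpha AND the mRNA is differential;
    * ``correlated-only`` — a passing correlation that misses the
      high-confidence requirements;
    * ``predicted-only`` — predicted but with no passing correlation.

    Returns the annotated pair table and the count of unique high-confidence
    genes. Fails if the miRNA and mRNA id namespaces collide.
    """
    predictions_imported = predictions_imported or set()
    predictions_seed = predictions_seed or set()
    validated = validated or set()
    predicted_pairs = predictions_imported | predictions_seed

    mirna_ids = set(correlations["mirna"]) | {m for m, _ in predicted_pairs}
    mrna_ids = set(correlations["mrna"]) | {g for _, g in predicted_pairs}
    collision = mirna_ids & mrna_ids
    if collision:
        raise ValueError(f"id namespace collision between channels: {sorted(collision)[:5]}")

    corr_by_pair = {
        (row.mirna, row.mrna): row for row in correlations.itertuples(index=False)
    }
    universe = sorted(set(corr_by_pair) | predicted_pairs)

    records = []
    for mirna, mrna in universe:
        row = corr_by_pair.get((mirna, mrna))
        rho = float(row.rho) if row is not None else float("nan")
        p = float(row.p) if row is not None else float("nan")
        sign = row.sign_class if row is not None else "none"
        in_seed = (mirna, mrna) in predictions_seed
        in_imported = (mirna, mrna) in predictions_imported
        if in_seed and in_imported:
            predicted = "both"
        elif in_seed:
            predicted = "seed-match"
        elif in_imported:
            predicted = "imported"
        else:
            predicted = "none"
        is_diff = mrna in differential_mrnas
        high = (
            predicted != "none"
            and sign == "negative"
            and abs(rho) > rho_cut
            and p <= alpha
            and is_diff
        )
        if high:
            tier = "high-confidence"
        elif row is not None:
            tier = "correlated-only"
        else:
            tier = "predicted-only"
        records.append(
            {
                "mirna": mirna,
                "mrna": mrna,
                "rho": rho,
                "p": p,
                "sign_class": sign,
                "predicted": predicted,
                "validated": (mirna, mrna) in validated,
                "differential_mrna": is_diff,
                "tier": tier,
            }
        )
    out = pd.DataFrame.from_records(
        records,
        columns=[
            "mirna",
            "mrna",
            "rho",
            "p",
            "sign_class",
            "predicted",
            "validated",
            "differential_mrna",
            "tier",
        ],
    )
    n_high_genes = int(out.loc[out["tier"] == "high-confidence", "mrna"].nunique())
    return out, n_high_genes
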