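"""Expression matrices: reading, normalization, intensity filtering, summarization.

The array platform here carries perfect-match probes only; its vendor's
normalization is proprietary, so :func:`normalize_pm_only` is a documented
stand-in (per-sample two-sided trimmed-mean scaling, MAS5-like in spirit).
Transcripts whose maximum intensity across all samples falls below a noise
threshold are removed, and each surviving transcript is summarized into one
geometric mean per condition, ordered by the study design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import StudyDesign


@dataclass
class ExpressionMatrix:
    """Transcripts x samples intensity table for one channel.

    ``values`` is a DataFrame indexed by unique transcript id with one column
    per sample; intensities are non-negative reals with no missing cells.
    ``channel`` is ``"mirna"`` or ``"mrna"``.
    """

    values: pd.DataFrame
    channel: str

    def __post_init__(self) -> None:
        if self.channel not in ("mirna", "mrna"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate transcript ids: {dupes}")

    @property
    def transcripts(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="transcript")


def read_expression_table(path, design: StudyDesign, channel: str, sep: str = "\t") -> ExpressionMatrix:
    """Read a delimited transcripts-x-samples table and validate it against the design.

    The header row names samples; all design samples must be present (extra
    columns are dropped). Fails with coordinates on negative or non-numeric
    cells and on duplicate transcript ids.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0)
    raw.index = raw.index.astype(str)
    for sample in design.samples:
        if sample not in raw.columns:
            raise ValueError(f"{path}: missing sample column {sample!r}")
    table = raw[design.samples]

    numeric = table.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & table.notna()
    if bad.to_numpy().any():
        row, col = next(zip(*np.nonzero(bad.to_numpy())))
        raise ValueError(
            f"{path}: non-numeric cell {table.iat[row, col]!r} at "
            f"transcript {table.index[row]!r}, sample {table.columns[col]!r}"
        )
    if numeric.isna().to_numpy().any():
        row, col = next(zip(*np.nonzero(numeric.isna().to_numpy())))
        raise ValueError(
            f"{path}: missing cell at transcript {table.index[row]!r}, "
            f"sample {table.columns[col]!r}"
        )
    neg = numeric.to_numpy() < 0
    if neg.any():
        row, col = next(zip(*np.nonzero(neg)))
        raise ValueError(
            f"{path}: negative intensity {numeric.iat[row, col]} at "
            f"transcript {table.index[row]!r}, sample {table.columns[col]!r}"
        )
    if numeric.index.duplicated().any():
        dupes = numeric.index[numeric.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate transcript ids: {dupes}")
    return ExpressionMatrix(values=numeric.astype(float), channel=channel)


def normalize_pm_only(
    matrix: ExpressionMatrix, target: float = 100.0, trim_fraction: float = 0.02
) -> ExpressionMatrix:
    """Scale each sample so its two-sided trimmed mean equals ``target``.

    This is a stand-in for the array vendor's unpublished PM-only algorithm:
    a pure per-sample rescaling, so within-sample intensity ratios are
    preserved exactly. ``trim_fraction`` is the proportion cut from each tail
    before averaging.
    """
    if target <= 0:
        raise ValueError("target must be positive")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    scaled = matrix.values.copy()
    for sample in scaled.columns:
        col = scaled[sample].to_numpy()
        if not (col > 0).any():
            raise ValueError(f"sample {sample!r} has no positive intensity")
        tm = stats.trim_mean(col, trim_fraction)
        if tm <= 0:
            raise ValueError(f"sample {sample!r}: trimmed mean is non-positive")
        scaled[sample] = col * (target / tm)
    return replace(matrix, values=scaled)


def filter_low_intensity(
    matrix: ExpressionMatrix, threshold: float = 10.0
) -> tuple[ExpressionMatrix, list[str]]:
    """Remove transcripts whose maximum intensity over all samples is below threshold.

    A transcript is retained iff its max across every sample is >= threshold;
    only strictly-lower maxima are removed. Returns the filtered matrix and
    the removed transcript ids.
    """
    maxima = matrix.values.max(axis=1)
    keep = maxima >= threshold
    removed = list(matrix.values.index[~keep])
    return replace(matrix, values=matrix.values.loc[keep]), removed


def condition_geometric_means(
    matrix: ExpressionMatrix, design: StudyDesign, floor: float = 0.5
) -> pd.DataFrame:
    """Per-condition geometric means of the replicates, ordered by the design.

    Intensities are clipped to ``floor`` (> 0) before the log so zero cells
    cannot annihilate the product; the result is a transcripts x conditions
    DataFrame of strictly positive values — the 6-point profiles X_i / Y_i
    that feed the rank-correlation stage.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    clipped = matrix.values.clip(lower=floor)
    out = {}
    for condition in design.conditions:
        reps = clipped[design.samples_for(condition)]
        out[condition] = np.exp(np.log(reps).mean(axis=1))
    return pd.DataFrame(out, index=matrix.values.index)[list(design.conditions)]
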