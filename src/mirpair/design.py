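"""Study design: ordered cellular states and the sample -> (condition, replicate) map.

The reference design is six ordered states — hormone-receptor-negative cells,
receptor-positive cells, and four time points of hormone exposure — profiled in
triplicate (18 samples per channel). All downstream summaries (per-condition
geometric means, contrasts, rank correlations over the six states) take their
ordering from this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Canonical condition order: receptor-negative, receptor-positive, then
#: 1/4/8/20 h of hormone exposure.
DEFAULT_CONDITIONS: tuple[str, ...] = ("LHR-", "LHR+", "LH1", "LH4", "LH8", "LH20")


@dataclass(frozen=True)
class StudyDesign:
    """Ordered conditions plus a sample map.

    Parameters
    ----------
    conditions
        Condition labels in their fixed biological order (index 0..k-1).
    sample_map
        Mapping ``sample id -> (condition, replicate)``. Sample ids must be
        unique and every condition must own at least one sample.
    """

    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    sample_map: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.conditions) < 2:
            raise ValueError("design needs at least two conditions")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if not self.sample_map:
            object.__setattr__(
                self,
                "sample_map",
                {
                    f"{c}_r{r}": (c, r)
                    for c in self.conditions
                    for r in (1, 2, 3)
                },
            )
        known = set(self.conditions)
        seen: set[str] = set()
        for sample, (cond, _rep) in self.sample_map.items():
            if cond not in known:
                raise ValueError(f"sample {sample!r} maps to unknown condition {cond!r}")
            seen.add(cond)
        missing = known - seen
        if missing:
            raise ValueError(f"conditions without samples: {sorted(missing)}")

    # -- accessors ---------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        """All sample ids, ordered by condition order then replicate index."""
        order = {c: i for i, c in enumerate(self.conditions)}
        return sorted(self.sample_map, key=lambda s: (order[self.sample_map[s][0]], self.sample_map[s][1]))

    def samples_for(self, condition: str) -> list[str]:
        if condition not in self.conditions:
            raise ValueError(f"unknown condition {condition!r}")
        return [
            s
            for s in sorted(self.sample_map, key=lambda s: self.sample_map[s][1])
            if self.sample_map[s][0] == condition
        ]

    @property
    def replicates_per_condition(self) -> int:
        """Common replicate count across conditions (the study uses 3)."""
        counts = {c: len(self.samples_for(c)) for c in self.conditions}
        values = set(counts.values())
        if len(values) != 1:
            raise ValueError(f"unbalanced design: {counts}")
        return values.pop()

    # -- contrasts ---------------------------------------------------------

    def baseline_contrast(self) -> tuple[str, str, str]:
        """(name, reference, test) for the receptor contrast (index 1 vs 0)."""
        ref, test = self.conditions[0], self.conditions[1]
        return (f"{test}_vs_{ref}", ref, test)

    def treatment_contrasts(self) -> list[tuple[str, str, str]]:
        """Each hormone time point (index >= 2) against the receptor-positive state."""
        ref = self.conditions[1]
        return [(f"{c}_vs_{ref}", ref, c) for c in self.conditions[2:]]

    def contrasts(self) -> list[tuple[str, str, str]]:
        return [self.baseline_contrast(), *self.treatment_contrasts()]

    # -- io ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample": s, "condition": c, "replicate": r}
            for s, (c, r) in self.sample_map.items()
        ]
        frame = pd.DataFrame(rows)
        order = {c: i for i, c in enumerate(self.conditions)}
        return frame.sort_values(
            by=["condition", "replicate"], key=lambda col: col.map(order) if col.name == "condition" else col
        ).reset_index(drop=True)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_design(path, conditions: tuple[str, ...] = DEFAULT_CONDITIONS) -> StudyDesign:
    """Read a design table (columns: sample, condition, replicate)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str})
    required = {"sample", "condition", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"design file {path} lacks columns: {sorted(missing)}")
    if frame["sample"].duplicated().any():
        dupes = frame.loc[frame["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids in design: {dupes}")
    sample_map = {
        row.sample: (row.condition, int(row.replicate)) for row in frame.itertuples()
    }
    present = [c for c in conditions if c in set(frame["condition"])]
    return StudyDesign(conditions=tuple(present), sample_map=sample_map)
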