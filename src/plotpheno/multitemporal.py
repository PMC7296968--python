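"""Multi-temporal feature accumulation across phenological stages.

Cassava stages, in order: EL (elongation), EBK (early bulking), LBK (late
bulking), DMA (dry-matter accumulation). A stage combination sums (or
averages) each of the 77 per-stage features over its member stages, widening
the predictor set; nine combinations turn 77 columns into 693.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import MissingStageError, PlotPhenoError
from .features import FEATURE_COLUMNS

STAGES = ("EL", "EBK", "LBK", "DMA")


@dataclass(frozen=True)
class StageCombination:
    """Ordered subset of stages, e.g. label "EL+EBK" for (EL, EBK)."""

    stages: tuple[str, ...]

    def __post_init__(self):
        if not self.stages:
            raise PlotPhenoError("empty stage combination")
        if len(set(self.stages)) != len(self.stages):
            raise PlotPhenoError(f"duplicate stages in {self.stages}")
        order = [STAGES.index(s) for s in self.stages]  # KeyError -> ValueError
        if order != sorted(order):
            raise PlotPhenoError(f"stages out of phenological order: {self.stages}")

    @property
    def label(self) -> str:
        return "+".join(self.stages)

    @classmethod
    def parse(cls, label: str) -> "StageCombination":
        return cls(tuple(label.split("+")))


def default_combinations() -> list[StageCombination]:
    """Shipped default: singletons, cumulative prefixes from EL, and EL+LBK."""
    combos = [StageCombination((s,)) for s in STAGES]
    for k in range(2, len(STAGES) + 1):
        combos.append(StageCombination(STAGES[:k]))
    combos.append(StageCombination(("EL", "LBK")))
    return combos


def accumulate_stages(table: pd.DataFrame,
                      combos: list[StageCombination] | None = None,
                      op: str = "sum") -> pd.DataFrame:
    """Widen a multi-stage feature table to one row per plot.

    For each combination and each base feature a column
    ``{feature}_{label}`` holds the sum (default) or mean of that feature
    over the combination's stages. Output column count = 77 x len(combos).
    """
    if op not in ("sum", "mean"):
        raise PlotPhenoError(f"unknown accumulation op {op!r}")
    combos = combos if combos is not None else default_combinations()

    feature_cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    if len(feature_cols) != len(FEATURE_COLUMNS):
        missing = set(FEATURE_COLUMNS) - set(feature_cols)
        raise PlotPhenoError(f"feature table missing columns: {sorted(missing)}")

    by_stage = {stage: sub.set_index("plot_id")
                for stage, sub in table.groupby("timing_point")}
    plot_ids = list(dict.fromkeys(table["plot_id"]))

    needed = {s for c in combos for s in c.stages}
    for stage in needed:
        if stage not in by_stage:
            raise MissingStageError(plot_ids[0], stage)
        present = set(by_stage[stage].index)
        for pid in plot_ids:
            if pid not in present:
                raise MissingStageError(pid, stage)

    pieces = []
    for combo in combos:
        acc = sum(by_stage[s].loc[plot_ids, feature_cols].astype(float)
                  for s in combo.stages)
        if op == "mean":
            acc = acc / len(combo.stages)
        acc.columns = [f"{c}_{combo.label}" for c in feature_cols]
        pieces.append(acc)
    wide = pd.concat(pieces, axis=1)
    wide = wide[sorted(wide.columns)]
    wide.insert(0, "plot_id", plot_ids)
    return wide.reset_index(drop=True)
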