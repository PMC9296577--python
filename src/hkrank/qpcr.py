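"""Comparative 2^-delta-delta-Ct quantification against a reference panel.

Relative RT-qPCR quantification: per sample, the target gene's threshold
cycle (Ct) is referenced against a single reference gene or a panel of them;
the panel's combined Ct is the arithmetic mean of the member Cts, which is
the geometric mean of their linear expression — the standard multi-reference
practice. Then

    dCt(sample)  = Ct_target(sample) - Ct_reference(sample)
    ddCt(sample) = dCt(sample) - mean dCt over the control group
    fold change  = 2 ** (-ddCt)

Amplification efficiency is fixed at 2 per cycle (no efficiency correction).
Group summaries are reported as mean +/- SEM of the per-sample fold changes.

Using a panel dilutes artifacts of any single reference gene: a reference
gene shifted by +1 Ct in the condition group alone inflates the target's
apparent fold change 2-fold, but only 2^(1/k)-fold inside a k-gene panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import CONDITION, CONTROL, GROUPS
from .errors import AnnotationError, FormatError, MissingDataError


@dataclass(frozen=True)
class CtTable:
    """Per-sample Ct measurements: a ``group`` label plus one column per gene."""

    data: pd.DataFrame  # index: sample_id; columns: group + gene names

    def __post_init__(self) -> None:
        if "group" not in self.data.columns:
            raise FormatError("Ct table needs a 'group' column")
        bad = set(self.data["group"].unique()) - set(GROUPS)
        if bad:
            raise AnnotationError(f"Ct table groups must be in {GROUPS}, got {sorted(bad)!r}")

    @property
    def genes(self) -> list[str]:
        return [c for c in self.data.columns if c != "group"]

    def cts(self, gene: str) -> pd.Series:
        if gene not in self.data.columns:
            raise MissingDataError(f"no Ct column for gene {gene!r}")
        col = pd.to_numeric(self.data[gene], errors="coerce")
        if col.isna().any():
            missing = list(col.index[col.isna()])
            raise MissingDataError(f"missing Ct for {gene!r} in samples {missing!r}")
        return col

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CtTable":
        frame = pd.read_csv(Path(path), sep="\t", index_col=0)
        return cls(data=frame)


def panel_reference_ct(table: CtTable, panel: Sequence[str]) -> pd.Series:
    """Per-sample combined reference Ct: arithmetic mean over the panel genes.

    Equivalent to the geometric mean of the panel's linear expression values.
    A panel of one gene returns that gene's Ct unchanged.
    """
    if len(panel) < 1:
        raise MissingDataError("reference panel must contain at least one gene")
    cols = pd.concat([table.cts(g) for g in panel], axis=1)
    return cols.mean(axis=1)


def ddct_fold_change(
    table: CtTable, target: str, panel: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample 2^-ddCt fold changes of ``target`` versus a reference panel.

    Returns ``(per_sample, summary)``: per-sample dCt, ddCt (relative to the
    mean control-group dCt) and fold change for every sample, and a per-group
    summary with mean fold change and SEM.
    """
    groups = table.data["group"]
    if (groups == CONTROL).sum() == 0:
        raise AnnotationError("ddCt requires a non-empty control group")
    if (groups == CONDITION).sum() == 0:
        raise AnnotationError("ddCt requires a non-empty condition group")
    ref_ct = panel_reference_ct(table, panel)
    dct = table.cts(target) - ref_ct
    ddct = dct - dct[groups == CONTROL].mean()
    fold = np.exp2(-ddct)
    per_sample = pd.DataFrame(
        {"group": groups, "dct": dct, "ddct": ddct, "fold_change": fold}
    )
    summary = (
        per_sample.groupby("group")["fold_change"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0,
             n="size")
        .loc[[g for g in (CONDITION, CONTROL) if g in set(groups)]]
    )
    return per_sample, summary
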