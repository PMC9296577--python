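"""NormFinder-style expression-stability scoring.

A candidate reference gene should keep the same expression level in every
sample group. On log2 expression, let z_ig be the mean of gene i in group g.
Removing the gene's overall level (alpha_i, mean of z_ig over groups) and the
group's global mRNA shift (theta_g, the group mean over genes centered on the
grand mean) leaves a residual

    f_ig = z_ig - theta_g - alpha_i

that is zero for a perfectly stable gene. The stability value collapses the
residuals into one number per gene,

    rho_i = | mean_g(f_ig) + sd_g(f_ig) |,

small rho meaning stable; genes with rho below a cutoff (default 0.15) are
called stable. theta_g is centered so that an all-constant data set scores
exactly zero; sd is the sample standard deviation over groups.

This is the lightweight screening rendition of the NormFinder idea (within-
plus between-group variation), not the original full variance-decomposition
model-based estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .errors import AnnotationError, HkrankError, InsufficientDataError

DEFAULT_CUTOFF = 0.15


@dataclass(frozen=True)
class StabilityResult:
    """Per-gene stability: group residuals f_ig, rho, and the stable call."""

    gene_id: str
    f_values: tuple[float, ...]
    rho: float
    stable: bool


def normfinder_stability(
    dataset: ExpressionDataset, cutoff: float = DEFAULT_CUTOFF
) -> list[StabilityResult]:
    """Score every gene's expression stability across the sample groups.

    Values are log2-transformed internally (the data set must be linear scale
    with positive values, or already log2). Genes with a nonpositive linear
    value are dropped with a warning. Requires >= 2 groups and >= 2 genes.
    """
    dataset.require_annotated()
    group_names = sorted(dataset.groups.unique())
    if len(group_names) < 2:
        raise AnnotationError(f"{dataset.dataset_id}: stability needs >= 2 sample groups")
    if dataset.n_genes < 2:
        raise InsufficientDataError(f"{dataset.dataset_id}: stability needs >= 2 genes")

    values = dataset.values
    if dataset.scale == "log2":
        log2 = values
    else:
        ok = (values > 0).all(axis=1)
        if not ok.all():
            warnings.warn(
                f"{dataset.dataset_id}: dropping {(~ok).sum()} gene(s) with nonpositive values",
                stacklevel=2,
            )
            values = values.loc[ok]
            if values.shape[0] < 2:
                raise InsufficientDataError(
                    f"{dataset.dataset_id}: fewer than 2 genes with positive values"
                )
        log2 = np.log2(values)

    # z: genes x groups matrix of group-mean log2 expression
    z = np.column_stack(
        [
            log2.loc[:, dataset.groups.index[dataset.groups == g]].mean(axis=1).to_numpy()
            for g in group_names
        ]
    )
    alpha = z.mean(axis=1)  # per-gene level
    theta = z.mean(axis=0) - z.mean()  # centered global group effect
    f = z - theta[None, :] - alpha[:, None]
    rho = np.abs(f.mean(axis=1) + f.std(axis=1, ddof=1))

    return [
        StabilityResult(
            gene_id=g,
            f_values=tuple(float(x) for x in f[i]),
            rho=float(rho[i]),
            stable=bool(rho[i] < cutoff),
        )
        for i, g in enumerate(log2.index)
    ]


def stability_table(results: Sequence[StabilityResult]) -> pd.DataFrame:
    """Results as a DataFrame indexed by gene with columns rho, stable."""
    return pd.DataFrame(
        {"rho": [r.rho for r in results], "stable": [r.stable for r in results]},
        index=pd.Index([r.gene_id for r in results], name="gene_id"),
    )


def concordance_with_ranking(
    top_genes: Sequence[str], stability: Sequence[StabilityResult]
) -> float:
    """Fraction of the top-ranked genes that the stability score calls stable."""
    by_gene = {r.gene_id: r for r in stability}
    missing = [g for g in top_genes if g not in by_gene]
    if missing:
        raise HkrankError(f"no stability result for gene(s) {missing!r}")
    if not top_genes:
        raise HkrankError("empty top-gene list")
    return sum(by_gene[g].stable for g in top_genes) / len(top_genes)
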