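"""Per-dataset gene scoring and cross-dataset bootstrap rank aggregation.

The scoring idea: a good reference gene shows low dispersion across all
samples of a study (coefficient of variation, CV = sd / mean) and no response
to the experimental condition (group fold change, reciprocated when < 1 so
that 1 means "unchanged" and larger always means "more changed"). Within each
data set, genes are ranked separately by CV and by inverted fold change
(ascending; low is good, ties averaged) and the two ranks are multiplied into
a rank product; the ascending rank of the rank product is the gene's score in
that data set. Working on ranks makes studies from different platforms
directly comparable without cross-platform normalization.

Aggregation resamples whole data sets with replacement (the bootstrap unit is
the study, not the sample): each repetition draws D of the D data sets with
replacement, averages each gene's per-dataset rank over the drawn studies
(genes absent from every drawn study score the worst plausible rank, the
universe size), and re-ranks the genes by that mean. Over many repetitions
this yields, per gene, a distribution of aggregate ranks whose mean and
spread quantify how sensitive the gene's standing is to study selection.

The final ordering penalizes genes that were not measured everywhere:
``penalized_score = mean_bootstrap_rank * n_datasets / presence_count``. A
gene seen in all studies keeps its mean rank; a gene seen in half of them has
its rank doubled; a gene seen nowhere is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datasets import CONDITION, CONTROL, ExpressionDataset
from .errors import AnnotationError, ConfigurationError, InsufficientDataError


def coefficient_of_variation(values: np.ndarray) -> float:
    """CV = sample standard deviation (n-1 denominator) / arithmetic mean.

    Unitless dispersion of a gene's expression across samples; requires at
    least two strictly positive values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("CV needs at least 2 values")
    if np.any(arr <= 0):
        raise InsufficientDataError("CV requires strictly positive expression values")
    return float(np.std(arr, ddof=1) / np.mean(arr))


def group_fold_change(condition_values: np.ndarray, control_values: np.ndarray) -> float:
    """Ratio of condition to control group means, reciprocated when < 1.

    The inversion maps down- and up-regulation onto the same "magnitude of
    change" axis, so 1 is "no change" and larger is always worse for a
    reference-gene candidate.
    """
    cond = np.asarray(condition_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if cond.size == 0 or ctrl.size == 0:
        raise AnnotationError("fold change needs non-empty condition and control groups")
    fc = float(np.mean(cond) / np.mean(ctrl))
    return 1.0 / fc if fc < 1.0 else fc


@dataclass(frozen=True)
class DatasetRanking:
    """Per-gene scores and ranks within a single data set.

    ``scores`` columns: cv, fc, rank_cv, rank_fc, rank_product, dataset_rank.
    """

    dataset_id: str
    scores: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def dataset_rank(self) -> pd.Series:
        return self.scores["dataset_rank"]


def score_dataset(dataset: ExpressionDataset) -> DatasetRanking:
    """Compute CV, inverted fold change, and the joint rank-product rank.

    CV is taken over ALL samples (both groups) — a reference gene must be
    quiet overall, not merely within groups. Both criteria are ranked
    ascending with average ties; the rank product is re-ranked so the final
    per-dataset score lives on a common 1..n_genes scale across studies.
    """
    dataset.require_annotated()
    if dataset.scale != "linear":
        raise InsufficientDataError(
            f"{dataset.dataset_id}: scoring requires linear-scale values (call to_linear first)"
        )
    if dataset.n_genes < 2:
        raise InsufficientDataError(f"{dataset.dataset_id}: need at least 2 genes to rank")

    mat = dataset.values.to_numpy(dtype=float)
    cv = np.std(mat, axis=1, ddof=1) / np.mean(mat, axis=1)

    cond_cols = np.asarray(dataset.groups.to_numpy() == CONDITION)
    ctrl_cols = np.asarray(dataset.groups.to_numpy() == CONTROL)
    fc = mat[:, cond_cols].mean(axis=1) / mat[:, ctrl_cols].mean(axis=1)
    fc = np.where(fc < 1.0, 1.0 / fc, fc)

    rank_cv = rankdata(cv, method="average")
    rank_fc = rankdata(fc, method="average")
    rank_product = rank_cv * rank_fc
    dataset_rank = rankdata(rank_product, method="average")

    scores = pd.DataFrame(
        {
            "cv": cv,
            "fc": fc,
            "rank_cv": rank_cv,
            "rank_fc": rank_fc,
            "rank_product": rank_product,
            "dataset_rank": dataset_rank,
        },
        index=dataset.values.index,
    )
    return DatasetRanking(dataset_id=dataset.dataset_id, scores=scores)


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: number of repetitions (default 10,000) and seed."""

    repetitions: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ConfigurationError("bootstrap repetitions must be >= 1")


@dataclass(frozen=True)
class RankDistribution:
    """Bootstrap rank distribution over the gene universe.

    ``rank_samples`` is a genes x repetitions array of per-repetition ranks;
    ``summary`` carries mean_bootstrap_rank, rank_sd, presence_count per gene.
    """

    universe: list[str]
    rank_samples: np.ndarray
    summary: pd.DataFrame
    n_datasets: int
    config: BootstrapConfig

    @property
    def mean_rank(self) -> pd.Series:
        return self.summary["mean_bootstrap_rank"]

    @property
    def rank_sd(self) -> pd.Series:
        return self.summary["rank_sd"]

    @property
    def presence_count(self) -> pd.Series:
        return self.summary["presence_count"]


def bootstrap_rankings(
    rankings: Sequence[DatasetRanking],
    universe: Sequence[str] | None = None,
    config: BootstrapConfig | None = None,
) -> RankDistribution:
    """Aggregate per-dataset ranks by resampling data sets with replacement.

    For each repetition, D study indices are drawn with replacement (D = the
    number of studies); each gene's score is the mean of its dataset_rank over
    the drawn studies in which it is present, or the universe size if absent
    from all of them; the genes are then re-ranked by that mean (ascending,
    average ties). Returns the full rank-sample matrix plus per-gene mean,
    standard deviation, and presence count.
    """
    if len(rankings) < 2:
        raise ConfigurationError("bootstrap aggregation needs at least two data sets")
    config = config or BootstrapConfig()
    if universe is None:
        genes: set[str] = set()
        for r in rankings:
            genes.update(r.gene_ids)
        universe = sorted(genes)
    universe = list(universe)
    n_genes, n_ds = len(universe), len(rankings)

    # genes x datasets matrix of per-dataset ranks, NaN where a gene is absent
    rank_matrix = np.full((n_genes, n_ds), np.nan)
    index = pd.Index(universe)
    for j, r in enumerate(rankings):
        pos = index.get_indexer(r.scores.index)
        if (pos < 0).any():
            raise ConfigurationError(
                f"{r.dataset_id}: genes outside the supplied universe"
            )
        rank_matrix[pos, j] = r.scores["dataset_rank"].to_numpy()
    presence = (~np.isnan(rank_matrix)).sum(axis=1)

    rng = np.random.default_rng(config.seed)
    draws = rng.integers(0, n_ds, size=(config.repetitions, n_ds))
    filled = np.nan_to_num(rank_matrix, nan=0.0)
    present = ~np.isnan(rank_matrix)
    means = np.empty((n_genes, config.repetitions))
    for r in range(config.repetitions):
        cols = draws[r]
        cnt = present[:, cols].sum(axis=1)
        tot = filled[:, cols].sum(axis=1)
        # genes absent from every drawn study get the worst plausible rank
        means[:, r] = np.divide(tot, cnt, out=np.full(n_genes, float(n_genes)),
                                where=cnt > 0)
    rank_samples = rankdata(means, method="average", axis=0)

    summary = pd.DataFrame(
        {
            "mean_bootstrap_rank": rank_samples.mean(axis=1),
            "rank_sd": rank_samples.std(axis=1, ddof=1)
            if config.repetitions > 1
            else np.zeros(n_genes),
            "presence_count": presence,
        },
        index=pd.Index(universe, name="gene_id"),
    )
    return RankDistribution(
        universe=universe,
        rank_samples=rank_samples,
        summary=summary,
        n_datasets=n_ds,
        config=config,
    )


@dataclass(frozen=True)
class FinalRanking:
    """Penalized final ordering of reference-gene candidates.

    ``table`` is ordered ascending by penalized_score (ties broken
    lexicographically by gene id) with columns mean_bootstrap_rank, rank_sd,
    presence_count, penalized_score, final_rank.
    """

    table: pd.DataFrame
    top_n: int = 25

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def top(self, k: int | None = None) -> list[str]:
        """The first k finite-score candidates (default: the stored top_n)."""
        k = self.top_n if k is None else k
        finite = self.table[np.isfinite(self.table["penalized_score"])]
        return list(finite.index[:k])


def final_ranking(dist: RankDistribution, top_n: int = 25) -> FinalRanking:
    """Order genes by mean bootstrap rank with a multiplicative absence penalty.

    ``penalized_score = mean_bootstrap_rank * n_datasets / presence_count``;
    genes measured nowhere get +inf and can never enter the reported top list.
    """
    if top_n < 1:
        raise ConfigurationError("top_n must be >= 1")
    presence = dist.presence_count.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        penalty = np.where(presence > 0, dist.n_datasets / presence, np.inf)
    score = dist.mean_rank.to_numpy() * penalty

    table = dist.summary.copy()
    table["penalized_score"] = score
    # lexicographic base order + stable sort = deterministic tie-break on gene id
    table = table.sort_index().sort_values("penalized_score", kind="mergesort")
    table["final_rank"] = np.arange(1, len(table) + 1)
    return FinalRanking(table=table, top_n=top_n)
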