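"""Model/Results interface over the ranking and stability machinery.

:class:`ReferenceGeneModel` is built from a collection of annotated
expression data sets (or straight from files); ``fit()`` runs preprocessing,
per-dataset scoring, and the dataset-level bootstrap, returning a
:class:`RankingResults` carrying the per-gene estimates (mean bootstrap
rank), their uncertainty (bootstrap rank sd), the presence diagnostics, the
penalized final ordering, and a ``summary()`` table. Simulation of new
candidate lists under reseeding and plotting hang off the results object.

:class:`NormFinder` wraps the stability score the same way.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import datasets as dio
from .datasets import ExpressionDataset, MappingTable, gene_universe, to_linear
from .errors import ConfigurationError
from .normfinder import (
    DEFAULT_CUTOFF,
    StabilityResult,
    concordance_with_ranking,
    normfinder_stability,
    stability_table,
)
from .ranking import (
    BootstrapConfig,
    DatasetRanking,
    FinalRanking,
    RankDistribution,
    bootstrap_rankings,
    final_ranking,
    score_dataset,
)


class ReferenceGeneModel:
    """Reference-gene discovery across >= 2 expression data sets.

    Parameters
    ----------
    datasets : sequence of ExpressionDataset
        Annotated data sets (probe-collapsed if from microarray). Scale may be
        mixed; log2 data are exponentiated during preprocessing.
    orthology : MappingTable, optional
        Gene -> ortholog-group table, required when organisms differ.
    """

    def __init__(
        self,
        datasets: Sequence[ExpressionDataset],
        orthology: MappingTable | None = None,
    ) -> None:
        if len(datasets) < 2:
            raise ConfigurationError("at least two data sets are required")
        self.datasets = list(datasets)
        self.orthology = orthology
        self._prepared: list[ExpressionDataset] | None = None

    @classmethod
    def from_files(
        cls,
        dataset_paths: Sequence[str | Path],
        annotation_paths: Sequence[str | Path],
        probe_mapping: str | Path | None = None,
        orthology: str | Path | None = None,
    ) -> "ReferenceGeneModel":
        """Build a model from matrix files (GEO series-matrix or TSV) plus
        per-dataset sample-annotation TSVs."""
        if len(dataset_paths) != len(annotation_paths):
            raise ConfigurationError("one annotation file per data set is required")
        mapping = dio.read_mapping_table(probe_mapping) if probe_mapping else None
        orth = dio.read_mapping_table(orthology, direction="ortholog") if orthology else None
        loaded = []
        for dpath, apath in zip(dataset_paths, annotation_paths):
            dpath = Path(dpath)
            if _looks_like_series_matrix(dpath):
                ds = dio.read_series_matrix(dpath)
            else:
                ds = dio.read_tsv_matrix(dpath)
            if mapping is not None:
                ds = dio.collapse_probes(ds, mapping)
            ds = dio.annotate_samples(ds, dio.read_annotation(apath))
            loaded.append(ds)
        return cls(loaded, orthology=orth)

    def prepare(self) -> list[ExpressionDataset]:
        """Linearize, drop unusable rows, and harmonize gene namespaces."""
        if self._prepared is None:
            linear = [to_linear(d) for d in self.datasets]
            self._prepared = dio.harmonize_genes(linear, self.orthology)
        return self._prepared

    def fit(
        self,
        repetitions: int = 10_000,
        seed: int | None = None,
        top_n: int = 25,
    ) -> "RankingResults":
        """Score every data set, bootstrap the per-dataset ranks, and return
        the penalized final ranking with per-gene uncertainty."""
        prepared = self.prepare()
        rankings = [score_dataset(d) for d in prepared]
        universe = gene_universe(prepared)
        config = BootstrapConfig(repetitions=repetitions, seed=seed)
        dist = bootstrap_rankings(rankings, universe=universe, config=config)
        final = final_ranking(dist, top_n=top_n)
        return RankingResults(self, rankings, dist, final)


def _looks_like_series_matrix(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.startswith("!")
    return False


class RankingResults:
    """Fitted reference-gene ranking: estimates, uncertainty, diagnostics."""

    def __init__(
        self,
        model: ReferenceGeneModel,
        dataset_rankings: Sequence[DatasetRanking],
        distribution: RankDistribution,
        final: FinalRanking,
    ) -> None:
        self.model = model
        self.dataset_rankings = list(dataset_rankings)
        self.distribution = distribution
        self.final = final

    # -- estimates ---------------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        """Full ordered ranking table (one row per universe gene)."""
        return self.final.table

    @property
    def mean_rank(self) -> pd.Series:
        return self.distribution.mean_rank

    @property
    def rank_sd(self) -> pd.Series:
        return self.distribution.rank_sd

    def top(self, k: int | None = None) -> list[str]:
        return self.final.top(k)

    # -- presentation ------------------------------------------------------
    def summary(self, k: int | None = None) -> str:
        """Human-readable summary of the top candidates."""
        k = k if k is not None else self.final.top_n
        cfg = self.distribution.config
        head = self.table.head(k)
        lines = [
            "Reference-gene ranking",
            "=" * 70,
            f"data sets: {len(self.dataset_rankings)}    "
            f"gene universe: {len(self.distribution.universe)}",
            f"bootstrap repetitions: {cfg.repetitions}    seed: {cfg.seed}",
            "-" * 70,
            f"{'rank':>4}  {'gene':<14}{'mean_bs_rank':>12}{'rank_sd':>9}"
            f"{'presence':>9}{'score':>10}",
        ]
        for gene, row in head.iterrows():
            lines.append(
                f"{int(row.final_rank):>4}  {str(gene):<14}"
                f"{row.mean_bootstrap_rank:>12.2f}{row.rank_sd:>9.2f}"
                f"{int(row.presence_count):>6}/{len(self.dataset_rankings)}"
                f"{row.penalized_score:>10.2f}"
            )
        lines.append("=" * 70)
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        """Write the full ranking table as TSV."""
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(Path(path), sep="\t", float_format="%.6g")

    def session(self, command: str = "rank", **extra) -> dict:
        """JSON-serializable session record: parameters + result payload."""
        cfg = self.distribution.config
        return {
            "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
            "command": command,
            "parameters": {
                "repetitions": cfg.repetitions,
                "seed": cfg.seed,
                "top_n": self.final.top_n,
                "dataset_ids": [r.dataset_id for r in self.dataset_rankings],
                **extra,
            },
            "top_candidates": self.top(),
            "n_genes": len(self.distribution.universe),
        }

    def save_session(self, path: str | Path, command: str = "rank", **extra) -> None:
        Path(path).write_text(json.dumps(self.session(command, **extra), indent=2))

    # -- plotting ----------------------------------------------------------
    def plot_rank_distribution(self, genes: Sequence[str] | None = None, ax=None):
        """Box plot of bootstrap rank distributions for the given genes
        (default: the stored top candidates), ordered by final rank."""
        import matplotlib.pyplot as plt

        genes = list(genes) if genes is not None else self.top()
        idx = pd.Index(self.distribution.universe)
        pos = idx.get_indexer(genes)
        if (pos < 0).any():
            raise ConfigurationError("gene(s) not in the ranking universe")
        samples = [self.distribution.rank_samples[p] for p in pos]
        if ax is None:
            _, ax = plt.subplots(figsize=(max(6, 0.4 * len(genes)), 4))
        ax.boxplot(samples, tick_labels=genes, showfliers=False)
        ax.set_ylabel("bootstrap rank")
        ax.set_xlabel("candidate (final-rank order)")
        ax.tick_params(axis="x", rotation=90)
        return ax


class NormFinder:
    """Expression-stability scoring of one annotated data set."""

    def __init__(self, dataset: ExpressionDataset, cutoff: float = DEFAULT_CUTOFF) -> None:
        self.dataset = dataset
        self.cutoff = cutoff

    def fit(self) -> "StabilityResults":
        results = normfinder_stability(self.dataset, cutoff=self.cutoff)
        return StabilityResults(self, results)


class StabilityResults:
    """Fitted stability scores with stable/unstable calls."""

    def __init__(self, model: NormFinder, results: Sequence[StabilityResult]) -> None:
        self.model = model
        self.results = list(results)

    @property
    def table(self) -> pd.DataFrame:
        return stability_table(self.results)

    def concordance(self, top_genes: Sequence[str]) -> float:
        """Fraction of the given ranked genes called stable here."""
        return concordance_with_ranking(top_genes, self.results)

    def summary(self, k: int = 20) -> str:
        tab = self.table.sort_values("rho").head(k)
        lines = [
            "Expression stability (NormFinder-style)",
            "=" * 46,
            f"data set: {self.model.dataset.dataset_id}    cutoff: {self.model.cutoff}",
            f"stable genes: {int(self.table['stable'].sum())} / {len(self.table)}",
            "-" * 46,
            f"{'gene':<16}{'rho':>10}  stable",
        ]
        for gene, row in tab.iterrows():
            lines.append(f"{str(gene):<16}{row.rho:>10.4f}  {'yes' if row.stable else 'no'}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(Path(path), sep="\t", float_format="%.6g")
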