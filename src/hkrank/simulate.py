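"""Synthetic multi-study expression compendia with known ground truth.

Emulates the heterogeneity of a public-repository compendium — several
platforms measuring overlapping but not identical gene sets, some studies
deposited on log2 scale and some linear — while planting three gene roles:

* ``stable``: high baseline expression, low multiplicative noise, no
  condition response — the genes a reference-gene search should recover;
* ``responsive``: genes whose condition-group mean is shifted by a fold
  change drawn from a configured range (random direction), the decoys a good
  method must avoid;
* ``background``: ordinary genes with larger multiplicative noise and no
  systematic condition effect.

Noise is log-normal (multiplicative): a target coefficient of variation CV
maps to a log2-scale standard deviation sigma = sqrt(ln(1 + CV^2)) / ln 2, so
the simulated linear-scale CV matches the configured value exactly in
expectation. Each study independently drops a fraction of genes uniformly at
random (platform coverage differences); everything is reproducible from the
config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import CONDITION, CONTROL, ExpressionDataset
from .errors import ConfigurationError
from .ranking import FinalRanking


def cv_to_log2_sd(cv: float) -> float:
    """Log2-scale sd of a log-normal variable with linear-scale CV ``cv``."""
    return math.sqrt(math.log1p(cv * cv)) / math.log(2.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for a simulated compendium.

    Defaults describe a compendium of 4 studies x 2,000 genes with 50 planted
    stable genes and 200 condition-responsive decoys, 10 samples per group,
    10% per-study gene dropout, and half the studies on log2 scale — large
    enough to exercise tie handling and absence penalties, small enough for
    seconds-scale runs.
    """

    n_datasets: int = 4
    n_genes: int = 2000
    n_planted_stable: int = 50
    n_condition_responsive: int = 200
    samples_per_group: int = 10
    dropout_fraction: float = 0.10
    log_scale_fraction: float = 0.5
    noise_cv_stable: float = 0.10
    noise_cv_background: float = 0.50
    responsive_fc_range: tuple[float, float] = (2.0, 8.0)
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)  # log2 units
    seed: int = 0
    stable_genes: tuple[int, ...] | None = None  # explicit planted indices
    responsive_genes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if min(self.n_datasets, self.n_genes, self.n_planted_stable,
               self.n_condition_responsive, self.samples_per_group) < 1:
            raise ConfigurationError("all counts must be >= 1")
        if self.n_planted_stable + self.n_condition_responsive > self.n_genes:
            raise ConfigurationError("planted + responsive genes exceed n_genes")
        if not (0.0 <= self.dropout_fraction < 1.0):
            raise ConfigurationError("dropout_fraction must be in [0, 1)")
        if not (0.0 <= self.log_scale_fraction <= 1.0):
            raise ConfigurationError("log_scale_fraction must be in [0, 1]")
        if not (0.0 < self.noise_cv_stable < self.noise_cv_background):
            raise ConfigurationError("need 0 < noise_cv_stable < noise_cv_background")
        lo, hi = self.responsive_fc_range
        if not (1.0 < lo <= hi):
            raise ConfigurationError("responsive_fc_range must satisfy 1 < low <= high")
        lo, hi = self.baseline_mean_range
        if not lo < hi:
            raise ConfigurationError("baseline_mean_range must be ordered")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a simulated compendium.

    ``roles`` maps every gene id to stable / responsive / background;
    ``dataset_genes`` records which genes each study retained after dropout;
    ``dataset_scale`` the emitted scale; ``params`` per-dataset generative
    parameters (baseline log2 mean, cv, fc) as a DataFrame per study.
    """

    roles: pd.Series
    dataset_genes: dict[str, list[str]]
    dataset_scale: dict[str, str]
    params: dict[str, pd.DataFrame]
    config: SimulationConfig

    def genes_with_role(self, role: str) -> list[str]:
        return list(self.roles.index[self.roles == role])


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def simulate_collection(
    config: SimulationConfig | None = None,
) -> tuple[list[ExpressionDataset], SimulationTruth]:
    """Generate a compendium of annotated expression data sets plus its truth.

    Planted stable genes draw their baselines from the top quarter of
    ``baseline_mean_range`` (reference genes are typically highly expressed)
    and keep fold change exactly 1 in every study; responsive genes get a
    per-study fold change from ``responsive_fc_range`` applied to the
    condition group, up or down with equal probability. Dropout never removes
    all planted stable genes from a study.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    gene_index = pd.Index(genes, name="gene_id")

    if config.stable_genes is not None:
        stable_idx = np.asarray(config.stable_genes, dtype=int)
    else:
        stable_idx = rng.choice(config.n_genes, size=config.n_planted_stable, replace=False)
    remaining = np.setdiff1d(np.arange(config.n_genes), stable_idx)
    if config.responsive_genes is not None:
        responsive_idx = np.asarray(config.responsive_genes, dtype=int)
        if np.intersect1d(stable_idx, responsive_idx).size:
            raise ConfigurationError("stable and responsive gene sets overlap")
    else:
        responsive_idx = rng.choice(remaining, size=config.n_condition_responsive,
                                    replace=False)

    roles = pd.Series("background", index=gene_index)
    roles.iloc[stable_idx] = "stable"
    roles.iloc[responsive_idx] = "responsive"

    lo, hi = config.baseline_mean_range
    stable_lo = hi - 0.25 * (hi - lo)  # high expression band for planted genes

    n_log = int(round(config.log_scale_fraction * config.n_datasets))
    scales = ["log2"] * n_log + ["linear"] * (config.n_datasets - n_log)

    n_samples = 2 * config.samples_per_group
    group_labels = [CONDITION] * config.samples_per_group + [CONTROL] * config.samples_per_group

    datasets: list[ExpressionDataset] = []
    dataset_genes: dict[str, list[str]] = {}
    dataset_scale: dict[str, str] = {}
    params: dict[str, pd.DataFrame] = {}

    for d in range(config.n_datasets):
        ds_id = f"sim{d:02d}"
        baseline = rng.uniform(lo, hi, size=config.n_genes)
        baseline[stable_idx] = rng.uniform(stable_lo, hi, size=stable_idx.size)

        cv = np.full(config.n_genes, config.noise_cv_background)
        cv[stable_idx] = config.noise_cv_stable

        fc = np.ones(config.n_genes)
        fc_lo, fc_hi = config.responsive_fc_range
        magnitude = rng.uniform(fc_lo, fc_hi, size=responsive_idx.size)
        direction = rng.choice([1.0, -1.0], size=responsive_idx.size)
        fc[responsive_idx] = np.where(direction > 0, magnitude, 1.0 / magnitude)

        sigma = np.array([cv_to_log2_sd(c) for c in (config.noise_cv_stable,
                                                     config.noise_cv_background)])
        log2_sd = np.where(cv == config.noise_cv_stable, sigma[0], sigma[1])

        log2_mean = np.tile(baseline[:, None], (1, n_samples))
        cond = slice(0, config.samples_per_group)
        log2_mean[:, cond] += np.log2(fc)[:, None]
        noise = rng.normal(0.0, 1.0, size=(config.n_genes, n_samples)) * log2_sd[:, None]
        log2_values = log2_mean + noise

        keep = np.ones(config.n_genes, dtype=bool)
        if config.dropout_fraction > 0:
            n_drop = int(round(config.dropout_fraction * config.n_genes))
            drop = rng.choice(config.n_genes, size=n_drop, replace=False)
            keep[drop] = False
            if not keep[stable_idx].any():  # never lose every planted gene
                keep[stable_idx[0]] = True

        kept_genes = [genes[i] for i in np.flatnonzero(keep)]
        sample_ids = [f"{ds_id}_s{j:02d}" for j in range(n_samples)]
        scale = scales[d]
        mat = log2_values[keep] if scale == "log2" else np.exp2(log2_values[keep])
        values = pd.DataFrame(mat, index=pd.Index(kept_genes, name="gene_id"),
                              columns=sample_ids)
        groups = pd.Series(group_labels, index=sample_ids)
        datasets.append(
            ExpressionDataset(dataset_id=ds_id, values=values, scale=scale,
                              groups=groups, organism="simulated")
        )
        dataset_genes[ds_id] = kept_genes
        dataset_scale[ds_id] = scale
        params[ds_id] = pd.DataFrame(
            {"baseline_log2_mean": baseline, "cv": cv, "fc": fc}, index=gene_index
        ).loc[kept_genes]

    truth = SimulationTruth(
        roles=roles,
        dataset_genes=dataset_genes,
        dataset_scale=dataset_scale,
        params=params,
        config=config,
    )
    return datasets, truth


def validation_dataset(
    truth: SimulationTruth, seed: int, samples_per_group: int | None = None
) -> ExpressionDataset:
    """Generate one held-out data set sharing a compendium's gene roles.

    Mirrors an independent validation experiment: the same planted stable and
    responsive genes, fresh noise and fold-change draws, no gene dropout (a
    validation assay measures every candidate), linear scale.
    """
    cfg = truth.config
    idx = pd.Index(truth.roles.index)
    stable = tuple(int(idx.get_loc(g)) for g in truth.genes_with_role("stable"))
    responsive = tuple(int(idx.get_loc(g)) for g in truth.genes_with_role("responsive"))
    vcfg = SimulationConfig(
        n_datasets=1,
        n_genes=cfg.n_genes,
        n_planted_stable=len(stable),
        n_condition_responsive=len(responsive),
        samples_per_group=samples_per_group or cfg.samples_per_group,
        dropout_fraction=0.0,
        log_scale_fraction=0.0,
        noise_cv_stable=cfg.noise_cv_stable,
        noise_cv_background=cfg.noise_cv_background,
        responsive_fc_range=cfg.responsive_fc_range,
        baseline_mean_range=cfg.baseline_mean_range,
        seed=seed,
        stable_genes=stable,
        responsive_genes=responsive,
    )
    datasets, _ = simulate_collection(vcfg)
    ds = datasets[0]
    return ExpressionDataset(
        dataset_id="validation", values=ds.values, scale=ds.scale,
        groups=ds.groups, organism=ds.organism,
    )


def recovery_metrics(ranking: FinalRanking, truth: SimulationTruth, k: int = 10) -> float:
    """Fraction of the top-k final candidates whose true role is ``stable``.

    The in-silico analog of validating top candidates experimentally: with a
    perfect method the top of the list is exclusively planted stable genes.
    """
    universe = len(ranking.table)
    if k > universe:
        raise ConfigurationError(f"k={k} exceeds universe size {universe}")
    top = ranking.top(k)
    return sum(truth.roles.get(g) == "stable" for g in top) / k
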