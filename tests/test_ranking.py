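"""Per-dataset scoring and bootstrap aggregation, checked against oracles."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from hkrank import (
    BootstrapConfig,
    bootstrap_rankings,
    coefficient_of_variation,
    final_ranking,
    group_fold_change,
    score_dataset,
)
from hkrank.ranking import DatasetRanking
from hkrank.errors import AnnotationError, ConfigurationError, InsufficientDataError
from conftest import make_dataset


# -- coefficient of variation -------------------------------------------------

def test_cv_worked_examples():
    assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0
    assert coefficient_of_variation([2.0, 4.0, 6.0]) == pytest.approx(0.5)
    with pytest.raises(InsufficientDataError):
        coefficient_of_variation([5.0])


@given(st.floats(min_value=1e-3, max_value=1e6),
       st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=2, max_size=20))
@settings(deadline=None, max_examples=50)
def test_cv_scale_invariance(k, values):
    """CV is unchanged by positive rescaling of a gene's expression."""
    base = coefficient_of_variation(values)
    scaled = coefficient_of_variation([k * v for v in values])
    assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)


# -- fold change --------------------------------------------------------------

def test_fold_change_inversion_symmetry():
    assert group_fold_change([8.0, 8.0], [2.0, 2.0]) == pytest.approx(4.0)
    assert group_fold_change([2.0, 2.0], [8.0, 8.0]) == pytest.approx(4.0)
    assert group_fold_change([3.0, 5.0], [4.0, 4.0]) == pytest.approx(1.0)
    with pytest.raises(AnnotationError):
        group_fold_change([], [1.0])


@given(st.lists(st.floats(min_value=0.1, max_value=1e3), min_size=1, max_size=8),
       st.lists(st.floats(min_value=0.1, max_value=1e3), min_size=1, max_size=8))
@settings(deadline=None, max_examples=50)
def test_fold_change_at_least_one_and_symmetric(cond, ctrl):
    fc = group_fold_change(cond, ctrl)
    assert fc >= 1.0
    assert fc == pytest.approx(group_fold_change(ctrl, cond), rel=1e-9)


# -- per-dataset scoring ------------------------------------------------------

def _ranking_from_ranks(dataset_id, genes, dataset_rank):
    scores = pd.DataFrame({"dataset_rank": dataset_rank}, index=pd.Index(genes))
    return DatasetRanking(dataset_id=dataset_id, scores=scores)


def test_score_dataset_rank_product_tie_case(two_group_labels):
    # engineered so (rank_cv, rank_fc) = (1,2), (2,1), (3,3):
    # rank products 2, 2, 9 -> dataset ranks 1.5, 1.5, 3
    ds = make_dataset(
        [
            [10.0, 10.0, 12.0, 12.0],  # smallest cv (0.105), fc 1.2 -> fc rank 2
            [8.0, 12.0, 10.0, 10.0],   # cv 0.163 rank 2, fc exactly 1 -> rank 1
            [20.0, 2.0, 8.0, 8.0],     # most variable (cv 0.79), fc 1.375
        ],
        groups=two_group_labels,
    )
    scored = score_dataset(ds).scores
    assert scored["rank_cv"].tolist() == [1.0, 2.0, 3.0]
    assert scored["rank_fc"].tolist() == [2.0, 1.0, 3.0]
    assert scored["rank_product"].tolist() == [2.0, 2.0, 9.0]
    assert scored["dataset_rank"].tolist() == [1.5, 1.5, 3.0]


def test_score_dataset_constant_gene_dominates(two_group_labels):
    rng = np.random.default_rng(1)
    mat = rng.uniform(5, 500, size=(10, 4))
    mat[0] = 42.0  # constant, equal group means
    ds = make_dataset(mat, groups=two_group_labels)
    scored = score_dataset(ds).scores
    assert scored.loc["g0", "rank_cv"] == 1.0
    assert scored.loc["g0", "rank_fc"] == 1.0
    assert scored.loc["g0", "dataset_rank"] == 1.0


def test_score_dataset_permutation_invariance(two_group_labels):
    rng = np.random.default_rng(2)
    mat = rng.uniform(5, 500, size=(8, 4))
    ds = make_dataset(mat, groups=two_group_labels)
    perm = rng.permutation(8)
    ds_perm = make_dataset(mat[perm], gene_ids=[f"g{i}" for i in perm],
                           groups=two_group_labels)
    a = score_dataset(ds).scores["dataset_rank"].sort_index()
    b = score_dataset(ds_perm).scores["dataset_rank"].sort_index()
    pd.testing.assert_series_equal(a, b)


def test_score_dataset_requires_linear_annotated(two_group_labels):
    ds = make_dataset([[1.0, 2.0, 3.0, 4.0]] * 2, groups=two_group_labels, scale="log2")
    with pytest.raises(InsufficientDataError):
        score_dataset(ds)
    with pytest.raises(AnnotationError):
        score_dataset(make_dataset([[1.0, 2.0]] * 2))


# -- bootstrap aggregation ----------------------------------------------------

def exact_bootstrap_expectation(rankings, universe):
    """Enumerate all ordered size-D draws of D datasets (each equally likely)
    and return the exact expected bootstrap rank per gene. Independent oracle
    for the Monte-Carlo aggregation path."""
    n = len(universe)
    idx = {g: i for i, g in enumerate(universe)}
    mats = []
    for r in rankings:
        col = np.full(n, np.nan)
        for g, dr in r.scores["dataset_rank"].items():
            col[idx[g]] = dr
        mats.append(col)
    D = len(rankings)
    expected = np.zeros(n)
    draws = list(product(range(D), repeat=D))
    for draw in draws:
        cols = np.column_stack([mats[j] for j in draw])
        cnt = (~np.isnan(cols)).sum(axis=1)
        tot = np.nansum(cols, axis=1)
        means = np.where(cnt > 0, tot / np.maximum(cnt, 1), float(n))
        expected += rankdata(means, method="average")
    return expected / len(draws)


@pytest.fixture
def two_partial_rankings():
    # 5-gene universe; gene e missing from A, gene a missing from B
    a = _ranking_from_ranks("A", ["a", "b", "c", "d"], [1.0, 2.0, 3.0, 4.0])
    b = _ranking_from_ranks("B", ["b", "c", "d", "e"], [4.0, 1.0, 2.0, 3.0])
    return [a, b], ["a", "b", "c", "d", "e"]


def test_bootstrap_matches_exhaustive_enumeration(two_partial_rankings):
    """Monte-Carlo mean bootstrap ranks agree with the exact expectation over
    resampling multisets within 3 standard errors at 10,000 repetitions."""
    rankings, universe = two_partial_rankings
    dist = bootstrap_rankings(rankings, universe,
                              BootstrapConfig(repetitions=10_000, seed=11))
    exact = exact_bootstrap_expectation(rankings, universe)
    mc = dist.mean_rank.to_numpy()
    se = dist.rank_sd.to_numpy() / np.sqrt(10_000)
    assert np.all(np.abs(mc - exact) <= 3 * se + 1e-9)


def test_bootstrap_identical_datasets_zero_spread():
    a = _ranking_from_ranks("A", ["a", "b", "c"], [1.0, 2.0, 3.0])
    b = _ranking_from_ranks("B", ["a", "b", "c"], [1.0, 2.0, 3.0])
    dist = bootstrap_rankings([a, b], ["a", "b", "c"],
                              BootstrapConfig(repetitions=200, seed=0))
    assert dist.rank_sd.tolist() == [0.0, 0.0, 0.0]
    assert dist.mean_rank.tolist() == [1.0, 2.0, 3.0]


def test_bootstrap_seeded_determinism_and_valid_rankings(two_partial_rankings):
    rankings, universe = two_partial_rankings
    d1 = bootstrap_rankings(rankings, universe, BootstrapConfig(500, seed=5))
    d2 = bootstrap_rankings(rankings, universe, BootstrapConfig(500, seed=5))
    np.testing.assert_array_equal(d1.rank_samples, d2.rank_samples)
    # every per-repetition ranking is a valid average-tie ranking
    n = len(universe)
    np.testing.assert_allclose(d1.rank_samples.sum(axis=0), n * (n + 1) / 2)


def test_bootstrap_needs_two_datasets(two_partial_rankings):
    rankings, universe = two_partial_rankings
    with pytest.raises(ConfigurationError):
        bootstrap_rankings(rankings[:1], universe, BootstrapConfig(10, seed=0))


# -- final ranking ------------------------------------------------------------

def _distribution(universe, mean_rank, presence, n_datasets):
    from hkrank.ranking import RankDistribution
    summary = pd.DataFrame(
        {"mean_bootstrap_rank": mean_rank,
         "rank_sd": np.zeros(len(universe)),
         "presence_count": presence},
        index=pd.Index(universe, name="gene_id"),
    )
    return RankDistribution(universe=list(universe),
                            rank_samples=np.asarray(mean_rank)[:, None],
                            summary=summary, n_datasets=n_datasets,
                            config=BootstrapConfig(1, seed=0))


def test_final_ranking_penalty_and_exclusion():
    dist = _distribution(["full", "half", "ghost"], [10.0, 10.0, 1.0],
                         [4, 2, 0], n_datasets=4)
    fr = final_ranking(dist, top_n=2)
    assert fr.table.loc["full", "penalized_score"] == pytest.approx(10.0)
    assert fr.table.loc["half", "penalized_score"] == pytest.approx(20.0)
    assert np.isinf(fr.table.loc["ghost", "penalized_score"])
    assert fr.top(2) == ["full", "half"]  # absent-everywhere gene never reported


def test_final_ranking_lexicographic_tiebreak_and_monotone_penalty():
    dist = _distribution(["zz", "aa"], [10.0, 10.0], [4, 4], n_datasets=4)
    assert final_ranking(dist).genes == ["aa", "zz"]
    # decreasing presence at fixed mean rank never improves the position
    for p in (3, 2, 1):
        worse = _distribution(["x", "ref"], [10.0, 10.0], [p, 4], n_datasets=4)
        assert final_ranking(worse).genes.index("x") >= 1
    with pytest.raises(ConfigurationError):
        final_ranking(dist, top_n=0)
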