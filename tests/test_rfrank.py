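"""Response draws, forest importance, resampled and jack-knifed rankings."""

import numpy as np
import pandas as pd
import pytest

import hostdiscrim as hd
from hostdiscrim.rfrank import (
    RankDistribution,
    RfRunConfig,
    draw_responses,
    forest_importance,
    jackknife_ranking,
    resampled_ranking,
    select_top_bins,
    spearman_screen_fdr,
    top_bins_r2,
)


def _species_index(names):
    return pd.Index(names, name="species")


def test_draw_responses_zero_se_returns_means():
    means = pd.Series([1.0, -2.0], index=_species_index(["A", "B"]))
    ses = pd.Series([0.0, 0.0], index=means.index)
    rng = np.random.default_rng(0)
    out = draw_responses(means, ses, rng)
    pd.testing.assert_series_equal(out, means)


def test_draw_responses_deterministic_and_distributed():
    means = pd.Series([2.0], index=_species_index(["A"]))
    ses = pd.Series([0.5], index=means.index)
    a = draw_responses(means, ses, np.random.default_rng(42))
    b = draw_responses(means, ses, np.random.default_rng(42))
    pd.testing.assert_series_equal(a, b)
    draws = np.array(
        [draw_responses(means, ses, np.random.default_rng(i)).iloc[0]
         for i in range(10_000)]
    )
    assert abs(draws.mean() - 2.0) < 4 * 0.5 / 100
    assert abs(draws.std() - 0.5) / 0.5 < 0.05


def test_draw_responses_missing_se():
    means = pd.Series([1.0, 2.0], index=_species_index(["A", "B"]))
    ses = pd.Series([0.1, np.nan], index=means.index)
    with pytest.raises(ValueError, match="pool_se"):
        draw_responses(means, ses, np.random.default_rng(0))
    out = draw_responses(means, ses, np.random.default_rng(0), pool_se=True)
    assert np.isfinite(out).all()


def _signal_data(n=60, m=30, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, m))
    y = X[:, 4].copy()
    return X, y


def test_forest_importance_finds_signal_bin():
    X, y = _signal_data()
    imp = forest_importance(X, y, RfRunConfig(n_trees=100, seed=1))
    assert imp.argmax() == 4
    assert (imp >= 0).all()


def test_forest_importance_errors():
    X, _ = _signal_data()
    with pytest.raises(ValueError, match="constant"):
        forest_importance(X, np.ones(len(X)), RfRunConfig(n_trees=10))
    with pytest.raises(ValueError, match="10 rows"):
        forest_importance(X[:5], X[:5, 0], RfRunConfig(n_trees=10))


def test_permutation_breaks_association():
    """Under permuted responses the signal bin's rank is uniform-like."""
    X, y = _signal_data()
    rng = np.random.default_rng(3)
    ranks = []
    for i in range(20):
        imp = forest_importance(
            X, rng.permutation(y), RfRunConfig(n_trees=60, seed=i)
        )
        ranks.append(np.argsort(-imp).tolist().index(4) + 1)
    med = np.median(ranks)
    assert 0.15 * X.shape[1] < med < 0.85 * X.shape[1]


def test_rank_multiset_averages_to_midpoint(small_matrix, small_scores):
    cfg = RfRunConfig(n_trees=30, n_resamples=3, seed=5)
    dist = resampled_ranking(small_matrix, small_scores, cfg=cfg)
    M = small_matrix.values.shape[1]
    for _, row in dist.ranks.iterrows():
        assert row.mean() == pytest.approx((M + 1) / 2)


def test_single_resample_has_zero_iqr(small_matrix, small_scores):
    cfg = RfRunConfig(n_trees=30, n_resamples=1, seed=5)
    dist = resampled_ranking(small_matrix, small_scores, cfg=cfg)
    assert (dist.iqr == 0).all()


def test_resampled_ranking_deterministic(small_matrix, small_scores):
    cfg = RfRunConfig(n_trees=30, n_resamples=4, seed=9)
    a = resampled_ranking(small_matrix, small_scores, cfg=cfg)
    b = resampled_ranking(small_matrix, small_scores, cfg=cfg)
    pd.testing.assert_frame_equal(a.ranks, b.ranks)


def test_exclude_plants_changes_fit(small_matrix, small_scores):
    cfg = RfRunConfig(n_trees=30, n_resamples=2, seed=9)
    excl = small_matrix.values.index[:3].tolist()
    ranker = hd.ResampledForestRanker(
        n_trees=30, n_resamples=2, random_state=9
    ).fit(
        small_matrix.values,
        small_scores.set_index("species")["discrimination"],
        small_scores.set_index("species")["se"],
        small_matrix.species,
        exclude_plants=excl,
    )
    assert ranker.ranks_.shape[0] == 2


def test_select_top_bins_tie_rules():
    ranks = pd.DataFrame({"b1": [2, 2], "b2": [1, 3], "b3": [1, 1], "b4": [9, 9]})
    dist = RankDistribution.from_ranks(ranks)
    # b3 median 1 iqr 0; b2 median 2 iqr 1; b1 median 2 iqr 0 -> b1 before b2
    assert select_top_bins(dist, 3) == ["b3", "b1", "b2"]
    assert select_top_bins(dist, 4) == ["b3", "b1", "b2", "b4"]
    with pytest.raises(ValueError):
        select_top_bins(dist, 5)


def test_top_bins_r2_perfect_fit(small_matrix, small_scores):
    sp_means = small_matrix.values.groupby(
        np.asarray(small_matrix.species)
    ).mean()
    bin0 = small_matrix.values.columns[0]
    fake = small_scores.copy()
    fake["discrimination"] = fake["species"].map(sp_means[bin0])
    r2 = top_bins_r2(fake, small_matrix, [bin0])
    assert r2 == pytest.approx(1.0, abs=1e-10)


def test_top_bins_r2_nesting(small_matrix, small_scores):
    cols = list(small_matrix.values.columns[:3])
    r2_small = top_bins_r2(small_scores, small_matrix, cols[:1])
    r2_big = top_bins_r2(small_scores, small_matrix, cols)
    assert r2_big >= r2_small - 1e-12


def test_top_bins_r2_null_expectation():
    """Null R^2 of one random regressor on n species is ~ 1/(n-1)."""
    rng = np.random.default_rng(0)
    n = 19
    vals = []
    for _ in range(150):
        y = rng.normal(size=n)
        x = rng.normal(size=n)
        xc, yc = x - x.mean(), y - y.mean()
        vals.append((xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc)))
    assert abs(np.mean(vals) - 1 / (n - 1)) < 0.025


def test_top_bins_r2_guards(small_matrix, small_scores):
    too_many = list(small_matrix.values.columns[:6])  # 6 species, need > bins+1
    with pytest.raises(ValueError, match="species"):
        top_bins_r2(small_scores, small_matrix, too_many)
    dup = [small_matrix.values.columns[0]] * 2
    with pytest.raises(ValueError, match="condition"):
        top_bins_r2(small_scores, small_matrix, dup)


def test_spearman_screen_sign_and_fdr(small_matrix, small_scores):
    sp_means = small_matrix.values.groupby(
        np.asarray(small_matrix.species)
    ).mean()
    bin0 = small_matrix.values.columns[0]
    fake = small_scores.copy()
    fake["discrimination"] = -fake["species"].map(sp_means[bin0])
    out = spearman_screen_fdr(
        fake, small_matrix, [bin0, small_matrix.values.columns[1]]
    )
    row = out.set_index("bin").loc[bin0]
    assert row["rho"] == pytest.approx(-1.0)
    assert row["q_value"] == out["q_value"].min()


def test_spearman_screen_constant_bin_warns(small_matrix, small_scores):
    m = small_matrix.values.copy()
    m[m.columns[0]] = 5.0
    with pytest.warns(UserWarning, match="constant"):
        out = spearman_screen_fdr(
            small_scores, m, [m.columns[0]], row_species=small_matrix.species
        )
    assert np.isnan(out["rho"].iloc[0])


def test_jackknife_requires_two_per_cell(small_matrix):
    rec = pd.DataFrame(
        {"species": ["A", "A", "B"], "race": ["MS", "TP", "MS"],
         "E2_total_min": [1.0, 2.0, 3.0]}
    )
    with pytest.raises(ValueError, match="fewer than 2"):
        jackknife_ranking(rec, "E2_total_min", small_matrix, n_jack=2)


def test_jackknife_zero_noise_gives_zero_iqr():
    cfg = hd.SyntheticConfig(seed=6, n_species=6, n_medicago=3,
                             plants_per_species=3, sigma_aphid=0.0,
                             sigma_clone=0.0, miss_rate=0.0, n_epg_vars=10,
                             n_dup_pairs=2, n_null_compounds=30,
                             fractions=("polar",))
    ds = hd.generate_dataset(cfg)
    from collections import defaultdict

    by_plant = defaultdict(list)
    for pl in ds.spectra:
        by_plant[pl.plant_id].append(pl)
    combined = [
        hd.combine_replicates([hd.bin_spectrum(p, cfg.binning) for p in pls])[0]
        for pls in by_plant.values()
    ]
    mat = hd.build_matrix(combined, fraction="polar")
    prof = ds.epg[["species", "race"]].copy()
    prof["E2_total_min"] = ds.epg["E2_total_min"].to_numpy()
    dist = jackknife_ranking(
        prof, "E2_total_min", mat,
        cfg=RfRunConfig(n_trees=30, seed=2), n_jack=5,
    )
    assert (dist.iqr == 0).all()


def test_jackknife_n2_cells_well_defined():
    rng = np.random.default_rng(1)
    rec = pd.DataFrame(
        {
            "species": np.repeat(["A", "B", "C"], 4),
            "race": ["MS", "MS", "TP", "TP"] * 3,
            "E2_total_min": rng.uniform(10, 300, 12),
        }
    )
    X = pd.DataFrame(
        rng.lognormal(0, 1, (15, 12)),
        index=[f"p{i}" for i in range(15)],
    )
    sp = pd.Series(np.repeat(["A", "B", "C"], 5), index=X.index)
    dist = jackknife_ranking(
        rec, "E2_total_min", X, cfg=RfRunConfig(n_trees=20, seed=3),
        n_jack=4, row_species=sp,
    )
    assert dist.ranks.shape == (4, 12)
    assert np.isfinite(dist.median_rank).all()
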