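"""EPG cleaning rules, imputation, and the per-race discriminant axis."""

import numpy as np
import pandas as pd
import pytest

import hostdiscrim as hd
from hostdiscrim.epg import (
    CleaningConfig,
    SpeciesLDA,
    clean_table,
    compute_ld1,
    extract_e2,
    feature_columns,
    filter_zero_inflated,
    impute_missing,
    prune_correlated,
)
from hostdiscrim.synth import SyntheticConfig, generate_epg_table, generate_latents


def _table(values: dict, n: int) -> pd.DataFrame:
    base = {
        "recording_id": [f"r{i}" for i in range(n)],
        "race": ["MS", "TP"] * (n // 2),
        "clone": ["c1"] * n,
        "species": ["spA", "spB"] * (n // 2),
        "genus": ["G"] * n,
        "E2_total_min": np.linspace(10, 300, n),
    }
    base.update(values)
    return pd.DataFrame(base)


# --- imputation -----------------------------------------------------------

def test_impute_identity_without_missing():
    t = _table({"var_001": np.arange(10.0)}, 10)
    out = impute_missing(t, seed=0, n_trees=20)
    pd.testing.assert_frame_equal(out, t)


def test_impute_constant_column_case():
    vals = np.full(10, 7.0)
    vals[3] = np.nan
    t = _table({"var_001": vals, "var_002": np.arange(10.0)}, 10)
    out = impute_missing(t, seed=0, n_trees=20)
    assert out.loc[3, "var_001"] == pytest.approx(7.0)
    # observed cells untouched
    assert (out.loc[out.index != 3, "var_001"] == 7.0).all()


def test_impute_errors_on_fully_missing_variable():
    t = _table({"var_001": [np.nan] * 10}, 10)
    with pytest.raises(ValueError, match="var_001"):
        impute_missing(t, seed=0, n_trees=20)


def test_impute_beats_global_mean_on_masked_cells():
    """Mask-and-recover: proximity imputation should use the correlated
    variable structure that a global mean ignores."""
    rmse_tree, rmse_mean = [], []
    for seed in range(5):
        cfg = SyntheticConfig(seed=seed, n_species=8, n_medicago=4,
                              miss_rate=0.0, n_epg_vars=20, n_dup_pairs=4,
                              fractions=("polar",))
        truth = generate_latents(cfg)
        epg = generate_epg_table(truth, cfg)
        cols = truth.epg_var_roles["informative"]
        rng = np.random.default_rng(100 + seed)
        masked = epg.copy()
        cells = []
        for c in cols:
            rows = rng.choice(len(epg), size=6, replace=False)
            masked.loc[rows, c] = np.nan
            cells += [(r, c) for r in rows]
        imputed = impute_missing(masked, seed=seed, n_trees=100)
        err_t = [imputed.loc[r, c] - epg.loc[r, c] for r, c in cells]
        err_m = [masked[c].mean() - epg.loc[r, c] for r, c in cells]
        rmse_tree.append(np.sqrt(np.mean(np.square(err_t))))
        rmse_mean.append(np.sqrt(np.mean(np.square(err_m))))
    assert np.mean(rmse_tree) < np.mean(rmse_mean)


# --- zero filter ----------------------------------------------------------

def test_zero_filter_boundary():
    t = _table(
        {
            "var_001": [0] * 5 + [1] * 5,     # exactly 50% zeros -> removed
            "var_002": [0] * 4 + [1] * 6,     # 40% zeros -> kept
            "var_003": [0] * 10,              # all zero -> removed
        },
        10,
    )
    out, rep = filter_zero_inflated(t)
    assert rep.zero_dropped == ["var_001", "var_003"]
    assert "var_002" in out.columns
    assert "E2_total_min" in out.columns and "race" in out.columns


# --- correlation pruning --------------------------------------------------

def test_prune_duplicate_drops_later_column():
    x = np.arange(10.0)
    alt = np.array([1.0, -1.0] * 5)  # uncorrelated with the ramp
    t = _table({"var_001": x, "var_002": x.copy(), "var_003": alt}, 10)
    out, rep = prune_correlated(t)
    assert [p[:2] for p in rep.pruned] == [("var_001", "var_002")]
    assert "var_001" in out.columns and "var_002" not in out.columns


def test_prune_exact_threshold_is_strict():
    # r is exactly 4/5 by construction: y = 4*zx + 3*zperp with equal norms
    zx = np.array([1.0, 1.0, -1.0, -1.0])
    zperp = np.array([1.0, -1.0, 1.0, -1.0])
    t = _table({"var_001": zx, "var_002": 4 * zx + 3 * zperp}, 4)
    r = np.corrcoef(zx, 4 * zx + 3 * zperp)[0, 1]
    assert r == 0.8  # exactly representable here
    out, rep = prune_correlated(t)
    assert rep.pruned == []
    assert {"var_001", "var_002"} <= set(out.columns)


def test_prune_chain_keeps_ends():
    # A~B and B~C above the threshold while A~C is below: B is dropped when
    # A is scanned, and C survives because the (B, C) pair is never reached
    rng = np.random.default_rng(0)
    n = 2000
    b = rng.normal(size=n)
    u, v = rng.normal(size=n), rng.normal(size=n)
    ea, ec = u, -0.84 * u + np.sqrt(1 - 0.84**2) * v
    a = 0.9 * b + np.sqrt(1 - 0.81) * ea
    c = 0.9 * b + np.sqrt(1 - 0.81) * ec
    assert abs(np.corrcoef(a, b)[0, 1]) > 0.8
    assert abs(np.corrcoef(b, c)[0, 1]) > 0.8
    assert abs(np.corrcoef(a, c)[0, 1]) < 0.8
    t = _table({"var_001": a, "var_002": b, "var_003": c}, n)
    out, rep = prune_correlated(t)
    assert [p[1] for p in rep.pruned] == ["var_002"]
    assert {"var_001", "var_003"} <= set(out.columns)


def test_prune_keeps_constant_column_with_warning():
    t = _table({"var_001": np.arange(10.0), "var_002": np.full(10, 3.0)}, 10)
    with pytest.warns(UserWarning, match="var_002"):
        out, _ = prune_correlated(t)
    assert "var_002" in out.columns


def test_cleaning_idempotent_and_decorrelated(small_dataset):
    imputed = impute_missing(small_dataset.epg, seed=0, n_trees=50)
    cleaned, rep = clean_table(imputed)
    again, rep2 = clean_table(cleaned)
    pd.testing.assert_frame_equal(cleaned, again)
    assert rep2.zero_dropped == [] and rep2.pruned == []
    cols = feature_columns(cleaned)
    corr = np.corrcoef(cleaned[cols].to_numpy(dtype=float), rowvar=False)
    np.fill_diagonal(corr, 0.0)
    finite = corr[np.isfinite(corr)]
    assert np.abs(finite).max() <= 0.80 + 1e-12


def test_cleaning_report_partition(small_dataset):
    imputed = impute_missing(small_dataset.epg, seed=0, n_trees=50)
    cleaned, rep = clean_table(imputed)
    dropped = set(rep.zero_dropped) | {p[1] for p in rep.pruned}
    assert dropped | set(rep.remaining) == set(feature_columns(imputed))
    assert not dropped & set(rep.remaining)


# --- LDA ------------------------------------------------------------------

def test_lda_separable_two_species():
    rng = np.random.default_rng(1)
    X = np.r_[rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))]
    y = ["A"] * 10 + ["B"] * 10
    lda = SpeciesLDA().fit(X, y)
    s = lda.transform(X)[:, 0]
    assert max(s[:10]) < min(s[10:]) or min(s[:10]) > max(s[10:])
    assert 0.0 <= lda.explained_variance_ratio_[0] <= 1.0


def test_lda_errors():
    X = np.random.default_rng(0).normal(size=(6, 3))
    with pytest.raises(ValueError):
        SpeciesLDA().fit(X, ["A"] * 6)
    with pytest.raises(ValueError):
        SpeciesLDA().fit(X, ["A", "A", "A", "A", "A", "B"])


def test_ld1_affine_invariance(small_dataset):
    imputed = impute_missing(small_dataset.epg, seed=0, n_trees=50)
    cleaned, _ = clean_table(imputed)
    scores, _ = compute_ld1(cleaned, "MS")
    rescaled = cleaned.copy()
    var = feature_columns(cleaned)[0]
    rescaled[var] = rescaled[var] * 37.0 - 4.2
    scores2, _ = compute_ld1(rescaled, "MS")
    # tolerance reflects the tiny relative ridge, which is not scale-free
    agree = np.allclose(scores["ld1"], scores2["ld1"], atol=1e-4)
    flipped = np.allclose(scores["ld1"], -scores2["ld1"], atol=1e-4)
    assert agree or flipped


def test_ld1_tracks_planted_race_means():
    hits = 0
    for seed in range(3):
        cfg = SyntheticConfig(seed=seed, n_epg_vars=40, miss_rate=0.0,
                              fractions=("polar",))
        truth = generate_latents(cfg)
        epg = generate_epg_table(truth, cfg)
        cleaned, _ = clean_table(epg)
        scores, lda = compute_ld1(cleaned, "MS")
        sp_mean = scores.groupby("species")["ld1"].mean()
        planted = truth.species.set_index("species")["m_MS"]
        r = np.corrcoef(sp_mean, planted.loc[sp_mean.index])[0, 1]
        assert 0.0 <= lda.explained_variance_ratio_[0] <= 1.0
        if abs(r) > 0.8:
            hits += 1
    assert hits == 3


# --- E2 -------------------------------------------------------------------

def test_extract_e2_validation():
    t = _table({"var_001": np.arange(4.0)}, 4)
    assert extract_e2(t).equals(t["E2_total_min"].astype(float))
    bad = t.copy()
    bad.loc[0, "E2_total_min"] = 400.0
    with pytest.raises(ValueError):
        extract_e2(bad)
    with pytest.raises(KeyError):
        extract_e2(t.drop(columns=["E2_total_min"]))
    zero = t.copy()
    zero.loc[0, "E2_total_min"] = 0.0
    assert extract_e2(zero).iloc[0] == 0.0
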