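"""Uncertainty-propagating random-forest importance ranking of m/z bins.

The central inference: which m/z bins predict a behavioural score
(discrimination or overall acceptability) across plant species?  A single
random-forest fit gives an importance ranking but ignores the sampling
uncertainty of the species-level scores.  Here that uncertainty is
propagated by resampling: for each of R runs, a response value per species
is drawn from Normal(mean, SE^2), every plant individual inherits its
species' draw, a regression forest is fitted on the plants x bins %TIC
matrix, and bins are ranked by impurity-decrease importance (rank 1 = most
important).  Per-bin median rank orders the bins; the interquartile range
of ranks measures consistency.

Two stability analyses complement the resampling: a jack-knife that deletes
one random recording per species x race cell before recomputing scores, and
an optional plant-exclusion rerun (dropping PCA outliers).  Follow-up
statistics — OLS R^2 of the score on the top bins' species means, and a
Spearman screen with Benjamini-Hochberg FDR — quantify how much of the
behavioural variation the selected bins explain.

Importance is the regression analogue of "mean decrease in Gini": the total
node-impurity (residual-sum-of-squares) decrease attributable to splits on a
bin, summed over nodes and averaged over trees, without per-tree
normalisation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.multitest import multipletests

from .scores import discrimination_acceptability, summarize_profiles
from .spectra import ProfileMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RfRunConfig",
    "RankDistribution",
    "draw_responses",
    "forest_importance",
    "ResampledForestRanker",
    "resampled_ranking",
    "JackknifeForestRanker",
    "jackknife_ranking",
    "select_top_bins",
    "top_bins_r2",
    "spearman_screen_fdr",
]


@dataclass(frozen=True)
class RfRunConfig:
    """Forest and resampling sizes (defaults follow common regression-forest
    practice: mtry = floor(M/3), minimum node size 5)."""

    n_trees: int = 1000
    n_resamples: int = 500
    top_k: int = 8
    mtry: int | None = None      # None -> floor(M/3)
    min_node: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trees", "n_resamples", "top_k", "min_node"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class RankDistribution:
    """Per-bin importance ranks across resamples, with median and IQR."""

    ranks: pd.DataFrame        # resamples x bins
    median_rank: pd.Series     # per bin
    iqr: pd.Series             # per bin

    @classmethod
    def from_ranks(cls, ranks: pd.DataFrame) -> "RankDistribution":
        med = ranks.median(axis=0)
        q1 = ranks.quantile(0.25, axis=0)
        q3 = ranks.quantile(0.75, axis=0)
        return cls(ranks=ranks, median_rank=med, iqr=q3 - q1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": self.median_rank.index,
             "median_rank": self.median_rank.to_numpy(),
             "iqr": self.iqr.to_numpy()}
        ).reset_index(drop=True)


def draw_responses(
    means: pd.Series,
    ses: pd.Series,
    rng: np.random.Generator,
    pool_se: bool = False,
) -> pd.Series:
    """One Normal(mean, SE^2) draw per species; SE = 0 returns the mean.

    Species with a missing SE (single-recording cells) raise unless
    ``pool_se`` is set, in which case the mean SE of the remaining species
    is substituted.
    """
    means = means.astype(float)
    ses = ses.reindex(means.index).astype(float)
    if ses.isna().any():
        missing = ses[ses.isna()].index.tolist()
        if not pool_se:
            raise ValueError(
                f"species without SE: {missing}; exclude them or set pool_se=True"
            )
        pooled = float(ses.dropna().mean())
        if np.isnan(pooled):
            raise ValueError("no SEs available to pool")
        ses = ses.fillna(pooled)
    draws = means.to_numpy() + rng.standard_normal(len(means)) * ses.to_numpy()
    return pd.Series(draws, index=means.index)


def forest_importance(
    X, y, cfg: RfRunConfig | None = None, random_state: int | None = None
) -> np.ndarray:
    """Impurity-decrease importance per bin from one regression forest.

    Importance is the RSS decrease from splits on each feature, summed over
    nodes and averaged over trees (no per-tree normalisation), so values are
    non-negative and on the response's variance scale.
    """
    cfg = cfg or RfRunConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 rows to fit a forest")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    mtry = cfg.mtry if cfg.mtry is not None else max(1, X.shape[1] // 3)
    forest = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=min(mtry, X.shape[1]),
        min_samples_leaf=cfg.min_node,
        random_state=cfg.seed if random_state is None else random_state,
        n_jobs=1,
    ).fit(X, y)
    imp = np.mean(
        [t.tree_.compute_feature_importances(normalize=False)
         for t in forest.estimators_],
        axis=0,
    )
    return imp


def _rank_descending(importance: np.ndarray) -> np.ndarray:
    """Rank 1 = largest importance; ties get average ranks."""
    return stats.rankdata(-importance, method="average")


class ResampledForestRanker(BaseEstimator):
    """Rank m/z bins by forest importance under response uncertainty.

    Parameters mirror :class:`RfRunConfig`.  ``fit`` takes the plants x bins
    matrix, per-species score means and SEs, and the species of each row;
    every plant inherits its species' drawn response.  Fitted attributes:
    ``ranks_`` (R x M frame), ``median_rank_``, ``iqr_``,
    ``rank_distribution_``.
    """

    def __init__(self, n_trees: int = 1000, n_resamples: int = 500,
                 mtry: int | None = None, min_node: int = 5,
                 pool_se: bool = False, random_state: int = 0):
        self.n_trees = n_trees
        self.n_resamples = n_resamples
        self.mtry = mtry
        self.min_node = min_node
        self.pool_se = pool_se
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, score_means: pd.Series, score_ses: pd.Series,
            row_species: pd.Series, exclude_plants: list | None = None):
        X = pd.DataFrame(X)
        row_species = pd.Series(row_species, index=X.index)
        if exclude_plants:
            keep = ~X.index.isin(exclude_plants)
            X, row_species = X.loc[keep], row_species.loc[keep]
        known = row_species.isin(score_means.index)
        if not known.all():
            missing = sorted(row_species[~known].unique().tolist())
            raise ValueError(f"rows with species missing from scores: {missing}")
        cfg = RfRunConfig(
            n_trees=self.n_trees, n_resamples=self.n_resamples,
            mtry=self.mtry, min_node=self.min_node, seed=self.random_state,
        )
        ss = np.random.SeedSequence(self.random_state)
        sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                     ss.spawn(self.n_resamples)]
        Xv = X.to_numpy(dtype=float)
        all_ranks = np.empty((self.n_resamples, X.shape[1]))
        for r in range(self.n_resamples):
            rng = np.random.default_rng(sub_seeds[r])
            draw = draw_responses(score_means, score_ses, rng, pool_se=self.pool_se)
            y = row_species.map(draw).to_numpy(dtype=float)
            imp = forest_importance(Xv, y, cfg, random_state=sub_seeds[r])
            all_ranks[r] = _rank_descending(imp)
        self.ranks_ = pd.DataFrame(all_ranks, columns=X.columns)
        dist = RankDistribution.from_ranks(self.ranks_)
        self.median_rank_ = dist.median_rank
        self.iqr_ = dist.iqr
        self.rank_distribution_ = dist
        return self


def _scores_for(score_table: pd.DataFrame, response: str,
                profile: str | None = None) -> tuple[pd.Series, pd.Series]:
    if response not in ("discrimination", "acceptability"):
        raise ValueError("response must be 'discrimination' or 'acceptability'")
    tab = score_table
    if profile is not None:
        tab = tab[tab["profile"] == profile]
    if tab.empty:
        raise ValueError("empty score table after profile filter")
    tab = tab.set_index("species")
    return tab[response], tab["se"]


def resampled_ranking(
    X: ProfileMatrix | pd.DataFrame,
    score_table: pd.DataFrame,
    response: str = "discrimination",
    cfg: RfRunConfig | None = None,
    profile: str | None = None,
    row_species: pd.Series | None = None,
    exclude_plants: list | None = None,
    pool_se: bool = False,
) -> RankDistribution:
    """Resampled-response forest ranking of every bin (functional wrapper)."""
    cfg = cfg or RfRunConfig()
    if isinstance(X, ProfileMatrix):
        row_species = X.species
        X = X.values
    if row_species is None:
        raise ValueError("row_species required when X is a plain DataFrame")
    means, ses = _scores_for(score_table, response, profile)
    ranker = ResampledForestRanker(
        n_trees=cfg.n_trees, n_resamples=cfg.n_resamples, mtry=cfg.mtry,
        min_node=cfg.min_node, pool_se=pool_se, random_state=cfg.seed,
    ).fit(X, means, ses, row_species, exclude_plants=exclude_plants)
    return ranker.rank_distribution_


class JackknifeForestRanker(BaseEstimator):
    """Rank stability under leave-one-recording-out jack-knifing.

    Each jack-knife replicate removes one random recording from every
    species x race cell of the per-recording profile table, recomputes the
    species-level point scores (no SE draw), fits one forest and ranks the
    bins.  Median/IQR across replicates measure how sensitive each bin's
    rank is to individual recordings.
    """

    def __init__(self, n_trees: int = 1000, n_jack: int = 500,
                 mtry: int | None = None, min_node: int = 5,
                 response: str = "discrimination",
                 cell_columns: tuple[str, str] = ("species", "race"),
                 random_state: int = 0):
        self.n_trees = n_trees
        self.n_jack = n_jack
        self.mtry = mtry
        self.min_node = min_node
        self.response = response
        self.cell_columns = cell_columns
        self.random_state = random_state

    def fit(self, recordings: pd.DataFrame, value_column: str,
            X: pd.DataFrame, row_species: pd.Series):
        cells = recordings.groupby(list(self.cell_columns), sort=True)
        sizes = cells.size()
        if (sizes < 2).any():
            bad = sizes[sizes < 2].index.tolist()
            raise ValueError(f"cell(s) with fewer than 2 recordings: {bad}")
        cfg = RfRunConfig(
            n_trees=self.n_trees, n_resamples=1, mtry=self.mtry,
            min_node=self.min_node, seed=self.random_state,
        )
        ss = np.random.SeedSequence(self.random_state)
        sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                     ss.spawn(self.n_jack)]
        # deletion RNG varies per replicate; the forest seed is fixed so that
        # identical jack-knife datasets yield identical ranks (the jack-knife
        # measures data sensitivity, not forest randomness)
        forest_seed = int(ss.generate_state(1)[0] % (2**31))
        Xv = X.to_numpy(dtype=float)
        groups = {key: grp.index.to_numpy() for key, grp in cells}
        all_ranks = np.empty((self.n_jack, X.shape[1]))
        for j in range(self.n_jack):
            rng = np.random.default_rng(sub_seeds[j])
            drop = [rng.choice(idx) for idx in groups.values()]
            sub = recordings.drop(index=drop)
            prof = summarize_profiles(sub, value_columns=[value_column])
            score = discrimination_acceptability(prof).set_index("species")
            y = row_species.map(score[self.response]).to_numpy(dtype=float)
            imp = forest_importance(Xv, y, cfg, random_state=forest_seed)
            all_ranks[j] = _rank_descending(imp)
        self.ranks_ = pd.DataFrame(all_ranks, columns=X.columns)
        dist = RankDistribution.from_ranks(self.ranks_)
        self.median_rank_ = dist.median_rank
        self.iqr_ = dist.iqr
        self.rank_distribution_ = dist
        return self


def jackknife_ranking(
    recordings: pd.DataFrame,
    value_column: str,
    X: ProfileMatrix | pd.DataFrame,
    cfg: RfRunConfig | None = None,
    n_jack: int = 500,
    response: str = "discrimination",
    cell_columns: tuple[str, str] = ("species", "race"),
    row_species: pd.Series | None = None,
) -> RankDistribution:
    """Jack-knife stability ranking (functional wrapper)."""
    cfg = cfg or RfRunConfig()
    if isinstance(X, ProfileMatrix):
        row_species = X.species
        X = X.values
    if row_species is None:
        raise ValueError("row_species required when X is a plain DataFrame")
    ranker = JackknifeForestRanker(
        n_trees=cfg.n_trees, n_jack=n_jack, mtry=cfg.mtry,
        min_node=cfg.min_node, response=response,
        cell_columns=cell_columns, random_state=cfg.seed,
    ).fit(recordings, value_column, X, row_species)
    return ranker.rank_distribution_


def select_top_bins(dist: RankDistribution, k: int) -> list:
    """The k bins with smallest median rank; ties broken by smaller IQR,
    then by ascending bin label."""
    frame = dist.to_frame()
    if k > len(frame):
        raise ValueError(f"k={k} exceeds the number of bins ({len(frame)})")
    frame = frame.sort_values(
        ["median_rank", "iqr", "bin"], kind="mergesort"
    )
    return frame["bin"].head(k).tolist()


def top_bins_r2(
    score_table: pd.DataFrame,
    X: ProfileMatrix | pd.DataFrame,
    bins: list,
    response: str = "discrimination",
    profile: str | None = None,
    row_species: pd.Series | None = None,
    max_condition: float = 1e10,
) -> float:
    """OLS R^2 of the species-level score on species-mean %TIC of the bins."""
    if isinstance(X, ProfileMatrix):
        row_species = X.species
        X = X.values
    if row_species is None:
        raise ValueError("row_species required when X is a plain DataFrame")
    means, _ = _scores_for(score_table, response, profile)
    sp_means = X[bins].groupby(np.asarray(row_species)).mean()
    common = means.index.intersection(sp_means.index)
    if len(common) <= len(bins) + 1:
        raise ValueError(
            f"need more species ({len(common)}) than bins + 1 ({len(bins) + 1})"
        )
    design = sm.add_constant(sp_means.loc[common].to_numpy())
    cond = np.linalg.cond(design)
    if cond > max_condition:
        raise ValueError(f"collinear design: condition number {cond:.3g}")
    fit = sm.OLS(means.loc[common].to_numpy(), design).fit()
    return float(fit.rsquared)


def spearman_screen_fdr(
    score_table: pd.DataFrame,
    X: ProfileMatrix | pd.DataFrame,
    bins: list,
    response: str = "discrimination",
    profile: str | None = None,
    row_species: pd.Series | None = None,
) -> pd.DataFrame:
    """Spearman rho of species-mean %TIC vs score per bin, with BH q-values.

    Constant bins yield NaN with a warning and are excluded from the FDR
    set.  Sign convention follows the score: bins abundant where TP-race
    acceptance dominates correlate negatively with an MS-positive
    discrimination score.
    """
    if isinstance(X, ProfileMatrix):
        row_species = X.species
        X = X.values
    if row_species is None:
        raise ValueError("row_species required when X is a plain DataFrame")
    means, _ = _scores_for(score_table, response, profile)
    if len(means) < 4:
        raise ValueError("need at least 4 species")
    sp_means = X[bins].groupby(np.asarray(row_species)).mean()
    common = means.index.intersection(sp_means.index)
    y = means.loc[common].to_numpy()
    rows = []
    for b in bins:
        v = sp_means.loc[common, b].to_numpy()
        if np.ptp(v) == 0:
            warnings.warn(f"bin {b!r} constant across species; rho undefined")
            rows.append((b, np.nan, np.nan))
            continue
        res = stats.spearmanr(v, y)
        rows.append((b, float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["bin", "rho", "p_value"])
    tested = out["p_value"].notna()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = multipletests(
            out.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    out["q_value"] = q
    return out
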