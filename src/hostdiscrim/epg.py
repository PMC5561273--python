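"""EPG feature-table cleaning and per-aphid acceptance summaries.

An EPG (electrical penetration graph) recording yields ~119 behavioural
variables per aphid (counts and durations of stylet-activity waveforms).
This module cleans those tables — proximity-based tree-ensemble imputation
of missing values, removal of variables that are zero in at least half the
recordings, and greedy pruning of one member of every highly correlated
pair — and computes the two per-recording acceptance summaries:

* **E2**: total duration (minutes) of passive phloem-sap ingestion, the
  direct behavioural acceptance measure;
* **LD1**: the score on the first axis of a Fisher linear discriminant
  analysis of the cleaned variables, fitted within one aphid race with
  plant species as the grouping factor — a broad behavioural summary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "LABEL_COLUMNS",
    "E2_COLUMN",
    "CleaningConfig",
    "CleaningReport",
    "feature_columns",
    "impute_missing",
    "filter_zero_inflated",
    "prune_correlated",
    "clean_table",
    "SpeciesLDA",
    "compute_ld1",
    "extract_e2",
]

LABEL_COLUMNS = ("recording_id", "race", "clone", "species", "genus")
E2_COLUMN = "E2_total_min"
MAX_RECORDING_MIN = 360.0  # 6-hour recording window


@dataclass(frozen=True)
class CleaningConfig:
    zero_frac_threshold: float = 0.50
    corr_threshold: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_frac_threshold <= 1.0:
            raise ValueError("zero_frac_threshold must be in [0, 1]")
        if not 0.0 <= self.corr_threshold <= 1.0:
            raise ValueError("corr_threshold must be in [0, 1]")


@dataclass
class CleaningReport:
    zero_dropped: list[str] = field(default_factory=list)
    pruned: list[tuple[str, str, float]] = field(default_factory=list)  # (kept, dropped, r)
    remaining: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Behavioural variable columns: everything except labels and E2."""
    skip = set(LABEL_COLUMNS) | {E2_COLUMN}
    return [c for c in table.columns if c not in skip]


def impute_missing(
    table: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 300,
    n_iter: int = 3,
) -> pd.DataFrame:
    """Proximity-weighted iterative tree-ensemble imputation, median start.

    Missing cells are initialised to the column median; each iteration fits
    a classification forest predicting plant species from all variables,
    derives the case-proximity matrix (fraction of trees in which two
    recordings land in the same leaf), and replaces each missing cell by
    the proximity-weighted mean of the observed values in its column.
    Observed cells are never altered.  The E2 column must be complete.
    """
    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    miss = np.isnan(X)
    if table[E2_COLUMN].isna().any():
        raise ValueError(f"{E2_COLUMN} must not contain missing values")
    if not miss.any():
        return table.copy()
    all_missing = [c for c, m in zip(cols, miss.all(axis=0)) if m]
    if all_missing:
        raise ValueError(f"variable(s) entirely missing: {all_missing}")
    n_obs_per_col = (~miss).sum(axis=0)
    if (n_obs_per_col < 2).any():
        bad = [c for c, n in zip(cols, n_obs_per_col) if n < 2]
        raise ValueError(f"variable(s) with fewer than 2 observed values: {bad}")

    med = np.nanmedian(X, axis=0)
    Xi = np.where(miss, med[None, :], X)
    y = table["species"].to_numpy()
    for it in range(n_iter):
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + it, n_jobs=1
        ).fit(Xi, y)
        leaves = forest.apply(Xi)  # n x T
        prox = _proximity(leaves)
        np.fill_diagonal(prox, 0.0)  # a case does not inform its own gap
        for k in np.where(miss.any(axis=0))[0]:
            obs = ~miss[:, k]
            w = prox[np.ix_(miss[:, k], obs)]
            wsum = w.sum(axis=1)
            vals = X[obs, k]
            est = np.where(wsum > 0, w @ vals / np.where(wsum > 0, wsum, 1.0), med[k])
            Xi[miss[:, k], k] = est
    out = table.copy()
    out[cols] = Xi
    return out


def _proximity(leaves: np.ndarray) -> np.ndarray:
    n, n_trees = leaves.shape
    prox = np.zeros((n, n), dtype=float)
    for t in range(n_trees):
        col = leaves[:, t]
        prox += col[:, None] == col[None, :]
    return prox / n_trees


def filter_zero_inflated(
    table: pd.DataFrame, config: CleaningConfig | None = None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop variables with >= ``zero_frac_threshold`` of values equal to zero."""
    config = config or CleaningConfig()
    cols = feature_columns(table)
    n = len(table)
    dropped = [
        c for c in cols
        if (table[c].to_numpy(dtype=float) == 0.0).sum() / n >= config.zero_frac_threshold
    ]
    report = CleaningReport(
        zero_dropped=dropped,
        remaining=[c for c in cols if c not in dropped],
    )
    return table.drop(columns=dropped), report


def prune_correlated(
    table: pd.DataFrame, config: CleaningConfig | None = None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Greedy pruning of correlated variable pairs, in column order.

    For each pair with Pearson ``|r|`` strictly above the threshold where
    both members are still present, the later column is dropped.  After the
    pass no remaining pair exceeds the threshold.  Zero-variance variables
    cannot enter a correlation and are kept with a warning.
    """
    config = config or CleaningConfig()
    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    sd = X.std(axis=0)
    constant = [c for c, s in zip(cols, sd) if s == 0.0]
    if constant:
        warnings.warn(f"zero-variance variable(s) kept, excluded from pruning: {constant}")
    active = [c for c in cols if c not in constant]
    idx = {c: cols.index(c) for c in cols}
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    alive = dict.fromkeys(active, True)
    pruned: list[tuple[str, str, float]] = []
    for i, ci in enumerate(active):
        if not alive[ci]:
            continue
        for cj in active[i + 1:]:
            if not alive[cj]:
                continue
            r = corr[idx[ci], idx[cj]]
            if abs(r) > config.corr_threshold:
                alive[cj] = False
                pruned.append((ci, cj, float(r)))
    dropped = [c for c in active if not alive[c]]
    report = CleaningReport(
        pruned=pruned,
        remaining=[c for c in cols if c not in dropped],
    )
    return table.drop(columns=dropped), report


def clean_table(
    table: pd.DataFrame, config: CleaningConfig | None = None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Zero-inflation filter followed by correlation pruning; merged report."""
    config = config or CleaningConfig()
    t1, rep1 = filter_zero_inflated(table, config)
    t2, rep2 = prune_correlated(t1, config)
    return t2, CleaningReport(
        zero_dropped=rep1.zero_dropped,
        pruned=rep2.pruned,
        remaining=rep2.remaining,
    )


class SpeciesLDA(BaseEstimator):
    """Fisher linear discriminant axis with plant species as groups.

    Solves the generalised eigenproblem of the among-species scatter against
    the pooled within-species covariance (a small ridge ``eps * trace / p``
    is added for numerical stability).  ``transform`` returns discriminant
    scores; the first column is the LD1 profile.  Sign convention: the
    largest-magnitude element of the first loading vector is positive.

    Fitted attributes: ``scalings_`` (p x k loadings),
    ``explained_variance_ratio_`` (fraction of among-species variance per
    axis), ``classes_``, ``means_``.
    """

    def __init__(self, ridge_eps: float = 1e-8):
        self.ridge_eps = ridge_eps

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("LDA needs at least 2 species groups")
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            small = classes[counts < 2].tolist()
            raise ValueError(f"every species needs >= 2 recordings; offending: {small}")
        n, p = X.shape
        grand = X.mean(axis=0)
        Sw = np.zeros((p, p))
        Sb = np.zeros((p, p))
        means = np.empty((classes.size, p))
        for g in range(classes.size):
            Xg = X[y_idx == g]
            mu = Xg.mean(axis=0)
            means[g] = mu
            Sw += (Xg - mu).T @ (Xg - mu)
            Sb += counts[g] * np.outer(mu - grand, mu - grand)
        Sw /= max(n - classes.size, 1)
        Sb /= max(classes.size - 1, 1)
        Sw += np.eye(p) * (self.ridge_eps * np.trace(Sw) / p)
        try:
            evals, evecs = scipy.linalg.eigh(Sb, Sw)
        except scipy.linalg.LinAlgError as exc:
            raise ValueError("within-species covariance singular even after "
                             "ridge regularisation") from exc
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        k = min(classes.size - 1, p)
        evals, evecs = np.clip(evals[:k], 0.0, None), evecs[:, :k]
        # sign convention: dominant element of each loading positive
        for j in range(k):
            lead = np.argmax(np.abs(evecs[:, j]))
            if evecs[lead, j] < 0:
                evecs[:, j] = -evecs[:, j]
        self.classes_ = classes
        self.means_ = means
        self.scalings_ = evecs
        total = evals.sum()
        self.explained_variance_ratio_ = (
            evals / total if total > 0 else np.zeros_like(evals)
        )
        self._grand_mean = grand
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self._grand_mean) @ self.scalings_


def compute_ld1(
    table: pd.DataFrame,
    race: str,
    ridge_eps: float = 1e-8,
    orient_by: str | None = E2_COLUMN,
    standardize: bool = True,
) -> tuple[pd.DataFrame, SpeciesLDA]:
    """Per-recording LD1 scores for one aphid race.

    A discriminant axis has arbitrary sign and scale, and the loading-based
    convention of :class:`SpeciesLDA` need not agree between races.  With
    ``orient_by`` (default: the E2 column) the axis is flipped, if needed,
    so LD1 correlates positively with that acceptance measure — positive
    LD1 then means preference for both races.  With ``standardize`` the
    scores are z-scored within the race, putting independently fitted axes
    on a common scale; both are required for cross-race sums and
    differences of LD1 means to be meaningful.  Pass ``orient_by=None``
    and ``standardize=False`` for the raw axis.

    Returns a frame (recording_id, species, race, clone, ld1) and the fitted
    :class:`SpeciesLDA` (loadings in ``scalings_``, LD1 among-species
    variance fraction in ``explained_variance_ratio_[0]``).
    """
    sub = table[table["race"] == race]
    if sub.empty:
        raise ValueError(f"no recordings for race {race!r}")
    cols = feature_columns(sub)
    lda = SpeciesLDA(ridge_eps=ridge_eps).fit(
        sub[cols].to_numpy(dtype=float), sub["species"].to_numpy()
    )
    scores = lda.transform(sub[cols].to_numpy(dtype=float))[:, 0]
    if orient_by is not None:
        if orient_by not in sub.columns:
            raise KeyError(f"orientation column {orient_by!r} absent")
        anchor = sub[orient_by].to_numpy(dtype=float)
        if np.std(anchor) > 0 and np.std(scores) > 0:
            if np.corrcoef(scores, anchor)[0, 1] < 0:
                scores = -scores
    if standardize and np.std(scores) > 0:
        scores = (scores - scores.mean()) / scores.std(ddof=1)
    out = sub.loc[:, [c for c in LABEL_COLUMNS if c in sub.columns]].copy()
    out["ld1"] = scores
    return out.reset_index(drop=True), lda


def extract_e2(table: pd.DataFrame) -> pd.Series:
    """Total E2 duration per recording, in minutes (validated <= 360)."""
    if E2_COLUMN not in table.columns:
        raise KeyError(f"column {E2_COLUMN!r} absent")
    e2 = table[E2_COLUMN].astype(float)
    bad = e2.dropna()
    if (bad < 0).any() or (bad > MAX_RECORDING_MIN).any():
        raise ValueError(
            f"E2 durations must lie in [0, {MAX_RECORDING_MIN}] minutes"
        )
    return e2
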