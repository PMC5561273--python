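"""Species-level acceptance profiles and discrimination/acceptability scores.

Per-recording acceptance summaries (E2 or LD1) are aggregated to
(species, race) cells as mean / SD / SE / n.  For each plant species the
**discrimination** score is the difference of race means (MS minus TP,
positive = greater acceptance by *Medicago*-adapted aphids) and **overall
acceptability** is their sum; standard errors propagate in quadrature.
Score tables are validated against aphid performance (fecundity) with
Pearson or Spearman correlations across species means.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "summarize_profiles",
    "discrimination_acceptability",
    "correlate",
]


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    n: int
    p_value: float
    method: str
    pair: str = ""


def summarize_profiles(
    profiles: pd.DataFrame,
    value_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Aggregate per-recording values to (species, race) mean/SD/SE/n.

    ``profiles`` needs ``species`` and ``race`` columns plus one or more
    numeric profile columns (e.g. ``E2_total_min``, ``ld1``).  Returns a
    long table with columns species, race, profile, mean, sd, se, n; SE is
    NaN for single-recording cells.
    """
    if value_columns is None:
        skip = {"recording_id", "race", "clone", "species", "genus"}
        value_columns = [c for c in profiles.columns if c not in skip]
    if not value_columns:
        raise ValueError("no profile value columns found")
    rows = []
    for (sp, race), grp in profiles.groupby(["species", "race"], sort=True):
        for col in value_columns:
            vals = grp[col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                raise ValueError(f"empty cell: species={sp!r} race={race!r} profile={col!r}")
            mean = float(vals.mean())
            if vals.size >= 2:
                sd = float(vals.std(ddof=1))
                se = sd / np.sqrt(vals.size)
            else:
                sd, se = np.nan, np.nan
            rows.append((sp, race, col, mean, sd, se, int(vals.size)))
    return pd.DataFrame(
        rows, columns=["species", "race", "profile", "mean", "sd", "se", "n"]
    )


def discrimination_acceptability(profile_table: pd.DataFrame) -> pd.DataFrame:
    """Per-species discrimination and acceptability scores with SEs.

    discrimination = mean_MS - mean_TP, acceptability = mean_MS + mean_TP,
    both with SE = sqrt(SE_MS^2 + SE_TP^2).  A species missing one race is
    dropped with a warning; a race absent from the whole table is an error.
    """
    races = set(profile_table["race"].unique())
    if not {"MS", "TP"}.issubset(races):
        missing = {"MS", "TP"} - races
        raise ValueError(f"race(s) absent from profile table: {sorted(missing)}")
    rows = []
    for (sp, prof), grp in profile_table.groupby(["species", "profile"], sort=True):
        cell = grp.set_index("race")
        if not {"MS", "TP"}.issubset(cell.index):
            logger.warning("species %r (%s) missing a race cell; dropped", sp, prof)
            continue
        ms, tp = cell.loc["MS"], cell.loc["TP"]
        se = float(np.sqrt(ms["se"] ** 2 + tp["se"] ** 2))
        rows.append(
            (
                sp, prof,
                float(ms["mean"] - tp["mean"]),
                float(ms["mean"] + tp["mean"]),
                se,
                float(ms["mean"]), float(tp["mean"]),
            )
        )
    if not rows:
        raise ValueError("no species with both race cells present")
    return pd.DataFrame(
        rows,
        columns=[
            "species", "profile", "discrimination", "acceptability",
            "se", "mean_MS", "mean_TP",
        ],
    )


def correlate(x, y, method: str = "pearson", pair: str = "") -> CorrelationResult:
    """Pearson or Spearman correlation across paired species means.

    Pearson P-values use the t approximation.  Spearman P-values are exact
    (full permutation enumeration) for n <= 10 and use the t approximation
    for larger n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    n = x.size
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return CorrelationResult(float(r), n, float(p), "pearson", pair)
    if method == "spearman":
        rho = float(stats.spearmanr(x, y).statistic)
        if n <= 10:
            p = _exact_spearman_p(x, y, rho)
        else:
            p = float(stats.spearmanr(x, y).pvalue)
        return CorrelationResult(rho, n, p, "spearman", pair)
    raise ValueError(f"unknown method {method!r}")


def _exact_spearman_p(x, y, rho_obs: float, chunk: int = 40320) -> float:
    """Two-sided exact permutation P for Spearman's rho at small n."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = rx.size
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    count = 0
    total = 0
    batch = []
    thresh = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        batch.append(perm)
        if len(batch) == chunk:
            count += _count_extreme(np.array(batch), rx_c, ry_c, denom, thresh)
            total += len(batch)
            batch = []
    if batch:
        count += _count_extreme(np.array(batch), rx_c, ry_c, denom, thresh)
        total += len(batch)
    return count / total


def _count_extreme(perms, rx_c, ry_c, denom, thresh) -> int:
    rhos = (ry_c[perms] @ rx_c) / denom
    return int((np.abs(rhos) >= thresh).sum())
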