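"""MALDI-TOF peak lists to plants x m/z-bin %TIC matrices.

A spectrum arrives as a two-column peak list (m/z, intensity).  Intensities
are summed into fixed 0.2-Da bins anchored at the lower end of the mass
range, converted to percent of total ion count (%TIC), averaged over the
technical replicates of each plant (with a coefficient-of-variation
concordance check per bin), and assembled into a plants x bins matrix per
extract fraction.  PCA gives an unsupervised overview with a robust
score-distance outlier flag; PLS-DA gives a supervised projection by plant
species with per-bin VIP scores.

Bins are half-open [left, left + width) and labelled by their left edge to
one decimal; the auxiliary nominal bin is floor(m/z), the integer label by
which bins are conventionally quoted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "BinningConfig",
    "PeakList",
    "BinnedProfile",
    "ProfileMatrix",
    "parse_peaklist",
    "bin_spectrum",
    "combine_replicates",
    "build_matrix",
    "pca_overview",
    "PcaOverview",
    "PLSDA",
    "plsda",
]


@dataclass(frozen=True)
class BinningConfig:
    bin_width: float = 0.2
    range_min: float = 50.0
    range_max: float = 1000.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.range_min >= self.range_max:
            raise ValueError("range_min must be below range_max")

    @property
    def n_bins(self) -> int:
        return int(round((self.range_max - self.range_min) / self.bin_width))

    @property
    def edges(self) -> np.ndarray:
        """Left edges of all bins, rounded to 1 decimal for labelling."""
        return np.round(self.range_min + np.arange(self.n_bins) * self.bin_width, 1)


@dataclass
class PeakList:
    """One acquired spectrum: peak m/z values (Da) and intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    species: str = ""
    plant_id: str = ""
    replicate: int = 0
    fraction: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and non-negative")

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class BinnedProfile:
    """%TIC per m/z bin for one spectrum or one combined plant profile."""

    tic_percent: np.ndarray
    config: BinningConfig
    species: str = ""
    plant_id: str = ""
    replicate: int | None = 0
    fraction: str = ""

    @property
    def edges(self) -> np.ndarray:
        return self.config.edges

    @property
    def nominal_bins(self) -> np.ndarray:
        return np.floor(self.edges).astype(int)


@dataclass
class ProfileMatrix:
    """Plants x bins %TIC matrix for one fraction, with row metadata."""

    values: pd.DataFrame          # index plant_id, columns bin left-edge labels
    species: pd.Series            # plant_id -> species
    fraction: str = ""
    nominal_bins: pd.Series = field(default=None)  # bin label -> floor label

    def __post_init__(self) -> None:
        if self.nominal_bins is None:
            self.nominal_bins = pd.Series(
                np.floor(self.values.columns.to_numpy(dtype=float)).astype(int),
                index=self.values.columns,
            )


def parse_peaklist(
    path,
    config: BinningConfig | None = None,
    species: str = "",
    plant_id: str = "",
    replicate: int = 0,
    fraction: str = "",
) -> PeakList:
    """Read a two-column (m/z TAB intensity) peak-list file.

    Peaks outside the configured mass range are dropped and counted in the
    log; malformed lines raise with their line number.
    """
    config = config or BinningConfig()
    mzs: list[float] = []
    intens: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            try:
                mz, inten = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}") from exc
            if inten < 0:
                raise ValueError(f"{path}: negative intensity at line {lineno}")
            mzs.append(mz)
            intens.append(inten)
    if not mzs:
        raise ValueError(f"{path}: empty peak list")
    mz_arr = np.array(mzs)
    keep = (mz_arr >= config.range_min) & (mz_arr <= config.range_max)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d peak(s) outside [%g, %g] Da",
                    path, n_dropped, config.range_min, config.range_max)
    return PeakList(
        mz=mz_arr[keep],
        intensity=np.array(intens)[keep],
        species=species,
        plant_id=plant_id,
        replicate=replicate,
        fraction=fraction,
    )


def bin_spectrum(peaks: PeakList, config: BinningConfig | None = None) -> BinnedProfile:
    """Sum intensity into half-open 0.2-Da bins and convert to %TIC."""
    config = config or BinningConfig()
    if len(peaks) == 0:
        raise ValueError("cannot bin an empty peak list")
    total = float(peaks.intensity.sum())
    if total <= 0:
        raise ValueError("zero total ion count")
    idx = np.floor((peaks.mz - config.range_min) / config.bin_width).astype(int)
    # a peak exactly at range_max belongs to the last bin
    idx = np.clip(idx, 0, config.n_bins - 1)
    binned = np.bincount(idx, weights=peaks.intensity, minlength=config.n_bins)
    return BinnedProfile(
        tic_percent=binned / total * 100.0,
        config=config,
        species=peaks.species,
        plant_id=peaks.plant_id,
        replicate=peaks.replicate,
        fraction=peaks.fraction,
    )


def combine_replicates(
    profiles: list[BinnedProfile],
    concordance_cv: float = 0.5,
    min_mean_tic: float = 0.01,
) -> tuple[BinnedProfile, pd.DataFrame]:
    """Average technical-replicate %TIC profiles of one plant and renormalise.

    Returns the combined profile plus a concordance report flagging bins
    whose replicate CV exceeds ``concordance_cv`` at mean %TIC above
    ``min_mean_tic`` (flagged, never removed).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 technical replicates to combine")
    first = profiles[0]
    for p in profiles[1:]:
        if (p.plant_id, p.fraction, p.species) != (first.plant_id, first.fraction, first.species):
            raise ValueError(
                f"replicate metadata mismatch: {p.plant_id}/{p.fraction} vs "
                f"{first.plant_id}/{first.fraction}"
            )
    stack = np.vstack([p.tic_percent for p in profiles])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    flagged = (cv > concordance_cv) & (mean > min_mean_tic)
    report = pd.DataFrame(
        {
            "bin": first.edges[flagged],
            "mean_tic": mean[flagged],
            "cv": cv[flagged],
        }
    )
    total = mean.sum()
    combined = BinnedProfile(
        tic_percent=mean / total * 100.0,
        config=first.config,
        species=first.species,
        plant_id=first.plant_id,
        replicate=None,
        fraction=first.fraction,
    )
    return combined, report


def build_matrix(
    profiles: list[BinnedProfile],
    fraction: str | None = None,
    drop_empty_bins: bool = True,
) -> ProfileMatrix:
    """Assemble combined per-plant profiles into a plants x bins matrix.

    All profiles share the binning grid, so alignment is positional; bins
    with no signal in any plant are dropped by default (they are zero
    everywhere, so row sums are unchanged).
    """
    if fraction is not None:
        profiles = [p for p in profiles if p.fraction == fraction]
    if not profiles:
        raise ValueError("no profiles to assemble")
    ids = [p.plant_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate plant_id(s): {dupes}")
    cfg = profiles[0].config
    mat = np.vstack([p.tic_percent for p in profiles])
    cols = cfg.edges
    if drop_empty_bins:
        nonzero = mat.any(axis=0)
        mat = mat[:, nonzero]
        cols = cols[nonzero]
    df = pd.DataFrame(mat, index=pd.Index(ids, name="plant_id"), columns=cols)
    species = pd.Series([p.species for p in profiles], index=df.index, name="species")
    return ProfileMatrix(values=df, species=species,
                         fraction=fraction or profiles[0].fraction)


@dataclass
class PcaOverview:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    outlier_flags: np.ndarray


def pca_overview(
    matrix: ProfileMatrix | pd.DataFrame,
    n_components: int = 5,
    outlier_z: float = 3.5,
) -> PcaOverview:
    """Column-centred PCA of the %TIC matrix with robust outlier flags.

    A plant is flagged when the robust z-score (median/MAD) of its score
    distance on the first two components exceeds ``outlier_z``.  Flags are
    informative only; rows are never removed here.
    """
    X = matrix.values if isinstance(matrix, ProfileMatrix) else matrix
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA overview needs at least 3 plants")
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    d = np.sqrt((scores[:, : min(2, k)] ** 2).sum(axis=1))
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    scale = 1.4826 * mad if mad > 0 else (d.std() or 1.0)
    flags = (d - med) / scale > outlier_z
    return PcaOverview(
        scores=scores,
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        outlier_flags=flags,
    )


class PLSDA(BaseEstimator):
    """Partial least squares discriminant analysis with VIP scores.

    A PLS2 (NIPALS) regression of centred X on one-hot group membership.
    Fitted attributes: ``x_scores_`` (orthogonal latent scores),
    ``x_loadings_``, ``x_weights_``, ``vip_`` (variable importance in
    projection, mean of squared VIP equal to 1), ``classes_``.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("PLS-DA needs at least 2 groups")
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            small = classes[counts < 2].tolist()
            raise ValueError(f"every group needs >= 2 rows; offending: {small}")
        Y = np.eye(classes.size)[y_idx]
        k = min(self.n_components, X.shape[1], X.shape[0] - 1)
        pls = PLSRegression(n_components=k, scale=False)
        pls.fit(X, Y)
        self.classes_ = classes
        self.n_components_ = k
        self.x_scores_ = pls.x_scores_
        self.x_weights_ = pls.x_weights_
        self.x_loadings_ = pls.x_loadings_
        self.y_loadings_ = pls.y_loadings_
        self.vip_ = self._vip(pls)
        self._pls = pls
        return self

    def transform(self, X):
        return self._pls.transform(np.asarray(X, dtype=float))

    @staticmethod
    def _vip(pls: PLSRegression) -> np.ndarray:
        T = pls.x_scores_
        W = pls.x_weights_
        Q = pls.y_loadings_
        p = W.shape[0]
        # variance of Y explained per component
        ssy = np.sum(T**2, axis=0) * np.sum(Q**2, axis=0)
        wnorm2 = (W**2) / np.sum(W**2, axis=0, keepdims=True)
        vip2 = p * (wnorm2 @ ssy) / ssy.sum()
        return np.sqrt(vip2)


def plsda(matrix: ProfileMatrix | pd.DataFrame, groups, n_components: int = 2) -> PLSDA:
    """Fit :class:`PLSDA` on a %TIC matrix with species labels."""
    X = matrix.values if isinstance(matrix, ProfileMatrix) else matrix
    if isinstance(matrix, ProfileMatrix) and groups is None:
        groups = matrix.species
    return PLSDA(n_components=n_components).fit(np.asarray(X, dtype=float), groups)
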