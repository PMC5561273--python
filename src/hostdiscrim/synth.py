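"""Synthetic EPG / metabolome / performance data with planted ground truth.

The generator emulates the structure of a two-host-race aphid feeding study:

* Each plant species *j* carries two latent traits — overall acceptability
  ``a_j ~ N(0, sigma_a^2)`` and race discrimination ``d_j``, drawn around
  ``+delta_genus`` for *Medicago* species and ``-delta_genus`` for
  *Trifolium*, so discrimination separates the genera.  The expected
  acceptance score of race r on species j is ``m_MS = (a_j + d_j) / 2`` and
  ``m_TP = (a_j - d_j) / 2``, which makes sum and difference of race means
  recover ``a_j`` and ``d_j`` exactly.
* EPG recordings add clone and per-aphid noise to the race mean; total E2
  (phloem ingestion) duration is ``360 * logistic(s)`` minutes, bounded by
  the 6-hour recording window.  The behavioural variable block contains
  informative (linear in the latent), zero-inflated, near-duplicate and pure
  noise variables, with optional MCAR missingness.
* Leaf spectra plant compounds whose log-abundance tracks ``d_j``
  (discriminative, either sign), ``a_j`` (acceptability-linked) or nothing
  (nuisance), under biological and technical lognormal noise, per-peak m/z
  jitter and a per-replicate global TIC scale factor that %TIC
  normalisation must remove.
* Fecundity is Poisson with log-mean linear in the race mean, so aphid
  performance correlates with acceptance.

All randomness flows from a single seed through named
``numpy.random.SeedSequence`` children, so datasets are reproducible and
every stage is testable by parameter recovery against the returned
:class:`GroundTruth`.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .spectra import BinningConfig, PeakList

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_latents",
    "generate_epg_table",
    "generate_spectra",
    "generate_performance",
    "generate_dataset",
]

RACES = ("MS", "TP")


@dataclass(frozen=True)
class SyntheticConfig:
    """Design constants of the emulated study; defaults match its scale."""

    n_species: int = 19
    n_medicago: int = 9
    plants_per_species: int = 6
    tech_reps: int = 3
    aphids_per_cell: int = 8          # recordings per race x species cell
    clones_per_race: int = 2
    n_epg_vars: int = 119
    frac_informative: float = 0.3
    frac_zero_inflated: float = 0.2
    n_dup_pairs: int = 10
    miss_rate: float = 0.02
    sigma_a: float = 1.0
    sigma_d: float = 1.0
    delta_genus: float = 1.5
    sigma_clone: float = 0.2
    sigma_aphid: float = 0.8
    n_disc_compounds: int = 4
    n_acc_compounds: int = 4
    n_null_compounds: int = 400
    gamma_disc: float = 0.8
    gamma_acc: float = 0.8
    cv_bio: float = 0.3
    cv_tech: float = 0.1
    sigma_species: float = 0.5        # SD of species-level log-abundance effects
    tic_scale_sd: float = 0.5         # SD of log global TIC factor per replicate
    mz_jitter_sd: float = 0.03
    mz_range: tuple[float, float] = (50.0, 1000.0)
    fractions: tuple[str, ...] = ("polar", "nonpolar")
    edge_stress: bool = False         # place planted m/z on bin edges
    perf_reps: int = 6                # fecundity replicates per species x race x clone
    eta0: float = 1.5
    eta1: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_informative", "frac_zero_inflated", "miss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_species", "plants_per_species", "tech_reps", "aphids_per_cell",
            "clones_per_race", "n_epg_vars", "perf_reps",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.n_medicago < self.n_species:
            raise ValueError("need 0 <= n_medicago < n_species")
        if self.mz_range[0] >= self.mz_range[1]:
            raise ValueError("mz_range lower bound must be below upper bound")
        n_special = (
            round(self.frac_informative * self.n_epg_vars)
            + round(self.frac_zero_inflated * self.n_epg_vars)
            + self.n_dup_pairs
        )
        if n_special > self.n_epg_vars:
            raise ValueError("informative + zero-inflated + duplicate variables "
                             "exceed n_epg_vars")
        if not self.fractions:
            raise ValueError("at least one fraction required")

    @property
    def binning(self) -> BinningConfig:
        return BinningConfig(range_min=self.mz_range[0], range_max=self.mz_range[1])


@dataclass
class GroundTruth:
    """Planted signal: species latents, compound registry, EPG variable roles."""

    species: pd.DataFrame       # species, genus, a, d, m_MS, m_TP
    compounds: pd.DataFrame     # compound, mz, klass, direction, gamma, fraction
    epg_var_roles: dict[str, list[str]]

    def race_mean(self, species: str, race: str) -> float:
        row = self.species.set_index("species").loc[species]
        return float(row["m_MS"] if race == "MS" else row["m_TP"])

    def to_json(self, path) -> None:
        payload = {
            "species": self.species.to_dict(orient="records"),
            "compounds": self.compounds.to_dict(orient="records"),
            "epg_var_roles": self.epg_var_roles,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SyntheticDataset:
    epg: pd.DataFrame
    spectra: list[PeakList]
    manifest: pd.DataFrame
    performance: pd.DataFrame
    truth: GroundTruth
    config: SyntheticConfig


def _rng(config: SyntheticConfig, label: str) -> np.random.Generator:
    # named, order-independent child streams off the master seed;
    # crc32 is stable across processes (unlike built-in str hashing)
    h = zlib.crc32(label.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=(config.seed, h)))


def generate_latents(config: SyntheticConfig) -> GroundTruth:
    """Draw species latents and the planted compound registry."""
    rng = _rng(config, "latents")
    n_med = config.n_medicago
    names = [f"Medicago_sp{i + 1:02d}" for i in range(n_med)] + [
        f"Trifolium_sp{i + 1:02d}" for i in range(config.n_species - n_med)
    ]
    genus = ["Medicago"] * n_med + ["Trifolium"] * (config.n_species - n_med)
    a = rng.normal(0.0, config.sigma_a, config.n_species)
    centre = np.where(np.arange(config.n_species) < n_med,
                      config.delta_genus, -config.delta_genus)
    d = rng.normal(centre, config.sigma_d)
    # reconstruct a, d from the race means so sum/difference recover them
    # exactly in floating point (recovery tests rely on the identity)
    m_ms, m_tp = (a + d) / 2.0, (a - d) / 2.0
    a, d = m_ms + m_tp, m_ms - m_tp
    species = pd.DataFrame(
        {
            "species": names,
            "genus": genus,
            "a": a,
            "d": d,
            "m_MS": m_ms,
            "m_TP": m_tp,
        }
    )
    compounds = _compound_registry(config, rng)
    roles = _epg_roles(config)
    return GroundTruth(species=species, compounds=compounds, epg_var_roles=roles)


def _compound_registry(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_disc, n_acc, n_null = (
        config.n_disc_compounds, config.n_acc_compounds, config.n_null_compounds,
    )
    klass = (
        ["disc_pos", "disc_neg"] * (n_disc // 2) + ["disc_pos"] * (n_disc % 2)
        + ["acc"] * n_acc
        + ["null"] * n_null
    )
    n_total = len(klass)
    direction = np.where([k == "disc_neg" for k in klass], -1.0, 1.0)
    gamma = np.array(
        [config.gamma_disc if k.startswith("disc") else
         config.gamma_acc if k == "acc" else 0.0 for k in klass]
    )
    fracs = [config.fractions[i % len(config.fractions)] for i in range(n_total)]
    mz = _draw_mz(config, rng, n_total)
    return pd.DataFrame(
        {
            "compound": [f"cmp_{i + 1:04d}" for i in range(n_total)],
            "mz": mz,
            "klass": klass,
            "direction": direction,
            "gamma": gamma,
            "fraction": fracs,
        }
    )


def _draw_mz(config: SyntheticConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    binning = config.binning
    width = binning.bin_width
    bins = rng.choice(binning.n_bins, size=n, replace=False)
    edges = binning.range_min + bins * width
    if config.edge_stress:
        return edges  # exactly on bin edges to stress bin-splitting
    margin = min(2.0 * config.mz_jitter_sd, 0.45 * width)
    offs = rng.uniform(margin, width - margin, size=n)
    return edges + offs


def _epg_roles(config: SyntheticConfig) -> dict[str, list[str]]:
    names = [f"var_{i + 1:03d}" for i in range(config.n_epg_vars)]
    n_inf = round(config.frac_informative * config.n_epg_vars)
    n_zi = round(config.frac_zero_inflated * config.n_epg_vars)
    n_dup = config.n_dup_pairs
    informative = names[:n_inf]
    zero_inflated = names[n_inf:n_inf + n_zi]
    dups = names[n_inf + n_zi:n_inf + n_zi + n_dup]
    noise = names[n_inf + n_zi + n_dup:]
    # duplicate sources cycle through informative (or noise if none)
    src_pool = informative if informative else noise
    dup_sources = [src_pool[i % len(src_pool)] for i in range(n_dup)] if src_pool else []
    return {
        "informative": informative,
        "zero_inflated": zero_inflated,
        "duplicates": dups,
        "duplicate_sources": dup_sources,
        "noise": noise,
    }


def generate_epg_table(truth: GroundTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Per-recording behavioural table with planted variable structure."""
    rng = _rng(config, "epg")
    roles = truth.epg_var_roles
    clone_ids = {
        r: [f"{r}_clone{c + 1}" for c in range(config.clones_per_race)] for r in RACES
    }
    clone_eff = {
        cid: rng.normal(0.0, config.sigma_clone)
        for r in RACES for cid in clone_ids[r]
    }
    rows = []
    for _, sp in truth.species.iterrows():
        for race in RACES:
            m = sp["m_MS"] if race == "MS" else sp["m_TP"]
            per_clone = _split_counts(config.aphids_per_cell, config.clones_per_race)
            for cid, n_aph in zip(clone_ids[race], per_clone):
                for _ in range(n_aph):
                    s = m + clone_eff[cid] + rng.normal(0.0, config.sigma_aphid)
                    rows.append((sp["species"], sp["genus"], race, cid, s))
    meta = pd.DataFrame(rows, columns=["species", "genus", "race", "clone", "latent"])
    n = len(meta)
    s = meta.pop("latent").to_numpy()

    names = [f"var_{i + 1:03d}" for i in range(config.n_epg_vars)]
    data = pd.DataFrame(index=range(n), columns=names, dtype=float)
    for v in roles["informative"]:
        alpha, beta = rng.normal(0.0, 1.0), rng.uniform(0.5, 2.0) * rng.choice([-1, 1])
        data[v] = alpha + beta * s + rng.normal(0.0, 1.0, n)
    for v in roles["zero_inflated"]:
        nonzero = rng.random(n) >= 0.6  # >= 50% zeros in expectation
        data[v] = np.where(nonzero, np.abs(rng.normal(1.0, 1.0, n)), 0.0)
    for v, src in zip(roles["duplicates"], roles["duplicate_sources"]):
        base = data[src].to_numpy()
        sd = base.std() or 1.0
        data[v] = base + rng.normal(0.0, 0.1 * sd, n)  # population r ~ 0.995
    for v in roles["noise"]:
        data[v] = rng.normal(0.0, 1.0, n)

    if config.miss_rate > 0:
        mask = rng.random(data.shape) < config.miss_rate
        data = data.mask(mask)

    out = pd.concat(
        [
            pd.Series([f"rec_{i + 1:04d}" for i in range(n)], name="recording_id"),
            meta[["race", "clone", "species", "genus"]],
            data,
            pd.Series(360.0 * expit(s), name="E2_total_min"),
        ],
        axis=1,
    )
    return out


def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def generate_spectra(
    truth: GroundTruth, config: SyntheticConfig
) -> tuple[list[PeakList], pd.DataFrame]:
    """Triplicate peak lists per plant and fraction, plus a manifest."""
    rng = _rng(config, "spectra")
    base_abundance = 100.0
    sd_bio = float(np.sqrt(np.log1p(config.cv_bio**2)))
    sd_tech = float(np.sqrt(np.log1p(config.cv_tech**2)))
    lo, hi = config.mz_range
    peaklists: list[PeakList] = []
    manifest_rows = []
    # species-level log-abundance effects unrelated to behaviour: every
    # compound differs among species (as in real leaf metabolomes), so
    # nuisance bins carry species structure without tracking the latents
    registry_by_fraction = {
        f: truth.compounds[truth.compounds["fraction"] == f]
        for f in config.fractions
    }
    species_effects = {
        (sp, f): rng.normal(0.0, config.sigma_species, len(reg))
        for sp in truth.species["species"]
        for f, reg in registry_by_fraction.items()
    }
    for _, sp in truth.species.iterrows():
        latents = {"disc": sp["d"], "acc": sp["a"], "null": 0.0}
        for p in range(config.plants_per_species):
            plant_id = f"{sp['species']}_p{p + 1}"
            for fraction in config.fractions:
                reg = registry_by_fraction[fraction]
                key = reg["klass"].str.split("_").str[0].map(latents).to_numpy()
                mean_ab = base_abundance * np.exp(
                    reg["gamma"].to_numpy() * reg["direction"].to_numpy() * key
                    + species_effects[(sp["species"], fraction)]
                )
                bio = mean_ab * np.exp(rng.normal(0.0, sd_bio, len(reg)))
                for rep in range(1, config.tech_reps + 1):
                    tic_scale = float(np.exp(rng.normal(0.0, config.tic_scale_sd)))
                    inten = bio * np.exp(rng.normal(0.0, sd_tech, len(reg))) * tic_scale
                    mz = reg["mz"].to_numpy() + rng.normal(
                        0.0, config.mz_jitter_sd, len(reg)
                    )
                    mz = np.clip(mz, lo, hi)
                    pl = PeakList(
                        mz=mz, intensity=inten, species=sp["species"],
                        plant_id=plant_id, replicate=rep, fraction=fraction,
                    )
                    peaklists.append(pl)
                    manifest_rows.append(
                        (f"{plant_id}_{fraction}_r{rep}.tsv", sp["species"],
                         plant_id, rep, fraction)
                    )
    manifest = pd.DataFrame(
        manifest_rows, columns=["file", "species", "plant_id", "replicate", "fraction"]
    )
    return peaklists, manifest


def generate_performance(truth: GroundTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Fecundity counts (live young per adult) per species x race x clone."""
    rng = _rng(config, "performance")
    rows = []
    for _, sp in truth.species.iterrows():
        for race in RACES:
            m = sp["m_MS"] if race == "MS" else sp["m_TP"]
            lam = float(np.exp(config.eta0 + config.eta1 * m))
            for c in range(config.clones_per_race):
                clone = f"{race}_clone{c + 1}"
                young = rng.poisson(lam, config.perf_reps)
                rows += [
                    (sp["species"], race, clone, r + 1, int(y))
                    for r, y in enumerate(young)
                ]
    return pd.DataFrame(
        rows, columns=["species", "race", "clone", "replicate", "live_young"]
    )


def generate_dataset(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Generate all tables; optionally write them in the interchange formats.

    Files written: ``epg.csv``, ``performance.csv``, ``manifest.csv``, one
    two-column TSV per spectrum under ``spectra/``, and
    ``ground_truth.json``.
    """
    truth = generate_latents(config)
    epg = generate_epg_table(truth, config)
    peaklists, manifest = generate_spectra(truth, config)
    perf = generate_performance(truth, config)
    ds = SyntheticDataset(
        epg=epg, spectra=peaklists, manifest=manifest,
        performance=perf, truth=truth, config=config,
    )
    if out_dir is not None:
        out = Path(out_dir)
        (out / "spectra").mkdir(parents=True, exist_ok=True)
        epg.to_csv(out / "epg.csv", index=False)
        perf.to_csv(out / "performance.csv", index=False)
        manifest.to_csv(out / "manifest.csv", index=False)
        for fname, pl in zip(manifest["file"], peaklists):
            lines = [f"{m:.5f}\t{i:.6f}" for m, i in zip(pl.mz, pl.intensity)]
            (out / "spectra" / fname).write_text("\n".join(lines) + "\n")
        truth.to_json(out / "ground_truth.json")
    return ds
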