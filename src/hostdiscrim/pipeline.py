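"""End-to-end orchestration: simulate -> epg -> scores -> spectra -> rank -> annotate.

Reads the interchange formats (EPG CSV, peak-list TSVs plus manifest,
performance CSV), runs each stage with a master seed, writes stage outputs
as CSV/JSON, and returns a machine-readable run report with row/column
counts, seeds, and accumulated warnings.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annot import annotate_bins, load_compound_table
from .epg import CleaningConfig, clean_table, compute_ld1, extract_e2, impute_missing
from .rfrank import (
    RfRunConfig,
    jackknife_ranking,
    resampled_ranking,
    select_top_bins,
    spearman_screen_fdr,
    top_bins_r2,
)
from .scores import correlate, discrimination_acceptability, summarize_profiles
from .spectra import (
    BinningConfig,
    bin_spectrum,
    build_matrix,
    combine_replicates,
    parse_peaklist,
    pca_overview,
)
from .synth import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]


@dataclass
class PipelineConfig:
    """Paths, stage options, and the master seed for a full run."""

    workdir: str = "."
    simulate: bool = True
    epg_path: str | None = None           # input EPG CSV (if not simulating)
    manifest_path: str | None = None      # spectra manifest CSV
    performance_path: str | None = None
    compounds_path: str | None = None     # optional custom compound table
    profile: str = "E2_total_min"         # response profile: E2 column or "ld1"
    responses: tuple[str, ...] = ("discrimination", "acceptability")
    fractions: tuple[str, ...] | None = None  # None -> all in manifest
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    binning: BinningConfig = field(default_factory=BinningConfig)
    rf: RfRunConfig = field(default_factory=RfRunConfig)
    annotation_tolerance_da: float = 0.1
    log_level: str = "INFO"


def load_pipeline_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key, cls in (
        ("synthetic", SyntheticConfig),
        ("cleaning", CleaningConfig),
        ("binning", BinningConfig),
        ("rf", RfRunConfig),
    ):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = cls(**{k: _coerce(v) for k, v in raw[key].items()})
    for key in ("responses", "fractions"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _coerce(v):
    return tuple(v) if isinstance(v, list) else v


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write outputs under ``config.workdir``.

    Returns the run report (also written as ``run_report.json``).  Any stage
    exception aborts the run with the stage name attached.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.workdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {},
                    "warnings": []}
    stage = "simulate"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if config.simulate:
                syn = config.synthetic or SyntheticConfig(seed=config.seed)
                ds = generate_dataset(syn, out_dir=out / "synthetic")
                epg_path = out / "synthetic" / "epg.csv"
                manifest_path = out / "synthetic" / "manifest.csv"
                performance_path = out / "synthetic" / "performance.csv"
                report["stages"]["simulate"] = {
                    "n_species": syn.n_species,
                    "n_recordings": len(ds.epg),
                    "n_spectra": len(ds.spectra),
                }
            else:
                if not config.epg_path or not config.manifest_path:
                    raise FileNotFoundError(
                        "epg_path and manifest_path required when simulate=False"
                    )
                epg_path = Path(config.epg_path)
                manifest_path = Path(config.manifest_path)
                performance_path = (
                    Path(config.performance_path) if config.performance_path else None
                )
                report["stages"]["simulate"] = {"skipped": True}

            stage = "epg"
            epg = pd.read_csv(epg_path)
            epg = impute_missing(epg, seed=config.seed)
            cleaned, clean_report = clean_table(epg, config.cleaning)
            clean_report.to_json(out / "cleaning_report.json")
            profiles = cleaned[["recording_id", "race", "clone", "species"]].copy()
            profiles["E2_total_min"] = extract_e2(cleaned).to_numpy()
            if config.profile == "ld1":
                ld_parts = []
                for race in ("MS", "TP"):
                    ld_scores, _ = compute_ld1(cleaned, race)
                    ld_parts.append(ld_scores)
                ld_all = pd.concat(ld_parts, ignore_index=True)
                profiles = profiles.merge(
                    ld_all[["recording_id", "ld1"]], on="recording_id"
                )
            value_col = "ld1" if config.profile == "ld1" else config.profile
            report["stages"]["epg"] = {
                "n_recordings": len(cleaned),
                "n_variables_remaining": len(clean_report.remaining),
            }

            stage = "scores"
            prof_table = summarize_profiles(profiles, value_columns=[value_col])
            score_table = discrimination_acceptability(prof_table)
            prof_table.to_csv(out / "profile_table.csv", index=False)
            score_table.to_csv(out / "score_table.csv", index=False)
            if performance_path is not None and Path(performance_path).exists():
                perf = pd.read_csv(performance_path)
                perf_means = perf.groupby(["species", "race"])["live_young"].mean()
                corr_rows = []
                for race in ("MS", "TP"):
                    merged = (
                        prof_table[prof_table["race"] == race]
                        .set_index("species")["mean"]
                        .to_frame("profile_mean")
                        .join(perf_means.xs(race, level="race").rename("perf"),
                              how="inner")
                        .dropna()
                    )
                    if len(merged) >= 3:
                        res = correlate(merged["profile_mean"], merged["perf"],
                                        method="pearson",
                                        pair=f"{value_col}~performance ({race})")
                        corr_rows.append(
                            {"race": race, "r": res.coefficient, "n": res.n,
                             "p_value": res.p_value}
                        )
                pd.DataFrame(corr_rows).to_csv(
                    out / "performance_correlations.csv", index=False
                )
            report["stages"]["scores"] = {"n_species": score_table["species"].nunique()}

            stage = "spectra"
            manifest = pd.read_csv(manifest_path)
            spectra_dir = Path(manifest_path).parent / "spectra"
            fractions = (
                config.fractions
                if config.fractions is not None
                else tuple(sorted(manifest["fraction"].unique()))
            )
            matrices = {}
            for fraction in fractions:
                sub = manifest[manifest["fraction"] == fraction]
                combined = []
                for plant_id, grp in sub.groupby("plant_id", sort=True):
                    reps = [
                        bin_spectrum(
                            parse_peaklist(
                                spectra_dir / row["file"], config.binning,
                                species=row["species"], plant_id=plant_id,
                                replicate=int(row["replicate"]), fraction=fraction,
                            ),
                            config.binning,
                        )
                        for _, row in grp.iterrows()
                    ]
                    prof, _ = combine_replicates(reps)
                    combined.append(prof)
                matrix = build_matrix(combined, fraction=fraction)
                matrices[fraction] = matrix
                matrix.values.to_csv(out / f"matrix_{fraction}.csv")
                pca = pca_overview(matrix)
                flagged = matrix.values.index[pca.outlier_flags].tolist()
                report["stages"].setdefault("spectra", {})[fraction] = {
                    "n_plants": matrix.values.shape[0],
                    "n_bins": matrix.values.shape[1],
                    "pca_outliers": flagged,
                }

            stage = "rank"
            rank_rows = []
            top_by_response: dict[str, list] = {}
            r2_report = {}
            for response in config.responses:
                per_fraction = {}
                for fraction, matrix in matrices.items():
                    dist = resampled_ranking(
                        matrix, score_table, response=response, cfg=config.rf
                    )
                    per_fraction[fraction] = (matrix, dist)
                    frame = dist.to_frame()
                    frame["fraction"] = fraction
                    frame["response"] = response
                    rank_rows.append(frame)
                # merge across fractions at top-bin selection
                candidates = []
                for fraction, (matrix, dist) in per_fraction.items():
                    frame = dist.to_frame()
                    frame["fraction"] = fraction
                    candidates.append(frame)
                cand = pd.concat(candidates).sort_values(
                    ["median_rank", "iqr", "bin"], kind="mergesort"
                )
                k = min(config.rf.top_k, len(cand))
                top = cand.head(k)
                top_by_response[response] = [
                    (row["fraction"], row["bin"]) for _, row in top.iterrows()
                ]
                r2_per_fraction = {}
                spearman_frames = []
                for fraction, (matrix, dist) in per_fraction.items():
                    bins = [b for f, b in top_by_response[response] if f == fraction]
                    if not bins:
                        continue
                    try:
                        r2_per_fraction[fraction] = top_bins_r2(
                            score_table, matrix, bins, response=response
                        )
                    except ValueError as exc:
                        report["warnings"].append(f"r2 ({response}/{fraction}): {exc}")
                    sp = spearman_screen_fdr(
                        score_table, matrix, bins, response=response
                    )
                    sp["fraction"] = fraction
                    sp["response"] = response
                    spearman_frames.append(sp)
                r2_report[response] = r2_per_fraction
                if spearman_frames:
                    pd.concat(spearman_frames).to_csv(
                        out / f"spearman_{response}.csv", index=False
                    )
            pd.concat(rank_rows).to_csv(out / "rank_table.csv", index=False)
            pd.DataFrame(
                [
                    {"response": resp, "fraction": f, "bin": b}
                    for resp, pairs in top_by_response.items()
                    for f, b in pairs
                ]
            ).to_csv(out / "top_bins.csv", index=False)
            (out / "r2.json").write_text(json.dumps(r2_report, indent=1))
            report["stages"]["rank"] = {
                resp: {"top_bins": [f"{f}:{b}" for f, b in pairs],
                       "r2": r2_report.get(resp, {})}
                for resp, pairs in top_by_response.items()
            }

            stage = "annotate"
            compounds = load_compound_table(config.compounds_path)
            all_top = sorted({b for pairs in top_by_response.values() for _, b in pairs})
            hits = annotate_bins(
                all_top, compounds,
                tolerance_da=config.annotation_tolerance_da,
                bin_width=config.binning.bin_width,
                range_min=config.binning.range_min,
            )
            pd.DataFrame(
                [
                    {
                        "bin": h.bin_label, "nominal_bin": h.nominal_bin,
                        "compound": h.compound.name, "adduct": h.adduct,
                        "theoretical_mz": h.theoretical_mz,
                        "mass_error_da": h.mass_error_da,
                    }
                    for h in hits
                ]
            ).to_csv(out / "annotations.csv", index=False)
            report["stages"]["annotate"] = {"n_hits": len(hits)}
            report["warnings"] += [str(w.message) for w in caught]
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        (out / "run_report.json").write_text(json.dumps(report, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "run_report.json").write_text(json.dumps(report, indent=1))
    return report
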