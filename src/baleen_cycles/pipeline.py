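"""End-to-end orchestration: simulate and analyze whole cohorts.

``run_analysis`` executes, per whale: optional analysis window -> Gaussian
detrend -> autocorrelation diagnostic -> AR-spectral period (T and, when
measured, the isotope series) -> 4-neighbour peak detection -> cycle
segmentation and plate summary -> phase offset vs the isotope series ->
per-cycle age assignment from the whale's best-available terminal age.  At
cohort level it fits the candidate mixed models for peak T ~ age and cycle
period ~ age and correlates the plate summaries with terminal age.  Reports
are deterministic for a fixed input and seed (no timestamps), so reruns are
byte-identical.

Per-whale failures are recorded and skipped; cohort stages run on the
whales that succeeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .age_models import GrowthConfig, best_available_age, default_growth_config, load_growth_config
from .cyclicity import (
    NoDominantCycleError,
    SpectralConfig,
    autocorrelation,
    estimate_period,
    estimate_series_period,
)
from .peaks import assign_cycle_ages, detect_peaks, segment_cycles, summarize_plate
from .phase import estimate_phase
from .preprocess import DetrendConfig, detrend
from .profile_io import (
    AnalysisWindow,
    HormoneProfile,
    WhaleMetadata,
    read_metadata,
    read_profiles,
    write_metadata,
    write_profiles,
)
from .synthetic import SyntheticWhaleSpec, generate_cohort, nine_whale_scenario
from .trend_models import ModelSelection, pearson_corr_test, select_model

__all__ = ["PipelineConfig", "run_analysis", "run_simulation", "AnalysisReport"]

CORRELATION_METRICS = (
    "mean_t",
    "median_t",
    "max_t",
    "min_t",
    "baseline",
    "cv_peaks_pct",
)


@dataclass(frozen=True)
class PipelineConfig:
    profiles_path: Path
    metadata_path: Path
    output_dir: Path
    detrend: DetrendConfig = DetrendConfig()
    spectral: SpectralConfig = SpectralConfig()
    age_mode: str = "best"  # "best" | "length_only"
    windows: dict = field(default_factory=dict)  # whale_id -> (start_cm, end_cm)
    growth_params_path: Optional[Path] = None
    #: drop local maxima with prominence below this many robust noise sds;
    #: None = the pure 4-neighbour rule
    peak_min_prominence_sd: Optional[float] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        det = DetrendConfig(**raw.get("detrend", {}))
        spec_kwargs = dict(raw.get("spectral", {}))
        if "period_band_cm" in spec_kwargs:
            spec_kwargs["period_band_cm"] = tuple(spec_kwargs["period_band_cm"])
        spec = SpectralConfig(**spec_kwargs)
        return cls(
            profiles_path=Path(raw["profiles"]),
            metadata_path=Path(raw["metadata"]),
            output_dir=Path(raw["output_dir"]),
            detrend=det,
            spectral=spec,
            age_mode=raw.get("age_mode", "best"),
            windows={k: tuple(v) for k, v in raw.get("windows", {}).items()},
            growth_params_path=(
                Path(raw["growth_params"]) if raw.get("growth_params") else None
            ),
            peak_min_prominence_sd=raw.get("peak_min_prominence_sd"),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class AnalysisReport:
    summary: pd.DataFrame
    phase: pd.DataFrame
    cycles: pd.DataFrame
    correlations: pd.DataFrame
    lmm_peak: Optional[ModelSelection]
    lmm_period: Optional[ModelSelection]
    errors: dict
    output_dir: Path


def _terminal_age(meta: WhaleMetadata, mode: str, growth: GrowthConfig) -> tuple[float, str]:
    if mode == "length_only":
        from .age_models import length_based_age

        if meta.age_override_yr is not None:
            return float(meta.age_override_yr), "override"
        if meta.length_age_yr is not None:
            return float(meta.length_age_yr), "length"
        return length_based_age(meta, growth)
    return best_available_age(meta, growth)


def _selection_to_dict(sel: ModelSelection) -> dict:
    best = sel.best
    return {
        "comparison": sel.comparison.drop(
            columns=[c for c in ("error",) if c in sel.comparison], errors="ignore"
        ).to_dict(orient="records"),
        "best_variant": sel.best_variant,
        "estimation": best.estimation,
        "loglik": best.loglik,
        "aicc": best.aicc,
        "n_obs": best.n_obs,
        "n_groups": best.n_groups,
        "fixed_effects": {
            term: {k: float(v) for k, v in row.items()}
            for term, row in best.fixed_effects.iterrows()
        },
        "variance_components": best.variance_components,
        "per_whale": {
            wid: {k: float(v) for k, v in row.items()}
            for wid, row in best.per_whale.iterrows()
        },
        "boundary_variance": best.boundary_variance,
        "residual_normality_W": sel.residual_normality_W,
        "residual_normality_p": sel.residual_normality_p,
        "scale_location_slope": sel.scale_location_slope,
    }


def run_analysis(config: PipelineConfig) -> AnalysisReport:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    growth = (
        load_growth_config(config.growth_params_path)
        if config.growth_params_path
        else default_growth_config()
    )
    profiles = {p.whale_id: p for p in read_profiles(config.profiles_path)}
    metadata = {m.whale_id: m for m in read_metadata(config.metadata_path)}

    summary_rows, phase_rows, cycle_rows = [], [], []
    peak_obs, period_obs = [], []
    errors: dict[str, str] = {}
    log_lines = [
        f"baleen-cycles {__version__}",
        f"seed: {config.seed}",
        f"age_mode: {config.age_mode}",
        f"detrend.sigma_cm: {config.detrend.sigma_cm}",
        f"spectral: max_order={config.spectral.max_order} "
        f"grid={config.spectral.grid_points} band={config.spectral.period_band_cm}",
    ]

    for wid in sorted(profiles):
        try:
            prof = profiles[wid]
            if wid in config.windows:
                start, end = config.windows[wid]
                prof = prof.window(AnalysisWindow(start, end))
            meta = metadata.get(wid)
            terminal_age, age_source = (
                _terminal_age(meta, config.age_mode, growth)
                if meta is not None
                else (None, "missing")
            )
            spacing = prof.spacing_cm

            acf = autocorrelation(prof.testosterone, min(prof.n_samples - 1, 40))
            spec_t = estimate_period(prof, config.detrend, config.spectral)

            min_prom = None
            if config.peak_min_prominence_sd is not None:
                from .peaks import estimate_noise_sd

                min_prom = config.peak_min_prominence_sd * estimate_noise_sd(
                    prof.testosterone
                )
            pk = detect_peaks(
                prof.testosterone,
                spacing,
                positions_cm=prof.positions,
                min_prominence=min_prom,
            )
            cyc = segment_cycles(prof.testosterone, pk, spacing)
            summ = summarize_plate(prof, pk, cyc)

            # phase vs isotope series, when measured
            if prof.d15n is not None:
                spec_n = estimate_series_period(
                    prof.d15n, spacing, config.detrend, config.spectral,
                    label=f"whale {wid} d15n",
                )
                ph = estimate_phase(
                    detrend(prof.testosterone, spacing, config.detrend),
                    detrend(prof.d15n, spacing, config.detrend),
                    spacing,
                    spec_t.period_cm,
                    spec_n.period_cm,
                )
                phase_rows.append(
                    {
                        "whale_id": wid,
                        "lag_samples": ph.lag_samples,
                        "lag_cm": ph.lag_cm,
                        "max_ccf": ph.max_ccf,
                        "offset_months": ph.offset_months,
                        "t_precedes_n": ph.t_precedes_n,
                        "significant": ph.significant,
                        "n_period_cm": spec_n.period_cm,
                    }
                )
                n_period_cm = spec_n.period_cm
            else:
                n_period_cm = np.nan

            # per-peak ages (the model's unit is the peak; one peak = one year)
            if terminal_age is not None and len(pk) >= 1:
                peak_ages = assign_cycle_ages(len(pk), terminal_age)
                # peaks are ordered recent-first by position; oldest peak gets
                # the earliest age
                order = np.argsort(-pk.positions_cm)
                for rank, j in enumerate(order):
                    peak_obs.append(
                        {
                            "whale_id": wid,
                            "age": float(peak_ages[rank]),
                            "response": float(pk.heights[j]),
                        }
                    )
                if cyc.n_cycles >= 1:
                    cyc_ages = assign_cycle_ages(cyc.n_cycles, terminal_age)
                    order_c = np.argsort(-cyc.left_peak_indices)
                    for rank, j in enumerate(order_c):
                        period_obs.append(
                            {
                                "whale_id": wid,
                                "age": float(cyc_ages[rank]),
                                "response": float(cyc.periods_cm[j]),
                            }
                        )
                        cycle_rows.append(
                            {
                                "whale_id": wid,
                                "cycle_index": int(rank),
                                "age_yr": float(cyc_ages[rank]),
                                "peak_ng_g": float(
                                    prof.testosterone[cyc.left_peak_indices[j]]
                                ),
                                "minimum_ng_g": float(cyc.min_values[j]),
                                "period_cm": float(cyc.periods_cm[j]),
                                "ratio": float(cyc.ratios[j]),
                            }
                        )

            summary_rows.append(
                {
                    "whale_id": wid,
                    "terminal_age_yr": terminal_age,
                    "age_source": age_source,
                    "n_samples": prof.n_samples,
                    "t_period_cm": spec_t.period_cm,
                    "ar_order": spec_t.ar_order,
                    "n_period_cm": n_period_cm,
                    "acf_significance_bound": acf.significance_bound,
                    "n_peaks": summ.n_peaks,
                    "mean_peak_ng_g": summ.mean_peak,
                    "sd_peak_ng_g": summ.sd_peak,
                    "baseline_ng_g": summ.baseline,
                    "mean_ratio": summ.mean_ratio,
                    "sd_ratio": summ.sd_ratio,
                    "max_t_ng_g": summ.max_t,
                    "min_t_ng_g": summ.min_t,
                    "mean_t_ng_g": summ.mean_t,
                    "median_t_ng_g": summ.median_t,
                    "cv_peaks_pct": summ.cv_peaks_pct,
                    "mean_cycle_period_cm": summ.mean_cycle_period_cm,
                }
            )
        except (ValueError, NoDominantCycleError) as exc:
            errors[wid] = str(exc)
            log_lines.append(f"ERROR {wid}: {exc}")

    summary = pd.DataFrame(summary_rows)
    phase_df = pd.DataFrame(
        phase_rows,
        columns=[
            "whale_id",
            "lag_samples",
            "lag_cm",
            "max_ccf",
            "offset_months",
            "t_precedes_n",
            "significant",
            "n_period_cm",
        ],
    )
    cycles_df = pd.DataFrame(
        cycle_rows,
        columns=[
            "whale_id",
            "cycle_index",
            "age_yr",
            "peak_ng_g",
            "minimum_ng_g",
            "period_cm",
            "ratio",
        ],
    )

    # cohort-level inference
    corr_rows = []
    if len(summary) >= 3 and summary["terminal_age_yr"].notna().all():
        ages = summary["terminal_age_yr"].to_numpy(dtype=float)
        col_map = {
            "mean_t": "mean_t_ng_g",
            "median_t": "median_t_ng_g",
            "max_t": "max_t_ng_g",
            "min_t": "min_t_ng_g",
            "baseline": "baseline_ng_g",
            "cv_peaks_pct": "cv_peaks_pct",
        }
        for metric in CORRELATION_METRICS:
            vals = summary[col_map[metric]]
            if vals.notna().all() and np.ptp(vals.to_numpy(dtype=float)) > 0:
                res = pearson_corr_test(ages, vals.to_numpy(dtype=float))
                corr_rows.append(
                    {
                        "metric": metric,
                        "age_mode": config.age_mode,
                        "n": res.n,
                        "r": res.r,
                        "r_squared": res.r_squared,
                        "p_two_tailed": res.p_two_tailed,
                        "significant": res.significant,
                    }
                )
    correlations = pd.DataFrame(
        corr_rows,
        columns=["metric", "age_mode", "n", "r", "r_squared", "p_two_tailed", "significant"],
    )

    lmm_peak = lmm_period = None
    peak_df = pd.DataFrame(peak_obs)
    period_df = pd.DataFrame(period_obs)
    if len(peak_df) and peak_df["whale_id"].nunique() >= 2:
        lmm_peak = select_model(peak_df)
    if len(period_df) and period_df["whale_id"].nunique() >= 2:
        lmm_period = select_model(period_df)

    # reports (units in headers via column names; float format fixed for
    # byte-stable reruns)
    summary.to_csv(outdir / "whale_summary.csv", index=False)
    phase_df.to_csv(outdir / "phase.csv", index=False)
    cycles_df.to_csv(outdir / "cycles.csv", index=False)
    correlations.to_csv(outdir / "correlations.csv", index=False)
    for name, sel in (("lmm_peak_t", lmm_peak), ("lmm_cycle_period", lmm_period)):
        if sel is not None:
            with open(outdir / f"{name}.json", "w") as fh:
                json.dump(_selection_to_dict(sel), fh, indent=2, sort_keys=True)
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return AnalysisReport(
        summary=summary,
        phase=phase_df,
        cycles=cycles_df,
        correlations=correlations,
        lmm_peak=lmm_peak,
        lmm_period=lmm_period,
        errors=errors,
        output_dir=outdir,
    )


def _spec_from_dict(d: dict) -> SyntheticWhaleSpec:
    return SyntheticWhaleSpec(**d)


def run_simulation(
    output_dir,
    specs: Optional[Sequence[SyntheticWhaleSpec]] = None,
    master_seed: int = 0,
) -> tuple[Path, Path, Path]:
    """Generate a cohort (default: the nine-whale study-shaped scenario) and
    write profiles.csv, metadata.csv and truth.json into ``output_dir``.

    The metadata file carries each synthetic whale's true terminal age in
    the AAR column so an analyze run reproduces the truth chronology.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if specs is None:
        specs = nine_whale_scenario()
    profiles, truths = generate_cohort(specs, master_seed=master_seed)
    prof_path = write_profiles(profiles, outdir / "profiles.csv")
    meta_path = write_metadata(
        [
            WhaleMetadata(
                whale_id=s.whale_id,
                body_length_m=12.0,
                collection_month=1,
                collection_year=2000,
                aar_age_yr=s.terminal_age_yr,
            )
            for s in specs
        ],
        outdir / "metadata.csv",
    )
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                t.whale_id: {
                    "peak_positions_cm": t.peak_positions_cm.tolist(),
                    "periods_cm": t.periods_cm.tolist(),
                    "mean_period_cm": t.mean_period_cm if t.n_cycles else None,
                    "baselines": t.baselines.tolist(),
                    "amplitudes": t.amplitudes.tolist(),
                    "ages_yr": t.ages_yr.tolist(),
                    "phase_lead_months": t.phase_lead_months,
                    "terminal_age_yr": t.terminal_age_yr,
                    "n_clipped": t.n_clipped,
                }
                for t in truths
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return prof_path, meta_path, truth_path
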