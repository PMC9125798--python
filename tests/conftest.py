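"""Shared fixtures: simulated cohorts and expensive simulation experiments.

Heavy Monte Carlo experiments (mixed-model recovery, model-selection rates,
the end-to-end simulate/analyze run) are session-scoped so unit tests and
the acceptance suite share one computation.
"""

from __future__ import annotations

import json
import numpy as np
import pandas as pd
import pytest

import baleen_cycles as bc

# the study's data shape: terminal ages and per-whale peak counts
STUDY_TERMINAL_AGES = (14, 18, 21, 23, 24, 44, 48, 115, 153)
STUDY_PEAK_COUNTS = (5, 11, 12, 12, 15, 13, 16, 20, 22)


def study_shape_lmm_data(
    rng: np.random.Generator,
    slope_sd: float,
    fixed_slope: float,
    intercept: float = 23.1,
    intercept_sd: float = 3.0,
    resid_sd: float = 1.5,
) -> pd.DataFrame:
    """Simulated per-peak observations at the nine-whale study shape."""
    rows = []
    for w, (terminal, k) in enumerate(zip(STUDY_TERMINAL_AGES, STUDY_PEAK_COUNTS)):
        b0 = rng.normal(0.0, intercept_sd)
        b1 = rng.normal(0.0, slope_sd)
        for age in np.arange(terminal - k, terminal):
            rows.append(
                {
                    "whale_id": f"w{w}",
                    "age": float(age),
                    "response": intercept
                    + b0
                    + (fixed_slope + b1) * age
                    + rng.normal(0.0, resid_sd),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def lmm_slope_recovery() -> dict:
    """100 seeded replicates at the study shape (true slope -0.163, slope SD
    0.2): fraction of REML fits whose fixed slope lies within 2 SE of
    truth."""
    hits = fails = 0
    for rep in range(100):
        rng = np.random.default_rng(1000 + rep)
        df = study_shape_lmm_data(rng, slope_sd=0.2, fixed_slope=-0.163)
        try:
            fit = bc.fit_lmm(df, "random_intercept_slope", "REML")
        except bc.trend_models.ConvergenceError:
            fails += 1
            continue
        row = fit.fixed_effects.loc["age"]
        hits += abs(row["estimate"] - (-0.163)) <= 2.0 * row["se"]
    return {"hits": hits, "fails": fails, "n": 100}


@pytest.fixture(scope="session")
def selection_rates() -> dict:
    """Model-selection behaviour over 100 seeded replicates each: under
    strong slope heterogeneity and under the null."""
    slope_selected = 0
    for rep in range(100):
        rng = np.random.default_rng(2000 + rep)
        df = study_shape_lmm_data(rng, slope_sd=0.3, fixed_slope=-0.163, resid_sd=1.0)
        sel = bc.select_model(df)
        slope_selected += sel.best_variant == "random_intercept_slope"
    simple_selected = 0
    for rep in range(100):
        rng = np.random.default_rng(3000 + rep)
        df = study_shape_lmm_data(rng, slope_sd=0.0, fixed_slope=0.0)
        sel = bc.select_model(df)
        simple_selected += sel.best_variant in ("null", "random_intercept")
    return {"heterogeneity": slope_selected, "null": simple_selected, "n": 100}


@pytest.fixture(scope="session")
def period_recovery_noisy() -> dict:
    """100 seeded replicates of a 320-cm plate with constant 16-cm period
    and T noise at 10% of the pulse amplitude: period-estimate errors."""
    errors = []
    for seed in range(100):
        spec = bc.SyntheticWhaleSpec(
            "rec",
            plate_length_cm=320.0,
            terminal_age_yr=60.0,
            period_start_cm=16.0,
            period_decline_cm_per_cycle=0.0,
            peak_amplitude_start=5.0,
            baseline_start=1.0,
            noise_sd_t=0.5,
            seed=seed,
        )
        profile, _ = bc.generate_profile(spec)
        errors.append(abs(bc.estimate_period(profile).period_cm - 16.0))
    return {"errors": np.asarray(errors)}


@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory) -> dict:
    """One simulate -> analyze round trip of the default nine-whale
    scenario (master seed 7), with the juvenile whale windowed to its
    cycling half and the prominence filter at 4 robust noise sds."""
    base = tmp_path_factory.mktemp("e2e")
    prof_path, meta_path, truth_path = bc.run_simulation(base / "sim", master_seed=7)
    config = bc.PipelineConfig(
        profiles_path=prof_path,
        metadata_path=meta_path,
        output_dir=base / "out",
        windows={"W1": (0.0, 96.0)},
        peak_min_prominence_sd=4.0,
        seed=7,
    )
    report = bc.run_analysis(config)
    with open(truth_path) as fh:
        truth = json.load(fh)
    return {
        "config": config,
        "report": report,
        "truth": truth,
        "specs": {s.whale_id: s for s in bc.nine_whale_scenario()},
        "paths": (prof_path, meta_path, truth_path),
        "base": base,
    }
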