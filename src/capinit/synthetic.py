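"""Synthetic datasets with the statistical structure of the study's measurements.

The experimental observables the model is fitted to are immunoblot
densitometry readings of total 4E-BP — each replicate expressed as percent of
its own t = 0 band — and radiolabel incorporation curves of accumulated
protein in arbitrary units.  The generators here forward-simulate a scenario,
sample it on the experimental time grid, and add i.i.d. Gaussian noise per
replicate and time point; 4E-BP replicates are then renormalized to their own
noisy t = 0 observation, mimicking the densitometry normalization.

Defaults follow the study conditions: times {0,5,10,15,20,30,45,60} min,
8-11 replicates depending on the experiment, and noise calibrated so the
pooled plateau SD is about 5 percentage points.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .model import RateParameters, TimeCourse, Totals, TABLE1_TOTALS, UNFERTILIZED_RATES
from .fitting import baseline_parameters, predict_total_4ebp_pct
from .scenarios import SCENARIOS, run_scenario

__all__ = [
    "DEFAULT_SAMPLE_TIMES_MIN",
    "gen_4ebp_timecourse",
    "gen_emetine_decay",
    "gen_protein_accumulation",
]

DEFAULT_SAMPLE_TIMES_MIN = (0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0)


def _scenario_config(scenario: str, params: RateParameters | None, totals: Totals):
    if scenario not in SCENARIOS:
        raise KeyError(f"unknown scenario {scenario!r}")
    cfg = SCENARIOS[scenario]
    # default: flux-balanced synthesis, matching the scenario runner
    p = baseline_parameters(totals, params or UNFERTILIZED_RATES)
    if cfg.get("kcat_zero"):
        p = p.replace(k_cat_4ebp=0.0)
    return cfg["fold_changes"], cfg["ramp_min"], p


def gen_4ebp_timecourse(
    scenario: str = "fertilization",
    sample_times_min: Sequence[float] = DEFAULT_SAMPLE_TIMES_MIN,
    noise_sd_pct: float = 5.0,
    n_replicates: int = 10,
    seed: int = 0,
    totals: Totals = TABLE1_TOTALS,
    params: RateParameters | None = None,
    fold_changes: Mapping[str, float] | None = None,
    ramp_min: float | None = None,
) -> TimeCourse:
    """Noisy replicate time courses of total 4E-BP (% of initial).

    ``fold_changes``/``ramp_min`` override the scenario's canonical
    perturbation (useful for generating data at arbitrary grid points).
    Deterministic function of the configuration and ``seed``.
    """
    if noise_sd_pct < 0:
        raise ValueError("noise_sd_pct must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    sc_folds, sc_ramp, p = _scenario_config(scenario, params, totals)
    folds = dict(sc_folds if fold_changes is None else fold_changes)
    ramp = sc_ramp if ramp_min is None else ramp_min

    times = np.asarray(sample_times_min, dtype=float)
    truth = predict_total_4ebp_pct(times, folds, ramp, totals, p)

    rng = np.random.default_rng(seed)
    t0_pos = np.flatnonzero(times == 0.0)
    all_t, all_v, all_r = [], [], []
    for rep in range(n_replicates):
        noisy = truth + rng.normal(0.0, noise_sd_pct, size=len(times))
        if noise_sd_pct > 0 and len(t0_pos):
            # densitometry normalization: each replicate is % of its own t=0 band
            noisy = 100.0 * noisy / noisy[t0_pos[0]]
        elif noise_sd_pct == 0:
            noisy = truth.copy()
        all_t.append(times)
        all_v.append(noisy)
        all_r.append(np.full(len(times), f"rep{rep + 1:02d}"))
    return TimeCourse(
        times_min=np.concatenate(all_t),
        values=np.concatenate(all_v),
        replicates=np.concatenate(all_r),
    )


def gen_emetine_decay(
    k_lys: float | None = None,
    sample_times_min: Sequence[float] = DEFAULT_SAMPLE_TIMES_MIN,
    noise_sd_pct: float = 5.0,
    n_replicates: int = 8,
    seed: int = 0,
    totals: Totals = TABLE1_TOTALS,
    params: RateParameters | None = None,
) -> TimeCourse:
    """Synthesis-blocked 4E-BP decay; optionally with a non-default k_lys."""
    p = params or UNFERTILIZED_RATES
    if k_lys is not None:
        p = p.replace(k_lys_4ebp=k_lys)
    return gen_4ebp_timecourse(
        "emetine", sample_times_min, noise_sd_pct, n_replicates, seed, totals, p
    )


def gen_protein_accumulation(
    scenario: str = "fertilization",
    sample_times_min: Sequence[float] = DEFAULT_SAMPLE_TIMES_MIN,
    noise_sd_au: float = 0.02,
    n_replicates: int = 11,
    seed: int = 0,
    totals: Totals = TABLE1_TOTALS,
    params: RateParameters | None = None,
    horizon_min: float | None = None,
) -> TimeCourse:
    """Noisy samples of the cumulative protein curve (arbitrary units).

    The noiseless curve is normalized so the unfertilized run reaches 1 AU at
    the final sample time; ``noise_sd_au`` is on that scale.
    """
    times = np.asarray(sample_times_min, dtype=float)
    horizon = float(times[-1]) if horizon_min is None else horizon_min
    ref = run_scenario("unfertilized", horizon_min=horizon, totals=totals, params=params)
    norm = ref.protein()[-1]
    res = run_scenario(scenario, horizon_min=horizon, totals=totals, params=params)
    curve = np.interp(times, res.trajectory.times_min, res.protein() / norm)

    rng = np.random.default_rng(seed)
    all_t, all_v, all_r = [], [], []
    for rep in range(n_replicates):
        noisy = curve + rng.normal(0.0, noise_sd_au, size=len(times)) if noise_sd_au > 0 else curve.copy()
        all_t.append(times)
        all_v.append(noisy)
        all_r.append(np.full(len(times), f"rep{rep + 1:02d}"))
    return TimeCourse(
        times_min=np.concatenate(all_t),
        values=np.concatenate(all_v),
        replicates=np.concatenate(all_r),
    )
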