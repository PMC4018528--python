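"""The four named experiments packaged as configured model runs.

* ``unfertilized`` — baseline parameters, no perturbation; the system sits at
  its steady state.
* ``emetine`` — protein-synthesis block: 4E-BP synthesis is switched off
  instantaneously at t = 0, isolating the degradation pathway.
* ``fertilization`` — k_off1 x8 and k_lys_4ebp x32.5, ramped linearly over
  5 minutes from t = 0.
* ``rapamycin`` — fertilization in the presence of the mTOR inhibitor:
  k_off1 unchanged, k_lys_4ebp x16, ramped over 33 minutes.

Every run starts from the equilibrium partition of the total pools with the
flux-balanced synthesis rate, so the unfertilized run is exactly stationary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np

from .model import (
    ParameterRamp,
    RateParameters,
    SpeciesState,
    TimeCourse,
    Totals,
    Trajectory,
    TABLE1_TOTALS,
    UNFERTILIZED_RATES,
    simulate,
)
from .fitting import baseline_parameters
from .steady_state import (
    equilibrium_partition,
    flux_balance_steady_state,
    fold_changes,
)

__all__ = ["SCENARIOS", "ScenarioResult", "run_scenario", "protein_accumulation"]

#: canonical fold changes and ramp durations per scenario
SCENARIOS: Dict[str, Dict] = {
    "unfertilized": {"fold_changes": {}, "ramp_min": 0.0},
    "emetine": {"fold_changes": {}, "ramp_min": 0.0, "kcat_zero": True},
    "fertilization": {
        "fold_changes": {"k_off1": 8.0, "k_lys_4ebp": 32.5},
        "ramp_min": 5.0,
    },
    "rapamycin": {
        "fold_changes": {"k_lys_4ebp": 16.0},
        "ramp_min": 33.0,
    },
}


@dataclass
class ScenarioResult:
    name: str
    trajectory: Trajectory
    initial_state: SpeciesState
    steady_state: SpeciesState | None
    fold_changes: Dict[str, float] | None
    total_4ebp_pct: np.ndarray
    plateau_pct: float

    def protein(self) -> np.ndarray:
        return self.trajectory.species("protein")


def run_scenario(
    name: str,
    overrides: Mapping | None = None,
    horizon_min: float = 60.0,
    dt_s: float = 30.0,
    totals: Totals = TABLE1_TOTALS,
    params: RateParameters | None = None,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
) -> ScenarioResult:
    """Simulate a named scenario from the unfertilized steady state.

    ``overrides`` may replace ``fold_changes`` or ``ramp_min``.  The summary
    includes the asymptotic flux-balance steady state under the final
    parameters and the per-species fold changes relative to the initial
    state (degenerate for the emetine run, whose asymptote is trivial).
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    cfg = dict(SCENARIOS[name])
    if overrides:
        cfg.update(overrides)

    base = baseline_parameters(totals, params or UNFERTILIZED_RATES)
    state0 = equilibrium_partition(totals, base.kd1, base.kd2)
    if cfg.get("kcat_zero"):
        base = base.replace(k_cat_4ebp=0.0)

    ramp = ParameterRamp(
        base, cfg["fold_changes"], t_start=0.0, duration=cfg["ramp_min"] * 60.0
    )
    t_grid = np.arange(0.0, horizon_min * 60.0 + 0.5 * dt_s, dt_s)
    traj = simulate(state0, ramp, t_grid, rel_tol=rel_tol, abs_tol=abs_tol)

    final = ramp.final
    if final.k_lys_4ebp > 0 and final.k_cat_4ebp > 0:
        ss = flux_balance_steady_state(totals.total_eif4e, totals.total_eif4g, final)
        folds = fold_changes(state0, ss)
    else:
        ss, folds = None, None

    pct = 100.0 * traj.total_4ebp() / state0.total_4ebp
    return ScenarioResult(
        name=name,
        trajectory=traj,
        initial_state=state0,
        steady_state=ss,
        fold_changes=folds,
        total_4ebp_pct=pct,
        plateau_pct=float(pct[-1]),
    )


def protein_accumulation(result: ScenarioResult, normalize_to: float | None = None) -> TimeCourse:
    """Accumulated-protein read-out of a scenario run, in arbitrary units.

    The protein state variable is the cumulative integral of
    k_cat_protein * [eIF4E:eIF4G]; it is nondecreasing and asymptotically
    linear with slope proportional to the steady-state complex level.
    ``normalize_to`` rescales so that value equals 1 at the final time
    (e.g. the 60-min unfertilized value for cross-scenario comparison).
    """
    values = result.protein().copy()
    if normalize_to is not None:
        values = values / normalize_to
    return TimeCourse(
        times_min=result.trajectory.times_min,
        values=values,
        replicates=np.full(len(values), "sim"),
    )
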