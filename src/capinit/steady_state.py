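"""Steady states of the translation-initiation model.

Two stationary conditions are used:

* the *equilibrium partition* of fixed total pools of eIF4E, 4E-BP and eIF4G
  between free forms and the two complexes, given the dissociation constants
  KD1 and KD2 (the unfertilized-egg calculation);
* the *flux-balance steady state* in which the total 4E-BP pool is itself an
  output, set by the balance between synthesis from the eIF4E:eIF4G complex
  (k_cat_4ebp) and degradation of free 4E-BP (k_lys_4ebp).

Both reduce to a one-dimensional root find in free eIF4E: every other species
is closed-form in free eIF4E, and the eIF4E-conservation residual is strictly
increasing, so the bracketed root on (0, total_eif4e) is unique.
"""

from __future__ import annotations

import math
from typing import Dict

from scipy.optimize import brentq

from .model import RateParameters, SpeciesState, Totals, SPECIES

__all__ = [
    "equilibrium_partition",
    "flux_balance_steady_state",
    "fold_changes",
    "flux_balanced_kcat",
]

_XTOL = 1e-15  # uM; residual tolerance well below the 1e-12 target


def equilibrium_partition(totals: Totals, kd1: float, kd2: float) -> SpeciesState:
    """Partition fixed total pools between free species and complexes.

    Solves the coupled binding equilibria

        [eIF4E][4E-BP] = KD1 [eIF4E:4E-BP]
        [eIF4E][eIF4G] = KD2 [eIF4E:eIF4G]

    subject to the three conservation identities for the total pools.  All
    concentrations in uM.  Protein is reported as 0.
    """
    if not (kd1 > 0 and kd2 > 0):
        raise ValueError("dissociation constants must be > 0")
    Bt, Et, Gt = totals.total_4ebp, totals.total_eif4e, totals.total_eif4g
    if Et == 0:
        return SpeciesState(0.0, Bt, Gt, 0.0, 0.0, 0.0)

    def residual(E: float) -> float:
        return E + Bt * E / (kd1 + E) + Gt * E / (kd2 + E) - Et

    E = _bracketed_root(residual, Et)
    C1 = Bt * E / (kd1 + E)
    C2 = Gt * E / (kd2 + E)
    return SpeciesState(
        eif4e_free=E,
        fourebp_free=Bt - C1,
        eif4g_free=Gt - C2,
        complex_eb=C1,
        complex_eg=C2,
        protein=0.0,
    )


def flux_balance_steady_state(
    total_eif4e: float, total_eif4g: float, params: RateParameters
) -> SpeciesState:
    """Steady state with 4E-BP synthesis balanced against degradation.

    eIF4E and eIF4G pools are conserved; the free 4E-BP level is pinned by
    k_cat_4ebp * [eIF4E:eIF4G] = k_lys_4ebp * [4E-BP], so total 4E-BP is an
    output of the computation, not an input.
    """
    if not (params.k_lys_4ebp > 0):
        raise ValueError("flux balance requires k_lys_4ebp > 0")
    kd1, kd2 = params.kd1, params.kd2
    Et, Gt = total_eif4e, total_eif4g
    ratio = params.k_cat_4ebp / params.k_lys_4ebp
    if Et == 0:
        return SpeciesState(0.0, 0.0, Gt, 0.0, 0.0, 0.0)

    def pieces(E: float):
        C2 = Gt * E / (kd2 + E)
        B = ratio * C2
        C1 = E * B / kd1
        return B, C2, C1

    def residual(E: float) -> float:
        B, C2, C1 = pieces(E)
        return E + C1 + C2 - Et

    E = _bracketed_root(residual, Et)
    B, C2, C1 = pieces(E)
    return SpeciesState(
        eif4e_free=E,
        fourebp_free=B,
        eif4g_free=Gt - C2,
        complex_eb=C1,
        complex_eg=C2,
        protein=0.0,
    )


def flux_balanced_kcat(totals: Totals, params: RateParameters) -> float:
    """Synthesis rate that holds total 4E-BP stationary at the partition state.

    At the equilibrium partition of ``totals`` the 4E-BP balance requires
    k_cat_4ebp = k_lys_4ebp * [4E-BP]_free / [eIF4E:eIF4G].
    """
    st = equilibrium_partition(totals, params.kd1, params.kd2)
    if st.complex_eg == 0:
        return 0.0
    return params.k_lys_4ebp * st.fourebp_free / st.complex_eg


def fold_changes(
    reference: SpeciesState, perturbed: SpeciesState
) -> Dict[str, float]:
    """Elementwise perturbed/reference ratios per species.

    Species with a zero reference concentration are reported as NaN
    (undefined) rather than infinite.
    """
    out: Dict[str, float] = {}
    for name in SPECIES:
        ref = getattr(reference, name)
        out[name] = getattr(perturbed, name) / ref if ref > 0 else math.nan
    return out


def _bracketed_root(residual, upper: float) -> float:
    lo, hi = 0.0, upper
    flo = residual(lo)
    if flo >= 0:  # residual(0) = -Et <= 0 always; equality means Et == 0
        return 0.0
    try:
        return brentq(residual, lo, hi, xtol=_XTOL, rtol=8.9e-16, maxiter=200)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"steady-state root find failed: {exc}") from exc
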