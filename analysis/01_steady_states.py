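"""Unfertilized steady state and the predicted fertilization/rapamycin shifts.

Solves the coupled eIF4E/4E-BP/eIF4G binding equilibria for the measured
total pools and dissociation constants, then computes the flux-balance
steady states under the fertilization (k_off1 x8, k_lys x32.5) and rapamycin
(k_lys x16) parameter changes.  Writes a table of species concentrations and
fold changes to results/steady_state.csv.
"""

from pathlib import Path

import pandas as pd

from capinit import (
    TABLE1_TOTALS,
    UNFERTILIZED_RATES,
    equilibrium_partition,
    flux_balance_steady_state,
    fold_changes,
)
from capinit.fitting import baseline_parameters
from capinit.model import SPECIES

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    totals, rates = TABLE1_TOTALS, UNFERTILIZED_RATES
    base = baseline_parameters(totals, rates)
    print(f"KD1 = {rates.kd1 * 1e3:.1f} nM, KD2 = {rates.kd2 * 1e3:.1f} nM")
    print(f"flux-balanced k_cat_4ebp = {base.k_cat_4ebp:.3e} s^-1")

    unf = equilibrium_partition(totals, rates.kd1, rates.kd2)
    fert = flux_balance_steady_state(
        totals.total_eif4e, totals.total_eif4g,
        base.scaled({"k_off1": 8.0, "k_lys_4ebp": 32.5}),
    )
    rap = flux_balance_steady_state(
        totals.total_eif4e, totals.total_eif4g,
        base.scaled({"k_lys_4ebp": 16.0}),
    )
    f_fert, f_rap = fold_changes(unf, fert), fold_changes(unf, rap)

    rows = [
        (s, getattr(unf, s), f_fert[s], f_rap[s])
        for s in SPECIES if s != "protein"
    ]
    df = pd.DataFrame(rows, columns=[
        "species", "unfertilized_uM", "fertilized_fold", "rapamycin_fold",
    ])
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "steady_state.csv", index=False, float_format="%.4g")
    print(df.to_string(index=False))
    print(
        f"\nActive-complex (eIF4E:eIF4G) fold: fertilization "
        f"{f_fert['complex_eg']:.2f}, rapamycin {f_rap['complex_eg']:.2f} — "
        "translation rises ~4-fold at fertilization and only ~2.6-fold "
        "when the degradation boost is attenuated and eIF4E:4E-BP stays stable."
    )


if __name__ == "__main__":
    main()
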