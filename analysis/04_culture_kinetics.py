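#!/usr/bin/env python
"""Fed-batch kinetics and deconvolution of the mid-process Hyl dip.

Computes IVCD, specific productivity, cell-specific iron uptake and per-cell
iron availability from the simulated culture, then inverts the cumulative
Hyl time course into per-interval newly-formed fractions and fits the
two-logistic dip model.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hylquant.io import read_culture_csv
from hylquant.kinetics import (
    fit_newly_formed,
    newly_formed_fraction,
    rate_report,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
OUT = RESULTS / "kinetics"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    series = read_culture_csv(RESULTS / "synthetic" / "culture.csv")

    rates = rate_report(series)
    pd.DataFrame({
        "day": rates.t,
        "ivcd_cell_day_per_ml": rates.ivcd,
        "iron_fmol_per_cell": rates.iron_per_cell,
    }).to_csv(OUT / "per_sample.csv", index=False)
    pd.DataFrame({
        "t_mid": rates.t_mid,
        "qp_pg_per_cell_day": rates.qp,
        "qs_iron_fmol_per_cell_day": rates.qs_iron,
        "dp_mg_per_l": rates.dp,
    }).to_csv(OUT / "per_interval.csv", index=False)

    print(f"final IVCD: {rates.ivcd[-1]:.3g} cell·day/mL; "
          f"harvest product {series.product[-1]:.0f} mg/L")
    print(f"mean qP {np.nanmean(rates.qp):.1f} pg/cell/day; mean qS_Iron "
          f"{np.nanmean(rates.qs_iron):.2f} fmol/cell/day (negative = "
          "consumption)")
    print(f"iron per cell falls {rates.iron_per_cell[0]:.1f} -> "
          f"{rates.iron_per_cell[-1]:.2f} fmol/cell over the process")

    nf = newly_formed_fraction(series)
    fit = fit_newly_formed(series, model="two_logistic")
    pd.DataFrame({
        "t_mid": nf.t_mid, "g_exact": nf.g, "g_fitted": fit.g,
    }).to_csv(OUT / "newly_formed.csv", index=False)

    dip_day = nf.t_mid[np.nanargmin(nf.g)]
    print(f"cumulative Hyl declines smoothly, but the newly-formed fraction "
          f"dips to {np.nanmin(nf.g) * 100:.1f}% around day {dip_day:.1f} "
          "— coincident with the low-iron stagnation phase")
    print("two-logistic fit:",
          {k: round(float(v), 3) for k, v in fit.params.items()})


if __name__ == "__main__":
    main()
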