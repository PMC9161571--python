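#!/usr/bin/env python
"""Survival stratified by EV PD-L1 dynamics.

Kaplan-Meier curves by increase/decrease class with at-risk counts every
6 months and 12/24-month landmarks, two-group log-rank tests, univariate
Cox hazard ratios for the decrease indicator, and a backward-stepwise
multivariate Cox model over dynamics class, TPS group and treatment line
for both PFS and OS.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from evrad import (
    cox_backward_stepwise,
    cox_fit,
    dynamics_table,
    km_estimate,
    load_cohort,
    logrank_test,
)
from evrad.models import tps_to_ordinal

COHORT = Path("results/cohort")
OUT = Path("results/survival.json")


def main() -> None:
    records, blots, _ = load_cohort(COHORT)
    ids = [r.patient_id for r in records]
    deltas = dynamics_table(blots).set_index("patient_id").loc[ids]
    decrease = (deltas["dynamics_class"] == "decrease").to_numpy().astype(int)
    tps = tps_to_ordinal(np.array([r.tissue_tps for r in records]))
    line = np.array([r.line for r in records], dtype=float)

    payload = {}
    for endpoint in ("pfs", "os"):
        times = np.array([getattr(r, f"{endpoint}_months") for r in records])
        events = np.array([getattr(r, f"{endpoint}_event") for r in records])
        chi2, p = logrank_test(times, events, decrease)
        uni = cox_fit(times, events, pd.DataFrame({"ev_decrease": decrease}))
        candidates = pd.DataFrame(
            {"ev_decrease": decrease, "tps_group": tps, "line": line}
        )
        candidates = candidates.loc[:, candidates.nunique() > 1]
        multi = cox_backward_stepwise(times, events, candidates)

        print(f"== {endpoint.upper()} ==")
        for label, flag in (("decrease", 1), ("increase", 0)):
            curve = km_estimate(times[decrease == flag], events[decrease == flag])
            med = ("not reached" if np.isinf(curve.median_months)
                   else f"{curve.median_months:.1f} mo")
            print(f"  {label:<9} 12-mo {curve.landmark_12m:.2f}  "
                  f"24-mo {curve.landmark_24m:.2f}  median {med}")
        hr = uni.hazard_ratios["ev_decrease"]
        print(f"  log-rank chi2={chi2:.2f} p={p:.4g}")
        print(f"  univariate Cox HR (decrease vs increase) = {hr:.2f} "
              f"[{uni.ci_lower['ev_decrease']:.2f}, {uni.ci_upper['ev_decrease']:.2f}], "
              f"p={uni.p_values['ev_decrease']:.4g}")
        print(f"  stepwise multivariate retained: {multi.retained or 'none'}")
        payload[endpoint] = {
            "logrank": {"chi2": chi2, "p": p},
            "cox_univariate_hr": hr,
            "stepwise_retained": multi.retained,
            "stepwise_hrs": multi.hazard_ratios,
        }
    OUT.write_text(json.dumps(payload, indent=2))
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
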