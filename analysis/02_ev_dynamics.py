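#!/usr/bin/env python
"""ΔEV PD-L1 dynamics vs durable response.

Recomputes the ratio statistic from the persisted blot table, classifies
each patient as increase/decrease, and tests whether non-responders show
higher Δ than responders (one-sided Mann-Whitney), mirroring the core
biomarker comparison. Also reports the apparent univariate ROC of Δ
against non-response with its Youden cut-point.
"""

from pathlib import Path

import numpy as np

from evrad import dynamics_table, load_cohort, mann_whitney_u, univariate_roc

COHORT = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    records, blots, _ = load_cohort(COHORT)
    table = dynamics_table(blots)
    table.to_csv(OUT / "deltas.csv", index=False)

    responder = np.array([r.durable_responder for r in records])
    delta = table.set_index("patient_id").loc[
        [r.patient_id for r in records], "delta"
    ].to_numpy()

    u, p = mann_whitney_u(delta[~responder], delta[responder], alternative="greater")
    roc = univariate_roc(delta, (~responder).astype(int))

    n_inc = int((table["dynamics_class"] == "increase").sum())
    print(f"{len(table)} evaluable patients: {n_inc} increase, {len(table) - n_inc} decrease")
    print(f"median delta  responders={np.median(delta[responder]):.2f}  "
          f"non-responders={np.median(delta[~responder]):.2f}")
    print(f"Mann-Whitney (non-responders > responders): U={u:.0f}, p={p:.4g}")
    print(f"apparent ROC of delta vs non-response: AUC={roc.auc:.3f}, "
          f"Youden cut-point={roc.cutpoint:.2f} "
          f"(sens={roc.sensitivity:.2f}, spec={roc.specificity:.2f})")


if __name__ == "__main__":
    main()
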