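#!/usr/bin/env python
"""Clinical outcome arithmetic on the published trial's event records.

Feeds the per-dog disposition records of the motivating 14-dog trial
(7 FMT / 7 placebo, one placebo exclusion, CCECAI- and FCS-based scoring)
through phase_outcomes and writes the responder/relapse table, cumulative
relapse, and the recruitment funnel under results/clinical/.
"""

from pathlib import Path

import pandas as pd

from fmtkit import trial_data
from fmtkit.clinical import cumulative_relapse, phase_outcomes

OUT = Path(__file__).resolve().parent.parent / "results" / "clinical"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for system, records in (
        ("CCECAI", trial_data.ccecai_disposition()),
        ("FCS", trial_data.fcs_disposition()),
    ):
        outcomes, p_values = phase_outcomes(records)
        for o in outcomes:
            rows.append({
                "score_system": system, "group": o.group, "phase": o.phase,
                "n_evaluable": o.n_evaluable, "n_relapsed": o.n_relapsed,
                "responder_percent": o.responder_percent,
                "relapse_percent": o.relapse_percent,
                "exact_test_p": round(p_values.get(o.phase, float("nan")), 3),
            })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "disposition_summary.tsv", sep="\t", index=False,
                 lineterminator="\n")

    n_rel, n_eval, pct = cumulative_relapse(trial_data.ccecai_disposition(), "FMT")
    funnel = trial_data.recruitment_percent()

    print(table.to_string(index=False))
    print(f"\nFMT cumulative relapse after post-treatment: {n_rel}/{n_eval} = {pct}%")
    print(f"recruitment funnel: {trial_data.RECRUITMENT['entered_treatment']}/"
          f"{trial_data.RECRUITMENT['suspected_tre']} = {funnel}%")
    print(f"wrote {OUT / 'disposition_summary.tsv'}")


if __name__ == "__main__":
    main()
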