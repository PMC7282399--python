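"""Construct centile standards from the simulated cohort.

Applies the prescriptive exclusion cascade, pools the retained children's
scaled scores across sites, estimates Harrell-Davis centiles per domain,
derives the direction-aware screening chart, compares estimates to the
generator's ground truth, and runs the girls-vs-boys rank-sum comparison.
Outputs under results/standards/.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np

from internda import (
    apply_cascade,
    build_centile_table,
    chart_from_table,
    compare_by_sex,
    normality_threshold,
)
from internda.hd import TABLE_CENTILES, centile_label
from internda import io

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "standards"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    children = io.read_cohort_csv(ROOT / "cohort" / "cohort.csv")
    scores = io.read_scores_csv(ROOT / "scores.csv")
    truth = json.loads((ROOT / "cohort" / "ground_truth.json").read_text())

    retained, audit = apply_cascade(children)
    (OUT / "cascade_audit.json").write_text(
        json.dumps(dataclasses.asdict(audit), indent=2)
    )
    print(f"cascade: {audit.n_input} assessed -> {audit.n_retained} retained")
    for reason, n in audit.exclusions.items():
        if n:
            print(f"  excluded {n:4d}  {reason}")

    ids = {c.child_id for c in retained}
    normative = scores[scores.child_id.isin(ids) & scores.scaled.notna()]
    by_domain = {d: g.scaled.to_numpy() for d, g in normative.groupby("domain")}
    table = build_centile_table(by_domain, centile_set=TABLE_CENTILES)
    io.write_centile_table(
        table, json_path=OUT / "centiles.json", csv_path=OUT / "centiles.csv"
    )

    errs = []
    for d, row in table.values.items():
        for q in TABLE_CENTILES:
            errs.append(abs(row[centile_label(q)] - truth["quantiles"][d][centile_label(q)]))
    print(f"centile recovery vs ground truth: max |error| = {max(errs):.2f}, "
          f"median = {np.median(errs):.2f} scaled-score points")

    chart = chart_from_table(table)
    (OUT / "chart.json").write_text(json.dumps(
        {"source": chart.source, "directions": chart.directions,
         "boundaries": chart.boundaries}, indent=2))
    print("normality thresholds (cohort-derived):")
    for d in chart.domains:
        thr, op = normality_threshold(chart, d)
        print(f"  {d:<20} {op}{thr:.1f}")

    sex = {c.child_id: c.sex for c in retained}
    rows = []
    for d, g in normative.groupby("domain"):
        s = g.child_id.map(sex)
        res = compare_by_sex(
            g.loc[s == "female", "scaled"], g.loc[s == "male", "scaled"], domain=d
        )
        rows.append(dataclasses.asdict(res))
        print(f"  sex comparison {d:<20} p = {res.p_value:.3g} ({res.method})")
    (OUT / "sex_comparison.json").write_text(json.dumps(rows, indent=2))
    print(f"wrote {OUT}/centiles.csv, centiles.json, chart.json, "
          "cascade_audit.json, sex_comparison.json")


if __name__ == "__main__":
    main()
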