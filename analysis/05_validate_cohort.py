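"""Cohort-normality checks on the simulated cohort.

Quantifies the between-site share of scaled-score variance per domain
(pooling across sites is defensible when the share stays below ~10%),
computes vision centiles against the Cardiff norm ranges, the proportion
of children achieving each WHO gross motor milestone within its window,
and descriptive summaries.  Writes results/validation.json.
"""

import json
from pathlib import Path

import pandas as pd

from internda import (
    describe_cohort,
    milestone_window_check,
    variance_components,
    vision_centile_check,
)
from internda import io

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    children = io.read_cohort_csv(ROOT / "cohort" / "cohort.csv")
    scores = io.read_scores_csv(ROOT / "scores.csv")
    vision = pd.read_csv(ROOT / "cohort" / "vision.csv")
    milestones = io.read_milestones_csv(ROOT / "cohort" / "milestones.csv")
    truth = json.loads((ROOT / "cohort" / "ground_truth.json").read_text())

    site = {c.child_id: c.site for c in children}
    report = {"variance_share": {}}
    print("between-site variance share (estimate vs generator truth):")
    for d, g in scores[scores.scaled.notna()].groupby("domain"):
        vd = variance_components(g.scaled.to_numpy(), g.child_id.map(site).to_numpy())
        report["variance_share"][d] = vd.between_share
        print(f"  {d:<20} {vd.between_share:.3f} vs {truth['between_share'][d]:.3f}")
    worst = max(report["variance_share"].values())
    report["pooling_justified"] = worst < 0.10
    print(f"max share = {worst:.3f} -> pooling "
          f"{'justified' if report['pooling_justified'] else 'NOT justified'} "
          "(criterion: < 0.10)")

    check = vision_centile_check(
        vision.acuity_logmar.to_numpy(), vision.contrast_percent.to_numpy()
    )
    report["vision"] = {"centiles": check.centiles, "in_norm": check.in_norm}
    print("vision medians:",
          f"acuity {check.centiles['acuity_logmar']['c50']:.2f} logMAR,",
          f"contrast {check.centiles['contrast_percent']['c50']:.2f}%",
          f"(in Cardiff norm range: {check.in_norm})")

    mw = milestone_window_check(milestones)
    report["milestones"] = mw.to_dict(orient="records")
    print("milestone windows: " + ", ".join(
        f"{r.milestone}={r.proportion_within:.2f}" for r in mw.itertuples()))

    cohort_df = pd.DataFrame(
        {"age_months": [c.age_at_assessment for c in children],
         "ga_weeks": [c.gestational_age_at_birth for c in children],
         "female": [c.sex == "female" for c in children]}
    )
    desc = describe_cohort(
        cohort_df, continuous=["age_months", "ga_weeks"], binary=["female"]
    )
    report["descriptives"] = desc.to_dict(orient="records")
    print(desc.to_string(index=False))

    (ROOT / "validation.json").write_text(
        json.dumps(report, indent=2, default=float)
    )
    print(f"wrote {ROOT}/validation.json")


if __name__ == "__main__":
    main()
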