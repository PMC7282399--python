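"""Cohort-normality checks justifying a pooled prescriptive sample.

Pooling a multi-site cohort into one normative sample is defensible when
site-level differences are small relative to between-child variability.
This module quantifies that via a one-way random-effects variance
decomposition (method of moments), and provides the independent
developmental checks used to confirm the cohort's low-risk profile:
visual acuity / contrast sensitivity centiles against Cardiff test norms,
the proportion of children achieving the six WHO gross motor milestones
within their normative windows of achievement, and generic descriptive
summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

from .hd import build_centile_table, centile_label

#: WHO Multicentre Growth Reference Study windows of achievement (months).
WHO_MOTOR_WINDOWS = {
    "sitting_without_support": (3.8, 9.2),
    "standing_with_assistance": (4.8, 11.4),
    "hands_and_knees_crawling": (5.2, 13.5),
    "walking_with_assistance": (5.9, 13.7),
    "standing_alone": (6.9, 16.9),
    "walking_alone": (8.2, 17.6),
}

#: Cardiff test normative ranges for 24-30-month-olds (editable config, not
#: hard-coded science): binocular acuity in logMAR (lower is better) and
#: contrast sensitivity in percent (lower is better).
CARDIFF_NORMS = {
    "acuity_logmar": (0.0, 0.6),
    "contrast_percent": (0.5, 3.0),
}

#: CBCL subscale centile cut-offs: borderline and clinical range.
CBCL_BORDERLINE_CENTILE = 93.0
CBCL_CLINICAL_CENTILE = 97.0


@dataclass
class VarianceDecomposition:
    """One-way random-effects decomposition of score variance by site."""

    sigma2_between: float
    sigma2_within: float
    n_per_site: dict[str, int]
    n_sites: int

    @property
    def between_share(self) -> float:
        total = self.sigma2_between + self.sigma2_within
        return self.sigma2_between / total if total > 0 else 0.0


@dataclass
class NormRange:
    measure: str
    lower: float
    upper: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"norm range for {self.measure!r} has lower > upper")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass
class MilestoneWindow:
    milestone: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"window for {self.milestone!r} must have lower < upper")


def default_milestone_windows() -> list[MilestoneWindow]:
    return [MilestoneWindow(m, lo, hi) for m, (lo, hi) in WHO_MOTOR_WINDOWS.items()]


def variance_components(
    scores: Sequence[float], site_labels: Sequence[str]
) -> VarianceDecomposition:
    """Method-of-moments one-way random-effects ANOVA by site.

    sigma2_within is the pooled within-site mean square; sigma2_between is
    max(0, (MS_between - MS_within) / n0) with the unbalanced-design
    effective group size n0 = (N - sum(n_j^2)/N) / (k - 1).  Sites with
    fewer than two children are dropped with a warning.
    """
    y = np.asarray(scores, dtype=float)
    labels = np.asarray(site_labels)
    if y.shape != labels.shape:
        raise ValueError("scores and site_labels must have equal length")
    keep = np.isfinite(y)
    y, labels = y[keep], labels[keep]
    sites, counts = np.unique(labels, return_counts=True)
    small = sites[counts < 2]
    if small.size:
        warnings.warn(
            f"excluding {small.size} site(s) with <2 children: {list(small)}",
            stacklevel=2,
        )
        mask = ~np.isin(labels, small)
        y, labels = y[mask], labels[mask]
        sites, counts = np.unique(labels, return_counts=True)
    k = sites.size
    if k < 2:
        raise ValueError("need at least 2 sites with >=2 children each")
    n_total = y.size
    grand = y.mean()
    group_means = np.array([y[labels == s].mean() for s in sites])
    ss_between = float(np.sum(counts * (group_means - grand) ** 2))
    ss_within = float(
        sum(np.sum((y[labels == s] - m) ** 2) for s, m in zip(sites, group_means))
    )
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k)
    n0 = (n_total - np.sum(counts**2) / n_total) / (k - 1)
    sigma2_between = max(0.0, (ms_between - ms_within) / n0)
    return VarianceDecomposition(
        sigma2_between=sigma2_between,
        sigma2_within=ms_within,
        n_per_site={str(s): int(c) for s, c in zip(sites, counts)},
        n_sites=int(k),
    )


@dataclass
class VisionCheck:
    centiles: dict[str, dict[str, float]]  # measure -> label -> value
    in_norm: dict[str, bool]
    norms: dict[str, NormRange]


def vision_centile_check(
    acuity_logmar: Sequence[float],
    contrast_percent: Sequence[float],
    norms: Mapping[str, NormRange] | None = None,
    centile_set=(0.10, 0.25, 0.50, 0.75, 0.90),
) -> VisionCheck:
    """Harrell-Davis vision centiles with direction-aware label mapping.

    Both Cardiff measures are better when lower (logMAR acuity, contrast
    threshold in %), so the value reported at centile label c is the
    (1 - c) quantile of the raw values: better performance appears at
    higher centile labels and the columns decrease down the table.  The
    verdict checks whether each measure's median lies within its norm range.
    """
    if norms is None:
        norms = {
            m: NormRange(m, lo, hi, source="Cardiff test norms (24-30 months)")
            for m, (lo, hi) in CARDIFF_NORMS.items()
        }
    samples = {
        "acuity_logmar": np.asarray(acuity_logmar, dtype=float),
        "contrast_percent": np.asarray(contrast_percent, dtype=float),
    }
    flipped = {m: {} for m in samples}
    for measure, x in samples.items():
        if x.size == 0:
            raise ValueError(f"empty sample for {measure!r}")
        table = build_centile_table(
            {measure: x}, centile_set=[1 - q for q in centile_set], min_n=1
        )
        for q in centile_set:
            flipped[measure][centile_label(q)] = table.values[measure][
                centile_label(1 - q)
            ]
    in_norm = {
        m: bool(norms[m].contains(flipped[m][centile_label(0.50)]))
        for m in samples
        if m in norms
    }
    return VisionCheck(centiles=flipped, in_norm=in_norm, norms=dict(norms))


def milestone_window_check(
    achievement_ages: pd.DataFrame,
    windows: Iterable[MilestoneWindow] | None = None,
) -> pd.DataFrame:
    """Proportion of children achieving each milestone within its window.

    ``achievement_ages`` is long format with columns child_id, milestone,
    age_months where age may be NaN (missing, excluded from the denominator)
    or +inf (reported never observed, counted outside the window).  Returns
    one row per milestone with n, n_within and proportion (NaN when no
    usable data).
    """
    windows = list(windows) if windows is not None else default_milestone_windows()
    by_name = {w.milestone: w for w in windows}
    unknown = set(achievement_ages["milestone"]) - set(by_name)
    if unknown:
        raise ValueError(f"unknown milestone name(s): {sorted(unknown)}")
    rows = []
    for w in windows:
        ages = achievement_ages.loc[
            achievement_ages["milestone"] == w.milestone, "age_months"
        ].astype(float)
        ages = ages[ages.notna()]
        n = int(ages.size)
        n_within = int(((ages >= w.lower) & (ages <= w.upper)).sum())
        rows.append(
            {
                "milestone": w.milestone,
                "window_lower": w.lower,
                "window_upper": w.upper,
                "n": n,
                "n_within": n_within,
                "proportion_within": n_within / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def describe_cohort(
    cohort: pd.DataFrame,
    continuous: Sequence[str] = (),
    binary: Sequence[str] = (),
    median_iqr: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-variable summaries in the conventional mean (SD) / n (%) style."""
    rows = []
    n = len(cohort)
    for var in continuous:
        x = cohort[var].astype(float).dropna()
        if x.empty:
            rows.append({"variable": var, "summary": "no data", "kind": "mean (SD)"})
            continue
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        rows.append(
            {
                "variable": var,
                "summary": f"{x.mean():.1f} ({sd:.2f})",
                "kind": "mean (SD)",
            }
        )
    for var in median_iqr:
        x = cohort[var].astype(float).dropna()
        if x.empty:
            rows.append({"variable": var, "summary": "no data", "kind": "median (IQR)"})
            continue
        q1, q2, q3 = x.quantile([0.25, 0.5, 0.75])
        rows.append(
            {
                "variable": var,
                "summary": f"{q2:.1f} ({q1:.1f}-{q3:.1f})",
                "kind": "median (IQR)",
            }
        )
    for var in binary:
        x = cohort[var].dropna().astype(bool)
        count = int(x.sum())
        pct = 100 * count / len(x) if len(x) else math.nan
        rows.append(
            {"variable": var, "summary": f"n={count} ({pct:.1f}%)", "kind": "n (%)"}
        )
    return pd.DataFrame(rows, columns=["variable", "summary", "kind"]).assign(n_cohort=n)
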