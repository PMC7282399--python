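"""Direction-aware normality thresholds and three-zone screening classification.

The screening chart divides each domain's 0-100 scaled-score axis into three
zones.  For domains where higher scores are better (all but negative
behaviour):

* normal  — score >= 10th centile (the normality threshold, inclusive);
* monitor — 3rd centile <= score < 10th centile ("yellow": routine referral);
* urgent  — score < 3rd centile ("orange": urgent referral).

For negative behaviour, where lower scores reflect better outcomes, the
rule is mirrored: normal <= 90th centile, monitor in (90th, 97th], urgent
above the 97th.  Boundary ties (e.g. c3 = c10 = 0) collapse the monitor
band to an empty interval; classification stays total.  The published
standards chart ships with the package and any computed
:class:`~internda.hd.CentileTable` can be turned into a chart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

HIGHER_IS_BETTER = "higher_is_better"
LOWER_IS_BETTER = "lower_is_better"

DEFAULT_DIRECTIONS = {
    "cognitive": HIGHER_IS_BETTER,
    "fine_motor": HIGHER_IS_BETTER,
    "gross_motor": HIGHER_IS_BETTER,
    "language": HIGHER_IS_BETTER,
    "positive_behaviour": HIGHER_IS_BETTER,
    "negative_behaviour": LOWER_IS_BETTER,
}

ZONES = ("normal", "monitor", "urgent")
ZONE_COLOURS = {"normal": "white", "monitor": "yellow", "urgent": "orange"}
REFERRAL_TEXT = {
    "normal": "no referral indicated",
    "monitor": "routine further assessment advised",
    "urgent": "urgent further assessment / specialist referral advised",
}


@dataclass
class StandardsChart:
    """Zone boundaries (c3/c10/c90/c97) per domain, plus score direction."""

    boundaries: dict[str, dict[str, float]]
    directions: dict[str, str]
    source: str = "computed from cohort"

    def __post_init__(self) -> None:
        for domain, row in self.boundaries.items():
            missing = {"c3", "c10", "c90", "c97"} - row.keys()
            if missing:
                raise ValueError(f"domain {domain!r} missing boundaries {sorted(missing)}")
            if not row["c3"] <= row["c10"] <= row["c90"] <= row["c97"]:
                raise ValueError(f"domain {domain!r} boundaries not ordered")
            if self.directions.get(domain) not in (HIGHER_IS_BETTER, LOWER_IS_BETTER):
                raise ValueError(f"domain {domain!r} lacks a valid direction")

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(self.boundaries)


def published_chart() -> StandardsChart:
    """The packaged published standards chart (2-year-old normative cohort)."""
    text = resources.files("internda.data").joinpath("table4_chart.json").read_text()
    raw = json.loads(text)
    return StandardsChart(
        boundaries=raw["boundaries"], directions=raw["directions"], source=raw["source"]
    )


def chart_from_table(table, directions: dict[str, str] | None = None) -> StandardsChart:
    """Derive a screening chart from a computed :class:`~internda.hd.CentileTable`."""
    directions = directions or DEFAULT_DIRECTIONS
    boundaries = {}
    for domain, row in table.values.items():
        try:
            boundaries[domain] = {k: row[k] for k in ("c3", "c10", "c90", "c97")}
        except KeyError as exc:
            raise ValueError(
                f"centile table lacks {exc} for domain {domain!r}; "
                "include 0.03, 0.10, 0.90, 0.97 in the centile set"
            ) from None
    return StandardsChart(
        boundaries=boundaries,
        directions={d: directions[d] for d in boundaries},
        source=table.source,
    )


@dataclass
class ZoneResult:
    domain: str
    score: float
    zone: str
    interval: tuple[float | None, float | None]  # boundary interval applied


def normality_threshold(chart: StandardsChart, domain: str) -> tuple[float, str]:
    """The normality cut-off and its comparison direction for a domain.

    Returns (c10, '>=') for higher-is-better domains and (c90, '<=') for
    lower-is-better ones.
    """
    if domain not in chart.boundaries:
        raise KeyError(f"domain {domain!r} not in chart")
    if chart.directions[domain] == HIGHER_IS_BETTER:
        return chart.boundaries[domain]["c10"], ">="
    return chart.boundaries[domain]["c90"], "<="


def classify_score(chart: StandardsChart, domain: str, score: float) -> ZoneResult:
    """Assign a scaled score to its screening zone.

    Zone rules are inclusive at the normality threshold and assign exact
    c3/c97 boundary values to the monitor zone (urgent is strictly beyond).
    """
    if domain not in chart.boundaries:
        raise KeyError(f"domain {domain!r} not in chart")
    if not 0 <= score <= 100:
        raise ValueError(f"score {score} outside the scaled-score range [0, 100]")
    b = chart.boundaries[domain]
    if chart.directions[domain] == HIGHER_IS_BETTER:
        if score >= b["c10"]:
            zone, interval = "normal", (b["c10"], None)
        elif score >= b["c3"]:
            zone, interval = "monitor", (b["c3"], b["c10"])
        else:
            zone, interval = "urgent", (None, b["c3"])
    else:
        if score <= b["c90"]:
            zone, interval = "normal", (None, b["c90"])
        elif score <= b["c97"]:
            zone, interval = "monitor", (b["c90"], b["c97"])
        else:
            zone, interval = "urgent", (b["c97"], None)
    return ZoneResult(domain=domain, score=score, zone=zone, interval=interval)


def render_chart(
    chart: StandardsChart,
    results: Iterable[ZoneResult],
    plot_path: str | None = None,
) -> dict:
    """Structured screening report: JSON-ready dict plus a plain-text table.

    ``plot_path`` optionally writes a zone-band chart figure (matplotlib).
    """
    results = list(results)
    rows = []
    for r in results:
        if r.domain not in chart.boundaries:
            raise KeyError(f"result references unknown domain {r.domain!r}")
        thr, op = normality_threshold(chart, r.domain)
        rows.append(
            {
                "domain": r.domain,
                "score": r.score,
                "zone": r.zone,
                "colour": ZONE_COLOURS[r.zone],
                "normality_threshold": f"{op}{thr:g}",
                "boundaries": chart.boundaries[r.domain],
                "guidance": REFERRAL_TEXT[r.zone],
            }
        )
    flagged = [row["domain"] for row in rows if row["zone"] != "normal"]
    header = f"{'domain':<20} {'score':>7} {'zone':<8} {'threshold':<10} guidance"
    lines = [header, "-" * len(header)]
    for row in rows:
        lines.append(
            f"{row['domain']:<20} {row['score']:>7.1f} {row['zone']:<8} "
            f"{row['normality_threshold']:<10} {row['guidance']}"
        )
    report = {
        "source": chart.source,
        "n_domains": len(rows),
        "rows": rows,
        "flagged_domains": flagged,
        "text": "\n".join(lines),
    }
    if plot_path is not None:
        _plot_chart(chart, results, plot_path)
        report["plot"] = plot_path
    return report


def _plot_chart(chart: StandardsChart, results: list[ZoneResult], path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    domains = list(chart.domains)
    fig, ax = plt.subplots(figsize=(8, 0.9 * len(domains) + 1.5))
    for y, domain in enumerate(domains):
        b = chart.boundaries[domain]
        if chart.directions[domain] == HIGHER_IS_BETTER:
            spans = [(0, b["c3"], "orange"), (b["c3"], b["c10"], "gold"), (b["c10"], 100, "white")]
        else:
            spans = [(0, b["c90"], "white"), (b["c90"], b["c97"], "gold"), (b["c97"], 100, "orange")]
        for lo, hi, colour in spans:
            ax.barh(y, hi - lo, left=lo, color=colour, edgecolor="grey", height=0.6)
    for r in results:
        ax.plot(r.score, domains.index(r.domain), "ko", markersize=8, zorder=5)
    ax.set_yticks(range(len(domains)), domains)
    ax.set_xlim(0, 100)
    ax.set_xlabel("scaled score")
    ax.set_title("Developmental screening zones")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
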