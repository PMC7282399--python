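"""Scoring of the 37-item INTER-NDA instrument.

The INTER-NDA (INTERGROWTH-21st Neurodevelopment Assessment) measures six
developmental domains in children aged 22-30 months: cognition, fine and
gross motor skills, language, and positive and negative behaviour.  Items
are ordinal, most on a five-point scale and six on a three-point scale.
Because the scales are mixed, raw per-domain mean scores are converted to
standardised scaled scores on a common 0-100 support: each item response is
min-max normalised to [0, 1] via (score - 1) / (scale_points - 1), the
normalised responses are averaged within domain over *answered* items, and
the mean is multiplied by 100.  Missing responses are prorated (mean over
answered items), never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

DOMAINS = (
    "cognitive",
    "fine_motor",
    "gross_motor",
    "language",
    "positive_behaviour",
    "negative_behaviour",
)

ADMIN_MODES = ("direct", "observation", "caregiver_report")


@dataclass(frozen=True)
class ItemDefinition:
    """One ordinal item of the instrument."""

    item_id: str
    domain: str
    scale_points: int
    admin_mode: str = "direct"

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r} for item {self.item_id!r}")
        if self.scale_points not in (3, 5):
            raise ValueError(
                f"scale_points must be 3 or 5, got {self.scale_points} for item {self.item_id!r}"
            )
        if self.admin_mode not in ADMIN_MODES:
            raise ValueError(f"unknown admin_mode {self.admin_mode!r}")


@dataclass
class ItemMap:
    """Ordered collection of item definitions with a version tag."""

    items: list[ItemDefinition]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item_id(s): {dupes}")
        self._by_id = {it.item_id: it for it in self.items}

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> ItemDefinition:
        return self._by_id[item_id]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    @property
    def domains(self) -> tuple[str, ...]:
        seen: list[str] = []
        for it in self.items:
            if it.domain not in seen:
                seen.append(it.domain)
        return tuple(seen)

    def items_for(self, domain: str) -> list[ItemDefinition]:
        return [it for it in self.items if it.domain == domain]


@dataclass
class AssessmentRecord:
    """One child's item responses plus assessment age in months."""

    child_id: str
    age_at_assessment: float
    responses: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_at_assessment < 0:
            raise ValueError("age_at_assessment must be non-negative")


@dataclass
class DomainScore:
    """Raw and scaled score for one domain of one assessment.

    ``scaled`` is None when no item of the domain was answered; then
    ``completeness`` is 0.
    """

    domain: str
    raw_mean: float | None
    scaled: float | None
    n_items_answered: int
    completeness: float


@dataclass
class CompletenessVerdict:
    child_id: str
    complete: bool
    incomplete_domains: list[str]


def load_item_map(config_source=None) -> ItemMap:
    """Build an :class:`ItemMap` from a config mapping, YAML path, or the default.

    The config is a mapping with a ``version`` key and an ``items`` list of
    entries with ``item_id``, ``domain``, ``scale_points`` and optional
    ``admin_mode``.  With no argument the packaged default 37-item map is
    returned (30 five-point, 6 three-point, plus one item of unstated scale
    treated as five-point).
    """
    if config_source is None:
        text = resources.files("internda.data").joinpath("item_map.yaml").read_text()
        cfg = yaml.safe_load(text)
    elif isinstance(config_source, Mapping):
        cfg = config_source
    else:
        with open(config_source) as fh:
            cfg = yaml.safe_load(fh)
    items = [
        ItemDefinition(
            item_id=str(entry["item_id"]),
            domain=entry["domain"],
            scale_points=int(entry["scale_points"]),
            admin_mode=entry.get("admin_mode", "direct"),
        )
        for entry in cfg["items"]
    ]
    return ItemMap(items=items, version=str(cfg.get("version", "unversioned")))


def compute_domain_scores(
    record: AssessmentRecord, item_map: ItemMap
) -> list[DomainScore]:
    """Score one assessment into per-domain raw means and 0-100 scaled scores.

    Raises ValueError if a response falls outside its item's scale range or
    references an item absent from the map.
    """
    per_domain: dict[str, list[tuple[int, int]]] = {d: [] for d in item_map.domains}
    for item_id, score in record.responses.items():
        if score is None:
            continue
        if item_id not in item_map:
            raise ValueError(
                f"child {record.child_id!r}: response for unknown item {item_id!r}"
            )
        item = item_map[item_id]
        if not (1 <= score <= item.scale_points):
            raise ValueError(
                f"child {record.child_id!r}: score {score} outside [1, "
                f"{item.scale_points}] for item {item_id!r}"
            )
        per_domain[item.domain].append((score, item.scale_points))

    out: list[DomainScore] = []
    for domain in item_map.domains:
        n_total = len(item_map.items_for(domain))
        answered = per_domain[domain]
        if not answered:
            out.append(DomainScore(domain, None, None, 0, 0.0))
            continue
        raw_mean = sum(s for s, _ in answered) / len(answered)
        scaled = 100.0 * sum((s - 1) / (k - 1) for s, k in answered) / len(answered)
        out.append(
            DomainScore(
                domain=domain,
                raw_mean=raw_mean,
                scaled=scaled,
                n_items_answered=len(answered),
                completeness=len(answered) / n_total,
            )
        )
    return out


def flag_completeness(
    child_id: str, scores: Iterable[DomainScore], min_fraction: float = 0.8
) -> CompletenessVerdict:
    """Flag a record incomplete if any domain's completeness < min_fraction.

    The threshold is inclusive: completeness exactly equal to
    ``min_fraction`` counts as complete.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    offending = [s.domain for s in scores if s.completeness < min_fraction]
    return CompletenessVerdict(
        child_id=child_id, complete=not offending, incomplete_domains=offending
    )
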