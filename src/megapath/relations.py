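"""Classifying literature relations against disease direction.

A regulator (here typically PPARG) touches genes that are themselves
disease markers or disease drivers.  A target is *contradirectional* when
the regulator's polarity opposes the target's direction in disease:

* ``suppressed_disease_promoter``  -- negative polarity on a gene that is
  up in disease (or is a disease promoter): the regulator pushes a harmful
  gene down.
* ``activated_disease_inhibitor``  -- positive polarity on a gene that is
  down in disease (or is a disease inhibitor): the regulator pushes a
  protective gene up.

Same-direction pairs are kept but labelled ``concordant_excluded``;
targets with unknown disease direction are dropped with a log message.
Promoter/inhibitor annotations share the same polarity algebra as
up/down expression annotations (promoter == up_in_disease,
inhibitor == down_in_disease).

Classes are then *confirmed* against mega-analysis output: a target is
confirmed when the pooled LFC's sign matches its literature direction at
p <= alpha, contradicted when the sign flips at p <= alpha, untested
otherwise.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .formats_io import (
    DOWN,
    INHIBITOR,
    NEGATIVE,
    POSITIVE,
    PROMOTER,
    UNKNOWN,
    UP,
    RelationRecord,
)
from .mega_analysis import MetaResult

logger = logging.getLogger(__name__)

SUPPRESSED_PROMOTER = "suppressed_disease_promoter"
ACTIVATED_INHIBITOR = "activated_disease_inhibitor"
CONCORDANT = "concordant_excluded"
CLASSES = (SUPPRESSED_PROMOTER, ACTIVATED_INHIBITOR, CONCORDANT)

CONFIRMED = "confirmed"
CONTRADICTED = "contradicted"
UNTESTED = "untested"

#: promoter/inhibitor annotations reduce to expression directions
_DIRECTION_CANON = {UP: UP, DOWN: DOWN, PROMOTER: UP, INHIBITOR: DOWN}


@dataclass(frozen=True)
class ClassifiedTarget:
    gene: str
    cls: str
    literature_direction: str  # up_in_disease | down_in_disease (canonical)
    regulator_polarity: str
    n_refs: int = 1
    confirmed_by_expression: str = UNTESTED

    def __post_init__(self) -> None:
        if self.cls not in CLASSES:
            raise ValueError(f"unknown class {self.cls!r}")
        contra_promoter = (
            self.regulator_polarity == NEGATIVE and self.literature_direction == UP
        )
        contra_inhibitor = (
            self.regulator_polarity == POSITIVE and self.literature_direction == DOWN
        )
        if (self.cls == SUPPRESSED_PROMOTER) != contra_promoter and self.cls != CONCORDANT:
            raise ValueError("class inconsistent with polarity/direction")
        if (self.cls == ACTIVATED_INHIBITOR) != contra_inhibitor and self.cls != CONCORDANT:
            raise ValueError("class inconsistent with polarity/direction")


def _resolve_duplicates(
    relations: Iterable[RelationRecord], regulator: str
) -> dict[str, RelationRecord]:
    """Collapse multiple relations per (regulator, target).

    Conflicting polarity: the record with more supporting references wins;
    a tie excludes the target entirely (no arbiter).  Same-polarity
    duplicates keep the better-supported record.
    """
    by_target: dict[str, list[RelationRecord]] = {}
    for rel in relations:
        if rel.regulator != regulator:
            continue
        by_target.setdefault(rel.target, []).append(rel)
    resolved: dict[str, RelationRecord] = {}
    for target, recs in by_target.items():
        polarities = {r.polarity for r in recs}
        if len(polarities) > 1:
            support = Counter()
            for r in recs:
                support[r.polarity] += r.n_refs
            ranked = support.most_common()
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                logger.warning(
                    "target %s excluded: conflicting polarity with tied "
                    "reference support", target,
                )
                continue
            winner = ranked[0][0]
            recs = [r for r in recs if r.polarity == winner]
            logger.info(
                "target %s: conflicting polarity resolved to %s by n_refs",
                target, winner,
            )
        resolved[target] = max(recs, key=lambda r: r.n_refs)
    return resolved


def classify_contradirectional(
    relations: Iterable[RelationRecord], regulator: str
) -> list[ClassifiedTarget]:
    """Classify each of ``regulator``'s targets against its disease direction.

    Pure function of (polarity, direction): permuting the input never
    changes the multiset of outputs.  Targets with unknown direction are
    excluded and logged.
    """
    resolved = _resolve_duplicates(relations, regulator)
    out: list[ClassifiedTarget] = []
    for target in sorted(resolved):
        rel = resolved[target]
        direction = _DIRECTION_CANON.get(rel.disease_direction)
        if direction is None:
            logger.info(
                "target %s excluded: disease direction unknown", target
            )
            continue
        if rel.polarity == NEGATIVE and direction == UP:
            cls = SUPPRESSED_PROMOTER
        elif rel.polarity == POSITIVE and direction == DOWN:
            cls = ACTIVATED_INHIBITOR
        else:
            cls = CONCORDANT
        out.append(
            ClassifiedTarget(
                gene=target,
                cls=cls,
                literature_direction=direction,
                regulator_polarity=rel.polarity,
                n_refs=rel.n_refs,
            )
        )
    return out


def confirm_with_expression(
    targets: Sequence[ClassifiedTarget],
    meta: Mapping[str, MetaResult],
    alpha: float = 0.05,
) -> list[ClassifiedTarget]:
    """Mark each target confirmed/contradicted/untested against pooled LFCs.

    Confirmed: sign(pooled LFC) matches the literature direction and
    p <= alpha.  Contradicted: sign mismatch at p <= alpha.  Untested:
    gene absent from ``meta``, insignificant, or pooled LFC exactly zero.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    out = []
    for t in targets:
        res = meta.get(t.gene)
        state = UNTESTED
        if res is not None and res.p_value <= alpha and res.pooled_lfc != 0.0:
            observed = UP if res.pooled_lfc > 0 else DOWN
            state = CONFIRMED if observed == t.literature_direction else CONTRADICTED
        out.append(replace(t, confirmed_by_expression=state))
    return out


def count_classes(targets: Iterable[ClassifiedTarget]) -> dict[str, int]:
    """Counts per class and per confirmation state; the class counts
    partition the input (they sum to its size)."""
    counts = {cls: 0 for cls in CLASSES}
    counts.update({CONFIRMED: 0, CONTRADICTED: 0, UNTESTED: 0})
    total = 0
    for t in targets:
        counts[t.cls] += 1
        counts[t.confirmed_by_expression] += 1
        total += 1
    counts["total"] = total
    return counts


def targets_to_rows(targets: Iterable[ClassifiedTarget]) -> list[dict]:
    return [
        {
            "gene": t.gene,
            "class": t.cls,
            "literature_direction": t.literature_direction,
            "regulator_polarity": t.regulator_polarity,
            "n_refs": t.n_refs,
            "confirmed_by_expression": t.confirmed_by_expression,
        }
        for t in targets
    ]
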