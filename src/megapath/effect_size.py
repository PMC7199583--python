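"""Per-study effect sizes: log2 fold-change and its standard error.

The effect size for a gene in one cohort is the difference of group means
on the log2 scale, LFC = mean(case) - mean(control).  Its uncertainty uses
the unpooled (Welch-style) standard error

    se = sqrt(s2_case / n_case + s2_control / n_control)

with s2 the unbiased sample variance per group, which is robust to unequal
group variances and to the extreme group imbalance some cohorts show
(e.g. 4 controls against 443 cases).  Single-sample groups contribute zero
variance and are flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .formats_io import ExpressionStudy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EffectEstimate:
    """One study's log2 fold-change for one gene."""

    gene: str
    study_id: str
    lfc: float
    se: float
    n_case: int
    n_control: int
    degenerate: bool = False  # a group of size 1 or zero variance in both groups

    def __post_init__(self) -> None:
        if not np.isfinite(self.lfc):
            raise ValueError(f"non-finite LFC for {self.gene!r}/{self.study_id!r}")
        if self.se < 0 or not np.isfinite(self.se):
            raise ValueError(f"invalid SE {self.se!r}")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("both groups must contain at least one sample")


def compute_effect(study: ExpressionStudy, gene: str) -> EffectEstimate:
    """LFC and Welch SE of ``gene`` in ``study``.

    Raises ``KeyError`` if the gene is absent.  A group of size one gets
    sample variance 0 and the estimate is flagged ``degenerate``.
    """
    control, case = study.group_values(gene)
    lfc = float(case.mean() - control.mean())
    var_control = float(control.var(ddof=1)) if control.size > 1 else 0.0
    var_case = float(case.var(ddof=1)) if case.size > 1 else 0.0
    se = float(np.sqrt(var_case / case.size + var_control / control.size))
    degenerate = control.size == 1 or case.size == 1 or se == 0.0
    if degenerate:
        logger.debug(
            "degenerate variance for %s in %s (n=%d/%d, se=%g)",
            gene, study.study_id, control.size, case.size, se,
        )
    return EffectEstimate(
        gene=gene,
        study_id=study.study_id,
        lfc=lfc,
        se=se,
        n_case=int(case.size),
        n_control=int(control.size),
        degenerate=degenerate,
    )


def effects_for_gene(
    studies: Iterable[ExpressionStudy], gene: str
) -> list[EffectEstimate]:
    """One estimate per study carrying the gene; studies lacking it are
    skipped with a log message (arrays differ in gene coverage)."""
    out: list[EffectEstimate] = []
    for study in studies:
        if gene not in study.genes:
            logger.info("gene %s absent from study %s; skipped", gene, study.study_id)
            continue
        out.append(compute_effect(study, gene))
    if not out:
        warnings.warn(f"gene {gene!r} found in no study", stacklevel=2)
    return out


def substitute_degenerate_se(
    effects: Sequence[EffectEstimate], floor_fraction: float = 0.1
) -> list[EffectEstimate]:
    """Replace se == 0 with the smallest positive se among the gene's
    studies times ``floor_fraction``, so inverse-variance weights stay
    finite.  If every se is zero the data carry no sampling noise at all;
    unit ses are substituted so pooling degrades to an unweighted mean."""
    positive = [e.se for e in effects if e.se > 0]
    if len(positive) == len(effects):
        return list(effects)
    if positive:
        floor = min(positive) * floor_fraction
    else:
        floor = 1.0
        logger.warning("all studies have zero-variance effects; using equal weights")
    out = []
    for e in effects:
        if e.se == 0.0:
            logger.info(
                "se=0 for %s in %s replaced by %g", e.gene, e.study_id, floor
            )
            e = replace(e, se=floor)
        out.append(e)
    return out
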