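"""Synthetic cohorts, gene sets and relation tables with known ground truth.

The generator emulates the structure of the 13 public lung-adenocarcinoma
case/control microarray cohorts the pipeline was designed around: per-arm
sample sizes from 4 to 443, country of origin and study age as covariates,
and Gaussian log2 intensities (microarray-style; no count model).  For a
study *s* and gene *g* the true study effect is

    delta_gs ~ Normal(true_lfc_g + covariate terms, tau2)

with control samples ~ Normal(baseline, noise_sd^2) and case samples
~ Normal(baseline + delta_gs, noise_sd^2).  Every generator takes a seed
and is byte-reproducible.

Gene-set simulation plants exact query overlaps per set (the published
top-10 geometry ships as ``TOP10_SET_GEOMETRY``), drawing overlap members
round-robin from a coverage pool so that which query genes are covered is
controlled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    CASE,
    CONTROL,
    DOWN,
    NEGATIVE,
    POSITIVE,
    UP,
    ExpressionStudy,
    GeneSetCollection,
    RelationRecord,
)

#: the 13-cohort case/control design the generator reproduces by default:
#: (study_id, n_control, n_case, country, study_age in years)
DEFAULT_STUDY_DESIGN: tuple[tuple[str, int, int, str, int], ...] = (
    ("GSE2088", 30, 9, "Japan", 11),
    ("GSE7670", 28, 27, "Taiwan", 13),
    ("GSE10072", 49, 58, "USA", 12),
    ("GSE31547", 20, 30, "USA", 9),
    ("GSE32863", 58, 58, "USA", 8),
    ("GSE32867", 58, 58, "USA", 8),
    ("GSE40791", 90, 94, "USA", 7),
    ("GSE43458", 30, 80, "USA", 7),
    ("GSE46539", 92, 92, "Taiwan", 4),
    ("GSE51852", 4, 49, "Japan", 6),
    ("GSE63459", 32, 33, "USA", 5),
    ("GSE68465", 4, 443, "USA", 5),
    ("GSE118370", 6, 6, "China", 1),
)

#: published top-10 enriched-set geometry against a 26-gene query:
#: (name, accession, set size, planted query overlap)
TOP10_SET_GEOMETRY: tuple[tuple[str, str, int, int], ...] = (
    ("GO: response to oxygen levels", "0070482", 544, 17),
    ("GO: response to mechanical stimulus", "0009612", 334, 14),
    ("GO: response to inorganic substance", "0010035", 803, 17),
    ("GO: response to acid chemical", "0001101", 662, 16),
    ("GO: response to peptide", "1901652", 553, 15),
    ("GO: regulation of smooth muscle cell proliferation", "0048660", 215, 12),
    ("GO: response to hypoxia", "0001666", 424, 14),
    ("GO: positive regulation of cell migration", "0030335", 603, 15),
    ("GO: response to decreased oxygen levels", "0036293", 461, 14),
    ("GO: positive regulation of cell motility", "2000147", 630, 15),
)


def design_frame(
    design: Sequence[tuple[str, int, int, str, int]] = DEFAULT_STUDY_DESIGN
) -> pd.DataFrame:
    """Study design as a metadata DataFrame indexed by study_id."""
    return pd.DataFrame(
        design, columns=["study_id", "n_control", "n_case", "country", "study_age"]
    ).set_index("study_id")


@dataclass
class SimulationConfig:
    """Parameters of the expression-cohort simulator.

    Defaults reflect the emulated design: the 13-cohort layout above,
    log2 baseline 8 (typical microarray intensity), per-sample noise SD 1
    and no between-study effect variance (tau2 = 0).
    """

    design: Sequence[tuple[str, int, int, str, int]] = DEFAULT_STUDY_DESIGN
    true_lfc: Mapping[str, float] = field(default_factory=dict)
    n_background_genes: int = 100
    baseline_mean: float = 8.0
    noise_sd: float = 1.0
    tau2: float = 0.0
    covariate_slopes: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for sid, nc, na, *_ in self.design:
            if nc < 1 or na < 1:
                raise ValueError(f"study {sid}: both arms need >= 1 sample")
        unknown = set(self.covariate_slopes) - {"sample_size", "study_age"}
        if unknown:
            raise ValueError(f"unknown covariate slopes {sorted(unknown)}")


def simulate_studies(
    cfg: SimulationConfig,
) -> tuple[list[ExpressionStudy], pd.DataFrame]:
    """Simulate the configured cohorts plus a ground-truth record.

    Returns the studies and a DataFrame with one row per (study, gene)
    giving the realised true study effect delta_gs.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = list(cfg.true_lfc) + [
        f"BG{i:05d}" for i in range(cfg.n_background_genes)
    ]
    tau = float(np.sqrt(cfg.tau2))
    studies: list[ExpressionStudy] = []
    truth_rows: list[dict] = []
    for study_id, n_control, n_case, country, study_age in cfg.design:
        total = n_control + n_case
        samples = [f"{study_id}_S{i:04d}" for i in range(total)]
        groups = pd.Series(
            [CONTROL] * n_control + [CASE] * n_case, index=samples
        )
        cov_shift = cfg.covariate_slopes.get("sample_size", 0.0) * total
        cov_shift += cfg.covariate_slopes.get("study_age", 0.0) * study_age
        matrix = np.empty((len(genes), total))
        for gi, gene in enumerate(genes):
            mu = cfg.true_lfc.get(gene, 0.0) + cov_shift
            delta = rng.normal(mu, tau) if tau > 0 else mu
            matrix[gi, :n_control] = rng.normal(
                cfg.baseline_mean, cfg.noise_sd, n_control
            )
            matrix[gi, n_control:] = rng.normal(
                cfg.baseline_mean + delta, cfg.noise_sd, n_case
            )
            truth_rows.append(
                {"study_id": study_id, "gene": gene, "true_effect": delta}
            )
        studies.append(
            ExpressionStudy(
                study_id=study_id,
                matrix=pd.DataFrame(matrix, index=genes, columns=samples),
                sample_groups=groups,
                country=country,
                study_age=study_age,
            )
        )
    return studies, pd.DataFrame(truth_rows)


def simulate_effect_estimates(
    design: pd.DataFrame,
    gene: str = "G1",
    *,
    true_lfc: float = 0.0,
    covariate_slopes: Mapping[str, float] | None = None,
    residual_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list:
    """Draw study-level LFCs directly (no per-sample matrices).

    The per-study effect is ``true_lfc + covariate terms + Normal(0,
    residual_sd^2)`` with i.i.d. residuals -- the pure-noise design used
    for regression calibration experiments.  Returns EffectEstimate
    objects with se = residual_sd.
    """
    from .effect_size import EffectEstimate

    rng = rng or np.random.default_rng(0)
    slopes = covariate_slopes or {}
    out = []
    for study_id, row in design.iterrows():
        total = int(row["n_control"] + row["n_case"])
        mu = true_lfc
        mu += slopes.get("sample_size", 0.0) * total
        mu += slopes.get("study_age", 0.0) * float(row["study_age"])
        out.append(
            EffectEstimate(
                gene=gene,
                study_id=str(study_id),
                lfc=float(rng.normal(mu, residual_sd)),
                se=residual_sd,
                n_case=int(row["n_case"]),
                n_control=int(row["n_control"]),
            )
        )
    return out


def simulate_genesets(
    n_sets: int,
    size_range: tuple[int, int],
    planted_query: Sequence[str],
    planted_overlaps: Sequence[int],
    universe_size: int,
    seed: int,
    *,
    coverage_pool: Sequence[str] | None = None,
    geometry: Sequence[tuple[str, str, int, int]] | None = None,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Gene sets with exact planted query overlaps.

    ``geometry`` fixes (name, accession, size, overlap) for the leading
    sets (e.g. ``TOP10_SET_GEOMETRY``); remaining sets get sizes drawn
    uniformly from ``size_range`` and overlaps from ``planted_overlaps``
    (cycled).  Overlap members come round-robin from ``coverage_pool``
    (default: the whole query) so total coverage is deterministic: with
    enough total overlap every pool gene is covered and no gene outside
    the pool ever is.  Non-overlap members are sampled from the universe
    excluding the query.
    """
    rng = np.random.default_rng(seed)
    query = list(dict.fromkeys(planted_query))
    pool = list(coverage_pool) if coverage_pool is not None else list(query)
    if not set(pool) <= set(query):
        raise ValueError("coverage_pool must be a subset of the query")
    background = [f"U{i:05d}" for i in range(universe_size - len(query))]
    universe = query + background

    specs: list[tuple[str, str, int, int]] = []
    geometry = list(geometry or [])
    for i in range(n_sets):
        if i < len(geometry):
            specs.append(geometry[i])
        else:
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            overlap = int(planted_overlaps[i % len(planted_overlaps)])
            specs.append((f"SYN: set {i + 1:03d}", f"SYN{i + 1:07d}", size, overlap))

    cursor = 0
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    truth_rows = []
    for name, accession, size, overlap in specs:
        if overlap > min(size, len(pool)):
            raise ValueError(
                f"set {name!r}: overlap {overlap} infeasible for size {size} "
                f"and pool {len(pool)}"
            )
        members: list[str] = []
        for _ in range(overlap):
            members.append(pool[cursor % len(pool)])
            cursor += 1
        filler = rng.choice(len(background), size=size - overlap, replace=False)
        members += [background[j] for j in filler]
        sets[name] = frozenset(members)
        descriptions[name] = accession
        truth_rows.append(
            {"name": name, "go_id": accession, "set_size": size, "overlap": overlap}
        )
    collection = GeneSetCollection(
        sets=sets, descriptions=descriptions, universe=frozenset(universe)
    )
    return collection, pd.DataFrame(truth_rows)


def simulate_relations(
    n_suppressed: int,
    n_activated: int,
    n_concordant: int = 0,
    n_unknown: int = 0,
    *,
    regulator: str = "REG1",
    seed: int = 0,
) -> tuple[list[RelationRecord], pd.DataFrame]:
    """Relation table with exactly the requested class composition.

    suppressed: negative polarity on an up-in-disease target;
    activated: positive polarity on a down-in-disease target;
    concordant: polarity matching the direction; unknown: direction
    missing.  Reference counts are drawn in 1..20.
    """
    rng = np.random.default_rng(seed)
    records: list[RelationRecord] = []
    truth_rows = []
    counter = 0

    def add(polarity: str, direction: str, cls: str) -> None:
        nonlocal counter
        counter += 1
        gene = f"T{counter:04d}"
        records.append(
            RelationRecord(
                regulator=regulator,
                target=gene,
                polarity=polarity,
                disease_direction=direction,
                n_refs=int(rng.integers(1, 21)),
            )
        )
        truth_rows.append({"gene": gene, "true_class": cls})

    for _ in range(n_suppressed):
        add(NEGATIVE, UP, "suppressed_disease_promoter")
    for _ in range(n_activated):
        add(POSITIVE, DOWN, "activated_disease_inhibitor")
    for _ in range(n_concordant):
        if rng.random() < 0.5:
            add(POSITIVE, UP, "concordant_excluded")
        else:
            add(NEGATIVE, DOWN, "concordant_excluded")
    for _ in range(n_unknown):
        add(
            POSITIVE if rng.random() < 0.5 else NEGATIVE,
            "unknown",
            "excluded_unknown_direction",
        )
    return records, pd.DataFrame(truth_rows)
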