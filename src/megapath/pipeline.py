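"""End-to-end orchestration: classify -> pool -> confirm -> regress ->
enrich -> network, with a reproducible run manifest.

Every stage writes a plain TSV (one file per worksheet analogue) into the
output directory; the manifest records package version, seed, thresholds
and SHA-256 digests of every input so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .covariates import fit_mlr, study_metadata
from .effect_size import effects_for_gene
from .enrichment import (
    fisher_enrich,
    filter_and_rank,
    genes_covered,
    results_to_rows,
)
from .formats_io import (
    GeneSetCollection,
    read_expression_study,
    read_gmt,
    read_relation_table,
    write_edge_list,
    write_expression_study,
    write_gmt,
    write_relation_table,
    write_results_table,
)
from .mega_analysis import MegaAnalysis
from .network import all_node_stats, build_network, edge_list, membership_from_enrichment
from .relations import (
    classify_contradirectional,
    confirm_with_expression,
    count_classes,
    targets_to_rows,
)
from .synthetic_data import (
    DEFAULT_STUDY_DESIGN,
    TOP10_SET_GEOMETRY,
    SimulationConfig,
    design_frame,
    simulate_genesets,
    simulate_studies,
)

logger = logging.getLogger(__name__)

#: planted log2 effects of the default synthetic bundle: the regulator is
#: down in disease; the confirmed subsets of its literature targets move
#: in their literature direction, the rest stay null.
DEFAULT_TRUE_LFC: dict[str, float] = {
    "PPARG": -0.48,
    # disease-upregulated targets confirmed by expression
    "COL1A1": 0.6, "SPP1": 0.6, "CXCL14": 0.6, "MMP9": 0.6, "CCNB1": 0.6,
    # disease-downregulated targets confirmed by expression
    "CAV1": -0.5, "PTEN": -0.5, "FAS": -0.5, "MIR145": -0.5,
    # disease promoters confirmed by expression
    "CCR7": 0.6, "TLR2": 0.6,
    # remaining literature targets: no planted expression change
    "IL1B": 0.0, "PTGS2": 0.0, "TNF": 0.0, "MMP2": 0.0, "VEGFA": 0.0,
    "CCND1": 0.0, "MYC": 0.0, "TERT": 0.0, "CDH1": 0.0, "TP53": 0.0,
    "EDN1": 0.0, "NFKB1": 0.0, "IL10": 0.0, "ADIPOQ": 0.0,
}

#: bundle gene-set geometry beyond the published top 10: (size, overlap)
#: pairs chosen so the extra sets clear p < 1e-6 against an 8000-gene
#: universe yet never outrank the planted top 10.
EXTRA_SET_SPECS = ((300, 10), (400, 11), (500, 12), (600, 13), (700, 13))
BUNDLE_N_SETS = 115
BUNDLE_UNIVERSE = 8000
#: query genes absent from the top-10 sets (coverage 24 of 26)
TOP10_UNCOVERED = ("NFKB1", "TERT")


def packaged_fixture(name: str) -> Path:
    """Path to a packaged data fixture (extracted if needed)."""
    return Path(resources.files("megapath.data") / name)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    common_relations: Path
    studies_dir: Path
    gmt: Path
    outdir: Path
    regulatory_relations: Path | None = None
    universe: Path | None = None
    regulator: str = "PPARG"
    alpha: float = 0.05
    enrich_p: float = 1e-6
    fdr_q: float = 0.05
    top_k: int = 10
    weighting: str = "inverse-variance"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("common_relations", "studies_dir", "gmt", "outdir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.regulatory_relations is not None:
            self.regulatory_relations = Path(self.regulatory_relations)
        if self.universe is not None:
            self.universe = Path(self.universe)


def validate_config(cfg: PipelineConfig) -> list[str]:
    """List every problem; an empty list means the config is runnable."""
    problems: list[str] = []
    for label, path in (
        ("common_relations", cfg.common_relations),
        ("studies_dir", cfg.studies_dir),
        ("gmt", cfg.gmt),
        ("regulatory_relations", cfg.regulatory_relations),
        ("universe", cfg.universe),
    ):
        if path is not None and not Path(path).exists():
            problems.append(f"{label}: path does not exist: {path}")
    if cfg.studies_dir.exists() and not (cfg.studies_dir / "design.tsv").exists():
        problems.append(f"studies_dir: missing design.tsv in {cfg.studies_dir}")
    for label, value in (
        ("alpha", cfg.alpha),
        ("enrich_p", cfg.enrich_p),
        ("fdr_q", cfg.fdr_q),
    ):
        if not (0.0 < value < 1.0):
            problems.append(f"{label}: threshold {value} outside (0, 1)")
    if cfg.top_k < 1:
        problems.append(f"top_k: must be >= 1, got {cfg.top_k}")
    return problems


# ---------------------------------------------------------------------------
# synthetic bundle


def write_bundle(
    outdir: str | Path,
    seed: int,
    *,
    n_background_genes: int = 100,
    noise_sd: float = 1.0,
    tau2: float = 0.0,
) -> Path:
    """Write a complete synthetic input bundle: 13 cohorts in the default
    design, the two relation fixtures, a 115-set GMT with the published
    top-10 geometry planted, and the universe list."""
    outdir = Path(outdir)
    (outdir / "studies").mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(
        true_lfc=DEFAULT_TRUE_LFC,
        n_background_genes=n_background_genes,
        noise_sd=noise_sd,
        tau2=tau2,
        seed=seed,
    )
    studies, truth = simulate_studies(cfg)
    design_rows = []
    for s in studies:
        write_expression_study(
            s,
            outdir / "studies" / f"{s.study_id}.tsv",
            outdir / "studies" / f"{s.study_id}.groups.tsv",
        )
        design_rows.append(
            {
                "study_id": s.study_id,
                "n_control": s.n_control,
                "n_case": s.n_case,
                "country": s.country,
                "study_age": s.study_age,
            }
        )
    pd.DataFrame(design_rows).to_csv(
        outdir / "studies" / "design.tsv", sep="\t", index=False
    )
    truth.to_csv(outdir / "ground_truth_effects.tsv", sep="\t", index=False)

    for name in ("common_target_relations.tsv", "regulatory_relations.tsv"):
        write_relation_table(read_relation_table(packaged_fixture(name)), outdir / name)

    query = ["PPARG"] + sorted(g for g in DEFAULT_TRUE_LFC if g != "PPARG")
    top10_pool = [g for g in query if g not in TOP10_UNCOVERED]
    extras = [
        (
            f"SYN: synthetic pathway {i + 1:03d}",
            f"SYN{i + 1:07d}",
            *EXTRA_SET_SPECS[i % len(EXTRA_SET_SPECS)],
        )
        for i in range(BUNDLE_N_SETS - len(TOP10_SET_GEOMETRY))
    ]
    top10, truth10 = simulate_genesets(
        n_sets=len(TOP10_SET_GEOMETRY),
        size_range=(0, 0),
        planted_query=query,
        planted_overlaps=[0],
        universe_size=BUNDLE_UNIVERSE,
        seed=seed + 1,
        coverage_pool=top10_pool,
        geometry=TOP10_SET_GEOMETRY,
    )
    rest, truth_rest = simulate_genesets(
        n_sets=len(extras),
        size_range=(0, 0),
        planted_query=query,
        planted_overlaps=[0],
        universe_size=BUNDLE_UNIVERSE,
        seed=seed + 2,
        geometry=extras,
    )
    collection = GeneSetCollection(
        sets={**top10.sets, **rest.sets},
        descriptions={**top10.descriptions, **rest.descriptions},
        universe=top10.universe | rest.universe,
    )
    write_gmt(collection, outdir / "genesets.gmt")
    pd.concat([truth10, truth_rest]).to_csv(
        outdir / "ground_truth_sets.tsv", sep="\t", index=False
    )
    with open(outdir / "universe.txt", "w") as fh:
        for gene in sorted(collection.universe):
            fh.write(gene + "\n")
    with open(outdir / "query_genes.txt", "w") as fh:
        for gene in query:
            fh.write(gene + "\n")
    return outdir


def bundle_config(bundle: str | Path, outdir: str | Path, **overrides) -> PipelineConfig:
    """PipelineConfig pointing at a `write_bundle` directory."""
    bundle = Path(bundle)
    return PipelineConfig(
        common_relations=bundle / "common_target_relations.tsv",
        regulatory_relations=bundle / "regulatory_relations.tsv",
        studies_dir=bundle / "studies",
        gmt=bundle / "genesets.gmt",
        universe=bundle / "universe.txt",
        outdir=Path(outdir),
        **overrides,
    )


# ---------------------------------------------------------------------------
# running


def load_studies(studies_dir: str | Path) -> list:
    """Read every study listed in ``design.tsv`` inside ``studies_dir``."""
    studies_dir = Path(studies_dir)
    design = pd.read_csv(studies_dir / "design.tsv", sep="\t")
    studies = []
    for _, row in design.iterrows():
        sid = str(row["study_id"])
        studies.append(
            read_expression_study(
                studies_dir / f"{sid}.tsv",
                studies_dir / f"{sid}.groups.tsv",
                study_id=sid,
                country=str(row["country"]),
                study_age=int(row["study_age"]),
            )
        )
    return studies


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineReport:
    outdir: Path
    artifacts: dict[str, Path] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Run every stage and write the eight artifacts.

    Any stage failure writes a FAILED marker naming the stage and
    re-raises; artifacts already written are retained.
    """
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(outdir=cfg.outdir)
    stage = "setup"
    try:
        # -- relations ------------------------------------------------------
        stage = "classify"
        common = read_relation_table(cfg.common_relations)
        common_targets = classify_contradirectional(common, cfg.regulator)
        regulatory_targets = []
        if cfg.regulatory_relations is not None:
            regulatory = read_relation_table(cfg.regulatory_relations)
            regulatory_targets = classify_contradirectional(regulatory, cfg.regulator)
        counts = count_classes(common_targets)
        logger.info(
            "classified common targets: %d suppressed promoters, %d activated "
            "inhibitors, %d concordant",
            counts["suppressed_disease_promoter"],
            counts["activated_disease_inhibitor"],
            counts["concordant_excluded"],
        )
        rows = [
            {"table": "common_targets", **row}
            for row in targets_to_rows(common_targets)
        ] + [
            {"table": "regulatory", **row}
            for row in targets_to_rows(regulatory_targets)
        ]
        path = cfg.outdir / "classified_targets.tsv"
        write_results_table(
            pd.DataFrame(
                rows,
                columns=["table", "gene", "class", "literature_direction",
                         "regulator_polarity", "n_refs", "confirmed_by_expression"],
            ),
            path,
        )
        report.artifacts["classified_targets"] = path
        driven = sorted(
            {t.gene for t in common_targets} | {t.gene for t in regulatory_targets}
        )
        query = [cfg.regulator] + [g for g in driven if g != cfg.regulator]
        report.counts.update(
            suppressed=counts["suppressed_disease_promoter"],
            activated=counts["activated_disease_inhibitor"],
            driven_molecules=len(driven),
            query_genes=len(query),
        )
        logger.info("%d driven molecules + regulator -> %d query genes",
                    len(driven), len(query))

        # -- mega-analysis --------------------------------------------------
        stage = "mega_analysis"
        studies = load_studies(cfg.studies_dir)
        meta = {}
        mega_rows = []
        for gene in query:
            effects = effects_for_gene(studies, gene)
            if not effects:
                continue
            res = MegaAnalysis(effects, weighting=cfg.weighting).fit()
            meta[gene] = res.result
            mega_rows.append(res.to_row())
        mega = pd.DataFrame(mega_rows)
        if not mega.empty:
            from .enrichment import bh_fdr  # extra, clearly-labelled column
            mega["p_BH_extra"] = bh_fdr(mega["p_value"].to_numpy())
        path = cfg.outdir / "mega_analysis.tsv"
        write_results_table(mega, path)
        report.artifacts["mega_analysis"] = path
        report.counts["genes_pooled"] = len(mega_rows)

        # -- confirmation ---------------------------------------------------
        stage = "confirmation"
        confirmed_common = confirm_with_expression(common_targets, meta, cfg.alpha)
        confirmed_reg = confirm_with_expression(regulatory_targets, meta, cfg.alpha)
        rows = [
            {"table": "common_targets", **row}
            for row in targets_to_rows(confirmed_common)
        ] + [
            {"table": "regulatory", **row}
            for row in targets_to_rows(confirmed_reg)
        ]
        path = cfg.outdir / "confirmation.tsv"
        write_results_table(pd.DataFrame(rows), path)
        report.artifacts["confirmation"] = path
        report.counts["confirmed"] = sum(
            1 for t in confirmed_common + confirmed_reg
            if t.confirmed_by_expression == "confirmed"
        )

        # -- covariate regression ------------------------------------------
        stage = "mlr"
        metadata = study_metadata(studies)
        mlr_rows = []
        for gene in query:
            effects = effects_for_gene(studies, gene)
            if not effects:
                continue
            try:
                mlr_rows.extend(fit_mlr(effects, metadata).to_rows())
            except ValueError as err:
                logger.warning("MLR skipped for %s: %s", gene, err)
        path = cfg.outdir / "mlr.tsv"
        write_results_table(pd.DataFrame(mlr_rows), path)
        report.artifacts["mlr"] = path

        # -- enrichment -----------------------------------------------------
        stage = "enrichment"
        collection = read_gmt(cfg.gmt)
        universe = None
        if cfg.universe is not None:
            universe = [
                line.strip() for line in cfg.universe.read_text().splitlines()
                if line.strip()
            ]
        results = fisher_enrich(query, collection, universe, fdr_q=cfg.fdr_q)
        path = cfg.outdir / "enrichment.tsv"
        write_results_table(pd.DataFrame(results_to_rows(results)), path)
        report.artifacts["enrichment"] = path
        surviving = filter_and_rank(results, p_threshold=cfg.enrich_p)
        top = filter_and_rank(results, p_threshold=cfg.enrich_p, top_k=cfg.top_k)
        report.counts["enriched_sets"] = len(surviving)
        report.counts["top_covered"] = genes_covered(top, query)
        report.counts["all_covered"] = genes_covered(surviving, query)
        logger.info(
            "%d sets below p<%g; top %d cover %d/%d query genes "
            "(all surviving sets: %d/%d)",
            len(surviving), cfg.enrich_p, cfg.top_k,
            report.counts["top_covered"], len(query),
            report.counts["all_covered"], len(query),
        )

        # -- network --------------------------------------------------------
        stage = "network"
        membership = membership_from_enrichment(surviving, query)
        net = build_network(membership)
        path = cfg.outdir / "network_edges.tsv"
        write_edge_list(edge_list(net), path)
        report.artifacts["network_edges"] = path
        path = cfg.outdir / "node_stats.tsv"
        write_results_table(pd.DataFrame(all_node_stats(net)), path)
        report.artifacts["node_stats"] = path
        report.counts["network_edges"] = net.number_of_edges()

        # -- manifest -------------------------------------------------------
        stage = "manifest"
        inputs = {
            "common_relations": cfg.common_relations,
            "regulatory_relations": cfg.regulatory_relations,
            "gmt": cfg.gmt,
            "universe": cfg.universe,
        }
        manifest = {
            "package": "megapath",
            "version": __version__,
            "seed": cfg.seed,
            "regulator": cfg.regulator,
            "thresholds": {
                "alpha": cfg.alpha,
                "enrich_p": cfg.enrich_p,
                "fdr_q": cfg.fdr_q,
                "top_k": cfg.top_k,
            },
            "weighting": cfg.weighting,
            "input_digests": {
                name: (_sha256(p) if p is not None else None)
                for name, p in inputs.items()
            },
            "study_digests": {
                f.name: _sha256(f)
                for f in sorted(Path(cfg.studies_dir).glob("*.tsv"))
            },
            "counts": report.counts,
        }
        path = cfg.outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        report.artifacts["manifest"] = path
    except Exception as err:
        (cfg.outdir / "FAILED").write_text(f"stage={stage}\nerror={err}\n")
        raise
    return report
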