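"""End-to-end orchestration: module discovery -> metabolic subtyping ->
signature scoring -> immune phenotype and EGFR strata -> survival contrasts
-> optional ORA and meta-analysis, with every result table written to disk
and a JSON run report recording seed, parameters, and group sizes.

Result tables are deterministic under a fixed config and seed; logging goes
to stderr and never interleaves with results.
"""
from __future__ import annotations

import json
import logging
import platform
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__, datasets
from .consensus import ConsensusParams, ConsensusResult, consensus_cluster, spearman_distance
from .io import (
    ExpressionMatrix,
    GeneSet,
    read_clinical_table,
    read_expression_tsv,
    read_gmt,
    read_meta_table,
    write_gmt,
)
from .meta import egger_test, funnel_coordinates, leave_one_out, pool_effects
from .scoring import OraParams, ScoreParams, estimate_scores, ora_enrichment, score_collection, ssgsea_score, weighted_signature_score
from .stratify import (
    assign_immune_phenotype,
    assign_subtypes,
    median_center_genes,
    pathway_median_score,
    stratify_samples,
    zscore_genes,
)
from .survival import kaplan_meier, logrank_test

logger = logging.getLogger("metimm")

__all__ = ["AnalysisConfig", "run_pipeline", "select_pathway_modules"]


@dataclass
class AnalysisConfig:
    """Paths and parameters for one pipeline run.

    When ``metabolic_gmt`` is omitted the packaged glycolysis/cholesterol
    candidate stand-ins are used; ORA and meta-analysis stages run only when
    their inputs are supplied.
    """

    expression: str | Path
    clinical: str | Path
    outdir: str | Path
    metabolic_gmt: str | Path | None = None
    meta_table: str | Path | None = None
    ora_background_gmt: str | Path | None = None
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    score: ScoreParams = field(default_factory=ScoreParams)
    centering: str = "zscore"  # {zscore, median-center, none}
    min_module_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.centering not in ("zscore", "median-center", "none"):
            raise ValueError(f"unknown centering {self.centering!r}")


class StageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def select_pathway_modules(
    result: ConsensusResult,
    expr: ExpressionMatrix,
    origins: Mapping[str, str],
    min_size: int = 5,
) -> dict[str, GeneSet]:
    """One co-expressed module per pathway from a consensus solution.

    Each cluster of size >= min_size is labelled by the majority pathway
    origin of its members and scored by mean pairwise Spearman correlation;
    the best-scoring cluster per pathway wins (ties to the smaller label).
    """
    best: dict[str, tuple[float, int, list[str]]] = {}
    for label in sorted(result.assignments.unique()):
        genes = list(result.assignments.index[result.assignments == label])
        if len(genes) < min_size:
            continue
        tags = [origins.get(g, "?") for g in genes]
        majority = max(sorted(set(tags)), key=tags.count)
        corr = 1.0 - spearman_distance(expr, genes).to_numpy()
        score = float(corr[~np.eye(len(genes), dtype=bool)].mean())
        current = best.get(majority)
        if current is None or (score, -label) > (current[0], -current[1]):
            best[majority] = (score, int(label), genes)
    return {
        pathway: GeneSet(f"{pathway}_module", tuple(genes))
        for pathway, (_, _, genes) in best.items()
    }


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the full stratification analysis; returns the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package": "metimm",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": {
            "consensus": vars(config.consensus) | {},
            "score": {"alpha": config.score.alpha, "normalize": config.score.normalize},
            "centering": config.centering,
            "min_module_size": config.min_module_size,
        },
        "stages": [],
    }

    def stage(name: str):
        logger.info("stage %s", name)
        report["stages"].append(name)
        return time.perf_counter()

    def done(name: str, t0: float) -> None:
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

    # ---- load -------------------------------------------------------------
    t0 = stage("load")
    try:
        expr = read_expression_tsv(config.expression)
        clinical = read_clinical_table(config.clinical)
        if config.metabolic_gmt is not None:
            candidates = read_gmt(config.metabolic_gmt)
        else:
            candidates = datasets.load_metabolic_candidates()
        gep = datasets.load_tcell_inflamed_signature()
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", exc) from exc
    missing_clinical = set(expr.sample_ids) - set(clinical.index)
    if missing_clinical:
        raise StageError(
            "load",
            ValueError(f"samples without clinical rows: {sorted(missing_clinical)[:5]}"),
        )
    done("load", t0)

    # ---- centering --------------------------------------------------------
    t0 = stage("centering")
    try:
        if config.centering == "zscore":
            centered = zscore_genes(expr)
        elif config.centering == "median-center":
            centered = median_center_genes(expr)
        else:
            centered = expr
    except Exception as exc:  # noqa: BLE001
        raise StageError("centering", exc) from exc
    done("centering", t0)

    # ---- module discovery -------------------------------------------------
    t0 = stage("modules")
    try:
        origins: dict[str, str] = {}
        for name, gs in candidates.items():
            tag = "glycolytic" if "GLYCOL" in name.upper() else "cholesterol"
            for g in gs.genes:
                origins.setdefault(g, tag)
        candidate_genes = [g for g in origins if g in set(expr.gene_ids)]
        absent = len(origins) - len(candidate_genes)
        if absent:
            warnings.warn(f"{absent} candidate metabolic genes absent from matrix")
        result = consensus_cluster(expr, candidate_genes, config.consensus)
        modules = select_pathway_modules(
            result, expr, origins, config.min_module_size
        )
        if "glycolytic" not in modules or "cholesterol" not in modules:
            raise ValueError(
                f"could not recover both pathway modules; found {sorted(modules)}"
            )
        gly_module, chol_module = modules["glycolytic"], modules["cholesterol"]
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("modules", exc) from exc
    _write_tsv(
        pd.DataFrame(result.consensus, index=result.item_ids, columns=result.item_ids),
        outdir / "consensus_matrix.tsv",
    )
    _write_tsv(result.assignments.to_frame(), outdir / "module_assignments.tsv")
    write_gmt(
        {m.name: m for m in (gly_module, chol_module)}, outdir / "modules.gmt"
    )
    report["modules"] = {
        "n_candidate_genes": len(candidate_genes),
        "glycolytic_module_size": len(gly_module),
        "cholesterol_module_size": len(chol_module),
    }
    done("modules", t0)

    # ---- subtyping --------------------------------------------------------
    t0 = stage("subtyping")
    try:
        gly_median = pathway_median_score(centered, gly_module)
        chol_median = pathway_median_score(centered, chol_module)
        subtype = assign_subtypes(gly_median, chol_median)
    except Exception as exc:  # noqa: BLE001
        raise StageError("subtyping", exc) from exc
    done("subtyping", t0)

    # ---- signature scoring ------------------------------------------------
    t0 = stage("scoring")
    try:
        gep_score = weighted_signature_score(expr, gep)
        chol_score = ssgsea_score(expr, chol_module, config.score)
        chol_score.name = "cholesterol_score"
        stromal_sig, immune_sig = datasets.load_estimate_signatures()
        estimate = estimate_scores(expr, stromal_sig, immune_sig)
        panel = score_collection(expr, datasets.load_immune_signatures(), config.score)
        driver, suppressor = datasets.load_ferroptosis_signatures()
        ferro = pd.DataFrame(
            {
                "ferroptosis_driver": ssgsea_score(expr, driver, config.score),
                "ferroptosis_suppressor": ssgsea_score(expr, suppressor, config.score),
            }
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("scoring", exc) from exc
    _write_tsv(estimate, outdir / "estimate_scores.tsv")
    _write_tsv(panel, outdir / "immune_panel_scores.tsv")
    _write_tsv(ferro, outdir / "ferroptosis_scores.tsv")
    done("scoring", t0)

    # ---- strata -----------------------------------------------------------
    t0 = stage("strata")
    try:
        wt_samples = [
            s for s in expr.sample_ids if clinical.loc[s, "egfr_status"] == "wild-type"
        ]
        if len(wt_samples) >= 2:
            phenotype = assign_immune_phenotype(gep_score[wt_samples])
        else:
            phenotype = pd.Series(dtype=object, name="immune_phenotype")
        strata = stratify_samples(clinical.loc[list(expr.sample_ids)], phenotype)
    except Exception as exc:  # noqa: BLE001
        raise StageError("strata", exc) from exc
    calls = pd.DataFrame(
        {
            "gly_median": gly_median,
            "chol_median": chol_median,
            "metabolic_subtype": subtype,
            "tcell_inflamed_score": gep_score,
            "cholesterol_score": chol_score,
            "immune_phenotype": phenotype.reindex(expr.sample_ids),
            "stratum": strata.reindex(expr.sample_ids),
        }
    )
    calls.index.name = "sample_id"
    _write_tsv(calls, outdir / "sample_calls.tsv")
    report["group_sizes"] = {
        "n_samples": expr.n_samples,
        "subtype": subtype.value_counts().to_dict(),
        "phenotype": phenotype.value_counts().to_dict(),
        "stratum": strata.value_counts().to_dict(),
    }
    done("strata", t0)

    # ---- survival ---------------------------------------------------------
    t0 = stage("survival")
    try:
        surv_rows = []
        km_frames = []
        contrasts = {
            "stratum": strata.reindex(expr.sample_ids),
            "metabolic_subtype": subtype,
        }
        hot_cold = calls["immune_phenotype"].dropna()
        for phen in ("hot", "cold"):
            members = hot_cold.index[hot_cold == phen]
            if len(members):
                contrasts[f"subtype_within_{phen}"] = subtype[members]
        for contrast, labels in contrasts.items():
            labels = labels.dropna()
            samples = list(labels.index)
            times = clinical.loc[samples, "os_time"].to_numpy()
            events = clinical.loc[samples, "os_event"].to_numpy()
            groups = labels.to_numpy()
            for group in sorted(pd.unique(groups)):
                mask = groups == group
                curve = kaplan_meier(times[mask], events[mask])
                km_frames.append(
                    pd.DataFrame(
                        {
                            "contrast": contrast,
                            "group": group,
                            "time": curve.times,
                            "survival": curve.survival,
                            "at_risk": curve.at_risk,
                            "n_events": curve.n_events,
                        }
                    )
                )
            if len(pd.unique(groups)) >= 2:
                res = logrank_test(times, events, groups)
                surv_rows.append(
                    {
                        "contrast": contrast,
                        "groups": len(pd.unique(groups)),
                        "chi2": res.chi2,
                        "df": res.df,
                        "p": res.p,
                    }
                )
    except Exception as exc:  # noqa: BLE001
        raise StageError("survival", exc) from exc
    km_table = (
        pd.concat(km_frames, ignore_index=True)
        if km_frames
        else pd.DataFrame(columns=["contrast", "group", "time", "survival", "at_risk", "n_events"])
    )
    _write_tsv(km_table.set_index("contrast"), outdir / "km_curves.tsv")
    _write_tsv(
        pd.DataFrame(surv_rows).set_index("contrast")
        if surv_rows
        else pd.DataFrame(columns=["contrast"]).set_index("contrast"),
        outdir / "logrank_tests.tsv",
    )
    report["survival_contrasts"] = [r["contrast"] for r in surv_rows]
    done("survival", t0)

    # ---- optional ORA -----------------------------------------------------
    if config.ora_background_gmt is not None:
        t0 = stage("ora")
        try:
            background = read_gmt(config.ora_background_gmt)
            universe_genes = tuple(sorted({g for gs in background.values() for g in gs.genes}))
            _, suppressor = datasets.load_ferroptosis_signatures()
            params = OraParams(universe=GeneSet("universe", universe_genes))
            ora = ora_enrichment(suppressor, background, params)
        except Exception as exc:  # noqa: BLE001
            raise StageError("ora", exc) from exc
        _write_tsv(ora.set_index("term"), outdir / "ora_results.tsv")
        report["ora_terms_tested"] = int(len(ora))
        done("ora", t0)

    # ---- optional meta ----------------------------------------------------
    if config.meta_table is not None:
        t0 = stage("meta")
        try:
            studies = read_meta_table(config.meta_table)
            pooled = {
                method: pool_effects(studies, method=method)
                for method in ("fixed", "random-DL")
            }
            loo = leave_one_out(studies)
            egger = egger_test(studies) if len(studies) >= 3 else None
        except Exception as exc:  # noqa: BLE001
            raise StageError("meta", exc) from exc
        _write_tsv(loo, outdir / "meta_leave_one_out.tsv")
        _write_tsv(funnel_coordinates(studies), outdir / "funnel_coordinates.tsv")
        meta_report = {}
        for method, res in pooled.items():
            lo, hi = res.ci95
            meta_report[method] = {
                "k": res.k,
                "pooled_hr": res.hr,
                "ci95": [lo, hi],
                "q": res.q,
                "i2": res.i2,
                "tau2": res.tau2,
                "p": res.p,
            }
        if egger is not None:
            meta_report["egger"] = {
                "intercept": egger.intercept,
                "se": egger.intercept_se,
                "t": egger.t,
                "p": egger.p,
            }
        meta_report["total_enrollment"] = int(sum(s.n for s in studies))
        report["meta"] = meta_report
        with open(outdir / "meta_results.json", "w") as handle:
            json.dump(meta_report, handle, indent=2, sort_keys=True)
        done("meta", t0)

    report["complete"] = True
    with open(outdir / "run_report.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
    return report
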