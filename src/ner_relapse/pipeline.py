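"""End-to-end analysis: four subgroup comparisons, scores, skew, survival.

The canonical run takes a (probe- or gene-level) expression matrix plus a
paired diagnosis/relapse annotation, and emits, per dataset and for the
reference-normalized combination of datasets:

* the four directional pathway comparisons — early diagnosis-vs-relapse
  (paired), late diagnosis-vs-relapse (paired), early-vs-late at diagnosis
  (unpaired), early-vs-late at relapse (unpaired) — each as a per-gene TSV
  plus a pathway chi-square summary, with Fisher's exact test comparing the
  up-gene proportions between the two datasets;
* the per-sample NER score table and its group summary;
* the per-patient score-trajectory skew test per relapse class;
* high/low score-stratified survival records, KM medians and the log-rank
  test with O/E hazard ratio.

Everything is written as TSV/JSON with deterministic ordering; a manifest
records the configuration hash and package version so identical runs yield
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .expression import (
    DataError,
    GeneExpressionMatrix,
    NERPanel,
    extract_panel,
    collapse_probes,
    normalize_to_reference,
    read_annotation,
    read_expression_table,
    read_probe_map,
)
from .score import (
    DEFAULT_RELAPSE_CUTOFF_MONTHS,
    classify_relapse,
    compute_ner_scores,
    summarize_scores,
    write_score_table,
)
from .simulate import SyntheticConfig, write_cohort
from .stats import (
    ComparisonSpec,
    DirectionSummary,
    fisher_between_datasets,
    gene_directions,
    score_skew_test,
)
from .survival import km_curve, logrank_compare, plot_km, stratify_by_score

__all__ = [
    "AnalysisConfig",
    "PipelineError",
    "COMPARISON_NAMES",
    "annotate_relapse_class",
    "standard_comparisons",
    "run_full_analysis",
    "simulate",
]

log = logging.getLogger(__name__)

COMPARISON_NAMES = (
    "early_diagnosis_vs_relapse",
    "late_diagnosis_vs_relapse",
    "early_vs_late_at_diagnosis",
    "early_vs_late_at_relapse",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run (see ``docs`` for the schema)."""

    expression_path: str
    annotation_path: str
    out_dir: str
    probe_map_path: str | None = None
    expression_dialect: str = "tsv"  # or "geo_series_matrix"
    expression_level: str = "probe"  # level of the input matrix
    panel: Sequence[str] | None = None  # None -> canonical 20 NER genes
    relapse_cutoff_months: float = DEFAULT_RELAPSE_CUTOFF_MONTHS
    stratification_rule: str = "above_mean"  # or "above_value"
    stratification_value: float | None = None
    welch: bool = False
    table_two_sided: bool = True
    log2_transform: bool = False  # exploratory only; linear scale is the default
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relapse_cutoff_months <= 0:
            raise DataError("relapse_cutoff_months must be > 0")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def annotate_relapse_class(ann: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Return the annotation with a relapse_class column added."""
    classes = classify_relapse(ann, cutoff=cutoff)
    ann = ann.copy()
    ann["relapse_class"] = classes.loc[ann["patient_id"]].to_numpy()
    return ann


def _select(phase: str | None, relapse_class: str | None):
    def predicate(ann: pd.DataFrame) -> pd.Series:
        mask = pd.Series(True, index=ann.index)
        if phase is not None:
            mask &= ann["phase"] == phase
        if relapse_class is not None:
            mask &= ann["relapse_class"] == relapse_class
        return mask

    return predicate


def standard_comparisons() -> dict[str, tuple[ComparisonSpec, object]]:
    """The four subgroup comparisons with their combined-run references.

    Each value is ``(spec, reference_predicate)``: group a is always the
    hypothesized-higher group (relapse over diagnosis; early over late),
    and the reference predicate picks, within each dataset, the samples
    whose per-gene mean anchors cross-dataset normalization — the diagnosis
    samples of the compared class for the paired analyses, the late
    relapsers of the compared phase for the unpaired ones.
    """
    out: dict[str, tuple[ComparisonSpec, object]] = {}
    for cls in ("early", "late"):
        out[f"{cls}_diagnosis_vs_relapse"] = (
            ComparisonSpec(
                kind="paired_diagnosis_vs_relapse",
                group_a=_select("relapse", cls),
                group_b=_select("diagnosis", cls),
                label=f"{cls}_diagnosis_vs_relapse",
            ),
            _select("diagnosis", cls),
        )
    for phase in ("diagnosis", "relapse"):
        out[f"early_vs_late_at_{phase}"] = (
            ComparisonSpec(
                kind="unpaired_group_vs_group",
                group_a=_select(phase, "early"),
                group_b=_select(phase, "late"),
                label=f"early_vs_late_at_{phase}",
            ),
            _select(phase, "late"),
        )
    return out


def _check_class_counts(ann: pd.DataFrame) -> None:
    counts = ann.drop_duplicates("patient_id")["relapse_class"].value_counts()
    for cls in ("early", "late"):
        if counts.get(cls, 0) < 2:
            raise DataError(
                f"subgroup comparisons need >= 2 patients per relapse class; "
                f"got {int(counts.get(cls, 0))} {cls} relapser(s)"
            )


def _direction_scope(
    panel_matrix: GeneExpressionMatrix,
    ann: pd.DataFrame,
    welch: bool,
    combined: bool,
) -> dict[str, DirectionSummary]:
    """Run the four comparisons on one scope (a dataset, or the combination).

    For the combined scope the matrix is first reference-normalized per
    dataset with each comparison's own reference group.
    """
    results: dict[str, DirectionSummary] = {}
    for name, (spec, reference) in standard_comparisons().items():
        m = (
            normalize_to_reference(panel_matrix, ann, reference)
            if combined
            else panel_matrix
        )
        results[name] = gene_directions(m, ann, spec, welch=welch)
    return results


def _paired_score_list(scores: pd.DataFrame) -> list[tuple[float, float]]:
    wide = scores.pivot(index="patient_id", columns="phase", values="score")
    wide = wide.dropna()
    return list(zip(wide["diagnosis"], wide["relapse"]))


def _survival_scope(
    scores: pd.DataFrame,
    rule: str,
    value: float | None,
) -> tuple[pd.DataFrame, dict]:
    """Stratify on diagnosis scores and compare the strata's survival."""
    diag = scores[scores["phase"] == "diagnosis"]
    strata = stratify_by_score(diag, rule=rule, value=value)
    records = diag[["patient_id", "time_to_relapse_months"]].rename(
        columns={"time_to_relapse_months": "time"}
    )
    records = records.assign(
        event=True, stratum=strata.loc[records["patient_id"]].to_numpy()
    )
    records = records.sort_values(["stratum", "time", "patient_id"], kind="mergesort")
    high = records[records["stratum"] == "high"]
    low = records[records["stratum"] == "low"]
    if high.empty or low.empty:
        raise DataError("stratification produced an empty stratum")
    result = logrank_compare(high["time"], low["time"])
    summary = {
        "n_high": int(len(high)),
        "n_low": int(len(low)),
        "median_high": km_curve(high["time"]).median,
        "median_low": km_curve(low["time"]).median,
        "logrank": result.to_json_dict(),
    }
    return records, summary


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_full_analysis(cfg: AnalysisConfig) -> dict:
    """Run every stage and write the report bundle under ``cfg.out_dir``.

    Returns the in-memory summary (directions, score summary, skew,
    survival) keyed by scope. Any stage failure removes files already
    written for this run and raises :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit_json(obj, rel: str) -> None:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        _write_json(obj, path)
        written.append(path)

    def emit_tsv(frame: pd.DataFrame, rel: str) -> None:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)

    stage = "load_inputs"
    try:
        matrix = read_expression_table(
            cfg.expression_path,
            dialect=cfg.expression_dialect,
            level=cfg.expression_level,
        )
        ann = read_annotation(cfg.annotation_path)
        ann = ann[ann["sample_id"].isin(matrix.data.columns)].reset_index(drop=True)
        if ann.empty:
            raise DataError("annotation matches no matrix samples")

        stage = "collapse_probes"
        if cfg.probe_map_path is not None:
            probe_map = read_probe_map(cfg.probe_map_path)
            gene_matrix = collapse_probes(matrix, probe_map)
        elif matrix.level == "gene" or cfg.expression_level == "gene":
            gene_matrix = GeneExpressionMatrix(matrix.data, "gene", matrix.dataset_label)
        else:
            raise DataError("probe-level input requires a probe map")
        if cfg.log2_transform:
            import numpy as np

            gene_matrix = GeneExpressionMatrix(
                np.log2(gene_matrix.data + 1.0), "gene", gene_matrix.dataset_label
            )

        stage = "extract_panel"
        panel = NERPanel(tuple(cfg.panel)) if cfg.panel is not None else NERPanel()
        panel_matrix = extract_panel(gene_matrix, panel)

        stage = "classify_relapse"
        ann = annotate_relapse_class(ann, cfg.relapse_cutoff_months)
        _check_class_counts(ann)
        datasets = sorted(ann["dataset_label"].unique())

        stage = "pathway_directions"
        directions: dict[str, dict[str, DirectionSummary]] = {}
        for ds in datasets:
            sub = ann[ann["dataset_label"] == ds].reset_index(drop=True)
            directions[ds] = _direction_scope(
                panel_matrix.subset_samples(sub["sample_id"].tolist()),
                sub,
                cfg.welch,
                combined=False,
            )
        if len(datasets) > 1:
            directions["combined"] = _direction_scope(
                panel_matrix, ann, cfg.welch, combined=True
            )
        dir_summary: dict = {}
        for scope, comps in directions.items():
            dir_summary[scope] = {k: v.to_json_dict() for k, v in comps.items()}
            for name, summary in comps.items():
                emit_tsv(summary.per_gene, f"directions/{scope}__{name}.tsv")
        if len(datasets) == 2:
            a, b = datasets
            dir_summary["fisher_between_datasets"] = {
                name: fisher_between_datasets(
                    directions[a][name].n_up,
                    directions[a][name].n_up + directions[a][name].n_down,
                    directions[b][name].n_up,
                    directions[b][name].n_up + directions[b][name].n_down,
                )
                for name in COMPARISON_NAMES
            }
        emit_json(dir_summary, "directions/summary.json")

        stage = "ner_scores"
        scores = compute_ner_scores(panel_matrix, ann, cutoff=cfg.relapse_cutoff_months)
        path = out / "scores/scores.tsv"
        path.parent.mkdir(parents=True, exist_ok=True)
        write_score_table(scores, path)
        written.append(path)
        emit_json(
            summarize_scores(scores, two_sided=cfg.table_two_sided),
            "scores/summary.json",
        )

        stage = "score_skew"
        skew: dict = {}
        scopes = {ds: scores[scores["dataset_label"] == ds] for ds in datasets}
        if len(datasets) > 1:
            scopes["combined"] = scores
        for scope, tab in scopes.items():
            entry: dict = {}
            for cls in ("early", "late"):
                pairs = _paired_score_list(tab[tab["relapse_class"] == cls])
                if pairs:
                    res = score_skew_test(pairs)
                    entry[cls] = {
                        "n_increase": res.n_increase,
                        "n_decrease": res.n_decrease,
                        "chi2": res.chi2_statistic,
                        "p": res.p,
                    }
            if {"early", "late"} <= set(entry):
                entry["fisher_early_vs_late"] = fisher_between_datasets(
                    entry["early"]["n_increase"],
                    entry["early"]["n_increase"] + entry["early"]["n_decrease"],
                    entry["late"]["n_increase"],
                    entry["late"]["n_increase"] + entry["late"]["n_decrease"],
                )
            skew[scope] = entry
        emit_json(skew, "scores/skew.json")

        stage = "survival"
        survival: dict = {}
        for scope, tab in scopes.items():
            records, summary = _survival_scope(
                tab, cfg.stratification_rule, cfg.stratification_value
            )
            survival[scope] = summary
            emit_tsv(records, f"survival/records__{scope}.tsv")
            if cfg.make_plots:
                plot_path = out / f"survival/km__{scope}.svg"
                plot_km(
                    {
                        s: (grp["time"].tolist(), None)
                        for s, grp in records.groupby("stratum")
                    },
                    plot_path,
                    title=f"Disease-free survival by NER score ({scope})",
                )
                written.append(plot_path)
        emit_json(survival, "survival/summary.json")

        stage = "manifest"
        n_pairs = int(ann["patient_id"].nunique())
        emit_json(
            {
                "config": dataclasses.asdict(cfg),
                "config_hash": cfg.config_hash(),
                "package_version": __version__,
                "n_datasets": len(datasets),
                "n_samples": int(len(ann)),
                "n_patients": n_pairs,
                "n_panel_genes": int(panel_matrix.shape[0]),
            },
            "manifest.json",
        )
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    log.info("analysis complete: %d files under %s", len(written), out)
    return {
        "directions": dir_summary,
        "scores": summarize_scores(scores, two_sided=cfg.table_two_sided),
        "skew": skew,
        "survival": survival,
    }


def simulate(cfg: SyntheticConfig, out_dir: str | Path):
    """Write a synthetic cohort fixture directory (thin wrapper)."""
    return write_cohort(cfg, out_dir)
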