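"""The per-sample NER score and its group summaries.

The NER score collapses the 20-gene panel to one number per sample: each
gene is expressed relative to the mean of that gene over all relapse-phase
samples of the same dataset, and the 20 relative values are averaged. By
construction the mean score over a dataset's relapse samples is exactly 1,
so a diagnosis sample's score reads directly as "fraction of the cohort's
relapse-level pathway expression". Patients are classified as early
(< 36 months to relapse) or late (>= 36 months) relapsers; the score's
group means and their standard errors reproduce the cohort summary table.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .expression import DataError, GeneExpressionMatrix
from .stats import (
    ZeroVarianceError,
    t_test_one_tailed,
    two_sided_from_one_tailed,
)

__all__ = [
    "DEFAULT_RELAPSE_CUTOFF_MONTHS",
    "classify_relapse",
    "compute_ner_scores",
    "summarize_scores",
    "write_score_table",
]

log = logging.getLogger(__name__)

DEFAULT_RELAPSE_CUTOFF_MONTHS = 36.0


def classify_relapse(
    ann: pd.DataFrame, cutoff: float = DEFAULT_RELAPSE_CUTOFF_MONTHS
) -> pd.Series:
    """Map each patient to "early" (< cutoff months) or "late" (>= cutoff).

    The boundary value (exactly ``cutoff``) is late. Returns a Series
    indexed by patient_id.
    """
    if "time_to_relapse_months" not in ann.columns:
        raise DataError("annotation lacks time_to_relapse_months")
    if ann["time_to_relapse_months"].isna().any():
        raise DataError("missing time_to_relapse_months for some patients")
    times = ann.groupby("patient_id")["time_to_relapse_months"].first()
    if (times <= 0).any():
        raise DataError("time_to_relapse_months must be > 0")
    return pd.Series(
        np.where(times < cutoff, "early", "late"), index=times.index, name="relapse_class"
    )


def compute_ner_scores(
    m: GeneExpressionMatrix,
    ann: pd.DataFrame,
    cutoff: float = DEFAULT_RELAPSE_CUTOFF_MONTHS,
) -> pd.DataFrame:
    """Per-sample NER scores, normalized within each dataset to its relapse mean.

    For each dataset: let r_g be the mean of gene g over that dataset's
    relapse-phase samples; a sample's score is mean_g( value_gs / r_g ).
    The mean score over the dataset's relapse samples is 1 by construction
    (exactly, up to float roundoff), and every score is positive for
    positive inputs. Scores are invariant to rescaling the whole matrix.

    Returns a tidy frame: sample_id, patient_id, dataset_label, phase,
    relapse_class, time_to_relapse_months, score.
    """
    ann = ann[ann["sample_id"].isin(m.data.columns)].reset_index(drop=True)
    if ann.empty:
        raise DataError("no annotated samples present in the matrix")
    classes = classify_relapse(ann, cutoff=cutoff)
    out = []
    for dataset, grp in ann.groupby("dataset_label"):
        relapse_samples = grp.loc[grp["phase"] == "relapse", "sample_id"].tolist()
        if not relapse_samples:
            raise DataError(f"dataset {dataset!r} has no relapse-phase samples")
        r = m.data[relapse_samples].mean(axis=1)
        zero = r[r == 0]
        if len(zero):
            raise DataError(
                f"relapse-phase mean is 0 for gene {zero.index[0]!r} "
                f"in dataset {dataset!r}"
            )
        cols = grp["sample_id"].tolist()
        scores = m.data[cols].div(r, axis=0).mean(axis=0)
        sub = grp.copy()
        sub["score"] = scores.loc[sub["sample_id"]].to_numpy()
        sub["relapse_class"] = classes.loc[sub["patient_id"]].to_numpy()
        out.append(sub)
    table = pd.concat(out, ignore_index=True)
    return table[
        [
            "sample_id",
            "patient_id",
            "dataset_label",
            "phase",
            "relapse_class",
            "time_to_relapse_months",
            "score",
        ]
    ]


def _group_stats(scores: pd.Series) -> dict:
    n = int(scores.size)
    mean = float(scores.mean()) if n else float("nan")
    sem = float(scores.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return {"mean": mean, "sem": sem, "n": n}


def _safe_p(a: np.ndarray, b: np.ndarray, paired: bool, two_sided: bool) -> float:
    try:
        _, p = t_test_one_tailed(a, b, paired=paired)
    except ZeroVarianceError:
        log.warning("summarize_scores: zero variance, p recorded as 1")
        return 1.0
    return two_sided_from_one_tailed(p) if two_sided else p


def summarize_scores(
    table: pd.DataFrame,
    two_sided: bool = True,
    include_combined: bool = True,
) -> dict:
    """Group-mean summary of NER scores (the cohort summary table).

    For each dataset (and the pooled "combined" entry): per relapse class,
    the diagnosis and relapse group means +/- SEM with a paired t-test
    between phases; per phase, the late and early group means with an
    unpaired t-test between classes. The t-tests default to two-sided
    (``two_sided=False`` reverts to the one-tailed "first group greater"
    form used for the per-gene analyses). A size-1 group reports SEM as NaN.
    """
    datasets = {str(d): g for d, g in table.groupby("dataset_label")}
    if include_combined and len(datasets) > 1:
        datasets["combined"] = table
    result: dict = {}
    for name, sub in datasets.items():
        entry: dict = {}
        # diagnosis vs relapse within each relapse class (paired by patient)
        for cls in ("early", "late"):
            cls_tab = sub[sub["relapse_class"] == cls]
            if cls_tab.empty:
                continue
            wide = cls_tab.pivot(index="patient_id", columns="phase", values="score")
            if not {"diagnosis", "relapse"} <= set(wide.columns):
                continue
            wide = wide.dropna()
            block = {
                "diagnosis": _group_stats(wide["diagnosis"]),
                "relapse": _group_stats(wide["relapse"]),
            }
            if len(wide) >= 2:
                block["p"] = _safe_p(
                    wide["relapse"].to_numpy(),
                    wide["diagnosis"].to_numpy(),
                    paired=True,
                    two_sided=two_sided,
                )
            entry[cls] = block
        # early vs late within each phase (unpaired)
        for phase in ("diagnosis", "relapse"):
            ph = sub[sub["phase"] == phase]
            early = ph.loc[ph["relapse_class"] == "early", "score"]
            late = ph.loc[ph["relapse_class"] == "late", "score"]
            if early.empty or late.empty:
                continue
            block = {"late": _group_stats(late), "early": _group_stats(early)}
            if len(early) >= 2 and len(late) >= 2:
                block["p"] = _safe_p(
                    early.to_numpy(), late.to_numpy(), paired=False, two_sided=two_sided
                )
            entry[phase] = block
        result[name] = entry
    return result


def write_score_table(table: pd.DataFrame, path) -> None:
    """TSV writer with deterministic row order (dataset, patient, phase)."""
    ordered = table.sort_values(
        ["dataset_label", "patient_id", "phase"], kind="mergesort"
    ).reset_index(drop=True)
    ordered.to_csv(path, sep="\t", index=False)
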