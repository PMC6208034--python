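"""Directional pathway- and gene-level inference.

The pathway-level question is deliberately coarse: of the 20 panel genes,
how many moved up versus down between two sample groups? Under a no-change
null each gene is equally likely to land on either side, so the expected
split is 10/10 and the observed split is tested with a 1-df chi-square
goodness-of-fit statistic (no continuity correction). Per-gene inference is
a one-tailed Student's t-test (paired for diagnosis-vs-relapse within
patients, pooled-variance unpaired for early-vs-late subgroups). Up/down
proportions from two different cohorts are compared with Fisher's exact
test, and the per-patient score trajectory (did the NER score rise or fall
from diagnosis to relapse?) reuses the same chi-square against a 50/50 null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .expression import DataError, GeneExpressionMatrix

__all__ = [
    "ZeroVarianceError",
    "ComparisonSpec",
    "DirectionSummary",
    "SkewResult",
    "pathway_chisquare",
    "fisher_between_datasets",
    "t_test_one_tailed",
    "two_sided_from_one_tailed",
    "gene_directions",
    "score_skew_test",
]

log = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """The t statistic is undefined (zero variance in the relevant spread)."""


def pathway_chisquare(n_up: int, n_total: int) -> tuple[float, float]:
    """Chi-square goodness of fit of an up/down gene split vs an even null.

    With expected counts ``n_total/2`` up and ``n_total/2`` down,

        chi2 = (n_up - n/2)^2/(n/2) + (n_down - n/2)^2/(n/2) = (2*n_up - n)^2 / n

    and p is the upper tail of chi-square with 1 df. No Yates correction.

    >>> pathway_chisquare(15, 20)  # doctest: +ELLIPSIS
    (5.0, 0.0253...)
    """
    if not (isinstance(n_up, (int, np.integer)) and isinstance(n_total, (int, np.integer))):
        raise DataError("pathway_chisquare takes integer counts")
    if n_total < 1 or not 0 <= n_up <= n_total:
        raise DataError(f"need 0 <= n_up <= n_total >= 1, got ({n_up}, {n_total})")
    chi2 = (2.0 * n_up - n_total) ** 2 / n_total
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def fisher_between_datasets(n_up_a: int, n_a: int, n_up_b: int, n_b: int) -> float:
    """Two-sided Fisher's exact p for up-gene proportions in two cohorts."""
    for k, n in ((n_up_a, n_a), (n_up_b, n_b)):
        if n < 0 or not 0 <= k <= n:
            raise DataError(f"invalid 2x2 counts: ({n_up_a},{n_a},{n_up_b},{n_b})")
    table = [[n_up_a, n_a - n_up_a], [n_up_b, n_b - n_up_b]]
    return float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])


def t_test_one_tailed(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool,
    welch: bool = False,
) -> tuple[float, float]:
    """One-tailed Student's t-test of "mean of ``a`` exceeds mean of ``b``".

    Paired: t from the mean and SD of the within-pair differences,
    df = n - 1. Unpaired: pooled-variance Student's t with
    df = n_a + n_b - 2 (``welch=True`` switches to Welch's unequal-variance
    form). Returns ``(t, p)`` with ``p = P(T >= t)``.

    Raises
    ------
    ZeroVarianceError
        If the difference (paired) or both groups (unpaired) have zero
        variance, leaving t undefined. Callers typically map this to p = 1
        with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise DataError("paired test requires equal-length vectors")
        if a.size < 2:
            raise DataError("paired test requires >= 2 pairs")
        diffs = a - b
        if np.ptp(diffs) == 0:
            raise ZeroVarianceError("zero variance of paired differences")
        res = scipy.stats.ttest_rel(a, b, alternative="greater")
    else:
        if a.size < 2 or b.size < 2:
            raise DataError("unpaired test requires >= 2 values per group")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise ZeroVarianceError("zero variance in both groups")
        res = scipy.stats.ttest_ind(a, b, equal_var=not welch, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def two_sided_from_one_tailed(p_one_tailed: float) -> float:
    """Convert a one-tailed t-test p to its two-sided counterpart."""
    return 2.0 * min(p_one_tailed, 1.0 - p_one_tailed)


@dataclass(frozen=True)
class ComparisonSpec:
    """A two-group comparison over annotated samples.

    ``group_a`` / ``group_b`` are boolean-mask callables over the annotation
    table; the one-tailed alternative is always "group a mean exceeds
    group b mean", so callers order the groups to express the hypothesis
    (relapse > diagnosis; early > late). ``kind`` selects the paired
    (matched by patient_id) or unpaired test.
    """

    kind: str  # "paired_diagnosis_vs_relapse" | "unpaired_group_vs_group"
    group_a: Callable[[pd.DataFrame], pd.Series]
    group_b: Callable[[pd.DataFrame], pd.Series]
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("paired_diagnosis_vs_relapse", "unpaired_group_vs_group"):
            raise DataError(f"unknown comparison kind {self.kind!r}")


@dataclass
class DirectionSummary:
    """Per-gene direction calls plus the pathway-level chi-square."""

    per_gene: pd.DataFrame  # gene, mean_a, mean_b, mean_difference, direction, t, p
    n_up: int
    n_down: int
    chi2_statistic: float
    p_pathway: float
    label: str = ""

    def to_json_dict(self) -> dict:
        return {
            "label": self.label,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "chi2": self.chi2_statistic,
            "p_pathway": self.p_pathway,
        }


@dataclass
class SkewResult:
    """Counts of patient pairs whose NER score rose vs fell at relapse."""

    n_increase: int
    n_decrease: int
    chi2_statistic: float
    p: float


def _paired_columns(
    ann: pd.DataFrame, mask_a: pd.Series, mask_b: pd.Series
) -> tuple[list[str], list[str]]:
    """Sample columns for the two arms of a paired comparison, aligned by patient."""
    a = ann[mask_a]
    b = ann[mask_b]
    for name, grp in (("a", a), ("b", b)):
        if grp["patient_id"].duplicated().any():
            raise DataError(f"paired comparison: group {name} selects a patient twice")
    patients = sorted(set(a["patient_id"]) & set(b["patient_id"]))
    if len(patients) < 2:
        raise DataError(f"paired comparison needs >= 2 complete pairs, got {len(patients)}")
    a_idx = a.set_index("patient_id")["sample_id"]
    b_idx = b.set_index("patient_id")["sample_id"]
    return [a_idx[p] for p in patients], [b_idx[p] for p in patients]


def gene_directions(
    m: GeneExpressionMatrix,
    ann: pd.DataFrame,
    cmp: ComparisonSpec,
    welch: bool = False,
) -> DirectionSummary:
    """Call each panel gene up or down between two groups and test the pathway.

    A gene is "up" iff mean(group a) - mean(group b) > 0; an exact tie is
    counted as "down" (conservative against the upregulation alternative,
    and measure-zero for continuous intensities — logged when it occurs).
    Per-gene p comes from the one-tailed t-test; a gene whose t is undefined
    (zero variance) is recorded with p = 1 and a warning. The pathway fields
    are ``pathway_chisquare(n_up, n_genes)``.
    """
    ann = ann[ann["sample_id"].isin(m.data.columns)].reset_index(drop=True)
    mask_a = cmp.group_a(ann).astype(bool)
    mask_b = cmp.group_b(ann).astype(bool)
    if not mask_a.any() or not mask_b.any():
        raise DataError(f"comparison {cmp.label!r}: a group selected no samples")

    paired = cmp.kind == "paired_diagnosis_vs_relapse"
    if paired:
        cols_a, cols_b = _paired_columns(ann, mask_a, mask_b)
    else:
        cols_a = ann.loc[mask_a, "sample_id"].tolist()
        cols_b = ann.loc[mask_b, "sample_id"].tolist()

    va = m.data[cols_a].to_numpy()
    vb = m.data[cols_b].to_numpy()
    rows = []
    for i, gene in enumerate(m.data.index):
        mean_a = float(va[i].mean())
        mean_b = float(vb[i].mean())
        diff = mean_a - mean_b
        # ties at relative 1e-12: groups of different sizes accumulate
        # different summation roundoff, so an exact-zero test would call
        # mathematically tied means "up" or "down" at random
        if abs(diff) <= 1e-12 * max(abs(mean_a), abs(mean_b)):
            log.warning("gene %s: tie in means; counted as 'down'", gene)
            diff = 0.0
        direction = "up" if diff > 0 else "down"
        try:
            t, p = t_test_one_tailed(va[i], vb[i], paired=paired, welch=welch)
        except ZeroVarianceError:
            log.warning("gene %s: zero variance, t undefined; p recorded as 1", gene)
            t, p = float("nan"), 1.0
        rows.append((gene, mean_a, mean_b, diff, direction, t, p))

    per_gene = pd.DataFrame(
        rows,
        columns=["gene", "mean_a", "mean_b", "mean_difference", "direction", "t", "p"],
    )
    n_up = int((per_gene["direction"] == "up").sum())
    n_total = len(per_gene)
    chi2, p_pathway = pathway_chisquare(n_up, n_total)
    return DirectionSummary(
        per_gene=per_gene,
        n_up=n_up,
        n_down=n_total - n_up,
        chi2_statistic=chi2,
        p_pathway=p_pathway,
        label=cmp.label,
    )


def score_skew_test(paired_scores: Sequence[tuple[float, float]]) -> SkewResult:
    """Test whether per-patient NER scores skew upward from diagnosis to relapse.

    Each pair is classified as an increase (relapse score > diagnosis score)
    or a decrease; ties count as decreases (logged). The split is tested
    against a 50/50 null with the same 1-df chi-square as the pathway test.
    """
    pairs = list(paired_scores)
    if not pairs:
        raise DataError("score_skew_test requires >= 1 patient pair")
    n_increase = 0
    for diag, rel in pairs:
        if rel == diag:
            log.warning("score_skew_test: exact tie (%.6g); counted as decrease", diag)
        if rel > diag:
            n_increase += 1
    n = len(pairs)
    chi2, p = pathway_chisquare(n_increase, n)
    return SkewResult(
        n_increase=n_increase, n_decrease=n - n_increase, chi2_statistic=chi2, p=p
    )
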