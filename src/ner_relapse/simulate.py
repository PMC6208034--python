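"""Synthetic paired diagnosis/relapse expression cohorts.

The generator realizes the two-trajectory relapse model the analysis is
built to detect: early relapsers (< 36 months) carry elevated NER-panel
expression already at diagnosis and stay flat through relapse, late
relapsers (>= 36 months) start at baseline and rise by relapse, and with
``delta_late_relapse == delta_early`` the two classes converge to the same
relapse-phase level. Decoy genes sit at baseline throughout. Intensities
are linear-scale with multiplicative log-normal noise (the standard
microarray error model in the high-expression regime, parameterized by its
coefficient of variation), genes are expanded into probes with fixed
per-probe affinities so probe collapsing is a real operation, and two
cohorts are emitted on intensity scales differing by a constant factor so
reference normalization and cohort combination are exercised end to end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import (
    DEFAULT_NER_PANEL,
    ANNOTATION_COLUMNS,
    DataError,
    GeneExpressionMatrix,
    validate_annotation,
    write_expression_table,
)

__all__ = ["SyntheticConfig", "generate_cohort", "generate_survival_only", "write_cohort"]

log = logging.getLogger(__name__)


def _as_counts(value, n_datasets: int, name: str) -> tuple[int, ...]:
    """Normalize an int total (split near-evenly) or per-dataset sequence."""
    if isinstance(value, (int, np.integer)):
        if value < 0:
            raise DataError(f"{name} must be >= 0")
        base, extra = divmod(int(value), n_datasets)
        return tuple(base + (1 if i < extra else 0) for i in range(n_datasets))
    counts = tuple(int(v) for v in value)
    if len(counts) != n_datasets:
        raise DataError(f"{name} must list one count per dataset ({n_datasets})")
    if any(c < 0 for c in counts):
        raise DataError(f"{name} counts must be >= 0")
    return counts


@dataclass
class SyntheticConfig:
    """Study conditions for a two-cohort paired relapse simulation.

    Defaults mirror the combined-cohort class sizes (19 + 27 early, 8 + 22
    late relapsers across the two emitted datasets), a 20% panel elevation
    for both trajectories, and 15% multiplicative noise.

    Parameters
    ----------
    n_early, n_late
        Patients per relapse class: either a total (split near-evenly
        across datasets) or one count per dataset.
    n_genes, n_decoy_genes
        Panel size (20 uses the canonical NER symbols) and number of
        baseline-only background genes.
    probes_per_gene
        Probes per panel gene; ``None`` uses the default allocation of 51
        probes over a 20-gene panel (11 genes x 3 + 9 genes x 2). Decoy
        genes always get one probe.
    baseline_range
        Per-gene baseline intensity drawn log-uniformly from this range
        (linear scale, arbitrary units).
    delta_early
        Multiplicative panel elevation of early relapsers (both phases).
    delta_late_relapse
        Multiplicative panel increase of late relapsers from diagnosis to
        relapse; equal to ``delta_early`` the classes converge at relapse.
    noise_cv
        Coefficient of variation of the mean-1 log-normal noise on every
        cell; 0 gives exact closed-form values.
    early_window, late_window
        Uniform time-to-relapse windows (months) for the two classes.
    dataset_scales
        Global intensity scale per emitted dataset.
    seed
        Seed for all randomness; identical config + seed is bit-reproducible.
    """

    n_early: int | Sequence[int] = (19, 27)
    n_late: int | Sequence[int] = (8, 22)
    n_genes: int = 20
    n_decoy_genes: int = 100
    probes_per_gene: int | None = None
    baseline_range: tuple[float, float] = (50.0, 500.0)
    delta_early: float = 1.2
    delta_late_relapse: float = 1.2
    noise_cv: float = 0.15
    early_window: tuple[float, float] = (6.0, 36.0)
    late_window: tuple[float, float] = (36.0, 72.0)
    n_datasets: int = 2
    dataset_scales: Sequence[float] = (1.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise DataError("n_datasets must be >= 1")
        self.n_early = _as_counts(self.n_early, self.n_datasets, "n_early")
        self.n_late = _as_counts(self.n_late, self.n_datasets, "n_late")
        if self.n_genes < 1 or self.n_decoy_genes < 0:
            raise DataError("n_genes >= 1 and n_decoy_genes >= 0 required")
        if self.delta_early <= 0 or self.delta_late_relapse <= 0:
            raise DataError("delta parameters must be > 0")
        if self.noise_cv < 0:
            raise DataError("noise_cv must be >= 0")
        if not (0 < self.baseline_range[0] <= self.baseline_range[1]):
            raise DataError("baseline_range must be positive and ordered")
        if not (self.early_window[0] > 0 and self.early_window[1] <= 36.0):
            raise DataError("early_window must lie in (0, 36]")
        if self.late_window[0] < 36.0:
            raise DataError("late_window must start at >= 36 months")
        if len(tuple(self.dataset_scales)) != self.n_datasets:
            raise DataError("dataset_scales must list one scale per dataset")
        if any(s <= 0 for s in self.dataset_scales):
            raise DataError("dataset_scales must be > 0")
        if self.probes_per_gene is not None and self.probes_per_gene < 1:
            raise DataError("probes_per_gene must be >= 1")

    def panel_genes(self) -> list[str]:
        if self.n_genes == 20:
            return list(DEFAULT_NER_PANEL)
        return [f"PANEL{i + 1:02d}" for i in range(self.n_genes)]

    def probe_allocation(self) -> list[int]:
        """Probes per panel gene; default totals 51 over a 20-gene panel."""
        if self.probes_per_gene is not None:
            return [self.probes_per_gene] * self.n_genes
        if self.n_genes == 20:
            return [3] * 11 + [2] * 9  # 51 probes
        return [2] * self.n_genes


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=shape))


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[GeneExpressionMatrix, pd.Series, pd.DataFrame, dict]:
    """Generate a probe-level matrix, probe map, annotation, and truth record.

    The matrix holds all datasets' samples (annotation carries the dataset
    label of each). Expected panel values before noise: early patients sit
    at ``baseline * delta_early`` in both phases; late patients at
    ``baseline`` at diagnosis and ``baseline * delta_late_relapse`` at
    relapse; decoys at ``baseline`` always; every value further multiplied
    by the dataset scale and the probe affinity.
    """
    rng = np.random.default_rng(cfg.seed)
    panel = cfg.panel_genes()
    decoys = [f"DECOY{i + 1:03d}" for i in range(cfg.n_decoy_genes)]
    genes = panel + decoys

    lo, hi = cfg.baseline_range
    baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))

    alloc = cfg.probe_allocation() + [1] * cfg.n_decoy_genes
    probe_ids, probe_gene, gene_row_of_probe = [], [], []
    for gi, (gene, k) in enumerate(zip(genes, alloc)):
        for j in range(k):
            probe_ids.append(f"{gene}_p{j + 1}")
            probe_gene.append(gene)
            gene_row_of_probe.append(gi)
    affinities = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(probe_ids)))
    probe_map = pd.Series(probe_gene, index=probe_ids, name="gene_symbol")

    is_panel = np.array([g in set(panel) for g in genes])

    columns: list[str] = []
    ann_rows: list[dict] = []
    blocks: list[np.ndarray] = []
    for di in range(cfg.n_datasets):
        ds = f"cohort{di + 1}"
        scale = float(list(cfg.dataset_scales)[di])
        plan = [("early", k) for k in range(cfg.n_early[di])] + [
            ("late", k) for k in range(cfg.n_late[di])
        ]
        for cls, k in plan:
            pid = f"{ds}_{cls}{k + 1:03d}"
            if cls == "early":
                time = float(rng.uniform(*cfg.early_window))
                mult_dx, mult_rel = cfg.delta_early, cfg.delta_early
            else:
                time = float(rng.uniform(*cfg.late_window))
                mult_dx, mult_rel = 1.0, cfg.delta_late_relapse
            for phase, mult in (("diagnosis", mult_dx), ("relapse", mult_rel)):
                sid = f"{pid}_{'dx' if phase == 'diagnosis' else 'rel'}"
                gene_level = baselines * np.where(is_panel, mult, 1.0) * scale
                probe_level = gene_level[gene_row_of_probe] * affinities
                probe_level = probe_level * _lognormal_noise(
                    rng, cfg.noise_cv, probe_level.shape
                )
                columns.append(sid)
                blocks.append(probe_level)
                ann_rows.append(
                    {
                        "sample_id": sid,
                        "patient_id": pid,
                        "phase": phase,
                        "immunophenotype": "preB",
                        "time_to_relapse_months": time,
                        "dataset_label": ds,
                    }
                )

    data = pd.DataFrame(
        np.column_stack(blocks), index=pd.Index(probe_ids, name="probe_id"), columns=columns
    )
    matrix = GeneExpressionMatrix(data, level="probe", dataset_label="")
    ann = validate_annotation(pd.DataFrame(ann_rows, columns=list(ANNOTATION_COLUMNS)))
    truth = {
        "seed": cfg.seed,
        "n_early": list(cfg.n_early),
        "n_late": list(cfg.n_late),
        "n_genes": cfg.n_genes,
        "n_decoy_genes": cfg.n_decoy_genes,
        "n_probes": len(probe_ids),
        "delta_early": cfg.delta_early,
        "delta_late_relapse": cfg.delta_late_relapse,
        "noise_cv": cfg.noise_cv,
        "dataset_scales": list(cfg.dataset_scales),
        "dataset_labels": [f"cohort{i + 1}" for i in range(cfg.n_datasets)],
        "panel_genes": panel,
    }
    return matrix, probe_map, ann, truth


def generate_survival_only(
    n_per_stratum: int,
    hazard_ratio: float,
    base_hazard: float = 0.03,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two fully-evented exponential survival strata for testing the O/E HR.

    Stratum a has per-month event rate ``base_hazard * hazard_ratio``,
    stratum b ``base_hazard`` (default 0.03/month, i.e. median ~23 months —
    the scale of pediatric relapse cohorts). Returns (records_a, records_b)
    with columns patient_id, time, event, stratum.
    """
    if hazard_ratio <= 0 or base_hazard <= 0:
        raise DataError("hazard_ratio and base_hazard must be > 0")
    if n_per_stratum < 1:
        raise DataError("n_per_stratum must be >= 1")
    rng = np.random.default_rng(seed)
    times_a = rng.exponential(1.0 / (base_hazard * hazard_ratio), size=n_per_stratum)
    times_b = rng.exponential(1.0 / base_hazard, size=n_per_stratum)

    def frame(times: np.ndarray, stratum: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [f"{stratum}{i + 1:03d}" for i in range(times.size)],
                "time": times,
                "event": True,
                "stratum": stratum,
            }
        )

    return frame(times_a, "high"), frame(times_b, "low")


def write_cohort(
    cfg: SyntheticConfig, out_dir: str | Path
) -> tuple[GeneExpressionMatrix, pd.Series, pd.DataFrame, dict]:
    """Generate a cohort and write expression/probe-map/annotation/truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, probe_map, ann, truth = generate_cohort(cfg)
    write_expression_table(matrix, out / "expression.tsv")
    probe_map.rename_axis("probe_id").reset_index().to_csv(
        out / "probe_map.tsv", sep="\t", index=False
    )
    ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    log.info(
        "wrote synthetic cohort: %d probes x %d samples to %s",
        *matrix.shape,
        out,
    )
    return matrix, probe_map, ann, truth
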