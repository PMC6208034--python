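"""Expression-matrix handling for paired diagnosis/relapse cohorts.

The pipeline consumes an already-normalized, linear-scale expression matrix
(e.g. PLIER output for Affymetrix U133 Plus 2.0 arrays): rows are probe sets
or gene symbols, columns are samples, and every intensity is a non-negative
real. Probe-level matrices are collapsed to gene level by arithmetic
averaging on the linear scale, the NER gene panel is extracted, and cohorts
measured on different overall intensity scales are made comparable by
dividing each gene by its mean over a per-dataset reference sample group.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "GeneExpressionMatrix",
    "NERPanel",
    "DEFAULT_NER_PANEL",
    "ANNOTATION_COLUMNS",
    "read_expression_table",
    "read_probe_map",
    "read_annotation",
    "validate_annotation",
    "collapse_probes",
    "extract_panel",
    "normalize_to_reference",
    "write_expression_table",
]

log = logging.getLogger(__name__)

PHASES = ("diagnosis", "relapse")
IMMUNOPHENOTYPES = ("preB", "T")

#: The 20 canonical nucleotide excision repair genes used as the default
#: panel. Includes both damage recognition (XPC, RAD23B, DDB1/2), the TFIIH
#: core (GTF2H2/3/4, ERCC2, ERCC3, CDK7, CCNH), incision nucleases
#: (ERCC1-ERCC4/XPF, ERCC5/XPG), the RPA single-strand binding trimer and
#: transcription-coupled factors (ERCC6/CSB, ERCC8/CSA).
DEFAULT_NER_PANEL: tuple[str, ...] = (
    "CCNH", "CDK7", "DDB1", "DDB2", "ERCC1", "ERCC2", "ERCC3", "ERCC4",
    "ERCC5", "ERCC6", "ERCC8", "GTF2H2", "GTF2H3", "GTF2H4", "RAD23B",
    "RPA1", "RPA2", "RPA3", "XPA", "XPC",
)

ANNOTATION_COLUMNS = (
    "sample_id",
    "patient_id",
    "phase",
    "immunophenotype",
    "time_to_relapse_months",
    "dataset_label",
)


class DataError(ValueError):
    """A data contract violation (shape, sign, duplication, pairing)."""


@dataclass
class GeneExpressionMatrix:
    """Features x samples matrix of non-negative linear-scale intensities.

    Parameters
    ----------
    data
        DataFrame with unique feature ids as the index and unique sample ids
        as columns; all values finite and >= 0.
    level
        ``"probe"`` or ``"gene"``.
    dataset_label
        Free-text cohort name; empty for a multi-cohort (combined) matrix.
    """

    data: pd.DataFrame
    level: str
    dataset_label: str = ""

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise DataError(f"level must be 'probe' or 'gene', got {self.level!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DataError(f"duplicate feature id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise DataError(f"duplicate sample id: {dup!r}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise DataError("expression values must be numeric")
        if values.size:
            if not np.isfinite(values).all():
                raise DataError("expression values must be finite")
            if (values < 0).any():
                raise DataError(
                    "negative expression value: linear-scale intensities must be >= 0"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "GeneExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise DataError(f"samples absent from matrix: {missing}")
        return GeneExpressionMatrix(
            self.data.loc[:, list(sample_ids)], self.level, self.dataset_label
        )


@dataclass(frozen=True)
class NERPanel:
    """Ordered panel of the 20 canonical NER gene symbols (overridable)."""

    genes: tuple[str, ...] = DEFAULT_NER_PANEL

    def __post_init__(self) -> None:
        if len(self.genes) != 20:
            raise DataError(f"NER panel must list 20 genes, got {len(self.genes)}")
        if len(set(self.genes)) != len(self.genes):
            raise DataError("NER panel genes must be unique")
        if any(not g for g in self.genes):
            raise DataError("NER panel gene symbols must be non-empty")


def _parse_table(text: str, source: str) -> pd.DataFrame:
    """Parse a feature-id + samples table from tab-delimited text.

    Cells are validated one by one so a bad cell can be reported with its
    row and column rather than as a generic parse failure.
    """
    raw = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, index_col=0)
    raw.index = raw.index.astype(str).str.strip('"')
    raw.columns = raw.columns.astype(str).str.strip('"')
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise DataError(f"{source}: duplicate feature id: {dup!r}")
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"{source}: non-numeric value {raw.iat[r, c]!r} at feature "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise DataError(
            f"{source}: missing value at feature {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}"
        )
    return numeric.astype(float)


def read_expression_table(
    path: str | Path,
    dialect: str = "tsv",
    dataset_label: str = "",
    level: str = "probe",
) -> GeneExpressionMatrix:
    """Read an expression matrix from TSV or a GEO series-matrix export.

    The ``geo_series_matrix`` dialect tolerates the "!"-prefixed metadata
    lines of GEO's processed-data export and reads only the block between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` (quoted
    ids are unquoted). Values must be finite and non-negative — this reader
    enforces the linear-scale contract of PLIER-style output.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "geo_series_matrix":
        lines: list[str] = []
        inside = False
        for line in text.splitlines():
            low = line.strip().strip('"').lower()
            if low.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if low.startswith("!series_matrix_table_end"):
                inside = False
                continue
            if inside and line and not line.startswith("!"):
                lines.append(line)
        if not lines:
            raise DataError(f"{path}: no series_matrix table block found")
        text = "\n".join(lines)
    elif dialect != "tsv":
        raise DataError(f"unknown dialect {dialect!r}")
    frame = _parse_table(text, str(path))
    return GeneExpressionMatrix(frame, level=level, dataset_label=dataset_label)


def read_probe_map(path: str | Path) -> pd.Series:
    """Read a two-column (probe_id, gene_symbol) TSV with header."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise DataError(f"{path}: probe map needs two columns (probe_id, gene_symbol)")
    probes = frame.iloc[:, 0].astype(str)
    genes = frame.iloc[:, 1].astype(str)
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].iloc[0]
        raise DataError(f"{path}: duplicate probe id in map: {dup!r}")
    if (genes.str.len() == 0).any():
        raise DataError(f"{path}: empty gene symbol in probe map")
    return pd.Series(genes.to_numpy(), index=probes.to_numpy(), name="gene_symbol")


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-annotation table of paired diagnosis/relapse samples.

    Enforces: required columns; known phase and immunophenotype codes;
    strictly positive time to relapse; exactly one diagnosis and one relapse
    sample per patient within a dataset, with identical time for the pair.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise DataError(f"annotation missing columns: {missing}")
    ann = ann.copy()
    ann["time_to_relapse_months"] = pd.to_numeric(ann["time_to_relapse_months"])
    if ann["sample_id"].duplicated().any():
        dup = ann.loc[ann["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataError(f"duplicate sample id in annotation: {dup!r}")
    bad_phase = set(ann["phase"]) - set(PHASES)
    if bad_phase:
        raise DataError(f"unknown phase values: {sorted(bad_phase)}")
    bad_immuno = set(ann["immunophenotype"]) - set(IMMUNOPHENOTYPES)
    if bad_immuno:
        raise DataError(f"unknown immunophenotype values: {sorted(bad_immuno)}")
    if (ann["time_to_relapse_months"] <= 0).any():
        raise DataError("time_to_relapse_months must be > 0 for every sample")
    for (dataset, patient), grp in ann.groupby(["dataset_label", "patient_id"]):
        phases = sorted(grp["phase"])
        if phases != ["diagnosis", "relapse"]:
            raise DataError(
                f"patient {patient!r} in dataset {dataset!r} must have exactly one "
                f"diagnosis and one relapse sample, got phases {phases}"
            )
        if grp["time_to_relapse_months"].nunique() != 1:
            raise DataError(
                f"patient {patient!r}: diagnosis and relapse samples disagree on "
                "time_to_relapse_months"
            )
    return ann


def read_annotation(path: str | Path) -> pd.DataFrame:
    return validate_annotation(pd.read_csv(path, sep="\t"))


def collapse_probes(
    m: GeneExpressionMatrix, probe_map: pd.Series
) -> GeneExpressionMatrix:
    """Average multiple probes per gene (arithmetic mean, linear scale).

    Probes present in the matrix but absent from the map are dropped (the
    count is logged); a map entry whose probe is missing from the matrix is
    a hard error. Output gene order follows first appearance in the map.
    """
    if m.level != "probe":
        raise DataError("collapse_probes requires a probe-level matrix")
    map_probes = list(probe_map.index)
    absent = [p for p in map_probes if p not in m.data.index]
    if absent:
        raise DataError(f"probe map references probes absent from matrix: {absent[:5]}")
    dropped = len(m.data.index) - len(map_probes)
    n_shared = len(set(map_probes) & set(m.data.index))
    if n_shared == 0:
        raise DataError("no probes shared between matrix and probe map")
    if dropped:
        log.info("collapse_probes: dropping %d unmapped probes", dropped)
    sub = m.data.loc[map_probes]
    gene_order = list(dict.fromkeys(probe_map.to_numpy()))
    collapsed = sub.groupby(probe_map.reindex(sub.index), sort=False).mean()
    collapsed = collapsed.loc[gene_order]
    collapsed.index.name = m.data.index.name
    return GeneExpressionMatrix(collapsed, level="gene", dataset_label=m.dataset_label)


def extract_panel(
    m: GeneExpressionMatrix, panel: NERPanel | Sequence[str] = NERPanel()
) -> GeneExpressionMatrix:
    """Extract the NER panel rows, in panel order."""
    genes = list(panel.genes) if isinstance(panel, NERPanel) else list(panel)
    if m.level != "gene":
        raise DataError("extract_panel requires a gene-level matrix")
    missing = [g for g in genes if g not in m.data.index]
    if missing:
        raise DataError(f"panel genes absent from matrix: {missing}")
    return GeneExpressionMatrix(m.data.loc[genes], level="gene", dataset_label=m.dataset_label)


def normalize_to_reference(
    m: GeneExpressionMatrix,
    ann: pd.DataFrame,
    reference: Callable[[pd.DataFrame], pd.Series] | pd.Series,
) -> GeneExpressionMatrix:
    """Divide each gene, within each dataset, by its mean over that
    dataset's reference samples.

    ``reference`` is a boolean mask over annotation rows (or a callable
    producing one). After the transform the per-gene mean over each
    dataset's reference samples is exactly 1, which puts cohorts measured
    on different intensity scales on a common, unit-free footing so they
    can be combined.
    """
    ann = ann[ann["sample_id"].isin(m.data.columns)]
    mask = reference(ann) if callable(reference) else reference.loc[ann.index]
    mask = mask.astype(bool)
    out = m.data.copy().astype(float)
    for dataset, grp in ann.groupby("dataset_label"):
        ref_samples = grp.loc[mask.loc[grp.index], "sample_id"].tolist()
        if len(ref_samples) < 2:
            raise DataError(
                f"reference group in dataset {dataset!r} has {len(ref_samples)} "
                "samples; need >= 2"
            )
        ref_mean = m.data[ref_samples].mean(axis=1)
        zero = ref_mean[ref_mean == 0]
        if len(zero):
            raise DataError(
                f"reference mean is 0 for gene {zero.index[0]!r} in dataset {dataset!r}"
            )
        cols = grp["sample_id"].tolist()
        out[cols] = m.data[cols].div(ref_mean, axis=0)
    return GeneExpressionMatrix(out, level=m.level, dataset_label=m.dataset_label)


def write_expression_table(m: GeneExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with a deterministic (current) row/col order."""
    frame = m.data.copy()
    frame.index.name = frame.index.name or ("probe_id" if m.level == "probe" else "gene")
    frame.to_csv(path, sep="\t")
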