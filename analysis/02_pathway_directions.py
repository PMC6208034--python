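#!/usr/bin/env python
"""Directional pathway analysis: the four subgroup comparisons.

For each cohort and for the reference-normalized combination, counts how
many of the 20 NER panel genes are up in the hypothesized-higher group and
tests the split against the even 10/10 null. Expected from the simulated
two-trajectory model: late relapsers upregulated at relapse (n_up near 20,
p << .05), early relapsers unchanged, early elevated over late at diagnosis,
classes converged at relapse. Writes per-gene tables and the pathway
summary under results/directions/.
"""

import json
from pathlib import Path

from ner_relapse.expression import (
    collapse_probes, extract_panel, read_annotation, read_expression_table,
    read_probe_map,
)
from ner_relapse.pipeline import _direction_scope, annotate_relapse_class
from ner_relapse.stats import fisher_between_datasets

ROOT = Path(__file__).resolve().parents[1]
FIXTURE_DIR = ROOT / "scratch" / "synthetic_cohort"
OUT_DIR = ROOT / "results" / "directions"


def load_panel_and_annotation():
    if not (FIXTURE_DIR / "expression.tsv").exists():
        raise SystemExit("fixture missing - run analysis/01_simulate_cohorts.py first")
    matrix = read_expression_table(FIXTURE_DIR / "expression.tsv")
    probe_map = read_probe_map(FIXTURE_DIR / "probe_map.tsv")
    ann = annotate_relapse_class(read_annotation(FIXTURE_DIR / "annotation.tsv"), 36.0)
    return extract_panel(collapse_probes(matrix, probe_map)), ann


def main() -> None:
    panel, ann = load_panel_and_annotation()
    OUT_DIR.mkdir(parents=True, exist_ok=True)

    summary: dict = {}
    scopes = {}
    for ds in sorted(ann["dataset_label"].unique()):
        sub = ann[ann["dataset_label"] == ds].reset_index(drop=True)
        scopes[ds] = _direction_scope(
            panel.subset_samples(sub["sample_id"].tolist()), sub,
            welch=False, combined=False,
        )
    scopes["combined"] = _direction_scope(panel, ann, welch=False, combined=True)

    for scope, comps in scopes.items():
        summary[scope] = {}
        for name, res in comps.items():
            res.per_gene.to_csv(OUT_DIR / f"{scope}__{name}.tsv", sep="\t", index=False)
            summary[scope][name] = res.to_json_dict()
            print(f"{scope:9s} {name:28s} n_up={res.n_up:2d}/20 "
                  f"chi2={res.chi2_statistic:5.2f} p={res.p_pathway:.3g}")

    ds = sorted(set(scopes) - {"combined"})
    if len(ds) == 2:
        summary["fisher_between_datasets"] = {
            name: fisher_between_datasets(
                scopes[ds[0]][name].n_up, 20, scopes[ds[1]][name].n_up, 20
            )
            for name in scopes[ds[0]]
        }
    (OUT_DIR / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    print(f"\nwrote {OUT_DIR}/summary.json and per-gene tables")


if __name__ == "__main__":
    main()
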