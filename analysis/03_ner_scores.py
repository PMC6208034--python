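#!/usr/bin/env python
"""NER scores: per-sample values, group summary, and trajectory skew.

Each sample's score averages the 20 panel genes relative to the cohort's
relapse-phase means, so relapse scores center on 1. The group summary
(mean +/- SEM per relapse class and phase) shows the two trajectories:
early relapsers flat near 1, late relapsers rising from a diagnosis
deficit. The skew test counts per-patient score increases vs decreases
from diagnosis to relapse. Writes results/scores/.
"""

import importlib.util
import json
from pathlib import Path

from ner_relapse.score import compute_ner_scores, summarize_scores, write_score_table
from ner_relapse.stats import score_skew_test

ROOT = Path(__file__).resolve().parents[1]
OUT_DIR = ROOT / "results" / "scores"

spec = importlib.util.spec_from_file_location(
    "pathway_directions", Path(__file__).parent / "02_pathway_directions.py"
)
_mod = importlib.util.module_from_spec(spec)
spec.loader.exec_module(_mod)
load_panel_and_annotation = _mod.load_panel_and_annotation


def main() -> None:
    panel, ann = load_panel_and_annotation()
    OUT_DIR.mkdir(parents=True, exist_ok=True)

    scores = compute_ner_scores(panel, ann)
    write_score_table(scores, OUT_DIR / "scores.tsv")
    summary = summarize_scores(scores)
    (OUT_DIR / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )

    print("group means (score +/- SEM):")
    for scope, entry in summary.items():
        for cls in ("early", "late"):
            if cls in entry:
                b = entry[cls]
                print(f"  {scope:9s} {cls:5s}  diagnosis "
                      f"{b['diagnosis']['mean']:.3f}+/-{b['diagnosis']['sem']:.3f}  "
                      f"relapse {b['relapse']['mean']:.3f}+/-{b['relapse']['sem']:.3f}  "
                      f"p={b['p']:.3g}")

    skew = {}
    for scope, tab in {"combined": scores, **{
        ds: scores[scores["dataset_label"] == ds]
        for ds in sorted(scores["dataset_label"].unique())
    }}.items():
        skew[scope] = {}
        for cls in ("early", "late"):
            sub = tab[tab["relapse_class"] == cls]
            wide = sub.pivot(index="patient_id", columns="phase", values="score").dropna()
            if wide.empty:
                continue
            res = score_skew_test(list(zip(wide["diagnosis"], wide["relapse"])))
            skew[scope][cls] = {
                "n_increase": res.n_increase, "n_decrease": res.n_decrease,
                "chi2": res.chi2_statistic, "p": res.p,
            }
            print(f"  skew {scope:9s} {cls:5s}  {res.n_increase} up / "
                  f"{res.n_decrease} down  p={res.p:.3g}")
    (OUT_DIR / "skew.json").write_text(json.dumps(skew, indent=2, sort_keys=True) + "\n")
    print(f"\nwrote {OUT_DIR}/")


if __name__ == "__main__":
    main()
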