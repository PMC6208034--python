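#!/usr/bin/env python
"""Generate the two synthetic paired diagnosis/relapse cohorts.

Emits the default study conditions: cohort1 with 19 early / 8 late
relapsers, cohort2 with 27 early / 22 late (76 patients, 152 samples), a
20-gene NER panel expanded to 51 probes plus 100 decoy genes, 20% panel
elevation for both trajectories, 15% multiplicative noise, and a 3x
intensity-scale difference between the cohorts. The probe-level matrix,
probe map, annotation and true-parameter sidecar land under
scratch/synthetic_cohort/ (regenerable; rerun this script after deleting).
"""

from pathlib import Path

from ner_relapse.simulate import SyntheticConfig, write_cohort

ROOT = Path(__file__).resolve().parents[1]
FIXTURE_DIR = ROOT / "scratch" / "synthetic_cohort"
SEED = 1


def main() -> None:
    cfg = SyntheticConfig(seed=SEED)
    matrix, probe_map, ann, truth = write_cohort(cfg, FIXTURE_DIR)
    n_pat = ann["patient_id"].nunique()
    print(f"wrote {FIXTURE_DIR}")
    print(f"  probes x samples : {matrix.shape[0]} x {matrix.shape[1]}")
    print(f"  patients         : {n_pat} "
          f"({sum(truth['n_early'])} early, {sum(truth['n_late'])} late)")
    print(f"  panel probes     : 51 over {truth['n_genes']} NER genes, "
          f"{truth['n_decoy_genes']} decoy genes")
    print(f"  dataset scales   : {truth['dataset_scales']}")


if __name__ == "__main__":
    main()
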