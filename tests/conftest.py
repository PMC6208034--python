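import numpy as np
import pandas as pd
import pytest

from ner_relapse.expression import GeneExpressionMatrix
from ner_relapse.simulate import SyntheticConfig, generate_cohort


def make_annotation(rows):
    """Build an annotation frame from (sample, patient, phase, time, dataset)."""
    return pd.DataFrame(
        [
            {
                "sample_id": s,
                "patient_id": p,
                "phase": ph,
                "immunophenotype": "preB",
                "time_to_relapse_months": t,
                "dataset_label": d,
            }
            for s, p, ph, t, d in rows
        ]
    )


def paired_annotation(n_early, n_late, dataset="ds1", t_early=20.0, t_late=48.0):
    """Annotation for n_early + n_late patients, each with a dx/rel pair."""
    rows = []
    for cls, n, t in (("early", n_early, t_early), ("late", n_late, t_late)):
        for k in range(n):
            pid = f"{dataset}_{cls}{k}"
            rows.append((f"{pid}_dx", pid, "diagnosis", t, dataset))
            rows.append((f"{pid}_rel", pid, "relapse", t, dataset))
    return make_annotation(rows)


def gene_matrix(values, genes, samples, dataset=""):
    return GeneExpressionMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples),
        level="gene",
        dataset_label=dataset,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy two-dataset cohort shared by read-only tests."""
    cfg = SyntheticConfig(
        n_early=(6, 7), n_late=(4, 5), n_decoy_genes=10, noise_cv=0.15, seed=11
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Noise-free default-size cohort: pipeline outputs are closed-form."""
    cfg = SyntheticConfig(noise_cv=0.0, seed=3)
    return cfg, generate_cohort(cfg)
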