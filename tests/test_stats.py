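"""Directional chi-square, Fisher's exact, one-tailed t-tests, skew test."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from ner_relapse.expression import DataError
from ner_relapse.stats import (
    ComparisonSpec,
    ZeroVarianceError,
    fisher_between_datasets,
    gene_directions,
    pathway_chisquare,
    score_skew_test,
    t_test_one_tailed,
)

from conftest import gene_matrix, paired_annotation


class TestPathwayChisquare:
    def test_even_split_is_null(self):
        chi2, p = pathway_chisquare(10, 20)
        assert chi2 == 0.0
        assert p == 1.0

    def test_rejects_out_of_range_counts(self):
        with pytest.raises(DataError):
            pathway_chisquare(21, 20)
        with pytest.raises(DataError):
            pathway_chisquare(-1, 20)
        with pytest.raises(DataError):
            pathway_chisquare(0, 0)

    @given(st.integers(1, 60), st.data())
    @settings(derandomize=True, max_examples=60)
    def test_symmetry_up_down(self, n, data):
        k = data.draw(st.integers(0, n))
        assert pathway_chisquare(k, n) == pathway_chisquare(n - k, n)

    @given(st.integers(2, 60))
    @settings(derandomize=True, max_examples=40)
    def test_p_monotone_in_imbalance(self, n):
        ps = [pathway_chisquare(k, n)[1] for k in range(n // 2, n + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestFisherBetweenDatasets:
    @staticmethod
    def enumeration_oracle(ka, na, kb, nb):
        """Two-sided Fisher p by direct hypergeometric enumeration."""
        total_up = ka + kb
        support = range(max(0, total_up - nb), min(na, total_up) + 1)
        pmf = {
            k: math.comb(na, k) * math.comb(nb, total_up - k) / math.comb(na + nb, total_up)
            for k in support
        }
        p_obs = pmf[ka]
        return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))

    def test_identical_proportions_p_one(self):
        assert fisher_between_datasets(10, 20, 10, 20) == 1.0

    def test_matches_enumeration_on_paper_sized_table(self):
        assert fisher_between_datasets(19, 20, 7, 20) == pytest.approx(
            self.enumeration_oracle(19, 20, 7, 20), rel=1e-9
        )

    def test_extreme_table_closed_form(self):
        # 20/20 vs 0/20: only the two extreme tables are as improbable as observed
        p_extreme = scipy.stats.hypergeom.pmf([0, 20], 40, 20, 20).sum()
        assert fisher_between_datasets(20, 20, 0, 20) == pytest.approx(p_extreme, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            fisher_between_datasets(-1, 20, 0, 20)
        with pytest.raises(DataError):
            fisher_between_datasets(21, 20, 0, 20)

    def test_exhaustive_agreement_small_margins(self):
        for na in range(1, 13):
            for nb in range(1, 13):
                for ka in range(na + 1):
                    for kb in range(nb + 1):
                        assert fisher_between_datasets(ka, na, kb, nb) == pytest.approx(
                            self.enumeration_oracle(ka, na, kb, nb), rel=1e-8
                        )

    def test_sampled_agreement_margins_to_25(self):
        rng = np.random.default_rng(42)
        for _ in range(800):
            na, nb = rng.integers(1, 26, size=2)
            ka = int(rng.integers(0, na + 1))
            kb = int(rng.integers(0, nb + 1))
            assert fisher_between_datasets(ka, int(na), kb, int(nb)) == pytest.approx(
                self.enumeration_oracle(ka, int(na), kb, int(nb)), rel=1e-8
            )


class TestOneTailedT:
    def test_zero_mean_difference_gives_half(self):
        a = np.array([1.0, 4.0, 2.0, 5.0])
        b = np.array([4.0, 1.0, 5.0, 2.0])  # same values, shuffled
        t, p = t_test_one_tailed(a, b, paired=False)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_constant_paired_difference_is_degenerate(self):
        with pytest.raises(ZeroVarianceError):
            t_test_one_tailed([3.0, 4.0, 5.0], [1.0, 2.0, 3.0], paired=True)

    def test_unpaired_matches_pooled_variance_formula(self):
        a = np.array([5.0, 6.0, 7.0, 8.0])
        b = np.array([1.0, 2.0, 3.0, 4.0])
        sp2 = (
            (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
        ) / (a.size + b.size - 2)
        t_expect = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / a.size + 1 / b.size))
        p_expect = scipy.stats.t.sf(t_expect, a.size + b.size - 2)
        t, p = t_test_one_tailed(a, b, paired=False)
        assert t == pytest.approx(t_expect, rel=1e-12)
        assert p == pytest.approx(p_expect, rel=1e-12)

    def test_paired_matches_difference_formula(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.2, 0.3, size=9)
        b = rng.normal(1.0, 0.3, size=9)
        d = a - b
        t_expect = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
        t, p = t_test_one_tailed(a, b, paired=True)
        assert t == pytest.approx(t_expect, rel=1e-12)
        assert p == pytest.approx(scipy.stats.t.sf(t_expect, d.size - 1), rel=1e-12)

    @given(st.integers(0, 2**31 - 1), st.booleans())
    @settings(derandomize=True, max_examples=25)
    def test_direction_reversal_complements_p(self, seed, paired):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.5, 1.0, size=6)
        b = rng.normal(0.0, 1.0, size=6)
        _, p_ab = t_test_one_tailed(a, b, paired=paired)
        _, p_ba = t_test_one_tailed(b, a, paired=paired)
        assert p_ab + p_ba == pytest.approx(1.0, abs=1e-9)

    def test_welch_differs_under_unequal_variance(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([0.0, 10.0, -10.0, 20.0])
        _, p_pooled = t_test_one_tailed(a, b, paired=False)
        _, p_welch = t_test_one_tailed(a, b, paired=False, welch=True)
        assert p_pooled != p_welch


class TestGeneDirections:
    @staticmethod
    def _unpaired_spec():
        return ComparisonSpec(
            kind="unpaired_group_vs_group",
            group_a=lambda ann: ann["phase"] == "relapse",
            group_b=lambda ann: ann["phase"] == "diagnosis",
            label="relapse_vs_diagnosis",
        )

    def _fixture(self, n_up, n_genes=20, n_patients=8, seed=0):
        """Matrix where exactly n_up genes have higher relapse means."""
        ann = paired_annotation(n_patients, 0)
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(n_genes)]
        dx_cols = ann.loc[ann["phase"] == "diagnosis", "sample_id"].tolist()
        rel_cols = ann.loc[ann["phase"] == "relapse", "sample_id"].tolist()
        values = pd.DataFrame(
            rng.uniform(10, 20, size=(n_genes, len(ann))),
            index=genes,
            columns=ann["sample_id"],
        )
        for i, g in enumerate(genes):
            shift = 5.0 if i < n_up else -5.0
            values.loc[g, rel_cols] = values.loc[g, dx_cols].to_numpy() + shift
        return gene_matrix(values.to_numpy(), genes, list(values.columns)), ann

    def test_fifteen_of_twenty_up_reproduces_pathway_p(self):
        m, ann = self._fixture(15)
        res = gene_directions(m, ann, self._unpaired_spec())
        assert res.n_up == 15
        assert res.p_pathway == pytest.approx(0.025, abs=5e-4)

    def test_identical_groups_all_tie_down(self):
        m, ann = self._fixture(0)
        dx = ann.loc[ann["phase"] == "diagnosis", "sample_id"].tolist()
        rel = ann.loc[ann["phase"] == "relapse", "sample_id"].tolist()
        m.data[rel] = m.data[dx].to_numpy()  # groups identical
        paired = ComparisonSpec(
            kind="paired_diagnosis_vs_relapse",
            group_a=lambda a: a["phase"] == "relapse",
            group_b=lambda a: a["phase"] == "diagnosis",
        )
        res = gene_directions(m, ann, paired)
        assert res.n_up == 0
        assert (res.per_gene["mean_difference"] == 0).all()
        assert (res.per_gene["p"] == 1.0).all()  # zero-variance differences
        assert res.p_pathway == pytest.approx(pathway_chisquare(0, 20)[1])

    def test_n_up_matches_brute_force_recount(self):
        rng = np.random.default_rng(9)
        ann = paired_annotation(6, 0)
        genes = [f"G{i}" for i in range(20)]
        m = gene_matrix(
            rng.uniform(5, 50, size=(20, len(ann))), genes, ann["sample_id"].tolist()
        )
        spec = self._unpaired_spec()
        res = gene_directions(m, ann, spec)
        rel = ann.loc[ann["phase"] == "relapse", "sample_id"].tolist()
        dx = ann.loc[ann["phase"] == "diagnosis", "sample_id"].tolist()
        recount = int(
            (m.data[rel].mean(axis=1).to_numpy() > m.data[dx].mean(axis=1).to_numpy()).sum()
        )
        assert res.n_up == recount
        assert res.n_up + res.n_down == 20

    def test_paired_comparison_aligns_by_patient(self):
        ann = paired_annotation(5, 0)
        spec = ComparisonSpec(
            kind="paired_diagnosis_vs_relapse",
            group_a=lambda a: a["phase"] == "relapse",
            group_b=lambda a: a["phase"] == "diagnosis",
        )
        rng = np.random.default_rng(2)
        m = gene_matrix(
            rng.uniform(5, 50, size=(3, len(ann))),
            ["G0", "G1", "G2"],
            ann["sample_id"].tolist(),
        )
        res = gene_directions(m, ann, spec)
        # shuffling annotation rows must not change a patient-matched test
        shuffled = ann.sample(frac=1.0, random_state=4).reset_index(drop=True)
        res2 = gene_directions(m, shuffled, spec)
        pd.testing.assert_frame_equal(res.per_gene, res2.per_gene)

    def test_empty_group_is_error(self):
        m, ann = self._fixture(5)
        spec = ComparisonSpec(
            kind="unpaired_group_vs_group",
            group_a=lambda a: a["phase"] == "relapse",
            group_b=lambda a: pd.Series(False, index=a.index),
        )
        with pytest.raises(DataError, match="no samples"):
            gene_directions(m, ann, spec)


class TestScoreSkew:
    def test_balanced_pairs_null(self):
        pairs = [(1.0, 2.0)] * 10 + [(2.0, 1.0)] * 10
        res = score_skew_test(pairs)
        assert (res.n_increase, res.n_decrease) == (10, 10)
        assert res.p == 1.0

    def test_all_increases(self):
        res = score_skew_test([(0.8, 1.1)] * 20)
        assert res.n_increase == 20
        assert res.chi2_statistic == pytest.approx(20.0)
        assert res.p < 0.001

    def test_tie_counts_as_decrease(self):
        res = score_skew_test([(1.0, 1.0), (0.5, 1.5)])
        assert (res.n_increase, res.n_decrease) == (1, 1)

    def test_empty_input_is_error(self):
        with pytest.raises(DataError):
            score_skew_test([])
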