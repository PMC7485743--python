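"""Filtering, TMM normalization, correlation structure and DE testing."""

import math

import numpy as np
import pandas as pd
import pytest

import helpers
from longbat.expression import (
    ExpressionStudy,
    correlation_analysis,
    differential_expression,
    filter_unexpressed,
    normalize_log,
    selection_expression_association,
    tmm_factors,
)


def _study(counts: pd.DataFrame, n_a=2, n_b=2):
    samples = pd.DataFrame(
        {
            "sample_id": list(counts.columns),
            "species": ["A"] * n_a + ["B"] * n_b,
            "sex": (["F", "M"] * ((n_a + n_b) // 2 + 1))[: n_a + n_b],
        }
    ).set_index("sample_id")
    return ExpressionStudy(counts, samples, "A", "B")


class TestFilter:
    def test_and_rule(self):
        counts = pd.DataFrame(
            {
                "a1": [0, 0, 5],
                "a2": [0, 0, 5],
                "b1": [0, 3, 5],
                "b2": [0, 2, 5],
            },
            index=["both_zero", "zero_in_A_only", "expressed"],
        )
        out = filter_unexpressed(_study(counts))
        assert list(out.counts.index) == ["zero_in_A_only", "expressed"]

    def test_idempotent(self):
        counts = pd.DataFrame(
            np.random.default_rng(1).poisson(5, size=(20, 4)),
            index=[f"g{i}" for i in range(20)],
            columns=["a1", "a2", "b1", "b2"],
        )
        once = filter_unexpressed(_study(counts))
        twice = filter_unexpressed(once)
        assert once.counts.equals(twice.counts)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            filter_unexpressed(_study(pd.DataFrame(columns=["a1", "a2", "b1", "b2"], dtype=int)))


class TestTMM:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame(
            {"a1": [10, 20, 30], "a2": [10, 20, 30], "b1": [10, 20, 30], "b2": [10, 20, 30]}
        )
        assert tmm_factors(counts).to_numpy() == pytest.approx(np.ones(4), abs=1e-12)

    def test_pure_depth_scaling_unit_factors(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(50, size=200) + 1
        counts = pd.DataFrame({"s1": base, "s2": 3 * base})
        assert tmm_factors(counts).to_numpy() == pytest.approx(np.ones(2), abs=1e-6)

    def test_minority_shift_absorbed_into_factor(self):
        # 10% of genes doubled in sample 2: the doubled genes fall inside the
        # upper M trim, so the factor equalises the effective library of the
        # unchanged majority: lib2 * f2 / (lib1 * f1) -> 1
        rng = np.random.default_rng(3)
        base = rng.poisson(200, size=2000) + 20
        doubled = base.copy()
        doubled[:200] = 2 * doubled[:200]
        counts = pd.DataFrame({"s1": base, "s2": doubled})
        f = tmm_factors(counts)
        lib = counts.sum(axis=0)
        eff_ratio = (lib["s2"] * f["s2"]) / (lib["s1"] * f["s1"])
        assert eff_ratio == pytest.approx(1.0, rel=0.02)

    def test_single_sample_error(self):
        with pytest.raises(ValueError):
            tmm_factors(pd.DataFrame({"s1": [1, 2, 3]}))


class TestNormalize:
    def test_closed_form(self):
        counts = pd.DataFrame({"a1": [999], "a2": [999], "b1": [999], "b2": [999]})
        counts.loc[1] = [10 ** 6 - 999] * 4  # pad so the library size is exactly 1e6
        study = normalize_log(_study(counts))
        assert study.normalized.iloc[0, 0] == pytest.approx(math.log2(1000), abs=1e-9)

    def test_zero_count_maps_to_zero_at_default_pseudocount(self):
        counts = pd.DataFrame(
            {"a1": [0, 100], "a2": [0, 100], "b1": [0, 100], "b2": [0, 100]}
        )
        study = normalize_log(_study(counts))
        assert study.normalized.iloc[0].to_numpy() == pytest.approx(np.zeros(4))

    def test_invariant_to_per_sample_count_scaling(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.poisson(30, size=(300, 4)) + 1, columns=["a1", "a2", "b1", "b2"]
        )
        scaled = counts.copy()
        scaled["a2"] = scaled["a2"] * 7
        norm1 = normalize_log(_study(counts)).normalized
        norm2 = normalize_log(_study(scaled)).normalized
        assert np.abs(norm1.to_numpy() - norm2.to_numpy()).max() < 1e-10


class TestCorrelation:
    def test_matrix_properties_and_duplicates(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(40, size=100)
        counts = pd.DataFrame({"a1": base, "a2": base, "b1": rng.poisson(40, 100), "b2": rng.poisson(40, 100)})
        study = normalize_log(_study(counts))
        out = correlation_analysis(study)
        m = out["matrix"].to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert out["matrix"].loc["a1", "a2"] == pytest.approx(1.0)

    def test_species_structure_raises_intra_above_inter(self):
        truth = helpers.uniform_truth(400, f_species=0.5, direction="none")
        study = helpers.simulated_study(truth, seed=6)
        out = correlation_analysis(study)
        assert out["median_intra"] > out["median_inter"]
        assert out["test"].p_value < 0.01


class TestDifferentialExpression:
    def test_planted_shift_reaches_minimal_exact_p(self):
        # one gene with a huge species shift and near-zero residual: the
        # two-sided exact rank-sum floor at 8 vs 8 is 2 / C(16, 8)
        truth = helpers.uniform_truth(50, f_species=0.0)
        truth.genes.iloc[0] = [8.0, 0.999, 0.0, 0.001, "up_in_A", True, False, False]
        study = helpers.simulated_study(truth, seed=7)
        de = differential_expression(study).set_index("gene_id")
        assert de.loc["g0001", "p_value"] == pytest.approx(2 / math.comb(16, 8))
        assert de.loc["g0001", "log2_fc"] > 0

    def test_null_type_one_error_controlled(self):
        truth = helpers.uniform_truth(2000, f_species=0.0)
        study = helpers.simulated_study(truth, seed=8)
        de = differential_expression(study, fdr_threshold=0.05)
        # raw p at 0.05 should reject at about the nominal rate under the null
        assert (de["p_value"] < 0.05).mean() <= 0.07
        assert de["is_DEG"].mean() <= 0.01

    def test_too_few_samples_error(self):
        counts = pd.DataFrame({"a1": [5], "b1": [5]})
        samples = pd.DataFrame(
            {"sample_id": ["a1", "b1"], "species": ["A", "B"], "sex": ["F", "M"]}
        ).set_index("sample_id")
        study = ExpressionStudy(counts, samples, "A", "B")
        study.normalized = np.log2(counts + 1)
        with pytest.raises(ValueError):
            differential_expression(study)


class TestAssociation:
    def _tables(self, n=200, seed=9, n_psg=5, n_deg=60):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        de = pd.DataFrame(
            {
                "gene_id": genes,
                "log2_fc": rng.normal(size=n),
                "p_value": rng.random(n),
                "fdr": rng.random(n),
                "is_DEG": [i < n_deg for i in range(n)],
            }
        )
        kaks = pd.DataFrame(
            {
                "gene_id": genes,
                "omega": rng.lognormal(-2, 0.8, n),
                "classification": ["positive" if i % (n // n_psg) == 0 else "purifying" for i in range(n)],
            }
        )
        return de, kaks

    def test_independent_structure_not_significant(self):
        de, kaks = self._tables()
        out = selection_expression_association(de, kaks)
        assert out["ks"].p_value > 0.001
        assert out["chi2"].p_value > 0.001
        assert sum(out["table"][0]) + sum(out["table"][1]) == 200

    def test_all_deg_is_empty_stratum_error(self):
        de, kaks = self._tables()
        de["is_DEG"] = True
        with pytest.raises(ValueError, match="stratum"):
            selection_expression_association(de, kaks)

    def test_no_shared_genes_error(self):
        de, kaks = self._tables()
        kaks["gene_id"] = "x" + kaks["gene_id"]
        with pytest.raises(ValueError, match="shared"):
            selection_expression_association(de, kaks)
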