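import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synthrisk import (
    RiskParameters,
    attribute,
    compute_match_state,
    continuous_learn_new,
    discretize_continuous,
    mad,
    nominal_learn_new,
    record_learns_new,
)
from synthrisk.attribution import LEARNED, NOT_LEARNED


class TestNominalRule:
    def test_disagreement_never_learns(self):
        assert nominal_learn_new("a", "b", 0.9) == NOT_LEARNED
        assert nominal_learn_new("a", "b", 0.1) == NOT_LEARNED

    def test_minority_value_match_learns(self):
        # p=0.4: weighted distance 0.6 exceeds sqrt(0.24) ~ 0.4899
        assert nominal_learn_new("Hispanic", "Hispanic", 0.4) == LEARNED

    def test_zero_proportion_is_logic_error(self):
        with pytest.raises(ValueError):
            nominal_learn_new("a", "a", 0.0)

    @given(st.floats(min_value=0.001, max_value=1.0))
    @settings(max_examples=200, derandomize=True)
    def test_exact_match_learns_iff_minority(self, p):
        # (1-p) > sqrt(p(1-p))  <=>  p < 1/2
        expected = LEARNED if p < 0.5 else NOT_LEARNED
        assert nominal_learn_new("j", "j", p) == expected


class TestMad:
    def test_worked_example_incomes(self):
        assert mad([70, 100, 130, 65, 95]) == 25.0

    def test_constant_vector(self):
        assert mad([3.0] * 10) == 0.0

    def test_gaussian_consistency_constant(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        assert np.std(x) / mad(x) == pytest.approx(1.48, abs=0.02)


class TestDiscretize:
    def test_perfectly_separated_groups(self):
        cl = discretize_continuous([0, 0, 0, 100, 100])
        assert cl.k == 2
        assert cl.proportions.tolist() == [0.6, 0.6, 0.6, 0.4, 0.4]

    def test_cluster_proportions_partition_unity(self):
        x = np.random.default_rng(3).normal(size=120)
        cl = discretize_continuous(x)
        sizes = np.bincount(cl.labels)
        assert sizes.sum() == len(x)
        assert np.allclose(cl.proportions, sizes[cl.labels] / len(x))

    def test_majority_rule_finds_three_components(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-10, 0.5, 100), rng.normal(0, 0.5, 100),
                            rng.normal(10, 0.5, 100)])
        assert discretize_continuous(x).k == 3

    def test_all_identical_single_cluster(self):
        cl = discretize_continuous([5.0] * 8)
        assert cl.k == 1
        assert np.all(cl.proportions == 1.0)

    def test_deterministic_without_seed(self):
        x = np.random.default_rng(9).normal(size=200)
        a = discretize_continuous(x)
        b = discretize_continuous(x)
        assert a.k == b.k and np.array_equal(a.labels, b.labels)


class TestContinuousRule:
    def test_close_synthetic_value_learns(self):
        # |95-100| weighted by any p_s <= 1 is under 1.48*25 = 37
        assert continuous_learn_new(95, 100, 1.0, 25.0) == LEARNED
        assert continuous_learn_new(95, 100, 0.2, 25.0) == LEARNED

    def test_distant_synthetic_value_does_not_learn(self):
        # |70-110| = 40 with p_s=1 is not under 37
        assert continuous_learn_new(70, 110, 1.0, 25.0) == NOT_LEARNED

    def test_exact_value_always_learns_given_spread(self):
        assert continuous_learn_new(50, 50, 1.0, 0.001) == LEARNED

    @given(st.floats(min_value=1.0, max_value=5.0),
           st.floats(min_value=0.01, max_value=1.0))
    @settings(max_examples=100, derandomize=True)
    def test_widening_multiplier_monotone(self, mult, p_s):
        base = continuous_learn_new(70, 110, p_s, 25.0, multiplier=mult)
        wider = continuous_learn_new(70, 110, p_s, 25.0, multiplier=mult * 2)
        assert not (base == LEARNED and wider == NOT_LEARNED)


class TestRecordLearnsNew:
    def test_boundary_at_least_L_percent(self):
        # 1 of 20 sensitive variables learned = 5% >= L=5%
        assert record_learns_new([1 / 20], L=5) == 1
        assert record_learns_new([1 / 20 - 1e-9], L=5) == 0

    def test_no_learned_variables(self):
        assert record_learns_new([0.0, 0.0], L=5) == 0

    def test_any_partner_rule(self):
        assert record_learns_new([0.0, 0.6], L=5) == 1

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=5),
           st.floats(min_value=0, max_value=100))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_L(self, fractions, L):
        lower = max(0.0, L - 10.0)
        assert record_learns_new(fractions, lower) >= record_learns_new(fractions, L)


class TestAttributePipeline:
    def test_worked_example_every_matched_record_learns(self, worked):
        population, real, synthetic = worked
        ms = compute_match_state(real, synthetic, population, ["Origin"])
        attr = attribute(real, synthetic, ms)
        # income clusters are tight relative to 1.48*MAD=37, so all pairs learn
        assert attr.R.tolist() == [1, 1, 1, 1, 1]

    def test_r_defined_only_for_matched_records(self, worked):
        population, real, synthetic = worked
        sub = synthetic.records.iloc[[2]].reset_index(drop=True)
        from synthrisk import Dataset
        syn2 = Dataset(sub, synthetic.meta, "synthetic_sample")
        ms = compute_match_state(real, syn2, population, ["Origin"])
        attr = attribute(real, syn2, ms)
        assert np.all(attr.R[ms.I == 0] == 0)
        assert set(d["s"] for d in attr.detail) == set(np.flatnonzero(ms.I))

    def test_no_sensitive_variables_degrades_conservatively(self, worked):
        from synthrisk import Dataset
        population, real, synthetic = worked
        meta = [m for m in real.meta if m.role == "quasi_identifier"]
        real2 = Dataset(real.records[["Origin"]], meta, "real_sample")
        syn2 = Dataset(synthetic.records[["Origin"]], meta, "synthetic_sample")
        ms = compute_match_state(real2, syn2, population, ["Origin"])
        attr = attribute(real2, syn2, ms)
        assert attr.no_sensitive_variables
        assert np.all(attr.R[ms.I == 1] == 1)

    def test_missing_sensitive_value_skipped(self, worked):
        from synthrisk import Dataset
        population, real, synthetic = worked
        df = real.records.copy()
        df.loc[4, "Income"] = np.nan  # North African real income unknown
        real2 = Dataset(df, real.meta, "real_sample")
        ms = compute_match_state(real2, synthetic, population, ["Origin"])
        attr = attribute(real2, synthetic, ms)
        det = {d["s"]: d for d in attr.detail}
        verdicts = det[4]["partners"][0]["verdicts"]
        assert verdicts["Income"] == "skipped_missing"
        # with no applicable variable left the pair is conservatively learned
        assert attr.R[4] == 1
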