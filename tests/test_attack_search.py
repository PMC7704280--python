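import itertools

import numpy as np
import pandas as pd
import pytest

from synthrisk import (
    AttackConfig,
    Dataset,
    RiskParameters,
    SearchLimits,
    VariableMeta,
    apply_generalization,
    assess_config,
    control_synthetics,
    enumerate_configs,
    max_risk_search,
    sample_adjustments,
)
from synthrisk.attack_search import AttackSearchError


AGE_H = [{"type": "bands", "width": 10}, {"type": "suppress"}]
ZIP_H = [{"type": "prefix", "length": 4}, {"type": "prefix", "length": 3}]


def small_dataset():
    meta = [
        VariableMeta("age", role="quasi_identifier", kind="continuous", hierarchy=AGE_H),
        VariableMeta("zip", role="quasi_identifier", kind="nominal", hierarchy=ZIP_H),
        VariableMeta("sex", role="quasi_identifier", kind="binary"),
        VariableMeta("dx", role="sensitive", kind="nominal"),
    ]
    df = pd.DataFrame(
        {
            "age": [37.0, 42.0, 37.0, 65.0, 23.0, 51.0],
            "zip": ["98101", "98101", "98105", "10001", "10002", "98101"],
            "sex": ["f", "m", "f", "f", "m", "m"],
            "dx": ["a", "b", "a", "c", "b", "a"],
        }
    )
    return Dataset(df, meta, "population")


class TestApplyGeneralization:
    def test_ten_year_band(self):
        ds = small_dataset()
        out = apply_generalization(ds, AttackConfig(("age",), (1,)))
        assert out.records["age"].iloc[0] == "30-39"
        assert out.records["age"].iloc[3] == "60-69"
        assert out.meta_for("age").kind == "nominal"

    def test_zip_prefix(self):
        ds = small_dataset()
        out = apply_generalization(ds, AttackConfig(("zip",), (2,)))
        assert out.records["zip"].iloc[0] == "981**"

    def test_level_zero_is_identity(self):
        ds = small_dataset()
        out = apply_generalization(ds, AttackConfig(("zip", "sex"), (0, 0)))
        pd.testing.assert_frame_equal(out.records, ds.records)

    def test_suppression_collapses_to_star(self):
        ds = small_dataset()
        out = apply_generalization(ds, AttackConfig(("age",), (2,)))
        assert set(out.records["age"]) == {"*"}

    def test_level_beyond_depth_rejected(self):
        ds = small_dataset()
        with pytest.raises(AttackSearchError, match="exceeds hierarchy depth"):
            apply_generalization(ds, AttackConfig(("sex",), (1,)))


class TestEnumerate:
    def qis(self, n, depths=None):
        depths = depths or [0] * n
        return [
            VariableMeta(
                f"q{i}", role="quasi_identifier", kind="nominal",
                hierarchy=[{"type": "suppress"}] * depths[i] or None,
            )
            for i in range(n)
        ]

    def test_two_plain_qis_three_subsets(self):
        cfgs = enumerate_configs(self.qis(2))
        assert len(cfgs) == 3
        assert {c.qi_subset for c in cfgs} == {("q0",), ("q1",), ("q0", "q1")}

    def test_two_qis_with_one_extra_level_each(self):
        cfgs = enumerate_configs(self.qis(2, [1, 1]))
        assert len(cfgs) == 8  # 2 + 2 + 4

    def test_nine_plain_qis(self):
        assert len(enumerate_configs(self.qis(9))) == 511  # 2^9 - 1

    def test_enumeration_order_deterministic(self):
        a = enumerate_configs(self.qis(3, [1, 0, 1]))
        b = enumerate_configs(self.qis(3, [1, 0, 1]))
        assert a == b

    def test_cap_exceeded_raises_with_instruction(self):
        with pytest.raises(AttackSearchError, match="max-configs"):
            enumerate_configs(self.qis(9), SearchLimits(max_configs=100))

    def test_truncation_keeps_guaranteed_configs(self):
        cfgs = enumerate_configs(self.qis(9), SearchLimits(max_configs=100, truncate=True))
        subsets = {c.qi_subset for c in cfgs}
        assert tuple(f"q{i}" for i in range(9)) in subsets  # all-QIs raw
        for i in range(9):
            assert (f"q{i}",) in subsets
        assert len(cfgs) <= 100

    def test_continuous_qi_without_hierarchy_rejected(self):
        meta = [VariableMeta("age", role="quasi_identifier", kind="continuous")]
        with pytest.raises(AttackSearchError, match="binning hierarchy"):
            enumerate_configs(meta)

    def test_continuous_qi_never_enumerated_raw(self):
        meta = [
            VariableMeta("age", role="quasi_identifier", kind="continuous",
                         hierarchy=AGE_H),
        ]
        for cfg in enumerate_configs(meta):
            assert all(l >= 1 for l in cfg.levels)


class TestMaxRiskSearch:
    def triplet(self, seed=0):
        pop = small_dataset()
        rng = np.random.default_rng(seed)
        real = Dataset(pop.records.iloc[[0, 1, 3, 4]].reset_index(drop=True),
                       pop.meta, "real_sample")
        syn = control_synthetics(real, "permute", rng)
        return pop, real, syn

    def test_single_config_equals_direct_assessment(self, worked):
        population, real, synthetic = worked
        params = RiskParameters(seed=3)
        searched = max_risk_search(real, synthetic, population, params)
        adj = sample_adjustments(real.n, 1, params, np.random.default_rng(3))
        direct = assess_config(real, synthetic, population, ["Origin"], params, adj=adj)
        assert searched.overall == pytest.approx(direct.overall)
        assert searched.winning_config["qi_subset"] == ["Origin"]

    def test_max_dominates_every_config(self):
        pop, real, syn = self.triplet()
        params = RiskParameters(seed=5)
        rep = max_risk_search(real, syn, pop, params)
        adj = sample_adjustments(real.n, 1, params, np.random.default_rng(5))
        for cfg in enumerate_configs(real.meta):
            r = assess_config(
                apply_generalization(real, cfg),
                apply_generalization(syn, cfg),
                apply_generalization(pop, cfg),
                list(cfg.qi_subset), params, adj=adj,
            )
            assert rep.overall >= r.overall - 1e-12

    def test_exhaustive_oracle_agreement(self):
        # brute force outside the search harness: same argmax value
        pop, real, syn = self.triplet(seed=2)
        params = RiskParameters(seed=2)
        adj = sample_adjustments(real.n, 1, params, np.random.default_rng(2))
        best = -1.0
        for cfg in enumerate_configs(real.meta):
            r = assess_config(
                apply_generalization(real, cfg),
                apply_generalization(syn, cfg),
                apply_generalization(pop, cfg),
                list(cfg.qi_subset), params, adj=adj,
            )
            best = max(best, r.overall)
        rep = max_risk_search(real, syn, pop, params)
        assert rep.overall == pytest.approx(best, abs=1e-12)

    def test_deterministic_given_seed(self):
        pop, real, syn = self.triplet()
        params = RiskParameters(seed=9)
        a = max_risk_search(real, syn, pop, params)
        b = max_risk_search(real, syn, pop, params)
        assert a.overall == b.overall
        assert a.winning_config == b.winning_config
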