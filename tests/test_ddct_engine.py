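"""Pairwise ddCt ratios: hand-computed values and structural invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cypcna import (
    MissingDataError,
    SamplePair,
    gene_relative_cn,
    mean_ct,
    pair_ratio_table,
    pairwise_ratio,
)

from conftest import make_ct_table


def two_sample_table(panel, tumour_cts, control_cts):
    rows = []
    for gene, ct in tumour_cts.items():
        rows.append(("T", gene, 1, ct))
    for gene, ct in control_cts.items():
        rows.append(("C", gene, 1, ct))
    return make_ct_table(rows, panel)


PAIR = SamplePair("P", "T", "C", "blood")


class TestMeanCt:
    @pytest.mark.parametrize(
        "cts,expected",
        [([25.0, 25.2], 25.1), ([27.4], 27.4), ([24.0, float("nan"), 24.6], 24.3)],
    )
    def test_replicate_mean_ignores_missing(self, panel, cts, expected):
        rows = [("T", "ALB", i + 1, ct) for i, ct in enumerate(cts)]
        table = make_ct_table(rows, panel)
        assert mean_ct(table, "T", "ALB") == pytest.approx(expected)

    def test_all_missing_raises(self, panel):
        table = make_ct_table([("T", "ALB", 1, float("nan"))], panel)
        with pytest.raises(MissingDataError, match="ALB"):
            mean_ct(table, "T", "ALB")

    def test_max_ct_censoring(self, panel):
        table = make_ct_table([("T", "ALB", 1, 25.0), ("T", "ALB", 2, 39.0)], panel)
        assert mean_ct(table, "T", "ALB", max_ct=35.0) == pytest.approx(25.0)


class TestPairwiseRatio:
    def test_one_cycle_shift_halves_ratio(self, panel):
        table = two_sample_table(
            panel, {"CYP2C8": 25.0, "ALB": 24.0}, {"CYP2C8": 25.0, "ALB": 25.0}
        )
        r = pairwise_ratio(table, PAIR, "CYP2C8", "ALB")
        assert r.delta_delta_ct == pytest.approx(1.0)
        assert r.ratio == pytest.approx(0.5)

    def test_identical_cts_give_unity(self, panel):
        table = two_sample_table(
            panel, {"CYP2C8": 25.0, "ALB": 24.0}, {"CYP2C8": 25.0, "ALB": 24.0}
        )
        assert pairwise_ratio(table, PAIR, "CYP2C8", "ALB").ratio == pytest.approx(1.0)

    def test_self_comparison_is_exactly_one(self, panel, ok18_like):
        _, ct, pair, _ = ok18_like
        r = pairwise_ratio(ct, pair, "ALB", "ALB")
        assert r.ratio == 1.0 and r.delta_delta_ct == 0.0

    def test_ratio_matches_ddct_exactly(self, panel, ok18_like):
        _, ct, pair, _ = ok18_like
        table = pair_ratio_table(ct, pair, panel)
        np.testing.assert_array_equal(
            table["ratio"].to_numpy(), 2.0 ** (-table["delta_delta_ct"].to_numpy())
        )


class TestInvariants:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_reciprocity_under_random_cts(self, seed):
        """R(g,h) * R(h,g) = 1 for every ordered pair, any Ct configuration."""
        from cypcna import CallingConfig, default_panel

        panel, config = default_panel(), CallingConfig()
        rng = np.random.default_rng(seed)
        genes = panel.names
        table = two_sample_table(
            panel,
            {g: 20 + 10 * rng.random() for g in genes},
            {g: 20 + 10 * rng.random() for g in genes},
        )
        ratios = pair_ratio_table(table, PAIR, panel, config)
        lookup = {
            (r.gene_numerator, r.gene_denominator): r.ratio
            for r in ratios.itertuples()
        }
        for g, h in itertools.combinations(genes, 2):
            assert lookup[(g, h)] * lookup[(h, g)] == pytest.approx(1.0, rel=1e-12)

    def test_dose_offset_invariance(self, panel, config, ok18_like):
        """Adding a constant to every Ct of one sample leaves ratios unchanged."""
        from cypcna import CtTable

        _, ct, pair, _ = ok18_like
        base = pair_ratio_table(ct, pair, panel, config)
        shifted_df = ct.data.copy()
        shifted_df.loc[shifted_df["sample_id"] == "OK18_T", "ct"] += 3.7
        shifted = pair_ratio_table(CtTable(shifted_df, panel), pair, panel, config)
        np.testing.assert_allclose(
            base["ratio"].to_numpy(), shifted["ratio"].to_numpy(), rtol=1e-9
        )

    def test_control_self_pairing_sets_everything_to_one(self, panel, config, ok18_like):
        """Intrasample normalization of a diploid control gives R = 1 for all."""
        from cypcna import CtTable

        _, ct, _, _ = ok18_like
        dup = ct.data[ct.data["sample_id"] == "OK18_C"].copy()
        dup["sample_id"] = "OK18_C2"
        merged = CtTable(
            __import__("pandas").concat([ct.data, dup], ignore_index=True)[
                ["sample_id", "gene", "allele_label", "replicate", "ct"]
            ],
            panel,
        )
        self_pair = SamplePair("ctrl", "OK18_C2", "OK18_C", "blood")
        ratios = pair_ratio_table(merged, self_pair, panel, config)
        assert ratios["ratio"].to_numpy() == pytest.approx(1.0)
        for gene in panel.names:
            assert gene_relative_cn(ratios, gene).mean_ratio == pytest.approx(1.0)


class TestGeneRelativeCN:
    def test_mean_sd_partner_count(self, panel, ok18_like):
        _, ct, pair, _ = ok18_like
        ratios = pair_ratio_table(ct, pair, panel)
        cn = gene_relative_cn(ratios, "CYP2C8")
        assert cn.n_partners == 9  # ten-gene panel: nine partners
        assert cn.mean_ratio == pytest.approx(0.8)
        assert cn.sd_ratio == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_mean(self, panel):
        import pandas as pd

        ratios = pd.DataFrame(
            {
                "patient_id": ["P"] * 2,
                "gene_numerator": ["ALB"] * 2,
                "gene_denominator": ["TBP", "B2M"],
                "delta_delta_ct": [0.0, -1.0],
                "ratio": [1.0, 2.0],
            }
        )
        cn = gene_relative_cn(ratios, "ALB")
        assert cn.mean_ratio == pytest.approx(1.5)
        assert cn.n_partners == 2

    def test_no_partners_raises(self, panel):
        import pandas as pd

        with pytest.raises(MissingDataError):
            gene_relative_cn(pd.DataFrame({"gene_numerator": [], "ratio": [],
                                           "patient_id": []}), "ALB")
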