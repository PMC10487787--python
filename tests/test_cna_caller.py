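"""Scoring, calling, reference validation and absolute quantification."""

import itertools

import numpy as np
import pytest

from cypcna import (
    CallingConfig,
    CypCnaError,
    GeneScoreCard,
    SamplePair,
    SimulationConfig,
    TooFewReferencesError,
    absolute_cn,
    absolute_from_mean_ratio,
    call_from_score_sum,
    call_pair,
    pair_ratio_table,
    score_gene,
    score_pair,
    score_ratio,
    select_references,
    simulate_pair,
    tumour_fraction,
)

from conftest import OK18_SCORE_SUMS


class TestScoreRatio:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (1.0, 0),
            (0.80, 0),     # band boundaries are inclusive
            (1.25, 0),
            (0.799, -1),
            (1.251, +1),
            (1.30, +1),
            (0.583, -1),   # liver-metastasis CYP2C8 mean
        ],
    )
    def test_band_scoring(self, config, ratio, expected):
        assert score_ratio(ratio, config) == expected

    def test_nonpositive_ratio_rejected(self, config):
        with pytest.raises(CypCnaError):
            score_ratio(0.0, config)


class TestScoreGene:
    @pytest.mark.parametrize(
        "score_sum,expected_call",
        [(-5, "deletion"), (-8, "deletion"), (6, "multiplication"),
         (8, "multiplication"), (3, "none"), (-4, "none"), (0, "none")],
    )
    def test_threshold_calls(self, score_sum, expected_call):
        assert call_from_score_sum(score_sum, 5) == expected_call

    def test_score_gene_tallies_partners(self, config):
        ratios = {"ALB": 0.5, "TBP": 0.7, "B2M": 1.0, "MPO": 1.4}
        card = score_gene("P", "CYP2C8", ratios, config)
        assert card.per_partner_scores == {"ALB": -1, "TBP": -1, "B2M": 0, "MPO": 1}
        assert card.score_sum == -1 and card.call == "none"

    def test_high_mean_without_enough_votes_is_no_call(self, config):
        # mean 1.34 > 1.25 but only 3 partners vote +1: stays unflagged
        ratios = {f"G{i}": r for i, r in enumerate(
            [1.6, 1.6, 1.6, 1.24, 1.24, 1.24, 1.24, 1.24, 1.1])}
        card = score_gene("P", "BCKDHA", ratios, config)
        assert np.mean(list(ratios.values())) > config.upper_bound
        assert card.score_sum == 3 and card.call == "none"

    def test_scorecard_checks_partner_sum(self):
        with pytest.raises(CypCnaError):
            GeneScoreCard("P", "ALB", 2, "none", {"TBP": 1})

    def test_threshold_monotonicity(self):
        """Raising the threshold never converts none into an alteration."""
        for score_sum in range(-9, 10):
            called = [call_from_score_sum(score_sum, thr) for thr in range(1, 10)]
            # once a call becomes none at some threshold it stays none
            seen_none = False
            for c in called:
                if seen_none:
                    assert c == "none"
                seen_none = seen_none or c == "none"


def cards_from_sums(sums):
    return {
        gene: GeneScoreCard("OK18", gene, s, call_from_score_sum(s, 5))
        for gene, s in sums.items()
    }


class TestSelectReferences:
    def test_primary_tumour_reference_set(self, panel, config):
        cards = cards_from_sums(OK18_SCORE_SUMS["primary"])
        assert select_references(cards, panel, config) == [
            "ALB", "B2M", "BCKDHA", "CD36", "MPO", "TBP"
        ]

    def test_liver_metastasis_reference_set(self, panel, config):
        cards = cards_from_sums(OK18_SCORE_SUMS["liver_met"])
        assert select_references(cards, panel, config) == [
            "B2M", "BCKDHA", "CD36", "MPO", "TBP"
        ]

    def test_targets_never_selected(self, panel, config):
        cards = cards_from_sums({g: 0 for g in panel.names})
        refs = select_references(cards, panel, config)
        assert "CYP2C8" not in refs and "CYP3A4" not in refs

    def test_all_flagged_raises(self, panel, config):
        cards = cards_from_sums({g: 9 for g in panel.names})
        with pytest.raises(TooFewReferencesError):
            select_references(cards, panel, config)


class TestAbsoluteCN:
    def test_published_primary_tumour_value(self, config):
        assert absolute_from_mean_ratio(0.80, config) == pytest.approx(1.60)

    def test_hand_computed_reference_mean(self, panel, config):
        import pandas as pd

        refs = ["ALB", "TBP", "B2M"]
        ratios = pd.DataFrame(
            {
                "patient_id": ["P"] * 3,
                "gene_numerator": ["CYP2C8"] * 3,
                "gene_denominator": refs,
                "delta_delta_ct": [0.0] * 3,
                "ratio": [0.5, 0.5, 0.6],
            }
        )
        cn = absolute_cn(ratios, "CYP2C8", refs, panel, config)
        assert cn.copy_number == pytest.approx(2 * 0.5333333, rel=1e-5)
        assert cn.n_references_used == 3

    def test_reference_gene_excludes_itself(self, panel, config, ok18_like):
        _, ct, pair, _ = ok18_like
        ratios = pair_ratio_table(ct, pair, panel, config)
        refs = ["ALB", "TBP", "B2M"]
        cn = absolute_cn(ratios, "ALB", refs, panel, config)
        assert cn.n_references_used == 2
        assert "ALB" not in cn.reference_genes

    def test_control_self_pairing_is_diploid(self, panel, config):
        sim = SimulationConfig(noise_sd=0.0, seed=3)  # all genes diploid
        ct, _ = simulate_pair(sim, "P")
        pair = SamplePair("P", "P_T", "P_C", "blood")
        result = call_pair(ct, pair, panel, config)
        assert result.table["copy_number"].to_numpy() == pytest.approx(2.0)
        assert (result.table["call"] == "none").all()


class TestTumourFraction:
    @pytest.mark.parametrize(
        "cn,direction,fraction",
        [
            (1.60, "loss", 0.40),   # 40% of cells with a one-copy loss
            (2.0, "none", 0.0),
            (1.08, "loss", 0.92),   # deletion in essentially all cells
            (2.5, "gain", 0.5),
            (2.05, "none", 0.0),    # inside the no-call band
        ],
    )
    def test_single_copy_event_model(self, config, cn, direction, fraction):
        d, f = tumour_fraction(cn, config)
        assert d == direction
        assert f == pytest.approx(fraction)

    @pytest.mark.parametrize("cn", [0.5, 3.5])
    def test_outside_model_domain_omits_fraction(self, config, cn):
        d, f = tumour_fraction(cn, config)
        assert f is None
        assert d == ("loss" if cn < 2 else "gain")


class TestScoringProperties:
    def test_antisymmetry_and_zero_total(self, panel, config):
        """With a reciprocal band, score(g,h) = -score(h,g), so the panel's
        score sums cancel to zero."""
        rng = np.random.default_rng(11)
        sim = SimulationConfig(
            true_cn={"CYP2C8": 1.0, "F5": 3.0},
            noise_sd=0.15,
            seed=int(rng.integers(2**31)),
        )
        ct, _ = simulate_pair(sim, "P")
        pair = SamplePair("P", "P_T", "P_C", "blood")
        ratios = pair_ratio_table(ct, pair, panel, config)
        cards = score_pair(ratios, panel, config)
        for g, h in itertools.combinations(panel.names, 2):
            assert cards[g].per_partner_scores[h] == -cards[h].per_partner_scores[g]
        assert sum(c.score_sum for c in cards.values()) == 0

    def test_brute_force_rescoring_oracle(self, panel, config, ok18_like):
        """score_pair agrees with independently recomputing every ratio from
        raw mean Cts and tallying band votes."""
        from cypcna import mean_ct

        _, ct, pair, _ = ok18_like
        ratios = pair_ratio_table(ct, pair, panel, config)
        cards = score_pair(ratios, panel, config)
        for g in panel.names:
            total = 0
            for h in panel.names:
                if h == g:
                    continue
                ddct = (
                    mean_ct(ct, pair.tumour_sample_id, g)
                    - mean_ct(ct, pair.tumour_sample_id, h)
                ) - (
                    mean_ct(ct, pair.control_sample_id, g)
                    - mean_ct(ct, pair.control_sample_id, h)
                )
                r = 2.0 ** (-ddct)
                total += 0 if 0.8 <= r <= 1.25 else (-1 if r < 0.8 else 1)
            assert cards[g].score_sum == total
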