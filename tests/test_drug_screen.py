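"""Drug mechanisms, Matrix Content Score, and strategy classification."""

import numpy as np
import pytest

import fibrosex as fx
from fibrosex.drug_screen import DrugScreenConfig, OutputCategories
from fibrosex.exceptions import ModelValidationError, ProtocolError
from fibrosex.network_io import DrugTarget


@pytest.fixture(scope="module")
def dcfg():
    from fibrosex.synthetic_data import mini_output_categories

    return DrugScreenConfig(categories=mini_output_categories())


class TestMatrixContentScore:
    @pytest.mark.parametrize(
        "m, p, i, minus, plus",
        [
            (0.0, 0.0, 0.0, 0.0, 0.0),
            (1.0, 0.0, 0.0, 1.0, 1.0),
            (1.0, 1.0, 1.0, 1.0, 3.0),
            (0.2, 0.5, 0.1, -0.2, 0.8),
        ],
    )
    def test_both_conventions(self, m, p, i, minus, plus):
        assert fx.matrix_content_score(m, p, i) == pytest.approx(minus)
        assert fx.matrix_content_score(m, p, i, "plus") == pytest.approx(plus)

    def test_linear_in_arguments(self):
        base = fx.matrix_content_score(0.3, 0.2, 0.1)
        assert fx.matrix_content_score(0.6, 0.4, 0.2) == pytest.approx(2 * base)

    def test_unknown_convention_errors(self):
        with pytest.raises(ProtocolError):
            fx.matrix_content_score(0, 0, 0, "times")


class TestOutputCategories:
    def test_overlapping_panels_rejected(self):
        with pytest.raises(ModelValidationError, match="disjoint"):
            OutputCategories(matrix=("proCI",), protease=("proCI",),
                             inhibitor=("TIMP1",))

    def test_members_must_exist_in_model(self, mini):
        cats = OutputCategories(matrix=("proCI",), protease=("proMMP99",),
                                inhibitor=("TIMP1",))
        with pytest.raises(ModelValidationError, match="proMMP99"):
            cats.validate_against(mini)

    def test_restriction_to_model(self, mini):
        cats = OutputCategories.restricted_to(mini)
        assert cats.matrix == ("proCI",)
        assert cats.protease == ("proMMP9",)
        assert cats.inhibitor == ("TIMP1",)


class TestApplyDrug:
    def test_noncompetitive_antagonist_scales_ymax(self, mini):
        drug = DrugTarget("d", ("NFKB",), "antagonist", "noncompetitive")
        out = fx.apply_drug(mini, drug, 0.85)
        assert out.get_species("NFKB").ymax == pytest.approx(0.15)
        assert mini.get_species("NFKB").ymax == 1.0  # original untouched

    def test_competitive_antagonist_scales_producer_weights(self, mini):
        drug = DrugTarget("d", ("proCI",), "antagonist", "competitive")
        out = fx.apply_drug(mini, drug, 0.85)
        for r in out.reactions:
            if r.parsed().product == "proCI":
                assert r.w == pytest.approx(0.15)
        assert out.get_species("proCI").ymax == 1.0

    def test_agonist_adds_or_combined_source(self, mini):
        drug = DrugTarget("d", ("TIMP1",), "agonist", "noncompetitive")
        out = fx.apply_drug(mini, drug, 0.85)
        sources = [r for r in out.reactions
                   if r.parsed().is_source and r.parsed().product == "TIMP1"]
        assert len(sources) == 1 and sources[0].w == pytest.approx(0.85)

    def test_agonist_raises_steady_activity(self, mini):
        # TIMP1 sits at a low basal level; an agonist must strictly raise it
        weights = {"E2": 0.2, "AngII": 0.2, "tension": 0.2}
        before = fx.steady_state(mini, weights)
        drug = DrugTarget("d", ("TIMP1",), "agonist", "competitive")
        after = fx.steady_state(fx.apply_drug(mini, drug, 0.5), weights)
        assert after["TIMP1"] > before["TIMP1"]

    def test_zero_dose_leaves_model_unchanged(self, mini):
        for action, mech in [("agonist", "competitive"),
                             ("antagonist", "competitive"),
                             ("antagonist", "noncompetitive")]:
            out = fx.apply_drug(mini, DrugTarget("d", ("NFKB",), action, mech),
                                0.0)
            assert len(out.reactions) == len(mini.reactions)
            assert [r.w for r in out.reactions] == [r.w for r in mini.reactions]
            assert [s.ymax for s in out.species] == [s.ymax for s in mini.species]

    def test_full_noncompetitive_dose_forces_zero_activity(self, mini):
        drug = DrugTarget("d", ("NFKB",), "antagonist", "noncompetitive")
        out = fx.apply_drug(mini, drug, 1.0)
        ss = fx.steady_state(out, {"AngII": 1.0, "E2": 0.0, "tension": 0.5})
        assert ss["NFKB"] == pytest.approx(0.0, abs=1e-8)

    def test_multi_target_drug_hits_every_target(self, mini):
        drug = DrugTarget("d", ("NFKB", "AT1R"), "antagonist", "noncompetitive")
        out = fx.apply_drug(mini, drug, 0.85)
        assert out.get_species("NFKB").ymax == pytest.approx(0.15)
        assert out.get_species("AT1R").ymax == pytest.approx(0.15)

    def test_unknown_target_and_bad_dose_error(self, mini):
        with pytest.raises(ModelValidationError, match="TGFB1R"):
            fx.apply_drug(mini, DrugTarget("d", ("TGFB1R",), "agonist",
                                           "competitive"))
        with pytest.raises(ProtocolError):
            fx.apply_drug(mini, DrugTarget("d", ("NFKB",), "agonist",
                                           "competitive"), w_drug=1.5)


class TestRunDrugScreen:
    def test_empty_drug_list_empty_result(self, mini, dcfg):
        assert fx.run_drug_screen(mini, [], fx.make_condition("male"),
                                  dcfg) == []

    def test_zero_dose_drug_has_zero_deltas(self, mini):
        from fibrosex.synthetic_data import mini_output_categories

        cfg = DrugScreenConfig(w_drug=0.0,
                               categories=mini_output_categories())
        (eff,) = fx.run_drug_screen(
            mini, [DrugTarget("d", ("NFKB",), "antagonist", "noncompetitive")],
            fx.make_condition("male"), cfg)
        assert all(abs(v) < 1e-9 for v in eff.deltas.values())
        assert eff.mcs_delta == pytest.approx(0.0, abs=1e-9)

    def test_permutation_invariance(self, mini, dcfg):
        drugs = [
            DrugTarget("a", ("NFKB",), "antagonist", "noncompetitive"),
            DrugTarget("b", ("TIMP1",), "agonist", "competitive"),
            DrugTarget("c", ("smad3",), "antagonist", "competitive"),
        ]
        cond = fx.make_condition("female_post")
        fwd = fx.run_drug_screen(mini, drugs, cond, dcfg)
        rev = fx.run_drug_screen(mini, list(reversed(drugs)), cond, dcfg)
        fwd_by_id = {e.drug_id: e.mcs_delta for e in fwd}
        rev_by_id = {e.drug_id: e.mcs_delta for e in rev}
        assert fwd_by_id == pytest.approx(rev_by_id)

    def test_collagen_antagonist_is_antifibrotic(self, mini, dcfg):
        drug = DrugTarget("anti_col", ("proCI",), "antagonist", "competitive")
        (eff,) = fx.run_drug_screen(mini, [drug], fx.make_condition("male"),
                                    dcfg)
        assert eff.matrix_mean < 0
        assert eff.mcs_delta < 0

    def test_category_means_are_means_of_member_deltas(self, mini, dcfg):
        drug = DrugTarget("d", ("NFKB",), "antagonist", "noncompetitive")
        (eff,) = fx.run_drug_screen(mini, [drug], fx.make_condition("male"),
                                    dcfg)
        assert eff.matrix_mean == pytest.approx(eff.deltas["proCI"])
        assert eff.mcs_delta == pytest.approx(
            eff.matrix_mean - eff.protease_mean + eff.inhibitor_mean)


class TestClassifyStrategies:
    def _effect(self, drug_id, mcs):
        return fx.DrugEffect(drug_id=drug_id, deltas={}, matrix_mean=0.0,
                             protease_mean=0.0, inhibitor_mean=0.0,
                             mcs_delta=mcs)

    def test_threshold_labels(self):
        effects = {
            "male": [self._effect("d", -0.2)],
            "female_pre": [self._effect("d", 0.2)],
        }
        tab = fx.classify_drug_strategies(effects)
        assert tab.loc["d", "male"] == "antifibrotic"
        assert tab.loc["d", "female_pre"] == "profibrotic"
        assert bool(tab.loc["d", "divergent"])

    def test_all_zero_deltas_all_neutral(self):
        effects = {c: [self._effect("d", 0.0)]
                   for c in ("male", "female_post", "female_pre")}
        tab = fx.classify_drug_strategies(effects)
        assert (tab[["male", "female_post", "female_pre"]] == "neutral").all().all()
        assert not tab["divergent"].any()

    def test_epsilon_controls_neutral_band(self):
        effects = {"male": [self._effect("d", -0.03)]}
        assert fx.classify_drug_strategies(effects).loc["d", "male"] == "neutral"
        assert fx.classify_drug_strategies(
            effects, epsilon=0.01).loc["d", "male"] == "antifibrotic"

    def test_mismatched_drug_lists_error(self):
        effects = {"male": [self._effect("d1", 0.0)],
                   "female_pre": [self._effect("d2", 0.0)]}
        with pytest.raises(ProtocolError, match="different drug lists"):
            fx.classify_drug_strategies(effects)

    def test_opposite_sign_deltas_in_divergence_table(self, mini, dcfg):
        """End-to-end: an estrogen-pathway agonist produces condition-
        dependent MCS labels on the mini network."""
        drugs = [DrugTarget("protease_block", ("proMMP9",), "antagonist",
                            "noncompetitive"),
                 DrugTarget("col_block", ("proCI",), "antagonist",
                            "competitive")]
        effects = {
            name: fx.run_drug_screen(mini, drugs, fx.make_condition(name),
                                     dcfg)
            for name in ("male", "female_pre")
        }
        tab = fx.classify_drug_strategies(effects, epsilon=0.01)
        assert set(tab.index) == {"protease_block", "col_block"}
        assert tab.loc["col_block", "male"] == "antifibrotic"
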