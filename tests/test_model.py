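"""Model declaration, validation and serialization round-trips."""

import dataclasses

import pytest

from ddrsim.model import (
    ModelSpec,
    ModelValidationError,
    ParamEntry,
    ParameterSet,
    build_default_model,
    load_model,
    parse_rule,
    save_model,
)

EXPECTED_MOLECULES = {
    "Source_of_ROS", "ROS", "DNA", "Ku", "DNAPKcs", "LiIV", "PARP", "LiIII",
    "ATM", "P", "p53_mRNA", "p21_mRNA", "MDM2_mRNA", "GADD45", "p53", "MDM2",
    "p38", "Sen",
}


class TestBuildDefaultModel:
    @pytest.mark.parametrize("preset", ["MRC5", "MCF7", "high_p53"])
    def test_presets_build_and_validate(self, preset):
        model = build_default_model(preset)
        assert {m.name for m in model.molecules} == EXPECTED_MOLECULES
        assert len(model.molecules) == 18
        assert model.n_dna_sites == 50
        model.validate()  # no exception

    def test_unknown_preset_rejected(self):
        with pytest.raises(ModelValidationError, match="unknown preset"):
            build_default_model("HeLa")

    def test_mcf7_differs_only_in_senescence_accumulation_rate(self, mrc5):
        mcf7 = build_default_model("MCF7")
        diffs = {
            k for k in mrc5.parameters
            if mrc5.parameters[k].value != mcf7.parameters[k].value
        }
        assert diffs == {"k_sen_plus"}
        assert mcf7.parameters["k_sen_plus"].value < mrc5.parameters["k_sen_plus"].value

    def test_high_p53_raises_p53_turnover(self, mrc5):
        hp = build_default_model("high_p53")
        assert hp.parameters["k_p53_syn"].value > mrc5.parameters["k_p53_syn"].value
        assert hp.parameters["k_p53_deg"].value > mrc5.parameters["k_p53_deg"].value
        assert hp.parameters["init_p53"].value > mrc5.parameters["init_p53"].value

    def test_every_parameter_has_units_and_provenance(self, mrc5):
        for name, entry in mrc5.parameters.items():
            assert entry.units, name
            assert entry.provenance in (
                "original-NHEJ", "original-senescence", "merged", "new", "calibrated"
            )


class TestValidation:
    def test_dangling_rate_reference_rejected(self, mrc5):
        rules = list(mrc5.rules)
        rules[0] = dataclasses.replace(rules[0], rate="k_does_not_exist")
        broken = dataclasses.replace(mrc5, rules=tuple(rules))
        with pytest.raises(ModelValidationError, match="k_does_not_exist"):
            broken.validate()

    def test_unknown_state_in_rule_rejected(self, mrc5):
        bad = parse_rule(
            "bad: DNA(site~melted) -> DNA(site~ok) @ k_ros_dec [repair]"
        )
        broken = dataclasses.replace(mrc5, rules=(*mrc5.rules, bad))
        with pytest.raises(ModelValidationError, match="melted"):
            broken.validate()

    def test_negative_rate_constant_rejected(self):
        with pytest.raises(ModelValidationError):
            ParamEntry(-1.0, "1/min")

    def test_overrides_reject_unknown_parameter(self, mrc5):
        with pytest.raises(ModelValidationError):
            mrc5.with_overrides({"k_nonexistent": 1.0})

    def test_overrides_change_only_named_value(self, mrc5):
        m2 = mrc5.with_overrides({"k_ros_dec": 0.123})
        assert m2.parameters["k_ros_dec"].value == 0.123
        assert m2.parameters["k_ros_dec"].provenance == (
            mrc5.parameters["k_ros_dec"].provenance
        )
        assert mrc5.parameters["k_ros_dec"].value != 0.123


class TestRuleParsing:
    def test_published_style_rule_round_trips(self):
        text = (
            "h2ax_phos: DNA(site!?~sdsb, h2ax~u) + ATM(state~1, h2ax!-) -> "
            "DNA(site!?~sdsb, h2ax~p) + ATM(state~1, h2ax!-) @ kh2axp1 [focus]"
        )
        rule = parse_rule(text)
        assert rule.name == "h2ax_phos"
        assert rule.rate == "kh2axp1"
        dna = rule.reactants[0][0]
        assert dna.constraint("site").bond == "bound"
        assert dna.constraint("site").states == ("sdsb",)
        assert dna.constraint("h2ax").states == ("u",)

    def test_malformed_rule_rejected(self):
        with pytest.raises(ModelValidationError):
            parse_rule("not a rule at all")

    def test_unpaired_bond_label_rejected(self, mrc5):
        bad = parse_rule("bad: Ku(dna!1) -> Ku(dna!-) @ k_ku_red [repair]")
        broken = dataclasses.replace(mrc5, rules=(*mrc5.rules, bad))
        with pytest.raises(ModelValidationError, match="bond label"):
            broken.validate()


class TestSerialization:
    @pytest.mark.parametrize("preset", ["MRC5", "MCF7"])
    def test_save_load_round_trip_is_identical(self, tmp_path, preset):
        model = build_default_model(preset)
        path = tmp_path / "model.yaml"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.preset == model.preset
        assert loaded.molecules == model.molecules
        assert loaded.rules == model.rules
        assert loaded.functions == model.functions
        assert dict(loaded.parameters) == dict(model.parameters)
        assert loaded.observables == dict(model.observables)

    def test_parameter_file_round_trips_bit_exact(self, tmp_path, mrc5):
        p1, p2 = tmp_path / "a.yaml", tmp_path / "b.yaml"
        save_model(mrc5, p1)
        save_model(load_model(p1), p2)
        assert p1.read_text() == p2.read_text()


class TestShippedPresetFiles:
    @pytest.mark.parametrize("preset", ["MRC5", "MCF7", "high_p53"])
    def test_reference_file_matches_builder(self, preset, tmp_path):
        """The preset files in the package equal freshly built models."""
        from importlib import resources

        ref = resources.files("ddrsim") / "presets" / f"{preset.lower()}.yaml"
        fresh = tmp_path / "fresh.yaml"
        save_model(build_default_model(preset), fresh)
        assert ref.read_text() == fresh.read_text()
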