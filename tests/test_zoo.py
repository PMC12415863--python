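import json

import numpy as np
import pytest

import fishann as fa
from fishann import ActivationKind, Endpoint, Species
from fishann.zoo import (
    DoseRangeError,
    ModelCardError,
    dose_range,
    export_model_card,
    get_entry,
    import_model_card,
    load_transcription,
    load_zoo,
    validate_entry,
    zoo_predict,
)

from conftest import oracle_forward

# Spot checks typed directly from the published weight tables, independent of
# the packaged CSV: (species, endpoint, neuron i, column) -> printed string.
SPOT_CELLS = {
    ("common_carp", "IT", 1, "W1"): "-0.8556",
    ("common_carp", "IT", 10, "Lw"): "0.5051",
    ("common_carp", "WBC", 4, "theta_i"): "10.5147",
    ("common_carp", "RT", 10, "Lw"): "-8.22270",
    ("common_carp", "RBC", 7, "theta_i"): "19.5999",
    ("common_carp", "HGB", 1, "W1"): "-5.6239",
    ("common_carp", "HCT", 8, "W1"): "2.3678",
    ("danube_sturgeon", "IT", 1, "W1"): "-2718.79",
    ("danube_sturgeon", "IT", 1, "theta_i"): "124.454",
    ("danube_sturgeon", "IT", 8, "W1"): "-0.03700",
    ("danube_sturgeon", "IT", 8, "Lw"): "67.11",
    ("danube_sturgeon", "RT", 7, "Lw"): "-94.459",
    ("danube_sturgeon", "HCT", 10, "W1"): "2.475",
    ("rainbow_trout", "IT", 8, "W1"): "958.68",
    ("rainbow_trout", "WBC", 1, "theta_i"): "0.91",
    ("rainbow_trout", "RT", 6, "theta_i"): "22.4",
    ("rainbow_trout", "HGB", 4, "Lw"): "0.17",
    ("rainbow_trout", "HCT", 8, "theta_i"): "-22.395",
}

# Architecture / activation / trainer statements from the accompanying text.
EXPECTED_META = {
    ("common_carp", "IT"): ("1-10-1", "purelin", "traingda"),
    ("common_carp", "RT"): ("1-10-1", "purelin", "traingda"),
    ("common_carp", "WBC"): ("1-6-1", "purelin", "trainrp"),
    ("common_carp", "RBC"): ("1-7-1", "tansig", "traingda"),
    ("common_carp", "HGB"): ("1-5-1", "logsig", "trains"),
    ("common_carp", "HCT"): ("1-7-1", "tansig", "traingda"),
    ("danube_sturgeon", "IT"): ("1-10-1", "logsig", "traingda"),
    ("danube_sturgeon", "RT"): ("1-8-1", "tansig", "traingda"),
    ("danube_sturgeon", "WBC"): ("1-7-1", "purelin", "traingda"),
    ("danube_sturgeon", "RBC"): ("1-5-1", "tansig", "traingda"),
    ("danube_sturgeon", "HGB"): ("1-7-1", "purelin", "trains"),
    ("danube_sturgeon", "HCT"): ("1-10-1", "tansig", "traingda"),
    ("rainbow_trout", "IT"): ("1-8-1", "tansig", "trains"),
    ("rainbow_trout", "RT"): ("1-6-1", "tansig", "traingda"),
    ("rainbow_trout", "WBC"): ("1-5-1", "purelin", "traingda"),
    ("rainbow_trout", "RBC"): ("1-4-1", "logsig", "traingda"),
    ("rainbow_trout", "HGB"): ("1-10-1", "tansig", "trains"),
    ("rainbow_trout", "HCT"): ("1-8-1", "logsig", "traingda"),
}


@pytest.fixture(scope="module")
def zoo():
    return load_zoo()


def test_eighteen_unique_entries(zoo):
    assert len(zoo) == 18
    assert len({(e.species, e.endpoint) for e in zoo}) == 18


def test_metadata_matches_text_statements(zoo):
    for e in zoo:
        arch, act, trainer = EXPECTED_META[(e.species.value, e.endpoint.value)]
        assert e.architecture == arch
        assert e.hidden_activation_tag == act
        assert e.trainer_name == trainer
        assert e.params.output_activation is ActivationKind.PURELIN


def test_transcription_spot_cells():
    rows = {
        (r["species"], r["endpoint"], int(r["i"])): r for r in load_transcription()
    }
    for (sp, ep, i, col), want in SPOT_CELLS.items():
        assert rows[(sp, ep, i)][col] == want, (sp, ep, i, col)


def test_example_bias_value(zoo):
    e = get_entry(Species.DANUBE_STURGEON, Endpoint.IT)
    assert e.params.hidden_biases[0] == 124.454
    assert e.params.output_bias == 87.513


def test_carp_wbc_architecture(zoo):
    assert get_entry("common_carp", "WBC").architecture == "1-6-1"


def test_logsig_entries_use_scaled_dialect_by_default(zoo):
    e = get_entry("danube_sturgeon", "IT")
    assert e.params.hidden_activation is ActivationKind.LOGSIG_SCALED
    e2 = get_entry("danube_sturgeon", "IT", logsig_dialect=ActivationKind.LOGSIG)
    assert e2.params.hidden_activation is ActivationKind.LOGSIG


class TestValidation:
    def test_clean_entry_passes(self, zoo):
        report = validate_entry(get_entry("common_carp", "WBC"))
        assert report.passed

    def test_carp_hct_row_count_conflict_flagged(self, zoo):
        report = validate_entry(get_entry("common_carp", "HCT"))
        arch = {c.name: c for c in report.checks}["architecture_agreement"]
        assert not arch.passed
        assert "1-7-1" in arch.detail and "8 rows" in arch.detail
        assert report.caveats  # printed inconsistency is documented

    def test_trout_it_missing_row_flagged(self, zoo):
        report = validate_entry(get_entry("rainbow_trout", "IT"))
        arch = {c.name: c for c in report.checks}["architecture_agreement"]
        assert not arch.passed
        assert "i=3" in arch.detail and "1-8-1" in arch.detail

    def test_every_anomaly_has_a_caveat(self, zoo):
        for e in zoo:
            report = validate_entry(e)
            if not report.passed:
                assert e.caveats, f"{e.species}/{e.endpoint} fails checks w/o caveat"


class TestPredict:
    def test_matches_forward_on_random_doses(self, zoo):
        rng = np.random.default_rng(11)
        for e in zoo:
            lo, hi = dose_range(e.species)
            for c in rng.uniform(lo, hi, 5):
                got = zoo_predict(e.species, e.endpoint, float(c)).value
                assert got == pytest.approx(
                    fa.forward(e.params, float(c)), rel=1e-12, abs=1e-12
                )

    def test_matches_per_neuron_oracle(self, zoo):
        e = get_entry("common_carp", "WBC")
        got = zoo_predict("common_carp", "WBC", 800.0).value
        assert got == pytest.approx(oracle_forward(e.params, 800.0), rel=1e-9)

    def test_trout_rt_finite_at_tested_doses(self, zoo):
        for c in (400.0, 600.0, 800.0):
            assert np.isfinite(zoo_predict("rainbow_trout", "RT", c).value)

    def test_extrapolation_requires_override(self, zoo):
        with pytest.raises(DoseRangeError):
            zoo_predict("common_carp", "IT", 5000.0)
        pred = zoo_predict("common_carp", "IT", 5000.0, allow_extrapolation=True)
        assert np.isfinite(pred.value)

    def test_prediction_carries_provenance(self, zoo):
        pred = zoo_predict("common_carp", "HCT", 1000.0)
        assert pred.input_scale == "unverified"
        assert pred.scale_used == "raw_uL_per_L"
        assert pred.caveats

    def test_normalized_scale_option(self, zoo):
        e = get_entry("common_carp", "WBC")
        pred = zoo_predict("common_carp", "WBC", 1100.0, scale="normalized01")
        assert pred.value == pytest.approx(fa.forward(e.params, 0.5), rel=1e-12)

    def test_unknown_endpoint_is_lookup_error(self, zoo):
        with pytest.raises((KeyError, ValueError)):
            zoo_predict("common_carp", "LDH", 900.0)


class TestModelCards:
    def test_round_trip_every_entry(self, zoo):
        for e in zoo:
            doc = json.loads(json.dumps(export_model_card(e)))
            back = import_model_card(doc)
            assert back.species is e.species and back.endpoint is e.endpoint
            assert back.architecture == e.architecture
            assert back.trainer_name == e.trainer_name
            assert back.params == e.params
            assert back.neuron_indices == e.neuron_indices
            assert back.caveats == e.caveats

    def test_missing_field_names_it(self, zoo):
        doc = export_model_card(zoo[0])
        del doc["output_bias"]
        with pytest.raises(ModelCardError, match="output_bias"):
            import_model_card(doc)

    def test_minimal_hand_written_card_is_usable(self):
        doc = {
            "species": "common_carp",
            "endpoint": "IT",
            "architecture": "1-1-1",
            "hidden_activation": "purelin",
            "output_activation": "purelin",
            "trainer": "traingda",
            "input_weights": [1.0],
            "hidden_biases": [0.0],
            "output_weights": [1.0],
            "output_bias": 0.0,
            "neuron_indices": [1],
            "input_scale": "raw_uL_per_L",
            "caveats": [],
        }
        entry = import_model_card(doc)
        assert fa.forward(entry.params, 850.0) == pytest.approx(850.0)
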