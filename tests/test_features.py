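"""Feature flags: hand-computed scenarios, boundaries, ground-truth recovery."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxdivert import FEATURE_ORDER, FeatureParams, link_episodes, one_hot_encode
from rxdivert.features import extract_features, from_custody

from conftest import make_ledger

T0 = datetime(2024, 1, 1, 10, 0)
EMPTY_DISC = pd.DataFrame(columns=["stage", "reference", "medication",
                                   "expected_qty", "observed_qty",
                                   "shortfall", "responsible", "txn_id",
                                   "timestamp"])
EMPTY_OFF = pd.DataFrame(columns=["txn_id", "clinician", "event_type",
                                  "timestamp", "interval_start",
                                  "interval_end", "minutes_outside"])


def flags_for(ledger, txn="D1", **kwargs):
    custody = link_episodes(ledger)
    feats = from_custody(custody, EMPTY_DISC, EMPTY_OFF, ledger, **kwargs)
    row = feats.set_index("txn_id").loc[txn]
    return {c: int(row[c]) for c in FEATURE_ORDER}


def _scenario(events):
    rows = [{"txn_id": "D1", "event_type": "DISPENSE", "timestamp": T0,
             "quantity": 2.0}]
    for i, (etype, offset_min, qty, extra) in enumerate(events):
        row = {"txn_id": f"S{i}", "event_type": etype,
               "timestamp": T0 + timedelta(minutes=offset_min),
               "quantity": qty}
        row.update(extra)
        rows.append(row)
    return make_ledger(rows)


def _expect(**on):
    base = {c: 0 for c in FEATURE_ORDER}
    base.update(on)
    return base


@pytest.mark.parametrize(
    "events,expected",
    [
        # lawful: prompt full administration -> nothing flagged
        ([("ADMINISTER", 5, 2.0, {})], _expect()),
        # full waste 4 h 1 min after dispense: late AND full wasting
        ([("WASTE", 241, 2.0, {})],
         _expect(late_wasting=1, full_wasting=1)),
        # waste at exactly 4 h is NOT late (strict inequality)
        ([("WASTE", 240, 2.0, {})], _expect(full_wasting=1)),
        # administer half, never account for the rest
        ([("ADMINISTER", 5, 1.0, {})], _expect(partial_administration=1)),
        # nothing charted at all
        ([], _expect(no_administration=1)),
        # some waste exists but quantity still missing
        ([("WASTE", 10, 1.0, {})], _expect(partial_waste_return=1)),
        # late administration of the full dose
        ([("ADMINISTER", 245, 2.0, {})], _expect(late_administration=1)),
        # administration charted before the dispense (custody sequence)
        ([("ADMINISTER", -10, 2.0, {"link_ref": "D1"})],
         _expect(incorrect_order=1)),
        # administration charts a different medication
        ([("ADMINISTER", 5, 2.0, {"link_ref": "D1",
                                  "medication": "hydromorphone_1mg_inj"})],
         _expect(incorrect_medication=1)),
        # a second clinician settles the dispense
        ([("ADMINISTER", 5, 2.0, {"clinician": "C0002"})],
         _expect(handoffs=1)),
        # lawful partial: administer half, waste the remainder promptly
        ([("ADMINISTER", 5, 1.0, {}), ("WASTE", 15, 1.0, {})],
         _expect(partial_administration=1)),
        # unopened return is lawful
        ([("RETURN", 15, 2.0, {})], _expect()),
    ],
)
def test_flag_semantics_on_constructed_episodes(events, expected):
    assert flags_for(_scenario(events)) == expected


def test_late_threshold_is_strict_at_the_boundary():
    exactly = flags_for(_scenario([("WASTE", 240, 2.0, {})]))
    just_over = flags_for(_scenario([("WASTE", 241, 2.0, {})]))
    assert exactly["late_wasting"] == 0
    assert just_over["late_wasting"] == 1


@given(st.integers(min_value=1, max_value=600))
@settings(max_examples=30, deadline=None)
def test_raising_late_threshold_never_adds_late_flags(minutes):
    ledger = _scenario([("WASTE", 250, 2.0, {})])
    low = flags_for(ledger, params=FeatureParams(
        late_threshold_hours=minutes / 60))
    high = flags_for(ledger, params=FeatureParams(
        late_threshold_hours=(minutes + 60) / 60))
    assert high["late_wasting"] <= low["late_wasting"]


def test_bulk_wasting_needs_three_wastes_in_window():
    rows = []
    for k in range(3):
        rows.append({"txn_id": f"D{k}", "event_type": "DISPENSE",
                     "patient": f"P{k}", "timestamp": T0, "quantity": 2.0})
        rows.append({"txn_id": f"S{k}", "event_type": "WASTE",
                     "patient": f"P{k}", "link_ref": f"D{k}", "quantity": 2.0,
                     "timestamp": T0 + timedelta(minutes=30 + 3 * k)})
    ledger = make_ledger(rows)
    custody = link_episodes(ledger)
    feats = from_custody(custody, EMPTY_DISC, EMPTY_OFF, ledger)
    assert feats["bulk_wasting"].sum() == 3

    # spread the wastes an hour apart: no burst, no flag
    rows2 = [dict(r) for r in rows]
    for k in range(3):
        rows2[2 * k + 1]["timestamp"] = T0 + timedelta(minutes=30 + 60 * k)
    ledger2 = make_ledger(rows2)
    feats2 = from_custody(link_episodes(ledger2), EMPTY_DISC, EMPTY_OFF,
                          ledger2)
    assert feats2["bulk_wasting"].sum() == 0


def test_off_clock_flag_follows_reconciliation_output():
    ledger = _scenario([("ADMINISTER", 5, 2.0, {})])
    off = pd.DataFrame([{"txn_id": "D1", "clinician": "C0001",
                         "event_type": "DISPENSE", "timestamp": T0,
                         "interval_start": T0, "interval_end": T0,
                         "minutes_outside": 120.0}])
    feats = from_custody(link_episodes(ledger), EMPTY_DISC, off, ledger)
    assert feats.set_index("txn_id").at["D1", "off_clock_access"] == 1


def test_supply_shortfalls_emit_their_own_vectors():
    ledger = _scenario([("ADMINISTER", 5, 2.0, {})])
    disc = pd.DataFrame([
        {"stage": "WHL_TO_IIS", "reference": "INV1", "medication": "m",
         "expected_qty": 100.0, "observed_qty": 90.0, "shortfall": 10.0,
         "responsible": "C0002", "txn_id": "I1", "timestamp": T0},
        {"stage": "IIS_TO_ADC", "reference": "ISS1", "medication": "m",
         "expected_qty": 50.0, "observed_qty": 50.0, "shortfall": 0.0,
         "responsible": "C0002", "txn_id": "A1", "timestamp": T0},
    ])
    feats = from_custody(link_episodes(ledger), disc, EMPTY_OFF, ledger)
    assert len(feats) == 2  # one episode + one shortfall (zero excluded)
    sup = feats.set_index("txn_id").loc["I1"]
    assert sup["shipment_shortfall"] == 1 and sup["clinician"] == "C0002"


def test_pain_score_anomaly_window():
    ledger = _scenario([("ADMINISTER", 5, 2.0, {})])
    prn = {"oxycodone_5mg_tab"}
    near = pd.DataFrame([{"timestamp": T0 - timedelta(minutes=30),
                          "clinician": "C0001", "patient": "P0001",
                          "score": 7}])
    far = pd.DataFrame([{"timestamp": T0 - timedelta(minutes=90),
                         "clinician": "C0001", "patient": "P0001",
                         "score": 7}])
    assert flags_for(ledger, pain_scores=near,
                     prn_medications=prn)["pain_score_anomaly"] == 0
    assert flags_for(ledger, pain_scores=far,
                     prn_medications=prn)["pain_score_anomaly"] == 1
    # non-PRN medication never needs a pain score
    assert flags_for(ledger, pain_scores=far,
                     prn_medications={"other_med"})["pain_score_anomaly"] == 0


def test_handoff_emits_secondary_vector_for_settling_clinician():
    ledger = _scenario([("ADMINISTER", 5, 2.0, {"clinician": "C0002"})])
    feats = from_custody(link_episodes(ledger), EMPTY_DISC, EMPTY_OFF, ledger)
    assert len(feats) == 2
    sec = feats[feats["txn_id"].str.contains("::")]
    assert sec["clinician"].iloc[0] == "C0002"
    assert sec["handoffs"].iloc[0] == 1


def test_missing_reconciliation_input_is_hard_error():
    ledger = _scenario([])
    with pytest.raises(ValueError, match="missing reconciliation input"):
        extract_features(None, EMPTY_DISC, EMPTY_OFF, ledger)


class TestGroundTruthRecovery:
    def test_every_injected_behavior_sets_its_flag(self, noise0_result,
                                                   tags_by_behavior):
        """Per-feature sensitivity is 1.0 against injected tags when benign
        noise is off."""
        feats = noise0_result.features.set_index("txn_id")
        assert len(tags_by_behavior) >= 6  # default profiles are diverse
        for behavior, txns in tags_by_behavior.items():
            flagged = feats.loc[sorted(txns), behavior]
            assert (flagged == 1).all(), behavior

    def test_no_untagged_episode_sets_an_injected_flag(self, noise0_result,
                                                       tags_by_behavior):
        """Per-feature specificity is 1.0: without noise, a flag only ever
        fires on a transaction injected with that same behavior."""
        feats = noise0_result.features
        primary = feats[~feats["txn_id"].str.contains("::", regex=False)]
        primary = primary.set_index("txn_id")
        for behavior, txns in tags_by_behavior.items():
            others = primary.loc[~primary.index.isin(txns), behavior]
            assert others.sum() == 0, behavior


class TestOneHot:
    def test_matrix_shape_and_column_census(self, small_result):
        matrix, columns = one_hot_encode(small_result.features)
        assert matrix.shape == (len(small_result.features), 14)
        assert columns == FEATURE_ORDER

    def test_encoding_is_identity_on_binary_flags(self):
        ledger = _scenario([("WASTE", 241, 2.0, {})])
        feats = from_custody(link_episodes(ledger), EMPTY_DISC, EMPTY_OFF,
                             ledger)
        matrix, columns = one_hot_encode(feats)
        np.testing.assert_array_equal(
            matrix, feats[columns].to_numpy(dtype=float))

    def test_all_zero_vector_encodes_to_zero_row(self):
        ledger = _scenario([("ADMINISTER", 5, 2.0, {})])
        feats = from_custody(link_episodes(ledger), EMPTY_DISC, EMPTY_OFF,
                             ledger)
        matrix, _ = one_hot_encode(feats)
        assert matrix.sum() == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no feature vectors"):
            one_hot_encode(pd.DataFrame(columns=FEATURE_ORDER))
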