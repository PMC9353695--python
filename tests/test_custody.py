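"""Custody reconciliation: episode linking, conservation, supply, off-clock."""

from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from rxdivert import link_episodes, off_clock_events, reconcile_supply

from conftest import brute_force_links, make_ledger, random_linking_instance


def _episode(result, txn="X0000"):
    return result.episodes.set_index("dispense_txn").loc[txn]


class TestMissingQuantity:
    def test_fully_settled_dispense_has_zero_missing(self):
        ledger = make_ledger([
            {"txn_id": "D1", "event_type": "DISPENSE", "quantity": 2.0},
            {"txn_id": "S1", "event_type": "ADMINISTER", "quantity": 1.0,
             "source_system": "EMR",
             "timestamp": datetime(2024, 1, 1, 12, 30)},
            {"txn_id": "S2", "event_type": "WASTE", "quantity": 1.0,
             "timestamp": datetime(2024, 1, 1, 12, 40)},
        ])
        ep = _episode(link_episodes(ledger), "D1")
        assert ep["missing_qty"] == pytest.approx(0.0)
        assert ep["administered_qty"] == pytest.approx(1.0)
        assert ep["wasted_qty"] == pytest.approx(1.0)

    def test_uncharted_remainder_is_missing(self):
        """Dispense 2, administer 1, nothing wasted or returned: one unit is
        unaccounted for — the outer-join case investigators care about."""
        ledger = make_ledger([
            {"txn_id": "D1", "event_type": "DISPENSE", "quantity": 2.0},
            {"txn_id": "S1", "event_type": "ADMINISTER", "quantity": 1.0,
             "timestamp": datetime(2024, 1, 1, 12, 30)},
        ])
        ep = _episode(link_episodes(ledger), "D1")
        assert ep["missing_qty"] == pytest.approx(1.0)

    def test_dispense_with_no_events_keeps_episode(self):
        ledger = make_ledger([
            {"txn_id": "D1", "event_type": "DISPENSE", "quantity": 3.0},
        ])
        result = link_episodes(ledger)
        assert len(result.episodes) == 1
        assert _episode(result, "D1")["missing_qty"] == pytest.approx(3.0)

    def test_over_documentation_yields_negative_missing(self):
        ledger = make_ledger([
            {"txn_id": "D1", "event_type": "DISPENSE", "quantity": 1.0},
            {"txn_id": "S1", "event_type": "ADMINISTER", "quantity": 2.0,
             "timestamp": datetime(2024, 1, 1, 13, 0)},
        ])
        ep = _episode(link_episodes(ledger), "D1")
        assert ep["missing_qty"] == pytest.approx(-1.0)  # kept, not clamped


class TestLinkingRules:
    def test_link_ref_beats_time_matching(self):
        ledger = make_ledger([
            {"txn_id": "D1", "event_type": "DISPENSE",
             "timestamp": datetime(2024, 1, 1, 9, 0)},
            {"txn_id": "D2", "event_type": "DISPENSE",
             "timestamp": datetime(2024, 1, 1, 11, 0)},
            {"txn_id": "S1", "event_type": "WASTE", "link_ref": "D1",
             "timestamp": datetime(2024, 1, 1, 11, 30)},
        ])
        result = link_episodes(ledger)
        assert result.links.set_index("event_txn").at["S1", "dispense_txn"] == "D1"

    def test_nearest_preceding_dispense_wins(self):
        ledger = make_ledger([
            {"txn_id": "D1", "event_type": "DISPENSE",
             "timestamp": datetime(2024, 1, 1, 9, 0)},
            {"txn_id": "D2", "event_type": "DISPENSE",
             "timestamp": datetime(2024, 1, 1, 11, 0)},
            {"txn_id": "S1", "event_type": "ADMINISTER",
             "timestamp": datetime(2024, 1, 1, 11, 30)},
        ])
        result = link_episodes(ledger)
        assert result.links.at[0, "dispense_txn"] == "D2"

    def test_same_minute_tie_prefers_smaller_txn_id(self):
        ledger = make_ledger([
            {"txn_id": "D9", "event_type": "DISPENSE",
             "timestamp": datetime(2024, 1, 1, 9, 0)},
            {"txn_id": "D2", "event_type": "DISPENSE",
             "timestamp": datetime(2024, 1, 1, 9, 0)},
            {"txn_id": "S1", "event_type": "ADMINISTER",
             "timestamp": datetime(2024, 1, 1, 9, 30)},
        ])
        result = link_episodes(ledger)
        assert result.links.at[0, "dispense_txn"] == "D2"

    def test_unmatched_administration_is_orphaned_not_guessed(self):
        ledger = make_ledger([
            {"txn_id": "D1", "event_type": "DISPENSE", "patient": "P1",
             "timestamp": datetime(2024, 1, 1, 9, 0)},
            {"txn_id": "S1", "event_type": "ADMINISTER", "patient": "P2",
             "timestamp": datetime(2024, 1, 1, 9, 30)},
        ])
        result = link_episodes(ledger)
        assert len(result.links) == 0
        assert list(result.orphans["event_txn"]) == ["S1"]

    def test_event_outside_window_is_orphaned(self):
        ledger = make_ledger([
            {"txn_id": "D1", "event_type": "DISPENSE",
             "timestamp": datetime(2024, 1, 1, 9, 0)},
            {"txn_id": "S1", "event_type": "WASTE",
             "timestamp": datetime(2024, 1, 2, 10, 0)},  # 25 h later
        ])
        result = link_episodes(ledger)
        assert list(result.orphans["event_txn"]) == ["S1"]

    def test_dangling_link_ref_is_orphaned(self):
        ledger = make_ledger([
            {"txn_id": "D1", "event_type": "DISPENSE"},
            {"txn_id": "S1", "event_type": "WASTE", "link_ref": "D999",
             "timestamp": datetime(2024, 1, 1, 12, 30)},
        ])
        result = link_episodes(ledger)
        assert "link_ref" in result.orphans["reason"].iloc[0]


class TestInvariants:
    def test_episode_count_equals_dispense_count(self, small_result):
        n_disp = (small_result.ledger["event_type"] == "DISPENSE").sum()
        assert len(small_result.custody.episodes) == n_disp

    def test_attached_plus_orphans_account_for_every_settle_event(self, small_result):
        settles = small_result.ledger["event_type"].isin(
            ("ADMINISTER", "WASTE", "RETURN", "TRANSFER")).sum()
        assert len(small_result.custody.links) + len(small_result.custody.orphans) == settles

    def test_conservation_is_exact_for_every_episode(self, small_result):
        ep = small_result.custody.episodes
        resid = ep["dispensed_qty"] - (
            ep["administered_qty"] + ep["wasted_qty"] + ep["returned_qty"]
            + ep["transferred_qty"] + ep["missing_qty"])
        assert (resid.abs() <= 1e-9).all()

    def test_clean_world_reconciles_perfectly(self, noise0_result):
        """Without noise, only injected behaviors leave missing quantity."""
        ep = noise0_result.custody.episodes
        tagged = {t["txn"] for t in noise0_result.truth.tags}
        untouched = ep[~ep["dispense_txn"].isin(tagged)]
        assert (untouched["missing_qty"].abs() <= 1e-9).all()


def test_linking_matches_brute_force_oracle_on_random_instances():
    """Rule-based linking agrees with exhaustive enumeration on 200 random
    instances of <= 50 events."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        ledger = random_linking_instance(rng)
        result = link_episodes(ledger)
        got = dict(zip(result.links["event_txn"], result.links["dispense_txn"]))
        for orphan in result.orphans["event_txn"]:
            got[orphan] = None
        expected = brute_force_links(ledger)
        assert got == expected


class TestSupply:
    def test_full_receipt_has_zero_shortfall(self):
        ledger = make_ledger([
            {"txn_id": "W1", "event_type": "SHIP", "source_system": "WHL",
             "quantity": 100.0, "order_ref": "INV1", "clinician": None},
            {"txn_id": "I1", "event_type": "RECEIVE", "source_system": "IIS",
             "quantity": 100.0, "order_ref": "INV1",
             "timestamp": datetime(2024, 1, 1, 14, 0)},
        ])
        disc = reconcile_supply(ledger)
        row = disc[disc["stage"] == "WHL_TO_IIS"].iloc[0]
        assert row["shortfall"] == pytest.approx(0.0)

    def test_partial_receipt_computes_shortfall(self):
        ledger = make_ledger([
            {"txn_id": "W1", "event_type": "SHIP", "source_system": "WHL",
             "quantity": 100.0, "order_ref": "INV1", "clinician": None},
            {"txn_id": "I1", "event_type": "RECEIVE", "source_system": "IIS",
             "quantity": 90.0, "order_ref": "INV1", "clinician": "C0002",
             "timestamp": datetime(2024, 1, 1, 14, 0)},
        ])
        row = reconcile_supply(ledger).iloc[0]
        assert row["shortfall"] == pytest.approx(10.0)
        assert row["responsible"] == "C0002"

    def test_vault_issue_matches_restock(self):
        ledger = make_ledger([
            {"txn_id": "I1", "event_type": "VAULT_TRANSFER",
             "source_system": "IIS", "quantity": 50.0, "order_ref": "ISS1"},
            {"txn_id": "A1", "event_type": "RESTOCK", "source_system": "ADC",
             "quantity": 50.0, "link_ref": "ISS1",
             "timestamp": datetime(2024, 1, 1, 12, 15)},
        ])
        row = reconcile_supply(ledger).iloc[0]
        assert row["stage"] == "IIS_TO_ADC"
        assert row["shortfall"] == pytest.approx(0.0)

    def test_unreceived_shipment_is_full_shortfall(self):
        ledger = make_ledger([
            {"txn_id": "W1", "event_type": "SHIP", "source_system": "WHL",
             "quantity": 100.0, "order_ref": "INV1", "clinician": None},
        ])
        row = reconcile_supply(ledger).iloc[0]
        assert row["shortfall"] == pytest.approx(100.0)

    def test_overage_retained_and_flagged(self):
        ledger = make_ledger([
            {"txn_id": "W1", "event_type": "SHIP", "source_system": "WHL",
             "quantity": 100.0, "order_ref": "INV1", "clinician": None},
            {"txn_id": "I1", "event_type": "RECEIVE", "source_system": "IIS",
             "quantity": 110.0, "order_ref": "INV1",
             "timestamp": datetime(2024, 1, 1, 14, 0)},
        ])
        row = reconcile_supply(ledger).iloc[0]
        assert row["shortfall"] == pytest.approx(-10.0)
        assert bool(row["overage"])


class TestOffClock:
    def _ledger_with_shift(self, txn_time):
        return make_ledger([
            {"txn_id": "T1", "event_type": "CLOCK_IN", "source_system": "ETC",
             "timestamp": datetime(2024, 1, 1, 7, 0), "quantity": 0.0,
             "medication": None},
            {"txn_id": "T2", "event_type": "CLOCK_OUT", "source_system": "ETC",
             "timestamp": datetime(2024, 1, 1, 19, 0), "quantity": 0.0,
             "medication": None},
            {"txn_id": "D1", "event_type": "DISPENSE", "timestamp": txn_time},
        ])

    def test_on_shift_transaction_not_flagged(self):
        flagged, _ = off_clock_events(
            self._ledger_with_shift(datetime(2024, 1, 1, 12, 0)))
        assert len(flagged) == 0

    def test_after_shift_flagged_with_minutes_outside(self):
        """22:30 against a shift ending 19:00 with 30 min grace is 180
        minutes outside."""
        flagged, _ = off_clock_events(
            self._ledger_with_shift(datetime(2024, 1, 1, 22, 30)),
            grace_minutes=30)
        assert list(flagged["txn_id"]) == ["D1"]
        assert flagged["minutes_outside"].iloc[0] == pytest.approx(180.0)

    def test_within_grace_not_flagged(self):
        flagged, _ = off_clock_events(
            self._ledger_with_shift(datetime(2024, 1, 1, 19, 25)),
            grace_minutes=30)
        assert len(flagged) == 0

    def test_clinician_without_time_clock_is_reported(self):
        ledger = make_ledger([
            {"txn_id": "D1", "event_type": "DISPENSE", "clinician": "C0009"},
        ])
        flagged, skipped = off_clock_events(ledger)
        assert len(flagged) == 0
        assert list(skipped["clinician"]) == ["C0009"]
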