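"""Shared fixtures: small simulated worlds and a brute-force linking oracle."""

from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from rxdivert import RiskParams, SimConfig, run_pipeline
from rxdivert.ingestion import LEDGER_COLUMNS

ZERO_NOISE = {"partial_dose": 0.0, "late_charting": 0.0, "pain_miss": 0.0}


@pytest.fixture(scope="session")
def small_result(tmp_path_factory):
    """A small noisy world run through the whole pipeline."""
    cfg = SimConfig(
        n_clinicians=40,
        n_diverters=2,
        date_range=(date(2024, 1, 1), date(2024, 2, 14)),
        beds=40,
        seed=11,
    )
    return run_pipeline(cfg, tmp_path_factory.mktemp("small_world"))


@pytest.fixture(scope="session")
def noise0_result(tmp_path_factory):
    """A noise-free world: every anomaly traces to an injected behavior."""
    cfg = SimConfig(
        n_clinicians=40,
        n_diverters=2,
        date_range=(date(2024, 1, 1), date(2024, 2, 14)),
        beds=40,
        noise_rates=dict(ZERO_NOISE),
        seed=202,
    )
    # without benign noise, fewer than 2% of scores are nonzero, so the
    # percentile must be taken over the nonzero scores to stay meaningful
    params = RiskParams(percentile_over="nonzero", seed=202)
    return run_pipeline(cfg, tmp_path_factory.mktemp("noise0_world"),
                        params=params)


@pytest.fixture(scope="session")
def tags_by_behavior(noise0_result):
    out: dict[str, set] = {}
    for t in noise0_result.truth.tags:
        out.setdefault(t["behavior"], set()).add(t["txn"])
    return out


# --------------------------------------------------------------------------
# Mini-ledger construction and the independent linking oracle
# --------------------------------------------------------------------------

def make_ledger(rows: list[dict]) -> pd.DataFrame:
    """Build a ledger frame from sparse row dicts (defaults filled in)."""
    defaults = {
        "txn_id": "", "source_system": "ADC", "event_type": "DISPENSE",
        "timestamp": datetime(2024, 1, 1, 12, 0), "clinician": "C0001",
        "patient": "P0001", "medication": "oxycodone_5mg_tab",
        "quantity": 1.0, "unit": "each", "dosage_form": "oral_solid",
        "location": "RX-U01", "order_ref": "", "link_ref": "", "witness": "",
    }
    full = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["txn_id"] = f"X{i:04d}"
        rec.update(row)
        full.append(rec)
    frame = pd.DataFrame(full, columns=LEDGER_COLUMNS)
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    return frame


def brute_force_links(ledger: pd.DataFrame, window_hours: float = 24.0):
    """Independent oracle for episode linking: for every settling event,
    enumerate *all* dispenses, keep the feasible ones (same patient and
    medication, dispense at or before the event, within the window), and
    apply the documented optimum — smallest nonnegative gap, then smallest
    dispense txn_id.  Events with a link_ref use it directly.
    """
    window = timedelta(hours=window_hours)
    disp = ledger[ledger["event_type"] == "DISPENSE"]
    known = set(disp["txn_id"])
    settles = ledger[ledger["event_type"].isin(
        ("ADMINISTER", "WASTE", "RETURN", "TRANSFER"))]
    assignment = {}
    for ev in settles.itertuples(index=False):
        if isinstance(ev.link_ref, str) and ev.link_ref:
            assignment[ev.txn_id] = (ev.link_ref if ev.link_ref in known
                                     else None)
            continue
        best = None
        for d in disp.itertuples(index=False):
            if d.patient != ev.patient:
                continue
            dm, em = d.medication, ev.medication
            same_med = (dm == em) or (pd.isna(dm) and pd.isna(em))
            if not same_med:
                continue
            gap = ev.timestamp - d.timestamp
            if gap < timedelta(0) or gap > window:
                continue
            key = (gap, d.txn_id)
            if best is None or key < best:
                best = key
        assignment[ev.txn_id] = best[1] if best else None
    return assignment


@pytest.fixture(scope="session")
def linking_oracle():
    return brute_force_links


@pytest.fixture(scope="session")
def mini_ledger_factory():
    return make_ledger


def random_linking_instance(rng: np.random.Generator) -> pd.DataFrame:
    """A random custody-linking instance of <= 50 events."""
    n_disp = int(rng.integers(1, 16))
    n_settle = int(rng.integers(0, 35))
    patients = [f"P{i}" for i in range(1, int(rng.integers(2, 5)))]
    meds = ["med_a", "med_b"][: int(rng.integers(1, 3))]
    base = datetime(2024, 3, 1)
    rows = []
    for i in range(n_disp):
        rows.append({
            "txn_id": f"D{i:03d}",
            "event_type": "DISPENSE",
            "timestamp": base + timedelta(minutes=int(rng.integers(0, 2880))),
            "patient": str(rng.choice(patients)),
            "medication": str(rng.choice(meds)),
            "quantity": float(rng.integers(1, 4)),
        })
    for i in range(n_settle):
        row = {
            "txn_id": f"S{i:03d}",
            "event_type": str(rng.choice(
                ["ADMINISTER", "WASTE", "RETURN", "TRANSFER"])),
            "timestamp": base + timedelta(minutes=int(rng.integers(0, 4320))),
            "patient": str(rng.choice(patients)),
            "medication": str(rng.choice(meds)),
            "quantity": float(rng.integers(1, 4)),
        }
        u = rng.random()
        if u < 0.2 and n_disp:
            row["link_ref"] = f"D{int(rng.integers(0, n_disp)):03d}"
        elif u < 0.25:
            row["link_ref"] = "D999"  # dangling reference
        rows.append(row)
    return make_ledger(rows)
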