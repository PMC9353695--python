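"""One-hot diversion-risk features per custody episode and supply event.

Each custody episode (one per cabinet dispense) yields one binary feature
vector; each supply-stage reconciliation with a positive shortfall yields one
more, attributed to the responsible technician.  Flag semantics (defaults;
every threshold lives in :class:`FeatureParams`):

timing
    ``late_wasting`` / ``late_administration`` — earliest linked waste /
    administration strictly more than 4 hours after the dispense.  Four
    hours exactly is *not* late.
quantity
    ``no_administration`` — dispensed > 0 and nothing settled at all (no
    administration, waste or return charted; the whole dose is missing).
    ``partial_administration`` — some but not all of the dose administered.
    ``partial_waste_return`` — a waste or return exists yet quantity is
    still missing.
    ``full_wasting`` — the entire dose wasted, nothing administered.
    ``bulk_wasting`` — the episode's waste is part of a burst of >= 3
    wastes by the same clinician inside a 10-minute window.
practice
    ``handoffs`` — more than one clinician touches the episode between
    dispense and settlement (a custody gap).  Handoff episodes emit a
    secondary vector for the settling clinician so both parties are
    scoreable.
    ``incorrect_order`` — a linked event is charted *before* the dispense
    (custody-sequence violation).
    ``incorrect_medication`` — a linked administration charts a different
    canonical medication than was dispensed.
cross-system
    ``off_clock_access`` — the dispense happened outside the clinician's
    clocked shifts.
    ``shipment_shortfall`` / ``restock_shortfall`` — from supply
    reconciliation.
    ``pain_score_anomaly`` — a PRN analgesic dispensed with no pain score
    charted for the patient within +/- 1 hour (simplified clinical
    cross-check).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .custody import CustodyResult

FEATURE_ORDER = [
    "late_wasting",
    "late_administration",
    "no_administration",
    "partial_administration",
    "partial_waste_return",
    "full_wasting",
    "bulk_wasting",
    "handoffs",
    "incorrect_order",
    "incorrect_medication",
    "off_clock_access",
    "shipment_shortfall",
    "restock_shortfall",
    "pain_score_anomaly",
]

_QTY_EPS = 1e-9


class FeatureParams(BaseModel):
    """Tunable thresholds for the flag definitions."""

    late_threshold_hours: float = 4.0
    bulk_min_events: int = 3
    bulk_window_minutes: float = 10.0
    pain_window_minutes: float = 60.0


def _bulk_waste_txns(ledger: pd.DataFrame, params: FeatureParams) -> set:
    """Waste transactions that belong to a bulk-wasting burst."""
    wastes = ledger[ledger["event_type"] == "WASTE"]
    out: set = set()
    k = params.bulk_min_events
    win = np.timedelta64(int(params.bulk_window_minutes * 60), "s")
    for _, g in wastes.groupby("clinician"):
        if len(g) < k:
            continue
        g = g.sort_values(["timestamp", "txn_id"], kind="mergesort")
        ts = g["timestamp"].to_numpy()
        ids = g["txn_id"].to_numpy()
        for i in range(len(ts) - k + 1):
            if ts[i + k - 1] - ts[i] <= win:
                out.update(ids[i:i + k])
    return out


def extract_features(
    episodes: pd.DataFrame,
    discrepancies: pd.DataFrame,
    offclock: pd.DataFrame,
    ledger: pd.DataFrame,
    params: FeatureParams | None = None,
    *,
    links: pd.DataFrame | None = None,
    pain_scores: pd.DataFrame | None = None,
    prn_medications: set | None = None,
) -> pd.DataFrame:
    """One feature vector per custody episode, plus one per supply shortfall.

    Returns a frame with ``txn_id``, ``clinician``, ``timestamp`` and the 14
    binary flag columns of :data:`FEATURE_ORDER`.  ``links`` (from
    :func:`rxdivert.custody.link_episodes`) enables bulk-wasting attribution;
    ``pain_scores`` and ``prn_medications`` enable the pain cross-check.
    """
    for name, obj in (("episodes", episodes), ("discrepancies", discrepancies),
                      ("offclock", offclock), ("ledger", ledger)):
        if obj is None:
            raise ValueError(f"missing reconciliation input: {name}")
    params = params or FeatureParams()
    ep = episodes
    late = pd.Timedelta(hours=params.late_threshold_hours)

    disp_ts = pd.to_datetime(ep["dispense_ts"])
    first_waste = pd.to_datetime(ep["first_waste_ts"])
    first_admin = pd.to_datetime(ep["first_admin_ts"])
    dispensed = ep["dispensed_qty"].astype(float)
    administered = ep["administered_qty"].astype(float)
    wasted = ep["wasted_qty"].astype(float)
    returned = ep["returned_qty"].astype(float)
    missing = ep["missing_qty"].astype(float)

    f = pd.DataFrame({"txn_id": ep["dispense_txn"],
                      "clinician": ep["clinician"],
                      "timestamp": disp_ts})
    f["late_wasting"] = (first_waste.notna()
                         & ((first_waste - disp_ts) > late)).astype(int)
    f["late_administration"] = (first_admin.notna()
                                & ((first_admin - disp_ts) > late)).astype(int)
    nothing_settled = (
        (administered <= _QTY_EPS) & (wasted <= _QTY_EPS) & (returned <= _QTY_EPS)
        & first_admin.isna() & first_waste.isna()
    )
    f["no_administration"] = ((dispensed > _QTY_EPS) & nothing_settled
                              & (ep["n_settle_events"] == 0)).astype(int)
    f["partial_administration"] = (
        (administered > _QTY_EPS) & (administered < dispensed - _QTY_EPS)
    ).astype(int)
    f["partial_waste_return"] = (
        (missing > _QTY_EPS) & ((wasted > _QTY_EPS) | (returned > _QTY_EPS))
    ).astype(int)
    f["full_wasting"] = (
        (dispensed > _QTY_EPS)
        & ((wasted - dispensed).abs() <= _QTY_EPS)
        & (administered <= _QTY_EPS)
    ).astype(int)

    bulk_txns = _bulk_waste_txns(ledger, params)
    if links is not None and len(links) and bulk_txns:
        linked_wastes = links[(links["event_type"] == "WASTE")
                              & links["event_txn"].isin(bulk_txns)]
        bulk_eps = set(linked_wastes["dispense_txn"])
    else:
        bulk_eps = set()
    f["bulk_wasting"] = ep["dispense_txn"].isin(bulk_eps).astype(int)

    n_involved = ep["clinicians_involved"].map(
        lambda s: len(s.split("|")) if s else 0)
    f["handoffs"] = (n_involved > 1).astype(int)
    f["incorrect_order"] = ep["has_pre_dispense_event"].astype(int)
    f["incorrect_medication"] = ep["med_mismatch"].astype(int)

    off_txns = set(offclock["txn_id"]) if len(offclock) else set()
    f["off_clock_access"] = ep["dispense_txn"].isin(off_txns).astype(int)
    f["shipment_shortfall"] = 0
    f["restock_shortfall"] = 0

    # pain cross-check: PRN analgesic dispenses need a nearby pain assessment
    f["pain_score_anomaly"] = 0
    if pain_scores is not None and prn_medications:
        win = pd.Timedelta(minutes=params.pain_window_minutes)
        pain_by_patient: dict[str, np.ndarray] = {
            p: np.sort(g["timestamp"].to_numpy())
            for p, g in pain_scores.groupby("patient")
        }
        is_prn = ep["medication"].isin(prn_medications).to_numpy()
        flags = np.zeros(len(ep), dtype=int)
        pts = ep["patient"].to_numpy()
        tss = disp_ts.to_numpy()
        for i in np.flatnonzero(is_prn):
            times = pain_by_patient.get(pts[i])
            if times is None or len(times) == 0:
                flags[i] = 1
                continue
            j = np.searchsorted(times, tss[i])
            near = False
            if j < len(times) and times[j] - tss[i] <= win:
                near = True
            if j > 0 and tss[i] - times[j - 1] <= win:
                near = True
            flags[i] = 0 if near else 1
        f["pain_score_anomaly"] = flags

    frames = [f]

    # secondary vectors: each settling clinician of a handoff episode
    handoff_eps = ep.loc[f["handoffs"].to_numpy(dtype=bool)]
    if len(handoff_eps):
        sec_rows = []
        flag_src = f.set_index("txn_id")
        for row in handoff_eps.itertuples(index=False):
            for clin in (row.settle_clinicians.split("|")
                         if row.settle_clinicians else []):
                if clin and clin != row.clinician:
                    rec = {"txn_id": f"{row.dispense_txn}::{clin}",
                           "clinician": clin,
                           "timestamp": row.dispense_ts}
                    for col in FEATURE_ORDER:
                        rec[col] = int(flag_src.at[row.dispense_txn, col])
                    sec_rows.append(rec)
        if sec_rows:
            frames.append(pd.DataFrame(sec_rows))

    # supply-stage vectors
    short = discrepancies[discrepancies["shortfall"] > _QTY_EPS]
    if len(short):
        sup = pd.DataFrame({"txn_id": short["txn_id"],
                            "clinician": short["responsible"],
                            "timestamp": pd.to_datetime(short["timestamp"])})
        for col in FEATURE_ORDER:
            sup[col] = 0
        sup.loc[short["stage"].to_numpy() == "WHL_TO_IIS",
                "shipment_shortfall"] = 1
        sup.loc[short["stage"].to_numpy() == "IIS_TO_ADC",
                "restock_shortfall"] = 1
        frames.append(sup)

    out = pd.concat(frames, ignore_index=True)
    return out[["txn_id", "clinician", "timestamp"] + FEATURE_ORDER]


def from_custody(
    custody: CustodyResult,
    discrepancies: pd.DataFrame,
    offclock: pd.DataFrame,
    ledger: pd.DataFrame,
    **kwargs,
) -> pd.DataFrame:
    """Convenience wrapper wiring a :class:`CustodyResult` straight in."""
    return extract_features(custody.episodes, discrepancies, offclock, ledger,
                            links=custody.links, **kwargs)


def one_hot_encode(vectors: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Feature matrix + fixed column index.

    The flags are already binary, so encoding is the identity on the flag
    columns; the column order is :data:`FEATURE_ORDER` and is stable.
    """
    if len(vectors) == 0:
        raise ValueError("no feature vectors to encode")
    missing = [c for c in FEATURE_ORDER if c not in vectors.columns]
    if missing:
        raise ValueError(f"feature columns absent: {missing}")
    matrix = vectors[FEATURE_ORDER].to_numpy(dtype=np.float64)
    return matrix, list(FEATURE_ORDER)
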