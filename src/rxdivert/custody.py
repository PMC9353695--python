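"""Chain-of-custody reconciliation over the normalized ledger.

Three reconciliations, mirroring how investigators audit medication movement
end to end:

1. **Custody episodes** — every cabinet dispense becomes an episode; the
   administrations, wastes, returns and transfers that settle it are linked
   by explicit cabinet reference when present, otherwise by (patient,
   canonical medication, nearest preceding dispense within a linkage
   window).  The unaccounted remainder is the episode's *missing quantity*:

       missing = dispensed - administered - wasted - returned - transferred

   Outer-join semantics throughout: a dispense with no settling events keeps
   its episode (missing = full quantity) and an administration that matches
   no dispense goes to an orphan list, never attached arbitrarily.

2. **Supply discrepancies** — wholesaler shipments against vault receipts
   (was part of a shipment diverted in transit or at the dock?) and vault
   issues against cabinet restocks (was stock diverted between vault and
   cabinet?).

3. **Off-clock access** — medication transactions timestamped outside every
   clock-in/clock-out interval of the handling clinician, within a grace
   period.

Matching rule (deterministic, oracle-checkable): an event links to the
candidate dispense with the smallest nonnegative time gap within the window;
ties break toward the lexicographically smaller dispense transaction ID.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dialects import MEDICATION_EVENTS, SETTLE_EVENTS

#: link window after a dispense; generous against the 4-hour lateness
#: threshold so late settlements still reconcile
DEFAULT_WINDOW_HOURS = 24.0

#: minutes of slack around a clock interval before access counts as off-clock
DEFAULT_GRACE_MINUTES = 30.0

EPISODE_COLUMNS = [
    "dispense_txn", "clinician", "patient", "medication", "dosage_form",
    "location", "dispense_ts", "dispensed_qty", "administered_qty",
    "wasted_qty", "returned_qty", "transferred_qty", "missing_qty",
    "first_admin_ts", "first_waste_ts", "first_event_ts", "last_event_ts",
    "n_settle_events", "settle_clinicians", "clinicians_involved",
    "med_mismatch", "has_pre_dispense_event",
]


@dataclass
class CustodyResult:
    episodes: pd.DataFrame
    links: pd.DataFrame  # event_txn, event_type, dispense_txn, via
    orphans: pd.DataFrame  # event_txn, event_type, clinician, reason


def link_episodes(
    ledger: pd.DataFrame,
    window_hours: float = DEFAULT_WINDOW_HOURS,
) -> CustodyResult:
    """Build one custody episode per DISPENSE and attach settling events.

    Events carrying an explicit ``link_ref`` attach to that dispense
    directly (a mismatched reference orphans the event); all others use the
    nearest-preceding-dispense rule within ``window_hours``.
    """
    window = pd.Timedelta(hours=window_hours)
    disp = ledger[ledger["event_type"] == "DISPENSE"]
    settles = ledger[ledger["event_type"].isin(SETTLE_EVENTS)]

    disp_ids = disp["txn_id"].to_numpy()
    known_disp = set(disp_ids)

    # candidate index: (patient, medication) -> dispenses sorted by (ts, txn)
    groups: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    d_sorted = disp.sort_values(["timestamp", "txn_id"], kind="mergesort")
    for key, g in d_sorted.groupby(["patient", "medication"], dropna=False,
                                   sort=False):
        groups[key] = (g["timestamp"].to_numpy(), g["txn_id"].to_numpy())

    link_rows, orphan_rows = [], []
    for ev in settles.itertuples(index=False):
        ref = ev.link_ref
        if isinstance(ref, str) and ref:
            if ref in known_disp:
                link_rows.append((ev.txn_id, ev.event_type, ref, "ref"))
            else:
                orphan_rows.append((ev.txn_id, ev.event_type, ev.clinician,
                                    "link_ref matches no dispense"))
            continue
        key = (ev.patient, ev.medication)
        hit = None
        if key in groups:
            times, ids = groups[key]
            j = int(np.searchsorted(times, np.datetime64(ev.timestamp), side="right"))
            if j > 0:
                t_best = times[j - 1]
                if ev.timestamp - t_best <= window:
                    k = j - 1
                    while k > 0 and times[k - 1] == t_best:
                        k -= 1  # equal-gap tie: smallest txn_id (ids sorted)
                    hit = ids[k]
        if hit is not None:
            link_rows.append((ev.txn_id, ev.event_type, hit, "match"))
        else:
            orphan_rows.append((ev.txn_id, ev.event_type, ev.clinician,
                                "no dispense within window"))

    links = pd.DataFrame(link_rows, columns=["event_txn", "event_type",
                                             "dispense_txn", "via"])
    orphans = pd.DataFrame(orphan_rows, columns=["event_txn", "event_type",
                                                 "clinician", "reason"])

    # aggregate linked quantities per dispense
    ep = disp.set_index("txn_id")
    n = len(ep)
    agg = {
        "administered_qty": pd.Series(0.0, index=ep.index),
        "wasted_qty": pd.Series(0.0, index=ep.index),
        "returned_qty": pd.Series(0.0, index=ep.index),
        "transferred_qty": pd.Series(0.0, index=ep.index),
    }
    qty_key = {"ADMINISTER": "administered_qty", "WASTE": "wasted_qty",
               "RETURN": "returned_qty", "TRANSFER": "transferred_qty"}
    first_admin = pd.Series(pd.NaT, index=ep.index)
    first_waste = pd.Series(pd.NaT, index=ep.index)
    first_ev = ep["timestamp"].copy()
    last_ev = ep["timestamp"].copy()
    n_settle = pd.Series(0, index=ep.index)
    settle_clin: dict[str, set] = {t: set() for t in ep.index}
    mismatch = pd.Series(False, index=ep.index)

    if len(links):
        ev_lookup = settles.set_index("txn_id").drop(columns=["event_type"])
        joined = links.join(ev_lookup, on="event_txn")
        for row in joined.itertuples(index=False):
            d = row.dispense_txn
            agg[qty_key[row.event_type]][d] += float(row.quantity)
            n_settle[d] += 1
            ts = row.timestamp
            if row.event_type == "ADMINISTER":
                cur = first_admin[d]
                if pd.isna(cur) or ts < cur:
                    first_admin[d] = ts
            elif row.event_type == "WASTE":
                cur = first_waste[d]
                if pd.isna(cur) or ts < cur:
                    first_waste[d] = ts
            if ts < first_ev[d]:
                first_ev[d] = ts
            if ts > last_ev[d]:
                last_ev[d] = ts
            if isinstance(row.clinician, str) and row.clinician:
                settle_clin[d].add(row.clinician)
            ev_med = row.medication
            if not (pd.isna(ev_med) or ev_med == ep.at[d, "medication"]):
                mismatch[d] = True

    episodes = pd.DataFrame({
        "dispense_txn": ep.index,
        "clinician": ep["clinician"].to_numpy(),
        "patient": ep["patient"].to_numpy(),
        "medication": ep["medication"].to_numpy(),
        "dosage_form": ep["dosage_form"].to_numpy(),
        "location": ep["location"].to_numpy(),
        "dispense_ts": ep["timestamp"].to_numpy(),
        "dispensed_qty": ep["quantity"].to_numpy(dtype=float),
        "administered_qty": agg["administered_qty"].to_numpy(),
        "wasted_qty": agg["wasted_qty"].to_numpy(),
        "returned_qty": agg["returned_qty"].to_numpy(),
        "transferred_qty": agg["transferred_qty"].to_numpy(),
        "first_admin_ts": first_admin.to_numpy(),
        "first_waste_ts": first_waste.to_numpy(),
        "first_event_ts": first_ev.to_numpy(),
        "last_event_ts": last_ev.to_numpy(),
        "n_settle_events": n_settle.to_numpy(),
        "settle_clinicians": ["|".join(sorted(settle_clin[t])) for t in ep.index],
        "med_mismatch": mismatch.to_numpy(),
    })
    episodes["missing_qty"] = episodes["dispensed_qty"] - (
        episodes["administered_qty"] + episodes["wasted_qty"]
        + episodes["returned_qty"] + episodes["transferred_qty"]
    )
    involved = []
    for clin, others in zip(episodes["clinician"], episodes["settle_clinicians"]):
        s = set(others.split("|")) if others else set()
        if isinstance(clin, str) and clin:
            s.add(clin)
        involved.append("|".join(sorted(s)))
    episodes["clinicians_involved"] = involved
    episodes["has_pre_dispense_event"] = (
        episodes["first_event_ts"] < episodes["dispense_ts"]
    )
    episodes = episodes[EPISODE_COLUMNS].reset_index(drop=True)
    assert len(episodes) == n
    return CustodyResult(episodes, links, orphans)


# --------------------------------------------------------------------------
# Supply-stage reconciliation
# --------------------------------------------------------------------------

def reconcile_supply(ledger: pd.DataFrame) -> pd.DataFrame:
    """Match shipments to vault receipts and vault issues to cabinet
    restocks; compute per-reference shortfalls (negative = overage, kept and
    flagged separately).
    """
    rows = []

    ships = ledger[ledger["event_type"] == "SHIP"]
    receives = ledger[ledger["event_type"] == "RECEIVE"]
    rec_by_ref = receives.groupby(["order_ref", "medication"], dropna=False)
    rec_index = {key: g for key, g in rec_by_ref}
    for ship in ships.itertuples(index=False):
        key = (ship.order_ref, ship.medication)
        got = rec_index.get(key)
        observed = float(got["quantity"].sum()) if got is not None else 0.0
        obs_txn = got["txn_id"].iloc[0] if got is not None and len(got) else ""
        obs_clin = got["clinician"].iloc[0] if got is not None and len(got) else None
        rows.append({
            "stage": "WHL_TO_IIS",
            "reference": ship.order_ref,
            "medication": ship.medication,
            "expected_qty": float(ship.quantity),
            "observed_qty": observed,
            "shortfall": float(ship.quantity) - observed,
            "responsible": obs_clin,
            "txn_id": obs_txn or ship.txn_id,
            "timestamp": (got["timestamp"].iloc[0] if got is not None and len(got)
                          else ship.timestamp),
        })

    issues = ledger[ledger["event_type"] == "VAULT_TRANSFER"]
    restocks = ledger[ledger["event_type"] == "RESTOCK"]
    rst_index = {key: g for key, g in
                 restocks.groupby(["link_ref", "medication"], dropna=False)}
    for issue in issues.itertuples(index=False):
        key = (issue.order_ref, issue.medication)
        got = rst_index.get(key)
        observed = float(got["quantity"].sum()) if got is not None else 0.0
        obs_txn = got["txn_id"].iloc[0] if got is not None and len(got) else ""
        obs_clin = got["clinician"].iloc[0] if got is not None and len(got) else issue.clinician
        rows.append({
            "stage": "IIS_TO_ADC",
            "reference": issue.order_ref,
            "medication": issue.medication,
            "expected_qty": float(issue.quantity),
            "observed_qty": observed,
            "shortfall": float(issue.quantity) - observed,
            "responsible": obs_clin,
            "txn_id": obs_txn or issue.txn_id,
            "timestamp": (got["timestamp"].iloc[0] if got is not None and len(got)
                          else issue.timestamp),
        })

    frame = pd.DataFrame(rows, columns=["stage", "reference", "medication",
                                        "expected_qty", "observed_qty",
                                        "shortfall", "responsible", "txn_id",
                                        "timestamp"])
    frame["overage"] = frame["shortfall"] < 0
    return frame


# --------------------------------------------------------------------------
# Off-clock comparison
# --------------------------------------------------------------------------

def off_clock_events(
    ledger: pd.DataFrame,
    grace_minutes: float = DEFAULT_GRACE_MINUTES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag medication transactions outside every clock interval of the
    handling clinician.

    Returns ``(flagged, skipped)``: flagged rows carry the nearest interval
    and minutes outside it; clinicians with medication activity but no
    time-clock data are skipped and reported rather than silently passed.
    """
    grace = pd.Timedelta(minutes=grace_minutes)

    punches = ledger[ledger["event_type"].isin(("CLOCK_IN", "CLOCK_OUT"))]
    intervals: dict[str, list[tuple]] = {}
    for clin, g in punches.groupby("clinician"):
        g = g.sort_values(["timestamp", "txn_id"], kind="mergesort")
        current_in = None
        ivs = []
        for ev in g.itertuples(index=False):
            if ev.event_type == "CLOCK_IN":
                current_in = ev.timestamp
            elif current_in is not None:
                ivs.append((current_in, ev.timestamp))
                current_in = None
        if ivs:
            intervals[clin] = ivs

    med = ledger[
        ledger["event_type"].isin(MEDICATION_EVENTS)
        & ledger["clinician"].notna()
        & (ledger["clinician"] != "")
    ]

    flagged, skipped = [], []
    for clin, g in med.groupby("clinician"):
        ivs = intervals.get(clin)
        if not ivs:
            skipped.append({"clinician": clin, "n_transactions": len(g)})
            continue
        starts = np.array([iv[0] for iv in ivs], dtype="datetime64[ns]")
        ends = np.array([iv[1] for iv in ivs], dtype="datetime64[ns]")
        ts = g["timestamp"].to_numpy()
        j = np.searchsorted(starts, ts, side="right")
        prev = np.clip(j - 1, 0, len(ivs) - 1)
        nxt = np.clip(j, 0, len(ivs) - 1)
        in_prev = (ts >= starts[prev] - np.timedelta64(int(grace.total_seconds()), "s")) & (
            ts <= ends[prev] + np.timedelta64(int(grace.total_seconds()), "s"))
        # distance to nearest interval (0 inside)
        gap_prev = np.maximum(
            (ts - ends[prev]).astype("timedelta64[s]").astype(np.int64),
            (starts[prev] - ts).astype("timedelta64[s]").astype(np.int64),
        )
        gap_next = np.maximum(
            (ts - ends[nxt]).astype("timedelta64[s]").astype(np.int64),
            (starts[nxt] - ts).astype("timedelta64[s]").astype(np.int64),
        )
        gap = np.minimum(np.maximum(gap_prev, 0), np.maximum(gap_next, 0))
        outside = ~in_prev & (gap > grace.total_seconds())
        near = np.where(np.maximum(gap_prev, 0) <= np.maximum(gap_next, 0),
                        prev, nxt)
        for idx, row in zip(np.flatnonzero(outside),
                            g.iloc[np.flatnonzero(outside)].itertuples(index=False)):
            iv = ivs[near[idx]]
            flagged.append({
                "txn_id": row.txn_id,
                "clinician": clin,
                "event_type": row.event_type,
                "timestamp": row.timestamp,
                "interval_start": iv[0],
                "interval_end": iv[1],
                "minutes_outside": round((gap[idx] - grace.total_seconds()) / 60.0, 1),
            })

    flagged_df = pd.DataFrame(flagged, columns=["txn_id", "clinician",
                                                "event_type", "timestamp",
                                                "interval_start", "interval_end",
                                                "minutes_outside"])
    skipped_df = pd.DataFrame(skipped, columns=["clinician", "n_transactions"])
    return flagged_df, skipped_df
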