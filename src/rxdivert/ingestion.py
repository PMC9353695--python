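"""Ingest the five source-system extracts into one normalized movement ledger.

Each system exports its own flat-file dialect with local medication IDs and
local usernames.  Ingestion (1) parses each extract, routing malformed rows
to a reject report instead of dropping them silently, (2) maps medication and
clinician identities onto canonical spaces via the formulary and identity
cross-maps, converting quantities to each medication's base unit, and
(3) concatenates everything into a single ledger of movement transactions
with a deterministic total order.

Rows whose medication or username has no cross-map entry are *retained* with
a null canonical ID and counted in an unmapped report: downstream custody
reconciliation relies on outer-join semantics (a dispense with no matching
administration is exactly the thing worth seeing), so nothing may be thrown
away merely for failing to map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dialects import COLUMNS, DELIMITERS, EVENT_CODES, SYSTEMS

LEDGER_COLUMNS = [
    "txn_id",
    "source_system",
    "event_type",
    "timestamp",
    "clinician",
    "patient",
    "medication",
    "quantity",
    "unit",
    "dosage_form",
    "location",
    "order_ref",
    "link_ref",
    "witness",
]

_TS_FMT = {
    "EMR": "%m/%d/%Y, %H:%M",
    "ADC": "%m/%d/%Y %I:%M %p",
    "IIS": "%Y-%m-%d %H:%M",
    "WHL": "%Y-%m-%d",
    "ETC": "%Y-%m-%d %H:%M",
}


class FormularyMap:
    """(system, local medication id) -> canonical id, unit factor and form.

    The mapping must be a function: a local ID that maps to two different
    canonical IDs is a hard error.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"system", "local_med_id", "canonical_med_id",
                    "dosage_form", "factor_to_base", "base_unit"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"formulary map missing columns: {sorted(missing)}")
        dup = frame.duplicated(subset=["system", "local_med_id"], keep=False)
        if dup.any():
            conflict = frame.loc[dup].groupby(["system", "local_med_id"])[
                "canonical_med_id"].nunique()
            if (conflict > 1).any():
                raise ValueError("formulary map is not a function: "
                                 f"{conflict[conflict > 1].index.tolist()}")
        self.frame = frame
        key = list(zip(frame["system"], frame["local_med_id"].astype(str)))
        self._canonical = dict(zip(key, frame["canonical_med_id"]))
        self._factor = dict(zip(key, frame["factor_to_base"].astype(float)))
        self.dosage_form = dict(zip(frame["canonical_med_id"], frame["dosage_form"]))
        self.base_unit = dict(zip(frame["canonical_med_id"], frame["base_unit"]))
        if "prn_analgesic" in frame.columns:
            self.prn_analgesic = {
                med for med, flag in zip(frame["canonical_med_id"],
                                         frame["prn_analgesic"].astype(int))
                if flag
            }
        else:
            self.prn_analgesic = set()

    @classmethod
    def from_csv(cls, path: str | Path) -> "FormularyMap":
        return cls(pd.read_csv(path, dtype=str).assign(
            factor_to_base=lambda f: f["factor_to_base"].astype(float)))

    def canonical(self, system: str, local_id: str):
        return self._canonical.get((system, str(local_id)))

    def factor(self, system: str, local_id: str) -> float:
        return self._factor.get((system, str(local_id)), 1.0)


class IdentityMap:
    """(system, local username) -> canonical clinician id."""

    def __init__(self, frame: pd.DataFrame):
        required = {"system", "local_username", "canonical_clinician_id"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"identity map missing columns: {sorted(missing)}")
        dup = frame.duplicated(subset=["system", "local_username"], keep=False)
        if dup.any():
            conflict = frame.loc[dup].groupby(["system", "local_username"])[
                "canonical_clinician_id"].nunique()
            if (conflict > 1).any():
                raise ValueError("identity map is not a function: "
                                 f"{conflict[conflict > 1].index.tolist()}")
        self.frame = frame
        key = list(zip(frame["system"], frame["local_username"].astype(str)))
        self._canonical = dict(zip(key, frame["canonical_clinician_id"]))

    @classmethod
    def from_csv(cls, path: str | Path) -> "IdentityMap":
        return cls(pd.read_csv(path, dtype=str))

    def canonical(self, system: str, username: str):
        if username is None or username == "" or pd.isna(username):
            return None
        return self._canonical.get((system, str(username)))


@dataclass
class NormalizeResult:
    transactions: pd.DataFrame  # normalized MovementTransaction rows
    pain_scores: pd.DataFrame  # timestamp, clinician, patient, score
    unmapped: pd.DataFrame  # system, kind, local_id, txn_id
    counts: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------

def read_extract(path: str | Path, system: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse one extract file; returns ``(records, rejects)``.

    A header that does not match the system's schema is a hard error; a
    malformed row (bad timestamp, negative or non-numeric quantity, unknown
    transaction code) lands in the reject report with its 1-based data row
    number and a reason.  No silent drops: ``len(records) + len(rejects)``
    equals the number of data rows in the file.
    """
    if system not in SYSTEMS:
        raise ValueError(f"unknown system {system!r}")
    path = Path(path)
    raw = pd.read_csv(path, sep=DELIMITERS[system], dtype=str,
                      keep_default_na=False)
    if list(raw.columns) != COLUMNS[system]:
        raise ValueError(
            f"{path.name}: header does not match the {system} schema; "
            f"got {list(raw.columns)}"
        )
    raw = raw.reset_index(drop=True)
    reasons = pd.Series("", index=raw.index, dtype=object)

    if system == "IIS":
        ts_col = raw["MoveDate"].str.cat(raw["MoveTime"], sep=" ")
    else:
        ts_col = raw[{"EMR": "EventDateTime", "ADC": "TxnDateTime",
                      "WHL": "ShipDate", "ETC": "PunchDateTime"}[system]]
    parsed = pd.to_datetime(ts_col, format=_TS_FMT[system], errors="coerce")
    reasons[parsed.isna()] = "unparseable timestamp"
    raw = raw.assign(_ts=parsed)

    qty_col = {"EMR": "Dose", "ADC": "Qty", "IIS": "Quantity",
               "WHL": "PackagesShipped", "ETC": None}[system]
    if qty_col is not None:
        blank = raw[qty_col].str.strip() == ""
        qty = pd.to_numeric(raw[qty_col], errors="coerce")
        bad = (qty.isna() | (qty < 0)) & ~blank
        if system != "EMR":
            bad |= blank  # only the EMR carries quantity-less (pain) rows
        reasons[bad & (reasons == "")] = "invalid quantity"
        raw = raw.assign(_qty=qty.where(~blank, other=np.nan))

    code_col = {"EMR": "RecordType", "ADC": "TxnType", "IIS": "MoveType",
                "WHL": None, "ETC": "PunchType"}[system]
    if code_col is not None:
        known = set(EVENT_CODES[system]) | ({"PAIN"} if system == "EMR" else set())
        bad = ~raw[code_col].isin(known)
        reasons[bad & (reasons == "")] = "unknown transaction code"

    bad_mask = reasons != ""
    rejects = pd.DataFrame(
        {
            "system": system,
            "row_number": (raw.index[bad_mask] + 1).astype(int),
            "reason": reasons[bad_mask].to_numpy(),
        }
    )
    records = raw.loc[~bad_mask].reset_index(drop=True)
    return records, rejects


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

def _map_users(out: pd.DataFrame, raw_users: pd.Series, system: str,
               identities: IdentityMap, sso: bool, unmapped: list):
    if sso:
        canon = raw_users.where(raw_users != "", other=None)
    else:
        canon = raw_users.map(lambda u: identities.canonical(system, u))
    missing = canon.isna() & (raw_users != "")
    for txn, local in zip(out.loc[missing.to_numpy(), "txn_id"],
                          raw_users[missing]):
        unmapped.append({"system": system, "kind": "clinician",
                         "local_id": local, "txn_id": txn})
    return canon


def normalize(
    raw_records: dict[str, pd.DataFrame],
    formulary: FormularyMap,
    identities: IdentityMap,
    sso: bool = False,
) -> NormalizeResult:
    """Map all parsed extracts onto canonical spaces and one row shape.

    ``sso=True`` treats usernames as already canonical (hospitals with single
    sign-on); the default assumes independent username spaces per system.
    Unmapped medications/usernames keep the row (canonical ID null) and are
    counted in the unmapped report.
    """
    frames = []
    pain_frames = []
    unmapped: list[dict] = []
    counts: dict[str, dict] = {}

    for system, records in raw_records.items():
        if system not in SYSTEMS:
            raise ValueError(f"unknown system {system!r}")
        if records.empty:
            counts[system] = {"normalized": 0, "pain": 0}
            continue
        r = records

        if system == "EMR":
            is_pain = r["RecordType"] == "PAIN"
            pain = r.loc[is_pain]
            if len(pain):
                pain_users = pain["UserName"].map(
                    lambda u: u if sso else identities.canonical("EMR", u))
                pain_frames.append(pd.DataFrame({
                    "timestamp": pain["_ts"],
                    "clinician": pain_users,
                    "patient": pain["PatientID"],
                    "score": pd.to_numeric(pain["PainScore"], errors="coerce"),
                }))
            r = r.loc[~is_pain]
            out = pd.DataFrame({
                "txn_id": r["RecordID"],
                "source_system": "EMR",
                "event_type": r["RecordType"].map(EVENT_CODES["EMR"]),
                "timestamp": r["_ts"],
                "patient": r["PatientID"],
                "location": "",
                "order_ref": r["OrderID"],
                "link_ref": r["DispenseRef"],
                "witness": "",
            })
            med_local, med_system = r["MedCode"], "EMR"
            user_local = r["UserName"]
            qty = r["_qty"]
        elif system == "ADC":
            out = pd.DataFrame({
                "txn_id": r["TxnID"],
                "source_system": "ADC",
                "event_type": r["TxnType"].map(EVENT_CODES["ADC"]),
                "timestamp": r["_ts"],
                "patient": r["PatientID"],
                "location": r["Station"],
                "order_ref": r["OrderRef"],
                "link_ref": r["LinkRef"],
                "witness": r["WitnessID"],
            })
            med_local, med_system = r["MedID"], "ADC"
            user_local = r["UserID"]
            qty = r["_qty"]
        elif system == "IIS":
            out = pd.DataFrame({
                "txn_id": r["MoveID"],
                "source_system": "IIS",
                "event_type": r["MoveType"].map(EVENT_CODES["IIS"]),
                "timestamp": r["_ts"],
                "patient": "",
                "location": r["ToLoc"],
                "order_ref": r["RefNum"],
                "link_ref": "",
                "witness": "",
            })
            med_local, med_system = r["ItemNum"], "IIS"
            user_local = r["TechID"]
            qty = r["_qty"]
        elif system == "WHL":
            out = pd.DataFrame({
                "txn_id": r["InvoiceLineID"],
                "source_system": "WHL",
                "event_type": "SHIP",
                "timestamp": r["_ts"],
                "patient": "",
                "location": "DOCK",
                "order_ref": r["InvoiceNum"],
                "link_ref": "",
                "witness": "",
            })
            med_local, med_system = r["NDC"], "WHL"
            user_local = pd.Series("", index=r.index)
            qty = r["_qty"]
        else:  # ETC
            out = pd.DataFrame({
                "txn_id": r["PunchID"],
                "source_system": "ETC",
                "event_type": r["PunchType"].map(EVENT_CODES["ETC"]),
                "timestamp": r["_ts"],
                "patient": "",
                "location": "",
                "order_ref": "",
                "link_ref": "",
                "witness": "",
            })
            med_local = pd.Series("", index=r.index)
            med_system = "ETC"
            user_local = r["EmployeeID"]
            qty = pd.Series(0.0, index=r.index)

        if system == "ETC":
            out["medication"] = None
            out["quantity"] = 0.0
            out["unit"] = ""
            out["dosage_form"] = ""
        else:
            canon_med = med_local.map(
                lambda m: formulary.canonical(med_system, m))
            missing = canon_med.isna() & (med_local != "")
            for txn, local in zip(out.loc[missing.to_numpy(), "txn_id"],
                                  med_local[missing]):
                unmapped.append({"system": system, "kind": "medication",
                                 "local_id": local, "txn_id": txn})
            factor = med_local.map(lambda m: formulary.factor(med_system, m))
            out["medication"] = canon_med
            out["quantity"] = (qty * factor).fillna(0.0)
            out["unit"] = canon_med.map(formulary.base_unit).fillna("")
            out["dosage_form"] = canon_med.map(formulary.dosage_form).fillna("")

        out["clinician"] = _map_users(out, user_local, system, identities,
                                      sso, unmapped)
        if not sso and len(out):
            # witness usernames ride along mapped when possible
            out["witness"] = out["witness"].map(
                lambda w: identities.canonical(system, w) or w if w else "")
        frames.append(out[LEDGER_COLUMNS])
        counts[system] = {
            "normalized": len(out),
            "pain": int(is_pain.sum()) if system == "EMR" else 0,
        }

    transactions = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=LEDGER_COLUMNS)
    )
    pain_scores = (
        pd.concat(pain_frames, ignore_index=True)
        if pain_frames
        else pd.DataFrame(columns=["timestamp", "clinician", "patient", "score"])
    )
    unmapped_df = pd.DataFrame(unmapped,
                               columns=["system", "kind", "local_id", "txn_id"])
    return NormalizeResult(transactions, pain_scores, unmapped_df, counts)


def build_ledger(transactions: pd.DataFrame) -> pd.DataFrame:
    """Deterministically ordered ledger: (clinician, timestamp, txn_id).

    Ties within the same minute break lexicographically on ``txn_id``;
    duplicate transaction IDs are a hard error.
    """
    if transactions["txn_id"].duplicated().any():
        dups = transactions.loc[transactions["txn_id"].duplicated(), "txn_id"]
        raise ValueError(f"duplicate txn_id values: {dups.head().tolist()}")
    ledger = transactions.sort_values(
        ["clinician", "timestamp", "txn_id"],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return ledger


def ingest_directory(in_dir: str | Path, sso: bool = False):
    """Convenience wrapper: read all five extracts plus cross-maps from a
    simulator output directory and return (ledger, NormalizeResult, rejects).
    """
    in_dir = Path(in_dir)
    from .dialects import EXTRACT_FILENAMES

    formulary = FormularyMap.from_csv(in_dir / "formulary_map.csv")
    identities = IdentityMap.from_csv(in_dir / "identity_map.csv")
    raw, rejects = {}, []
    for system, fname in EXTRACT_FILENAMES.items():
        records, rej = read_extract(in_dir / fname, system)
        raw[system] = records
        rejects.append(rej)
    result = normalize(raw, formulary, identities, sso=sso)
    ledger = build_ledger(result.transactions)
    rejects_df = pd.concat(rejects, ignore_index=True)
    return ledger, result, rejects_df


def write_ledger(ledger: pd.DataFrame, path: str | Path):
    path = Path(path)
    if path.suffix == ".parquet":
        ledger.to_parquet(path, index=False)
    else:
        ledger.to_csv(path, index=False)


def read_ledger(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path, parse_dates=["timestamp"], keep_default_na=False,
                       na_values={"medication": [""], "clinician": [""]})
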