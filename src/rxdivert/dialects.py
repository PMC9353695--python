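"""Flat-file dialects of the five hospital source systems.

Each system exports delimited text with its own column names, delimiter,
timestamp convention, medication-ID space and username space:

* **EMR** — medication administration records (MAR) plus pain assessments.
* **ADC** — automated dispensing cabinet withdraw/waste/return/transfer and
  restock transactions (profiled and nonprofiled stations).
* **IIS** — internal inventory system: wholesaler receipts into the central
  narcotic vault and issues from the vault to cabinets.
* **WHL** — wholesaler shipment invoices (package-level quantities).
* **ETC** — employee time-clock punches.

The simulator writes these dialects and the ingestion layer reads them; the
schemas below are the single source of truth for both sides.
"""

from __future__ import annotations

from datetime import datetime

SYSTEMS = ("EMR", "ADC", "IIS", "WHL", "ETC")

#: event types a normalized ledger row may carry, and the systems allowed to
#: produce each (administrations only ever come from the EMR, cabinet events
#: only from the ADC, and so on).
EVENT_TYPES = {
    "SHIP": "WHL",
    "RECEIVE": "IIS",
    "VAULT_TRANSFER": "IIS",
    "RESTOCK": "ADC",
    "DISPENSE": "ADC",
    "ADMINISTER": "EMR",
    "WASTE": "ADC",
    "RETURN": "ADC",
    "TRANSFER": "ADC",
    "CLOCK_IN": "ETC",
    "CLOCK_OUT": "ETC",
}

#: cabinet/EMR events that settle quantity against a dispense
SETTLE_EVENTS = ("ADMINISTER", "WASTE", "RETURN", "TRANSFER")

#: events carrying a medication quantity handled by an identified clinician
MEDICATION_EVENTS = (
    "RECEIVE",
    "VAULT_TRANSFER",
    "RESTOCK",
    "DISPENSE",
    "ADMINISTER",
    "WASTE",
    "RETURN",
    "TRANSFER",
)

DOSAGE_FORMS = ("oral_solid", "injection", "infusion", "PCA", "patch")

DELIMITERS = {"EMR": ",", "ADC": "|", "IIS": "\t", "WHL": ";", "ETC": ","}

COLUMNS = {
    "EMR": [
        "RecordID",
        "RecordType",  # ADMIN | PAIN
        "EventDateTime",  # "5/24/2018, 07:09"
        "UserName",
        "PatientID",
        "MedCode",
        "Dose",
        "DoseUnit",
        "PainScore",
        "OrderID",
        "DispenseRef",
    ],
    "ADC": [
        "TxnID",
        "TxnDateTime",  # "1/21/2015 8:19 pm"
        "Station",
        "UserID",
        "WitnessID",
        "PatientID",
        "MedID",
        "TxnType",  # WITHDRAW | WASTE | RETURN | XFER | RESTOCK
        "Qty",
        "QtyUnit",
        "OrderRef",
        "LinkRef",
    ],
    "IIS": [
        "MoveID",
        "MoveDate",  # "2018-05-24"
        "MoveTime",  # "07:09"
        "ItemNum",
        "MoveType",  # RECEIPT | ISSUE
        "Quantity",
        "Unit",
        "FromLoc",
        "ToLoc",
        "TechID",
        "RefNum",
    ],
    "WHL": [
        "InvoiceLineID",
        "ShipDate",  # "2018-05-24"
        "InvoiceNum",
        "NDC",
        "ItemDescription",
        "PackagesShipped",
        "PackageUnit",
    ],
    "ETC": [
        "PunchID",
        "EmployeeID",
        "PunchDateTime",  # "2018-05-24 07:09"
        "PunchType",  # IN | OUT
    ],
}

EXTRACT_FILENAMES = {
    "EMR": "emr.csv",
    "ADC": "adc.csv",
    "IIS": "iis.csv",
    "WHL": "whl.csv",
    "ETC": "etc.csv",
}

#: raw transaction-type code -> normalized event type, per system
EVENT_CODES = {
    "EMR": {"ADMIN": "ADMINISTER"},
    "ADC": {
        "WITHDRAW": "DISPENSE",
        "WASTE": "WASTE",
        "RETURN": "RETURN",
        "XFER": "TRANSFER",
        "RESTOCK": "RESTOCK",
    },
    "IIS": {"RECEIPT": "RECEIVE", "ISSUE": "VAULT_TRANSFER"},
    "ETC": {"IN": "CLOCK_IN", "OUT": "CLOCK_OUT"},
}

_TS_FORMATS = (
    "%m/%d/%Y, %H:%M",  # EMR  "5/24/2018, 07:09"
    "%m/%d/%Y %I:%M %p",  # ADC  "1/21/2015 8:19 pm"
    "%Y-%m-%d %H:%M",  # ETC / IIS date+time
    "%Y-%m-%d",  # WHL date only
    "%m/%d/%Y",  # roster day dates
)


def parse_timestamp(text: str) -> datetime:
    """Parse any of the source-system timestamp dialects (minute resolution)."""
    text = str(text).strip()
    for fmt in _TS_FORMATS:
        try:
            return datetime.strptime(text, fmt)
        except ValueError:
            continue
    raise ValueError(f"unparseable timestamp: {text!r}")


def fmt_emr(ts: datetime) -> str:
    return f"{ts.month}/{ts.day}/{ts.year}, {ts.hour:02d}:{ts.minute:02d}"


def fmt_adc(ts: datetime) -> str:
    h = ts.hour % 12 or 12
    ampm = "am" if ts.hour < 12 else "pm"
    return f"{ts.month}/{ts.day}/{ts.year} {h}:{ts.minute:02d} {ampm}"


def fmt_iso_date(ts) -> str:
    return f"{ts.year:04d}-{ts.month:02d}-{ts.day:02d}"


def fmt_iso_minute(ts: datetime) -> str:
    return f"{fmt_iso_date(ts)} {ts.hour:02d}:{ts.minute:02d}"
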