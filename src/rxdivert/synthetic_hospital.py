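"""Ground-truthed synthetic hospital: multi-system extract generator.

Emulates the data environment of an acute-care inpatient hospital whose
medication movements are recorded across five independent IT systems (EMR,
ADC, IIS, WHL, ETC), each with its own flat-file dialect, medication-ID
space and username space.  Normal clinicians follow lawful workflows
(dispense -> administer promptly -> waste any remainder with a witness, or
return unopened); a configurable set of *diverters* additionally expresses
suspicious behaviors (full wasting, missing administrations, late charting,
off-clock cabinet access, ...) from a known onset date.  Every injected
behavior is tagged in a ground-truth file so downstream reconciliation,
feature extraction, risk scoring and detection-latency evaluation can be
validated against a known answer.

The generator is fully deterministic: the same :class:`SimConfig` (including
seed) produces byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .dialects import (
    COLUMNS,
    DELIMITERS,
    EXTRACT_FILENAMES,
    fmt_adc,
    fmt_emr,
    fmt_iso_date,
    fmt_iso_minute,
)

# --------------------------------------------------------------------------
# Behavior vocabulary
# --------------------------------------------------------------------------

#: behaviors expressed per dispense opportunity (nursing-side)
DISPENSE_BEHAVIORS = (
    "full_wasting",
    "no_administration",
    "late_wasting",
    "late_administration",
    "partial_waste_return",
    "bulk_wasting",
    "handoffs",
    "incorrect_order",
    "incorrect_medication",
    "off_clock_access",
    "pain_score_anomaly",
)

#: behaviors expressed per supply event (pharmacy-side)
SUPPLY_BEHAVIORS = ("shipment_shortfall", "restock_shortfall")

KNOWN_BEHAVIORS = DISPENSE_BEHAVIORS + SUPPLY_BEHAVIORS

#: base rates are not published anywhere; these defaults describe a
#: moderately active diverter and are fully config-exposed.
DEFAULT_BEHAVIOR_RATES = {
    "full_wasting": 0.12,
    "no_administration": 0.08,
    "late_wasting": 0.08,
    "late_administration": 0.06,
    "partial_waste_return": 0.04,
    "bulk_wasting": 0.03,
    "handoffs": 0.04,
    "incorrect_order": 0.02,
    "incorrect_medication": 0.02,
    "off_clock_access": 0.03,
    "pain_score_anomaly": 0.04,
}

#: benign documentation noise expressed by non-diverting clinicians
DEFAULT_NOISE_RATES = {
    "partial_dose": 0.02,  # lawful partial administration + witnessed waste
    "late_charting": 0.005,  # administration charted > 4 h after dispense
    "pain_miss": 0.005,  # PRN dispense without a charted pain score
}

DEFAULT_DOSAGE_FORM_MIX = {
    "oral_solid": 0.45,
    "injection": 0.30,
    "infusion": 0.10,
    "PCA": 0.10,
    "patch": 0.05,
}


# --------------------------------------------------------------------------
# Medication catalog (canonical space)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _Med:
    canonical: str
    form: str
    base_unit: str  # "each", "mg" or "mcg"
    prn_analgesic: bool
    package_size: float  # base units per wholesaler package
    dispense_qtys: tuple  # choices for one dispense, in base units


CATALOG = (
    _Med("oxycodone_5mg_tab", "oral_solid", "each", True, 100, (1, 2)),
    _Med("hydrocodone_apap_tab", "oral_solid", "each", True, 100, (1, 2)),
    _Med("morphine_2mg_inj", "injection", "mg", True, 50, (2.0, 4.0)),
    _Med("hydromorphone_1mg_inj", "injection", "mg", True, 25, (1.0, 2.0)),
    _Med("fentanyl_infusion_bag", "infusion", "mcg", False, 10000, (1000.0,)),
    _Med("morphine_pca_cassette", "PCA", "mg", True, 150, (30.0,)),
    _Med("fentanyl_50mcg_patch", "patch", "each", False, 5, (1,)),
)

_MEDS_BY_FORM: dict[str, list[_Med]] = {}
for _m in CATALOG:
    _MEDS_BY_FORM.setdefault(_m.form, []).append(_m)

_PRN_MEDS = [m for m in CATALOG if m.prn_analgesic]

# local medication-ID spaces, one per system
_EMR_IDS = {m.canonical: f"E{1000 + i:04d}" for i, m in enumerate(CATALOG)}
_ADC_IDS = {m.canonical: f"OMN-{100 + i:03d}" for i, m in enumerate(CATALOG)}
_IIS_IDS = {m.canonical: f"IIS-{5000 + i:04d}" for i, m in enumerate(CATALOG)}
_NDC_IDS = {m.canonical: f"00409-{1200 + i:04d}-01" for i, m in enumerate(CATALOG)}

_SURNAMES = (
    "SMITH JOHNSON WILLIAMS BROWN JONES GARCIA MILLER DAVIS RODRIGUEZ "
    "MARTINEZ HERNANDEZ LOPEZ GONZALEZ WILSON ANDERSON THOMAS TAYLOR MOORE "
    "JACKSON MARTIN LEE PEREZ THOMPSON WHITE HARRIS SANCHEZ CLARK RAMIREZ "
    "LEWIS ROBINSON WALKER YOUNG ALLEN KING WRIGHT SCOTT TORRES NGUYEN "
    "HILL FLORES GREEN ADAMS NELSON BAKER HALL RIVERA CAMPBELL MITCHELL "
    "CARTER ROBERTS GOMEZ PHILLIPS EVANS TURNER DIAZ PARKER CRUZ EDWARDS "
    "COLLINS REYES STEWART MORRIS MORALES MURPHY COOK ROGERS GUTIERREZ "
    "ORTIZ MORGAN COOPER PETERSON BAILEY REED KELLY HOWARD RAMOS KIM COX "
    "WARD RICHARDSON"
).split()

_INITIALS = "ABCDEFGHJKLMNPRSTW"


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

class BehaviorProfile(BaseModel):
    """One diverter's behavior mix from a known onset date.

    ``behavior_rates`` maps a behavior name to a probability per opportunity
    (per dispense for nursing behaviors, per supply event for
    ``shipment_shortfall`` / ``restock_shortfall``).  Behaviors are only
    expressed on or after ``onset_date``; before onset the clinician is
    indistinguishable from a careful colleague.
    """

    onset_date: date
    behavior_rates: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_RATES)
    )

    @field_validator("behavior_rates")
    @classmethod
    def _check_rates(cls, rates: dict[str, float]) -> dict[str, float]:
        for name, rate in rates.items():
            if name not in KNOWN_BEHAVIORS:
                raise ValueError(f"unknown behavior {name!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate for {name} must be in [0, 1]")
        disp = sum(r for n, r in rates.items() if n in DISPENSE_BEHAVIORS)
        if disp > 1.0 + 1e-9:
            raise ValueError("dispense-level behavior rates sum to > 1")
        return rates


class SimConfig(BaseModel):
    """Scale, composition and behavior parameters of the synthetic hospital.

    Defaults describe a single desk-scale hospital: 200 clinicians over 90
    days, roughly 1e5 movement transactions, with 2% of clinicians diverting.
    """

    n_clinicians: int = 200
    n_diverters: int = 4
    date_range: tuple[date, date] = (date(2024, 1, 1), date(2024, 3, 31))
    beds: int = 120
    dispense_rate: float = 4.0  # mean dispenses per clinician-shift
    dosage_form_mix: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_DOSAGE_FORM_MIX)
    )
    diverter_profiles: list[BehaviorProfile] | None = None
    identity_variant_rate: float = 0.05
    noise_rates: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_NOISE_RATES)
    )
    n_pharmacy_techs: int = 6
    shift_work_prob: float = 0.5
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "SimConfig":
        if abs(sum(self.dosage_form_mix.values()) - 1.0) > 1e-9:
            raise ValueError("dosage_form_mix proportions must sum to 1")
        for form in self.dosage_form_mix:
            if form not in _MEDS_BY_FORM:
                raise ValueError(f"unknown dosage form {form!r}")
        if self.n_diverters > self.n_clinicians:
            raise ValueError("n_diverters must not exceed n_clinicians")
        start, end = self.date_range
        if (end - start).days < 1:
            raise ValueError("date_range must span at least 1 day")
        if not 0.0 <= self.identity_variant_rate <= 1.0:
            raise ValueError("identity_variant_rate must be in [0, 1]")
        for name, rate in self.noise_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"noise rate {name} must be in [0, 1]")
        if self.diverter_profiles is not None:
            if len(self.diverter_profiles) != self.n_diverters:
                raise ValueError("need one BehaviorProfile per diverter")
            for prof in self.diverter_profiles:
                if not start <= prof.onset_date <= end:
                    raise ValueError("onset_date outside date_range")
        return self


@dataclass
class GroundTruth:
    """Which clinicians divert, from when, and which transactions carry which
    injected behavior (referenced by the raw extract transaction ID)."""

    diverters: list[dict]  # {"clinician", "onset", "behavior_rates"}
    tags: list[dict]  # {"txn", "behavior"}
    counts: dict[str, int] = field(default_factory=dict)  # raw rows per system
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "diverters": self.diverters,
                "tags": self.tags,
                "counts": self.counts,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            diverters=obj["diverters"],
            tags=obj["tags"],
            counts=obj["counts"],
            seed=obj.get("seed", 0),
        )

    def onset_of(self, clinician: str) -> date:
        for d in self.diverters:
            if d["clinician"] == clinician:
                return date.fromisoformat(d["onset"])
        raise KeyError(clinician)


# --------------------------------------------------------------------------
# Generator internals
# --------------------------------------------------------------------------

def _fq(q: float, unit: str) -> str:
    """Format a quantity: integers for 'each', 2 decimals otherwise."""
    if unit == "each":
        return str(int(round(q)))
    return f"{float(q):.2f}"


@dataclass
class _Clin:
    canonical: str
    role: str  # "nursing" | "pharmacy"
    emr_user: str
    adc_user: str
    iis_user: str
    etc_id: str
    shift_start: int  # hour
    shift_len: int  # hours
    profile: BehaviorProfile | None = None
    intervals: list = field(default_factory=list)  # (punch_in, punch_out)


class _World:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.rows: dict[str, list[list[str]]] = {s: [] for s in COLUMNS}
        self._ids = {"E": 0, "A": 0, "I": 0, "W": 0, "T": 0}
        self.tags: list[dict] = []
        self.order_counter = 0
        self.patients = [f"P{i:04d}" for i in range(1, config.beds * 3 + 1)]
        self.stations = [f"RX-U{i:02d}" for i in range(1, 4)] + ["OR-NP"]
        self.vault: dict[str, float] = {m.canonical: 0.0 for m in CATALOG}
        self.shifts_by_day: dict[date, list[tuple]] = {}
        # dosing-interval registry: a patient is not re-dispensed the same
        # medication within 8 h, which also keeps rule-based custody linkage
        # unambiguous (all settle delays are < 8 h)
        self.given_at: dict[tuple, list[datetime]] = {}

    # -- id helpers --------------------------------------------------------
    def _next(self, prefix: str) -> str:
        self._ids[prefix] += 1
        return f"{prefix}{self._ids[prefix]:07d}"

    def _order_id(self) -> str:
        self.order_counter += 1
        return f"ORD{self.order_counter:06d}"

    # -- row emitters (one per dialect) ------------------------------------
    def emr_row(self, rtype, ts, user, patient, med, dose, unit, pain="",
                order="", dispref=""):
        rid = self._next("E")
        self.rows["EMR"].append(
            [rid, rtype, fmt_emr(ts), user, patient, med, dose, unit,
             str(pain), order, dispref]
        )
        return rid

    def adc_row(self, ts, station, user, witness, patient, med, txntype, qty,
                unit, orderref="", linkref=""):
        rid = self._next("A")
        self.rows["ADC"].append(
            [rid, fmt_adc(ts), station, user, witness, patient, med, txntype,
             qty, unit, orderref, linkref]
        )
        return rid

    def iis_row(self, ts, item, movetype, qty, unit, fromloc, toloc, tech,
                ref):
        rid = self._next("I")
        self.rows["IIS"].append(
            [rid, fmt_iso_date(ts), f"{ts.hour:02d}:{ts.minute:02d}", item,
             movetype, qty, unit, fromloc, toloc, tech, ref]
        )
        return rid

    def whl_row(self, day, invoice, ndc, desc, packages):
        rid = self._next("W")
        self.rows["WHL"].append(
            [rid, fmt_iso_date(day), invoice, ndc, desc, str(packages),
             "package"]
        )
        return rid

    def etc_row(self, employee, ts, ptype):
        rid = self._next("T")
        self.rows["ETC"].append([rid, employee, fmt_iso_minute(ts), ptype])
        return rid

    def tag(self, txn: str, behavior: str):
        self.tags.append({"txn": txn, "behavior": behavior})

    # -- population --------------------------------------------------------
    def build_clinicians(self) -> list[_Clin]:
        cfg = self.cfg
        rng = self.rng
        clins: list[_Clin] = []
        taken: set[str] = set()
        for i in range(cfg.n_clinicians):
            surname = _SURNAMES[int(rng.integers(0, len(_SURNAMES)))]
            initial = _INITIALS[int(rng.integers(0, len(_INITIALS)))]
            emr_user = f"{surname}_{initial}"
            k = 2
            while emr_user in taken:
                emr_user = f"{surname}_{initial}{k}"
                k += 1
            taken.add(emr_user)
            # married/maiden variant: the ADC knows a different surname
            if rng.random() < cfg.identity_variant_rate:
                maiden = _SURNAMES[int(rng.integers(0, len(_SURNAMES)))]
                adc_user = f"{maiden}_{initial}"
                k = 2
                while adc_user in taken:
                    adc_user = f"{maiden}_{initial}{k}"
                    k += 1
                taken.add(adc_user)
            else:
                adc_user = emr_user
            iis_user = (initial + surname).lower()
            k = 2
            while iis_user in taken:
                iis_user = f"{(initial + surname).lower()}{k}"
                k += 1
            taken.add(iis_user)
            role = "pharmacy" if i < cfg.n_pharmacy_techs else "nursing"
            if role == "pharmacy":
                start, length = 6, 9
            else:
                start = 7 if rng.random() < 0.6 else 19
                length = 8 if rng.random() < 0.5 else 12
            clins.append(
                _Clin(
                    canonical=f"C{i + 1:04d}",
                    role=role,
                    emr_user=emr_user,
                    adc_user=adc_user,
                    iis_user=iis_user,
                    etc_id=f"EMP{i + 1:05d}",
                    shift_start=start,
                    shift_len=length,
                )
            )
        return clins

    def assign_diverters(self, clins: list[_Clin]) -> list[_Clin]:
        cfg = self.cfg
        start, end = cfg.date_range
        span = (end - start).days
        profiles = cfg.diverter_profiles
        if profiles is None:
            profiles = []
            for _ in range(cfg.n_diverters):
                # onset in the 30-60% band of the window, leaving room both
                # for a clean pre-onset history and a post-onset alert trail
                offset = int(self.rng.integers(int(span * 0.3),
                                               max(int(span * 0.6), int(span * 0.3) + 1)))
                profiles.append(BehaviorProfile(onset_date=start + timedelta(days=offset)))
        nurses = [c for c in clins if c.role == "nursing"]
        techs = [c for c in clins if c.role == "pharmacy"]
        diverters: list[_Clin] = []
        for prof in profiles:
            supply = any(prof.behavior_rates.get(b, 0) > 0 for b in SUPPLY_BEHAVIORS)
            pool = techs if supply else nurses
            pool = [c for c in pool if c.profile is None]
            if not pool:
                raise ValueError("not enough clinicians to host diverter profiles")
            chosen = pool[int(self.rng.integers(0, len(pool)))]
            chosen.profile = prof
            diverters.append(chosen)
        return diverters

    # -- shifts ------------------------------------------------------------
    def build_shifts(self, clins: list[_Clin]):
        cfg = self.cfg
        rng = self.rng
        start, end = cfg.date_range
        n_days = (end - start).days + 1
        for clin in clins:
            for d in range(n_days):
                day = start + timedelta(days=d)
                if clin.role == "pharmacy":
                    works = day.weekday() < 5
                else:
                    works = rng.random() < cfg.shift_work_prob
                if not works:
                    continue
                s = datetime(day.year, day.month, day.day, clin.shift_start)
                e = s + timedelta(hours=clin.shift_len)
                punch_in = s - timedelta(minutes=int(rng.integers(1, 4)))
                punch_out = e + timedelta(minutes=int(rng.integers(1, 4)))
                self.etc_row(clin.etc_id, punch_in, "IN")
                self.etc_row(clin.etc_id, punch_out, "OUT")
                clin.intervals.append((punch_in, punch_out))
                self.shifts_by_day.setdefault(day, []).append((clin, s, e))

    def partner_for(self, clin: _Clin, day: date, ts: datetime) -> _Clin | None:
        """A non-diverting nurse on the clock at ts, for witness/handoff."""
        cands = [
            c
            for (c, s, e) in self.shifts_by_day.get(day, [])
            if c is not clin and c.profile is None and c.role == "nursing"
            and s <= ts <= e
        ]
        if not cands:
            return None
        return cands[int(self.rng.integers(0, len(cands)))]

    # -- supply chain ------------------------------------------------------
    def weekly_need(self, med: _Med) -> float:
        cfg = self.cfg
        nurses = cfg.n_clinicians - cfg.n_pharmacy_techs
        weekly_disp = nurses * cfg.shift_work_prob * 7 * cfg.dispense_rate
        share = cfg.dosage_form_mix.get(med.form, 0) / len(_MEDS_BY_FORM[med.form])
        mean_qty = float(np.mean(med.dispense_qtys))
        return weekly_disp * share * mean_qty

    def build_supply(self, clins: list[_Clin]):
        cfg = self.cfg
        rng = self.rng
        techs = [c for c in clins if c.role == "pharmacy"]
        start, end = cfg.date_range
        n_days = (end - start).days + 1
        ndcs, iis_ids, adc_ids = _NDC_IDS, _IIS_IDS, _ADC_IDS
        invoice_n = 0
        issue_n = 0
        for d in range(n_days):
            day = start + timedelta(days=d)
            if day.weekday() == 0:  # Monday: shipment + receipt
                for med in CATALOG:
                    need = self.weekly_need(med)
                    packages = math.ceil(need / med.package_size) + 1
                    invoice_n += 1
                    invoice = f"INV{invoice_n:05d}"
                    self.whl_row(day, invoice, ndcs[med.canonical],
                                 med.canonical, packages)
                    shipped = packages * med.package_size
                    tech = techs[int(rng.integers(0, len(techs)))]
                    received = shipped
                    ts = datetime(day.year, day.month, day.day, 9,
                                  int(rng.integers(0, 60)))
                    prof = tech.profile
                    tagged = None
                    if (
                        prof is not None
                        and day >= prof.onset_date
                        and rng.random() < prof.behavior_rates.get("shipment_shortfall", 0)
                    ):
                        received = round(shipped * 0.8, 2)
                        tagged = "shipment_shortfall"
                    rid = self.iis_row(ts, iis_ids[med.canonical], "RECEIPT",
                                       _fq(received, med.base_unit),
                                       med.base_unit, "DOCK", "VAULT",
                                       tech.iis_user, invoice)
                    if tagged:
                        self.tag(rid, tagged)
                    self.vault[med.canonical] += received
            if day.weekday() in (1, 3):  # Tue/Thu: vault issues -> restocks
                for med in CATALOG:
                    per_issue = max(
                        med.package_size / 5,
                        self.weekly_need(med) / (2 * len(self.stations[:2])),
                    )
                    for station in self.stations[:2]:
                        qty = min(self.vault[med.canonical], per_issue)
                        if qty <= 0:
                            continue
                        if med.base_unit == "each":
                            qty = float(int(qty))
                            if qty < 1:
                                continue
                        tech = techs[int(rng.integers(0, len(techs)))]
                        issue_n += 1
                        ref = f"ISS{issue_n:05d}"
                        ts = datetime(day.year, day.month, day.day, 10,
                                      int(rng.integers(0, 60)))
                        self.iis_row(ts, iis_ids[med.canonical], "ISSUE",
                                     _fq(qty, med.base_unit), med.base_unit,
                                     "VAULT", station, tech.iis_user, ref)
                        self.vault[med.canonical] -= qty
                        restocked = qty
                        tagged = None
                        prof = tech.profile
                        if (
                            prof is not None
                            and day >= prof.onset_date
                            and rng.random() < prof.behavior_rates.get("restock_shortfall", 0)
                        ):
                            restocked = round(qty * 0.8, 2)
                            if med.base_unit == "each":
                                restocked = float(int(restocked))
                            tagged = "restock_shortfall"
                        rid = self.adc_row(ts + timedelta(minutes=15), station,
                                           tech.adc_user, "", "",
                                           adc_ids[med.canonical], "RESTOCK",
                                           _fq(restocked, med.base_unit),
                                           med.base_unit, linkref=ref)
                        if tagged:
                            self.tag(rid, tagged)

    # -- nursing workflow --------------------------------------------------
    def _pick_patient(self, med: _Med, ts: datetime) -> str:
        """A patient due for this medication (>= 8 h from any other dose).

        Dispenses are generated clinician-major, not chronologically, so the
        check runs against every prior dose of that (patient, medication).
        """
        patient = None
        for _ in range(20):
            patient = self.patients[int(self.rng.integers(0, len(self.patients)))]
            times = self.given_at.get((patient, med.canonical), ())
            if all(abs((ts - t).total_seconds()) >= 8 * 3600 for t in times):
                break
        self.given_at.setdefault((patient, med.canonical), []).append(ts)
        return patient

    def pick_med(self) -> _Med:
        forms = list(self.cfg.dosage_form_mix)
        probs = np.array([self.cfg.dosage_form_mix[f] for f in forms])
        form = forms[int(self.rng.choice(len(forms), p=probs / probs.sum()))]
        meds = _MEDS_BY_FORM[form]
        return meds[int(self.rng.integers(0, len(meds)))]

    def emit_pain(self, clin: _Clin, patient: str, ts: datetime):
        score = int(self.rng.integers(4, 10))
        self.emr_row("PAIN", ts, clin.emr_user, patient, "", "", "", pain=score)

    def emit_dispense(self, clin: _Clin, ts: datetime, med: _Med, qty: float,
                      station: str, patient: str, order: str) -> str:
        return self.adc_row(ts, station, clin.adc_user, "", patient,
                            _ADC_IDS[med.canonical], "WITHDRAW",
                            _fq(qty, med.base_unit), med.base_unit,
                            orderref=order)

    def emit_admin(self, clin: _Clin, ts: datetime, med: _Med, qty: float,
                   patient: str, order: str, dispref: str = "",
                   med_override: _Med | None = None) -> str:
        target = med_override or med
        return self.emr_row("ADMIN", ts, clin.emr_user, patient,
                            _EMR_IDS[target.canonical],
                            _fq(qty, med.base_unit), med.base_unit,
                            order=order, dispref=dispref)

    def emit_waste(self, clin: _Clin, ts: datetime, med: _Med, qty: float,
                   station: str, patient: str, dispense_id: str,
                   witness: _Clin | None):
        return self.adc_row(ts, station, clin.adc_user,
                            witness.adc_user if witness else "", patient,
                            _ADC_IDS[med.canonical], "WASTE",
                            _fq(qty, med.base_unit), med.base_unit,
                            linkref=dispense_id)

    def emit_return(self, clin: _Clin, ts: datetime, med: _Med, qty: float,
                    station: str, patient: str, dispense_id: str):
        return self.adc_row(ts, station, clin.adc_user, "", patient,
                            _ADC_IDS[med.canonical], "RETURN",
                            _fq(qty, med.base_unit), med.base_unit,
                            linkref=dispense_id)

    def lawful_settle(self, clin: _Clin, t0: datetime, med: _Med, qty: float,
                      station: str, patient: str, disp_id: str, order: str,
                      noisy: bool):
        """Administer (and waste/return) a dispense the way policy expects;
        non-diverters may express benign documentation noise."""
        rng = self.rng
        noise = self.cfg.noise_rates if noisy else {}
        delay = int(rng.integers(5, 46))
        if rng.random() < noise.get("late_charting", 0):
            delay = int(rng.integers(241, 400))
        t_admin = t0 + timedelta(minutes=delay)
        if rng.random() < 0.03:  # changed mind: return unopened
            self.emit_return(clin, t0 + timedelta(minutes=int(rng.integers(10, 60))),
                             med, qty, station, patient, disp_id)
            return
        divisible = qty > 1 if med.base_unit == "each" else qty > 0
        if divisible and rng.random() < noise.get("partial_dose", 0):
            half = int(qty // 2) if med.base_unit == "each" else round(qty / 2, 2)
            self.emit_admin(clin, t_admin, med, half, patient, order)
            witness = self.partner_for(clin, t0.date(), t_admin)
            self.emit_waste(clin, t_admin + timedelta(minutes=int(rng.integers(5, 16))),
                            med, qty - half, station, patient, disp_id, witness)
            return
        if med.form == "infusion":
            self.emit_admin(clin, t_admin, med, round(qty * 0.6, 2), patient, order)
            self.emit_admin(clin, t_admin + timedelta(minutes=60), med,
                            round(qty * 0.4, 2), patient, order)
        elif med.form == "PCA":
            split = round(qty / 3, 2)
            self.emit_admin(clin, t_admin, med, split, patient, order)
            self.emit_admin(clin, t_admin + timedelta(minutes=90), med, split,
                            patient, order)
            self.emit_admin(clin, t_admin + timedelta(minutes=180), med,
                            round(qty - 2 * split, 2), patient, order)
        else:
            self.emit_admin(clin, t_admin, med, qty, patient, order)

    def run_dispense(self, clin: _Clin, day: date, shift_start: datetime,
                     shift_end: datetime, t0: datetime):
        """One dispense opportunity: lawful workflow, benign noise, or — for a
        post-onset diverter — a drawn behavior."""
        rng = self.rng
        cfg = self.cfg
        med = self.pick_med()
        if med.form in ("PCA", "infusion"):
            # cumulative administrations run ~4 h; start them early enough
            # that the last dose is still charted on the clock
            latest = shift_end - timedelta(minutes=250)
            if t0 > latest:
                t0 = max(latest, shift_start + timedelta(minutes=15))
                t0 = t0.replace(second=0, microsecond=0)
        qty = float(med.dispense_qtys[int(rng.integers(0, len(med.dispense_qtys)))])
        station = self.stations[int(rng.integers(0, len(self.stations)))]
        order = self._order_id()

        prof = clin.profile
        behavior = None
        if prof is not None and day >= prof.onset_date:
            u = rng.random()
            acc = 0.0
            for name in DISPENSE_BEHAVIORS:
                acc += prof.behavior_rates.get(name, 0.0)
                if u < acc:
                    behavior = name
                    break

        if behavior == "pain_score_anomaly" and not med.prn_analgesic:
            med = _PRN_MEDS[int(rng.integers(0, len(_PRN_MEDS)))]
            qty = float(med.dispense_qtys[int(rng.integers(0, len(med.dispense_qtys)))])
        if (
            behavior in ("late_wasting", "partial_waste_return", "bulk_wasting")
            and med.base_unit == "each"
            and qty < 2
        ):
            qty = 2.0  # splittable quantity so a partial waste is possible
        if behavior == "off_clock_access":
            # access the cabinet well after the end of this shift
            t0 = shift_end + timedelta(minutes=int(rng.integers(95, 305)))
            t0 = t0.replace(second=0, microsecond=0)
        patient = self._pick_patient(med, t0)

        # pain assessment precedes any PRN analgesic dispense, unless the
        # behavior (or benign noise) is to skip it
        skip_pain = behavior == "pain_score_anomaly" or (
            behavior is None
            and prof is None
            and rng.random() < cfg.noise_rates.get("pain_miss", 0)
        )
        if med.prn_analgesic and not skip_pain:
            self.emit_pain(clin, patient, t0 - timedelta(minutes=int(rng.integers(5, 15))))

        disp_id = self.emit_dispense(clin, t0, med, qty, station, patient, order)

        if behavior is None:
            # diverters chart cleanly when not expressing a behavior, so that
            # every ground-truth alert traces to an injected tag
            self.lawful_settle(clin, t0, med, qty, station, patient, disp_id,
                               order, noisy=prof is None)
            return

        self.tag(disp_id, behavior)
        m = lambda lo, hi: timedelta(minutes=int(rng.integers(lo, hi)))
        witness = self.partner_for(clin, day, t0)
        if behavior == "full_wasting":
            self.emit_waste(clin, t0 + m(10, 31), med, qty, station, patient,
                            disp_id, witness)
        elif behavior == "no_administration":
            pass
        elif behavior == "late_wasting":
            half = int(qty // 2) if med.base_unit == "each" else round(qty / 2, 2)
            half = max(half, 0.5 if med.base_unit != "each" else 1)
            self.emit_admin(clin, t0 + m(10, 31), med, half, patient, order)
            self.emit_waste(clin, t0 + m(245, 420), med, qty - half, station,
                            patient, disp_id, witness)
        elif behavior == "late_administration":
            self.emit_admin(clin, t0 + m(245, 420), med, qty, patient, order)
        elif behavior == "partial_waste_return":
            part = int(qty // 2) if med.base_unit == "each" else round(qty / 2, 2)
            part = max(part, 0.5 if med.base_unit != "each" else 1)
            self.emit_waste(clin, t0 + m(10, 31), med, part, station, patient,
                            disp_id, witness)
        elif behavior == "bulk_wasting":
            # two sibling dispenses, then three wastes within a 10-min window
            half = int(qty // 2) if med.base_unit == "each" else round(qty / 2, 2)
            half = max(half, 0.5 if med.base_unit != "each" else 1)
            sibs = [(disp_id, t0, qty, patient)]
            for k in (1, 2):
                tk = t0 + timedelta(minutes=3 * k)
                sib_patient = self._pick_patient(med, tk)
                if med.prn_analgesic:
                    self.emit_pain(clin, sib_patient,
                                   tk - timedelta(minutes=int(rng.integers(5, 15))))
                sid = self.emit_dispense(clin, tk, med, qty, station,
                                         sib_patient, self._order_id())
                self.tag(sid, "bulk_wasting")
                sibs.append((sid, tk, qty, sib_patient))
            base = t0 + timedelta(minutes=40)
            for k, (sid, tk, q, pat) in enumerate(sibs):
                h = int(q // 2) if med.base_unit == "each" else round(q / 2, 2)
                h = max(h, 0.5 if med.base_unit != "each" else 1)
                self.emit_admin(clin, tk + timedelta(minutes=10), med, h,
                                pat, order)
                self.emit_waste(clin, base + timedelta(minutes=3 * k), med,
                                q - h, station, pat, sid, witness)
        elif behavior == "handoffs":
            partner = self.partner_for(clin, day, t0 + timedelta(minutes=20))
            if partner is None:
                self.tags.pop()
                self.lawful_settle(clin, t0, med, qty, station, patient,
                                   disp_id, order, noisy=False)
                return
            self.emit_admin(partner, t0 + m(10, 46), med, qty, patient, order)
        elif behavior == "incorrect_order":
            self.emit_admin(clin, t0 - m(5, 21), med, qty, patient, order,
                            dispref=disp_id)
        elif behavior == "incorrect_medication":
            others = [x for x in CATALOG if x.canonical != med.canonical]
            wrong = others[int(rng.integers(0, len(others)))]
            self.emit_admin(clin, t0 + m(10, 46), med, qty, patient, order,
                            dispref=disp_id, med_override=wrong)
        elif behavior == "off_clock_access":
            self.emit_admin(clin, t0 + m(5, 31), med, qty, patient, order)
        elif behavior == "pain_score_anomaly":
            self.emit_admin(clin, t0 + m(10, 46), med, qty, patient, order)

    def run_nursing(self, clins: list[_Clin]):
        rng = self.rng
        for clin in clins:
            if clin.role != "nursing":
                continue
            for punch_in, punch_out in clin.intervals:
                day = punch_in.date()
                shift_start = punch_in + timedelta(minutes=3)
                shift_end = punch_out - timedelta(minutes=3)
                n = int(rng.poisson(self.cfg.dispense_rate))
                span = int((shift_end - shift_start).total_seconds() // 60) - 135
                if span <= 0:
                    continue
                offsets = sorted(int(rng.integers(15, 15 + span)) for _ in range(n))
                for off in offsets:
                    t0 = (shift_start + timedelta(minutes=off)).replace(
                        second=0, microsecond=0)
                    self.run_dispense(clin, day, shift_start, shift_end, t0)


# --------------------------------------------------------------------------
# Public API
# --------------------------------------------------------------------------

def _write_delim(path: Path, system: str, rows: list[list[str]]):
    import csv

    # minimal quoting: EMR timestamps legitimately contain the comma delimiter
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=DELIMITERS[system],
                            quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
        writer.writerow(COLUMNS[system])
        for row in rows:
            writer.writerow([str(v) for v in row])


def _write_maps(out: Path, clins: list[_Clin]):
    lines = ["system,local_med_id,canonical_med_id,dosage_form,local_unit,"
             "factor_to_base,base_unit,prn_analgesic"]
    for i, med in enumerate(CATALOG):
        locals_ = {
            "EMR": (f"E{1000 + i:04d}", med.base_unit, 1),
            "ADC": (f"OMN-{100 + i:03d}", med.base_unit, 1),
            "IIS": (f"IIS-{5000 + i:04d}", med.base_unit, 1),
            "WHL": (f"00409-{1200 + i:04d}-01", "package", med.package_size),
        }
        for system, (lid, unit, factor) in locals_.items():
            lines.append(
                f"{system},{lid},{med.canonical},{med.form},{unit},"
                f"{factor},{med.base_unit},{int(med.prn_analgesic)}"
            )
    (out / "formulary_map.csv").write_text("\n".join(lines) + "\n", "utf-8")

    lines = ["system,local_username,canonical_clinician_id,role"]
    for c in clins:
        for system, user in (("EMR", c.emr_user), ("ADC", c.adc_user),
                             ("IIS", c.iis_user), ("ETC", c.etc_id)):
            lines.append(f"{system},{user},{c.canonical},{c.role}")
    (out / "identity_map.csv").write_text("\n".join(lines) + "\n", "utf-8")


def simulate(config: SimConfig, out_dir: str | Path) -> tuple[dict[str, Path], GroundTruth]:
    """Generate the five extract files plus cross-maps and ground truth.

    Returns a mapping of logical names to written paths, and the
    :class:`GroundTruth`.  Identical configs (including seed) produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world = _World(config)
    clins = world.build_clinicians()
    diverters = world.assign_diverters(clins)
    world.build_shifts(clins)
    world.build_supply(clins)
    world.run_nursing(clins)

    paths: dict[str, Path] = {}
    for system, fname in EXTRACT_FILENAMES.items():
        path = out / fname
        _write_delim(path, system, world.rows[system])
        paths[system] = path
    _write_maps(out, clins)
    paths["formulary_map"] = out / "formulary_map.csv"
    paths["identity_map"] = out / "identity_map.csv"

    truth = GroundTruth(
        diverters=[
            {
                "clinician": c.canonical,
                "onset": c.profile.onset_date.isoformat(),
                "behavior_rates": c.profile.behavior_rates,
            }
            for c in diverters
        ],
        tags=world.tags,
        counts={s: len(world.rows[s]) for s in world.rows},
        seed=config.seed,
    )
    truth_path = out / "truth.json"
    truth_path.write_text(truth.to_json(), "utf-8")
    paths["truth"] = truth_path
    return paths, truth


def write_known_incident_roster(
    truth: GroundTruth,
    out_path: str | Path,
    lag_days: tuple[float, float] = (10, 30),
    seed: int = 0,
    site: str = "synthetic",
    end_date: date | None = None,
):
    """Write the known-incident roster: one row per diverter with the date
    existing methods would have caught them (onset + a sampled lag).

    ``lag_days`` is the (low, high) of a uniform integer lag in days; both
    bounds must be nonnegative.  Detection dates are clamped to ``end_date``
    when given, keeping them inside the simulated window.
    """
    lo, hi = lag_days
    if lo < 0 or hi < lo:
        raise ValueError("lag_days must satisfy 0 <= low <= high")
    rng = np.random.default_rng(seed)
    import pandas as pd

    rows = []
    for d in truth.diverters:
        onset = date.fromisoformat(d["onset"])
        lag = int(rng.integers(int(lo), int(hi) + 1))
        detected = onset + timedelta(days=lag)
        if end_date is not None and detected > end_date:
            detected = end_date
        rows.append({"clinician": d["clinician"],
                     "detected_date": detected.isoformat(), "site": site})
    roster = pd.DataFrame(rows, columns=["clinician", "detected_date", "site"])
    roster.to_csv(out_path, index=False)
    return roster
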