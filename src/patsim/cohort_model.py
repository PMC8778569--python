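"""Domain types and I/O for sequential EMR cohorts.

A patient's hospitalization is modelled as (1) three timestamped event
sequences (laboratory tests, radiological examinations, procedures),
(2) a set of lab-test time series (a test observed on two or more days),
(3) cross-sectional features: four binary demographics, admission-only
lab values, and binary features extracted from radiology report text,
and (4) binary outcomes (in-hospital mortality, readmission) plus the
length of stay in days.

Days are 1-based integers (admission day = 1). Predictions are made at
three index time points — admission, day 7, discharge — and
:func:`truncate_cohort` restricts a cohort to the information available
at each of them.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

DOMAINS = ("lab", "rad", "pro")

#: registry names of the three event-sequence similarity features
SEQUENCE_FEATURES = {d: f"S_{d}-edit" for d in DOMAINS}

DEMOGRAPHIC_FIELDS = ("age_ge60", "male", "married", "insured")


class ValidationError(ValueError):
    """Raised when input rows violate the cohort data contracts."""


@dataclass(frozen=True)
class ClinicalEvent:
    """One clinical process: an event code and the day-of-stay it occurred."""

    code: str
    day: int

    def __post_init__(self) -> None:
        if not self.code:
            raise ValidationError("event code must be nonempty")
        if self.day < 1:
            raise ValidationError(
                f"event {self.code!r} has day {self.day}; days are 1-based"
            )


@dataclass(frozen=True)
class EventSequence:
    """Ordered clinical events of one domain for one patient.

    Events are sorted by day; same-day events are ordered alphabetically
    by code, so the sequence is a deterministic function of the raw rows.
    """

    domain: str
    events: tuple[ClinicalEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValidationError(f"unknown domain {self.domain!r}")

    @property
    def m(self) -> int:
        return len(self.events)

    def truncated(self, cutoff_day: float) -> "EventSequence":
        return EventSequence(
            self.domain, tuple(e for e in self.events if e.day <= cutoff_day)
        )


def build_event_sequence(
    raw_events: list[tuple[str, int]], domain: str
) -> EventSequence:
    """Order raw (code, day) rows into an :class:`EventSequence`.

    Events are placed by day; ties within a day are broken alphabetically
    by code. Duplicate (code, day) pairs are retained — a test can be
    repeated on the same day.
    """
    events = [ClinicalEvent(code, day) for code, day in raw_events]
    events.sort(key=lambda e: (e.day, e.code))
    return EventSequence(domain, tuple(events))


@dataclass(frozen=True)
class LabTimeSeries:
    """Temporally ordered numeric values of one lab test for one patient."""

    test_id: str
    values: tuple[float, ...]
    days: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.days) or not self.values:
            raise ValidationError(
                f"series {self.test_id!r}: values and days must align and be nonempty"
            )
        if any(b < a for a, b in zip(self.days, self.days[1:])):
            raise ValidationError(f"series {self.test_id!r}: days must be sorted")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def is_trend(self) -> bool:
        """A series qualifies as a trend feature only with >= 2 values."""
        return len(self.values) >= 2

    def truncated(self, cutoff_day: float) -> "LabTimeSeries | None":
        keep = [(v, d) for v, d in zip(self.values, self.days) if d <= cutoff_day]
        if not keep:
            return None
        vals, days = zip(*keep)
        return LabTimeSeries(self.test_id, vals, days)


@dataclass(frozen=True)
class DemographicVector:
    """Four binary indicators: age >= 60 years, male, married, insured."""

    age_ge60: int = 0
    male: int = 0
    married: int = 0
    insured: int = 0

    def __post_init__(self) -> None:
        for name in DEMOGRAPHIC_FIELDS:
            if getattr(self, name) not in (0, 1):
                raise ValidationError(f"demographic {name} must be 0 or 1")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.age_ge60, self.male, self.married, self.insured)


@dataclass(frozen=True)
class TimePoint:
    """Index time point up to which information is available."""

    label: str
    cutoff_day: float

    def __post_init__(self) -> None:
        if self.cutoff_day < 1:
            raise ValidationError("cutoff_day must be >= 1")


ADMISSION = TimePoint("admission", 1)
DAY7 = TimePoint("day7", 7)
DISCHARGE = TimePoint("discharge", math.inf)

TIMEPOINTS = {tp.label: tp for tp in (ADMISSION, DAY7, DISCHARGE)}


@dataclass
class PatientRecord:
    """Per-patient bundle of sequences, series, cross-sectional data, outcomes."""

    patient_id: str
    demographics: DemographicVector
    sequences: dict[str, EventSequence] = field(default_factory=dict)
    series: dict[str, LabTimeSeries] = field(default_factory=dict)
    cross_labs: dict[str, float] = field(default_factory=dict)
    report_text: str = ""
    text_features: tuple[int, ...] | None = None
    mortality: int = 0
    readmission: int = 0
    length_of_stay: int = 1
    excluded: bool = False  # short-stay exclusion flag for day-7 training

    def __post_init__(self) -> None:
        if self.mortality not in (0, 1) or self.readmission not in (0, 1):
            raise ValidationError(
                f"patient {self.patient_id}: outcomes must be binary"
            )
        if self.length_of_stay < 1:
            raise ValidationError(
                f"patient {self.patient_id}: length_of_stay must be >= 1"
            )
        for d in DOMAINS:
            self.sequences.setdefault(d, EventSequence(d))


@dataclass
class Cohort:
    """Ordered patient records plus the registry of candidate similarity features."""

    patients: list[PatientRecord]
    feature_registry: list[str] = field(default_factory=list)
    timepoint: TimePoint = DISCHARGE

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValidationError("patient_ids must be unique")
        if not self.feature_registry:
            self.feature_registry = default_registry(self.patients)
        if len(set(self.feature_registry)) != len(self.feature_registry):
            raise ValidationError("registry names must be unique")

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def trend_tests(self) -> list[str]:
        """Lab tests registered as trend features (>= 2 values for someone)."""
        tests: set[str] = set()
        for p in self.patients:
            tests.update(t for t, s in p.series.items() if s.is_trend)
        return sorted(tests)

    def outcomes(self, which: str) -> list[int]:
        if which not in ("mortality", "readmission"):
            raise ValidationError(f"unknown outcome {which!r}")
        return [getattr(p, which) for p in self.patients]


def default_registry(patients: list[PatientRecord]) -> list[str]:
    """Full feature registry at discharge: sequences, trends, cross-sectional."""
    registry = [SEQUENCE_FEATURES[d] for d in DOMAINS]
    tests: set[str] = set()
    for p in patients:
        tests.update(t for t, s in p.series.items() if s.is_trend)
    for t in sorted(tests):
        registry.append(f"S_dtw:{t}")
        registry.append(f"S_haar:{t}")
    registry += ["S_dem", "S_lab"]
    if any(p.report_text or p.text_features for p in patients):
        registry.append("S_text")
    return registry


# ---------------------------------------------------------------------------
# readers / writers


def read_cohort(events_path, labs_path, patients_path) -> Cohort:
    """Assemble a :class:`Cohort` from the three long-format CSV extracts.

    ``events.csv``: patient_id,domain,event_code,day;
    ``labs.csv``: patient_id,test_id,day,value;
    ``patients.csv``: patient_id,age_ge60,male,married,insured,mortality,
    readmission,length_of_stay,report_text.

    A patient's lab test with >= 2 values becomes a time series (trend
    feature); a test with a single value is routed to the admission-only
    cross-sectional panel.
    """
    events = pd.read_csv(events_path, dtype={"patient_id": str})
    labs = pd.read_csv(labs_path, dtype={"patient_id": str})
    patients = pd.read_csv(patients_path, dtype={"patient_id": str})

    bad = ~events["domain"].isin(DOMAINS)
    if bad.any():
        row = events.index[bad][0]
        raise ValidationError(
            f"{events_path}, row {row + 2}: unknown domain "
            f"{events.loc[row, 'domain']!r}"
        )
    if labs["value"].isna().any() or not pd.api.types.is_numeric_dtype(labs["value"]):
        bad_rows = labs.index[pd.to_numeric(labs["value"], errors="coerce").isna()]
        raise ValidationError(
            f"{labs_path}, row {bad_rows[0] + 2}: non-numeric lab value"
        )
    if patients["patient_id"].isna().any():
        row = patients.index[patients["patient_id"].isna()][0]
        raise ValidationError(f"{patients_path}, row {row + 2}: missing patient id")

    ev_by_pat = {pid: g for pid, g in events.groupby("patient_id")}
    lab_by_pat = {pid: g for pid, g in labs.groupby("patient_id")}

    records = []
    for row in patients.itertuples(index=False):
        pid = row.patient_id
        demo_vals = {}
        for name in DEMOGRAPHIC_FIELDS:
            v = getattr(row, name)
            if pd.isna(v):
                logger.warning("patient %s: missing demographic %s set to 0", pid, name)
                v = 0
            demo_vals[name] = int(v)
        sequences = {}
        g = ev_by_pat.get(pid)
        for d in DOMAINS:
            rows = [] if g is None else list(
                g.loc[g["domain"] == d, ["event_code", "day"]].itertuples(index=False)
            )
            sequences[d] = build_event_sequence(
                [(r.event_code, int(r.day)) for r in rows], d
            )
        series: dict[str, LabTimeSeries] = {}
        cross_labs: dict[str, float] = {}
        lg = lab_by_pat.get(pid)
        if lg is not None:
            for test, tg in lg.groupby("test_id"):
                tg = tg.sort_values("day")
                vals = tuple(float(v) for v in tg["value"])
                days = tuple(int(d) for d in tg["day"])
                if len(vals) >= 2:
                    series[test] = LabTimeSeries(test, vals, days)
                else:
                    cross_labs[test] = vals[0]
        text = "" if pd.isna(row.report_text) else str(row.report_text)
        records.append(
            PatientRecord(
                patient_id=pid,
                demographics=DemographicVector(**demo_vals),
                sequences=sequences,
                series=series,
                cross_labs=cross_labs,
                report_text=text,
                mortality=int(row.mortality),
                readmission=int(row.readmission),
                length_of_stay=int(row.length_of_stay),
            )
        )
    return Cohort(records)


def write_cohort(cohort: Cohort, events_path, labs_path, patients_path) -> None:
    """Write the three CSV extracts (inverse of :func:`read_cohort`)."""
    ev_rows, lab_rows, pat_rows = [], [], []
    for p in cohort.patients:
        for d in DOMAINS:
            for e in p.sequences[d].events:
                ev_rows.append((p.patient_id, d, e.code, e.day))
        for s in p.series.values():
            for v, d in zip(s.values, s.days):
                lab_rows.append((p.patient_id, s.test_id, d, v))
        for t, v in p.cross_labs.items():
            lab_rows.append((p.patient_id, t, 1, v))
        pat_rows.append(
            (p.patient_id, *p.demographics.as_tuple(), p.mortality,
             p.readmission, p.length_of_stay, p.report_text)
        )
    pd.DataFrame(
        ev_rows, columns=["patient_id", "domain", "event_code", "day"]
    ).to_csv(events_path, index=False)
    pd.DataFrame(
        lab_rows, columns=["patient_id", "test_id", "day", "value"]
    ).to_csv(labs_path, index=False)
    pd.DataFrame(
        pat_rows,
        columns=["patient_id", *DEMOGRAPHIC_FIELDS, "mortality", "readmission",
                 "length_of_stay", "report_text"],
    ).to_csv(patients_path, index=False)


def cohort_to_json(cohort: Cohort) -> str:
    """Serialize a cohort to JSON (fixture round-trips)."""
    payload = {
        "timepoint": cohort.timepoint.label,
        "registry": cohort.feature_registry,
        "patients": [
            {
                "patient_id": p.patient_id,
                "demographics": p.demographics.as_tuple(),
                "sequences": {
                    d: [[e.code, e.day] for e in p.sequences[d].events]
                    for d in DOMAINS
                },
                "series": {
                    t: {"values": list(s.values), "days": list(s.days)}
                    for t, s in p.series.items()
                },
                "cross_labs": p.cross_labs,
                "report_text": p.report_text,
                "text_features": list(p.text_features) if p.text_features else None,
                "mortality": p.mortality,
                "readmission": p.readmission,
                "length_of_stay": p.length_of_stay,
                "excluded": p.excluded,
            }
            for p in cohort.patients
        ],
    }
    return json.dumps(payload, indent=1)


def cohort_from_json(text: str) -> Cohort:
    payload = json.loads(text)
    records = []
    for p in payload["patients"]:
        records.append(
            PatientRecord(
                patient_id=p["patient_id"],
                demographics=DemographicVector(*p["demographics"]),
                sequences={
                    d: EventSequence(
                        d, tuple(ClinicalEvent(c, t) for c, t in evs)
                    )
                    for d, evs in p["sequences"].items()
                },
                series={
                    t: LabTimeSeries(t, tuple(s["values"]), tuple(s["days"]))
                    for t, s in p["series"].items()
                },
                cross_labs=p["cross_labs"],
                report_text=p["report_text"],
                text_features=tuple(p["text_features"]) if p["text_features"] else None,
                mortality=p["mortality"],
                readmission=p["readmission"],
                length_of_stay=p["length_of_stay"],
                excluded=p.get("excluded", False),
            )
        )
    return Cohort(
        records,
        feature_registry=payload["registry"],
        timepoint=TIMEPOINTS[payload["timepoint"]],
    )


# ---------------------------------------------------------------------------
# index-time-point truncation


def truncate_cohort(cohort: Cohort, timepoint: TimePoint) -> Cohort:
    """Restrict a cohort to the information available at an index time point.

    Discharge is the identity on event/series content. At day 7, events
    and series values after day 7 are dropped, series left with fewer
    than 2 values are demoted to the cross-sectional panel, report-text
    features are disabled (radiology reports are too sparse in the first
    week), and patients with a stay shorter than 7 days are flagged for
    exclusion from training. At admission only the cross-sectional
    demographic and lab features remain — no temporal feature can be
    computed from a single day, so the registry shrinks to S_dem, S_lab.
    """
    cutoff = timepoint.cutoff_day
    records = []
    for p in cohort.patients:
        if timepoint.label == "admission":
            # single-value series collapse into the cross-sectional panel
            cross = dict(p.cross_labs)
            for t, s in p.series.items():
                st = s.truncated(cutoff)
                if st is not None:
                    cross.setdefault(t, st.values[0])
            records.append(
                replace(
                    p,
                    sequences={d: EventSequence(d) for d in DOMAINS},
                    series={},
                    cross_labs=cross,
                    report_text="",
                    text_features=None,
                    excluded=False,
                )
            )
            continue
        sequences = {d: p.sequences[d].truncated(cutoff) for d in DOMAINS}
        series: dict[str, LabTimeSeries] = {}
        cross = dict(p.cross_labs)
        for t, s in p.series.items():
            st = s.truncated(cutoff)
            if st is None:
                continue
            if st.is_trend:
                series[t] = st
            else:
                cross.setdefault(t, st.values[0])
        rec = replace(p, sequences=sequences, series=series, cross_labs=cross)
        if timepoint.label == "day7":
            rec = replace(
                rec,
                report_text="",
                text_features=None,
                excluded=p.length_of_stay < 7,
            )
        records.append(rec)

    registry = default_registry(records)
    if timepoint.label == "admission":
        registry = ["S_dem", "S_lab"]
    truncated = Cohort(records, feature_registry=registry, timepoint=timepoint)
    return truncated
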