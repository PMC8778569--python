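"""Synthetic EMR cohort generator.

Emulates the statistical structure the similarity framework assumes:
per-patient timestamped event sequences in three domains (lab, rad,
pro) with uneven daily rates, variable-length lab time series observed
at irregular days (linear trend + Gaussian noise), binary demographics,
radiology-style report text built from a phrase lexicon, and binary
outcomes whose probability depends on a latent patient class.

Defaults follow the scale of a hospitalized acute-MI cohort: ~8.5%
mortality prevalence (class mix of 2% and 15% risk), mean stay ~10.5
days (SD ~6), ~6-7 procedures and ~3 radiological examinations per
stay. The latent class signals every feature family, with the
procedure sequence carrying the strongest, so that single-feature
ranking in dominant-feature selection is testable: class-1 patients
receive distinctive rescue procedures and a rising (rather than flat)
creatinine-like trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_model import (
    Cohort,
    DemographicVector,
    EventSequence,
    PatientRecord,
    ValidationError,
    build_event_sequence,
)
from .cohort_model import ClinicalEvent, LabTimeSeries
from .cross_sectional_similarity import TextLexicon, apply_lexicon
from .sequence_similarity import EditOperation, OperationSeries

#: default phrase lexicon for synthetic radiology reports
DEFAULT_LEXICON = TextLexicon(
    (
        "normal LVEF",
        "reduced LVEF",
        "pleural effusion",
        "pulmonary edema",
        "cardiomegaly",
        "wall motion abnormality",
    )
)


@dataclass(frozen=True)
class LabTrendParams:
    """Per-class linear trend of one lab test: value = intercept + slope*day + noise."""

    intercept: tuple[float, float]
    slope: tuple[float, float]
    noise_sd: float
    daily_rate: float  # expected observations per day of stay
    missing_prob: float = 0.05


def _default_lab_trends() -> dict[str, LabTrendParams]:
    return {
        # strongest trend signal: renal function deteriorates in class 1
        "serum_creatinine": LabTrendParams((1.0, 1.1), (0.0, 0.15), 0.15, 0.45, 0.05),
        "serum_glucose": LabTrendParams((6.0, 6.6), (0.0, 0.05), 0.8, 0.45, 0.05),
        "troponin": LabTrendParams((0.5, 1.0), (-0.05, 0.02), 0.4, 0.35, 0.10),
        "wbc_count": LabTrendParams((8.0, 8.5), (0.0, 0.0), 1.5, 0.35, 0.10),
    }


def _default_event_params() -> dict[str, dict]:
    # per domain: shared vocabulary, class-specific extra vocabulary, daily
    # rates, and an optional fixed per-class motif of (code, day) events.
    # The class-1 procedure motif — rescue procedures on characteristic early
    # days — is the dominant planted signal: between-class pairs must pay
    # delete+insert for every motif event, within-class pairs substitute
    # cheaply, so the procedure edit similarity separates the classes
    # more sharply than any other feature.
    return {
        "lab": {
            "vocab": ["cbc_panel", "chem_panel", "coag_panel", "abg", "lipids"],
            "class_vocab": [[], ["lactate", "bnp"]],
            "rate": (1.1, 1.2),
        },
        "rad": {
            "vocab": ["chest_xray", "color_sonography"],
            "class_vocab": [[], ["ct_chest"]],
            "rate": (0.28, 0.35),
        },
        "pro": {
            "vocab": ["pci", "ecg_monitoring"],
            "class_vocab": [[], []],
            "rate": (0.30, 0.35),
            "motif": [
                [("cardiac_rehab", 2), ("echo_followup", 5)],
                [("iabp", 1), ("crrt", 2), ("ventilation", 2), ("crrt", 4)],
            ],
        },
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator (see module docstring)."""

    n_patients: int = 300
    class_mixture: tuple[float, ...] = (0.5, 0.5)
    mortality_probs: tuple[float, ...] = (0.02, 0.15)
    readmission_probs: tuple[float, ...] = (0.04, 0.10)
    # length of stay ~ round(Gamma(shape, scale)) clipped to >= 1:
    # mean ~10.5 days, SD ~6
    los_gamma_shape: float = 3.0
    los_gamma_scale: float = 3.5
    demographic_probs: tuple[tuple[float, ...], ...] = (
        (0.6, 0.6, 0.7, 0.7),  # class 0: age>=60, male, married, insured
        (0.8, 0.7, 0.7, 0.7),  # class 1 skews older
    )
    text_phrase_probs: tuple[tuple[float, ...], ...] = (
        (0.6, 0.10, 0.12, 0.08, 0.18, 0.12),
        (0.4, 0.35, 0.25, 0.22, 0.30, 0.30),
    )
    cross_lab_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"ldl_cholesterol": (3.0, 3.4), "hba1c": (5.8, 6.2)}
    )
    cross_lab_sd: float = 0.5
    lab_trends: dict[str, LabTrendParams] = field(default_factory=_default_lab_trends)
    event_params: dict[str, dict] = field(default_factory=_default_event_params)
    lexicon: TextLexicon = DEFAULT_LEXICON
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValidationError("n_patients must be >= 2")
        if abs(sum(self.class_mixture) - 1.0) > 1e-9 or min(self.class_mixture) < 0:
            raise ValidationError("class mixture must be a probability vector")
        for probs in (self.mortality_probs, self.readmission_probs):
            if len(probs) != len(self.class_mixture) or not all(
                0 <= p <= 1 for p in probs
            ):
                raise ValidationError("per-class outcome probabilities invalid")


#: the feature the default configuration plants as strongest (class-specific
#: rescue procedures make the procedure sequence maximally class-separated)
PLANTED_STRONGEST_FEATURE = "S_pro-edit"


def generate_cohort(
    config: GeneratorConfig | None = None, return_classes: bool = False
):
    """Sample a reproducible synthetic cohort from ``config`` (seeded).

    With ``return_classes`` the latent class of each patient is returned
    alongside the cohort (useful for checking planted structure).
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n_classes = len(config.class_mixture)
    records = []
    classes = []
    for i in range(config.n_patients):
        cls = int(rng.choice(n_classes, p=config.class_mixture))
        classes.append(cls)
        los = max(1, int(round(rng.gamma(config.los_gamma_shape, config.los_gamma_scale))))
        sequences = {
            d: _sample_sequence(rng, d, cls, los, config.event_params[d])
            for d in ("lab", "rad", "pro")
        }
        series = {}
        for test, p in config.lab_trends.items():
            if rng.random() < p.missing_prob:
                continue
            s = _sample_series(rng, test, cls, los, p)
            if s is not None:
                series[test] = s
        cross = {
            t: float(rng.normal(means[cls], config.cross_lab_sd))
            for t, means in config.cross_lab_means.items()
        }
        demo = DemographicVector(
            *(int(rng.random() < q) for q in config.demographic_probs[cls])
        )
        present = [
            phrase
            for phrase, q in zip(config.lexicon.phrases, config.text_phrase_probs[cls])
            if rng.random() < q
        ]
        report = "Report: " + "; ".join(present) if present else "Report: unremarkable"
        records.append(
            PatientRecord(
                patient_id=f"p{i:04d}",
                demographics=demo,
                sequences=sequences,
                series=series,
                cross_labs=cross,
                report_text=report,
                mortality=int(rng.random() < config.mortality_probs[cls]),
                readmission=int(rng.random() < config.readmission_probs[cls]),
                length_of_stay=los,
            )
        )
    cohort = Cohort(records)
    apply_lexicon(cohort, config.lexicon)
    if return_classes:
        return cohort, np.array(classes)
    return cohort


def _sample_sequence(rng, domain, cls, los, params) -> EventSequence:
    vocab = list(params["vocab"]) + list(params["class_vocab"][cls])
    rate = params["rate"][cls]
    raw = []
    for day in range(1, los + 1):
        for _ in range(rng.poisson(rate)):
            raw.append((vocab[rng.integers(len(vocab))], day))
    for code, day in params.get("motif", [[], []])[cls]:
        if day <= los:
            raw.append((code, day))
    return build_event_sequence(raw, domain)


def _sample_series(rng, test, cls, los, p: LabTrendParams):
    n_obs = max(2, rng.poisson(p.daily_rate * los))
    n_obs = min(n_obs, los) if los >= 2 else 2
    if los >= 2:
        days = np.sort(rng.choice(np.arange(1, los + 1), size=n_obs, replace=False))
    else:
        days = np.array([1, 1])  # same-day repeat for a one-day stay
    values = (
        p.intercept[cls]
        + p.slope[cls] * days
        + rng.normal(0.0, p.noise_sd, size=days.size)
    )
    return LabTimeSeries(test, tuple(float(v) for v in values), tuple(int(d) for d in days))


# ---------------------------------------------------------------------------
# the printed worked example: two event sequences and two operation series


def generate_worked_example() -> tuple[EventSequence, EventSequence]:
    """The reference pair r1 = {(A,1),(B,2),(C,3),(D,4)}, r2 = {(A,2),(B,5),(C,8)}."""
    r1 = EventSequence(
        "pro", tuple(ClinicalEvent(c, d) for c, d in [("A", 1), ("B", 2), ("C", 3), ("D", 4)])
    )
    r2 = EventSequence(
        "pro", tuple(ClinicalEvent(c, d) for c, d in [("A", 2), ("B", 5), ("C", 8)])
    )
    return r1, r2


def worked_example_operation_series() -> tuple[OperationSeries, OperationSeries]:
    """Os1 (delete r1, insert r2; cost 7) and Os2 (substitute A,B,C; delete D; cost 5.5)."""
    os1 = OperationSeries(
        [
            EditOperation("Del", "A", source_day=1),
            EditOperation("Del", "B", source_day=2),
            EditOperation("Del", "C", source_day=3),
            EditOperation("Del", "D", source_day=4),
            EditOperation("Ins", "A", target_day=2),
            EditOperation("Ins", "B", target_day=5),
            EditOperation("Ins", "C", target_day=8),
        ]
    )
    os2 = OperationSeries(
        [
            EditOperation("Sub", "A", 1, 2),
            EditOperation("Sub", "B", 2, 5),
            EditOperation("Sub", "C", 3, 8),
            EditOperation("Del", "D", source_day=4),
        ]
    )
    return os1, os2
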