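"""Organised FIT screening overlaid on counterfactual life histories.

The programme walks each person's invitation calendar: biennial FIT between
50 and 69, positives referred to diagnostic colonoscopy, detected adenomas
excised (interrupting the adenoma-carcinoma sequence), adenoma findings
routed into the European surveillance schedule (1-year / 3-year recall or
return to FIT in 5 years), and screen-detected cancers diagnosed at their
current — earlier — stage with survival re-evaluated under common random
numbers.  Other-cause death ages are never touched by the overlay.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .natural_history import LifeHistory, redraw_survival
from .population import Individual, ProgramConfig

FIT_POSITIVE = True
FIT_NEGATIVE = False

COLONOSCOPY_PURPOSES = ("diagnostic", "surveillance", "clinical")


@dataclass
class TestCharacteristics:
    """Per-lesion test operating characteristics at the 20 ug/g FIT cut-off.

    Shipped defaults are literature surrogates (the programme-fitted values
    live in an unavailable supplement): FIT per-lesion sensitivity rises with
    lesion size, specificity is per person-test without lesions, colonoscopy
    sensitivity includes reach/completeness, and complications are tied to
    polypectomy.  ``systematic_fn_fraction`` is the share of adenomas that are
    persistently FIT-undetectable in the correlated false-negative scenario.
    """

    fit_sensitivity_small: float = 0.04
    fit_sensitivity_medium: float = 0.12
    fit_sensitivity_large: float = 0.32
    fit_sensitivity_crc: float = 0.75
    fit_specificity: float = 0.955
    colo_sensitivity_small: float = 0.75
    colo_sensitivity_medium: float = 0.85
    colo_sensitivity_large: float = 0.95
    colo_sensitivity_crc: float = 0.95
    complication_prob: float = 0.0025
    systematic_fn_fraction: float = 0.0

    __test__ = False  # keep pytest from collecting this as a test class

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")

    def fit_sensitivity(self, kind: str) -> float:
        return getattr(self, f"fit_sensitivity_{kind}" if kind != "crc"
                       else "fit_sensitivity_crc")

    def colo_sensitivity(self, kind: str) -> float:
        return getattr(self, f"colo_sensitivity_{kind}" if kind != "crc"
                       else "colo_sensitivity_crc")


@dataclass
class ParticipationModel:
    """FIT participation by age band and invitation round, plus colonoscopy
    compliance after a positive test.

    Default first-round rates bracket the 64.3 % overall participation
    observed in 2009-2011; successive rounds participate slightly more.
    """

    age_bands: tuple[tuple[int, int], ...] = ((50, 54), (55, 59), (60, 64), (65, 69))
    p_first: tuple[float, ...] = (0.60, 0.63, 0.66, 0.68)
    p_successive: tuple[float, ...] = (0.66, 0.69, 0.72, 0.74)
    colonoscopy_compliance: float = 0.92

    def __post_init__(self) -> None:
        probs = self.p_first + self.p_successive + (self.colonoscopy_compliance,)
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("participation probabilities must lie in [0, 1]")

    def fit_participation(self, age: float, first: bool) -> float:
        table = self.p_first if first else self.p_successive
        for (lo, hi), p in zip(self.age_bands, table):
            if lo <= age <= hi:
                return p
        # outside the banded range: use the nearest edge band
        return table[0] if age < self.age_bands[0][0] else table[-1]


@dataclass
class SurveillanceRules:
    """Size/count thresholds of the post-polypectomy surveillance schedule.

    Priority order: 1-year recall (> ``size_1y_mm`` or >= ``count_1y``
    adenomas), then 3-year recall (> ``size_3y_mm`` or 3-4 adenomas), then
    FIT in 5 years (1-2 adenomas all small), else routine biennial FIT.
    """

    size_1y_mm: float = 20.0
    count_1y: int = 5
    size_3y_mm: float = 10.0
    count_3y_min: int = 3
    count_5y_max: int = 2


@dataclass
class Findings:
    """Result of one colonoscopy."""

    adenoma_sizes_mm: list[float] = field(default_factory=list)
    crc_detected: bool = False
    detected_stage: int | None = None
    polypectomy: bool = False
    complication: bool = False


DISPOSITIONS = ("colonoscopy_in_1y", "colonoscopy_in_3y", "fit_in_5y",
                "routine_biennial_fit")


def next_disposition(findings: Findings, rules: SurveillanceRules) -> str:
    """Exactly one surveillance disposition for a CRC-free colonoscopy."""
    if findings.crc_detected:
        raise ValueError("CRC findings follow the treatment pathway, "
                         "not surveillance")
    sizes = findings.adenoma_sizes_mm
    n = len(sizes)
    if n == 0:
        return "routine_biennial_fit"
    biggest = max(sizes)
    if biggest > rules.size_1y_mm or n >= rules.count_1y:
        return "colonoscopy_in_1y"
    if biggest > rules.size_3y_mm or n >= rules.count_3y_min:
        return "colonoscopy_in_3y"
    return "fit_in_5y"


def perform_fit(lesions, chars: TestCharacteristics, rng) -> bool:
    """One FIT result for the lesion burden present at the test age.

    ``lesions`` is a sequence of (kind, systematically_missed) pairs with kind
    in {small, medium, large, crc}.  Without lesions the test is positive with
    probability 1 - specificity; otherwise every lesion triggers independently
    with its class sensitivity, flagged lesions never trigger (one uniform is
    still consumed per lesion, which keeps paired scenarios aligned).
    """
    if not lesions:
        return rng.random() < 1.0 - chars.fit_specificity
    positive = False
    for kind, missed in lesions:
        u = rng.random()
        if not missed and u < chars.fit_sensitivity(kind):
            positive = True
    return positive


class PersonOutcome:
    """One person's realised timeline in one arm, ready for costing.

    ``events`` are (age, type, detail) with types invitation / fit /
    fit_positive / colonoscopy (detail = (purpose, polypectomy)) /
    complication.  ``dx_records`` are (dx_age, stage_index, location,
    screen_detected) for every cancer diagnosed before death.
    """

    __slots__ = ("individual", "death_age", "cause_of_death", "events",
                 "dx_records", "excision_ages")

    def __init__(self, individual, death_age, cause_of_death, events,
                 dx_records, excision_ages=()):
        self.individual = individual
        self.death_age = death_age
        self.cause_of_death = cause_of_death
        self.events = events
        self.dx_records = dx_records
        self.excision_ages = excision_ages

    def count(self, etype: str) -> int:
        return sum(1 for e in self.events if e[1] == etype)


def unscreened_outcome(life: LifeHistory) -> PersonOutcome:
    """Counterfactual arm: clinical diagnoses only (with the work-up
    colonoscopy each implies)."""
    events, dx = [], []
    for c in life.diagnosed_cancers():
        a = c.symptomatic_dx_age
        events.append((a, "colonoscopy", ("clinical", False)))
        dx.append((a, c.dx_stage, c.location, False))
    return PersonOutcome(life.individual, life.death_age, life.cause_of_death,
                         events, dx)


def build_invitation_schedule(individual: Individual, program: ProgramConfig
                              ) -> list[tuple[int, int]]:
    """Biennial (calendar_year, age) invitations, truncated at other-cause
    death; empty when the person is never invited."""
    if individual.first_invitation_year is None:
        return []
    out = []
    year = individual.first_invitation_year
    while True:
        age = year - individual.birth_year
        if age > program.age_max or age >= individual.death_age_other:
            break
        out.append((year, age))
        year += program.screening_interval
    return out


class _Resolver:
    """Tracks lesion fates while the programme walks a person's calendar."""

    def __init__(self, life: LifeHistory):
        self.life = life
        self.adenomas = life.adenomas
        self.excision_age = [None] * len(self.adenomas)
        self.screen_fate = {}    # adenoma idx -> (dx_age, stage, crc_death_age)
        self.suppressed = set()  # detected-but-secondary cancers, managed

    def cancelled(self, i) -> bool:
        ad = self.adenomas[i]
        return (self.excision_age[i] is not None
                and (ad.malignant_age is None
                     or self.excision_age[i] < ad.malignant_age))

    def active_cancers(self):
        for i, ad in enumerate(self.adenomas):
            if ad.cancer is None or self.cancelled(i):
                continue
            if i in self.screen_fate or i in self.suppressed:
                continue
            yield i, ad.cancer

    def fates(self):
        out = []
        for i, ad in enumerate(self.adenomas):
            if ad.cancer is None or self.cancelled(i) or i in self.suppressed:
                continue
            if i in self.screen_fate:
                dx, _stage, cd = self.screen_fate[i]
                out.append((dx, cd))
            else:
                out.append((ad.cancer.symptomatic_dx_age,
                            ad.cancer.crc_death_age))
        return out

    def lesions_at(self, age: float, sfn: float):
        """(index, kind, missed) triples for lesions present at ``age``."""
        out = []
        for i, ad in enumerate(self.adenomas):
            if self.excision_age[i] is not None:
                continue
            state = ad.size_state_at(age)
            if state is not None:
                out.append((i, state, ad.u_missed < sfn))
            elif (ad.cancer is not None and ad.malignant_age is not None
                  and ad.malignant_age <= age and i not in self.screen_fate
                  and i not in self.suppressed):
                c = ad.cancer
                if c.symptomatic_dx_age is None or c.symptomatic_dx_age > age:
                    out.append((i, "crc", False))
        return out


def perform_colonoscopy(lesions, chars: TestCharacteristics, rng,
                        sizes_mm=None) -> tuple[list[int], list[int], Findings]:
    """Detect lesions independently with the class-wise colonoscopy
    sensitivity.

    Returns (detected adenoma indices, detected cancer indices, findings).
    Detected adenomas are excised by construction (polypectomy), and a
    complication is drawn only when a polypectomy happened.
    """
    det_adenomas, det_cancers = [], []
    findings = Findings()
    for i, kind, _missed in lesions:
        u = rng.random()
        if u >= chars.colo_sensitivity(kind):
            continue
        if kind == "crc":
            det_cancers.append(i)
        else:
            det_adenomas.append(i)
            if sizes_mm is not None:
                findings.adenoma_sizes_mm.append(sizes_mm[i])
    findings.polypectomy = bool(det_adenomas)
    if findings.polypectomy:
        findings.complication = rng.random() < chars.complication_prob
    findings.crc_detected = bool(det_cancers)
    return det_adenomas, det_cancers, findings


@dataclass
class ScreeningStreams:
    """Independent random streams for the three screening concerns."""

    participation: object
    fit: object
    colonoscopy: object


def run_screened_history(life: LifeHistory, program: ProgramConfig,
                         participation: ParticipationModel,
                         chars: TestCharacteristics,
                         rules: SurveillanceRules,
                         rng: ScreeningStreams, nh_params) -> PersonOutcome:
    """Overlay the full programme on one counterfactual history.

    Walks invitations, participation, FIT, diagnostic colonoscopy,
    polypectomy, surveillance scheduling and screen detection in event order;
    any diagnosis (screen or clinical) ends screening for the person.  The
    returned outcome shares the individual and the other-cause death age with
    the counterfactual arm.
    """
    ind = life.individual
    res = _Resolver(life)
    sfn = chars.systematic_fn_fraction
    r_part, r_fit, r_colo = rng.participation, rng.fit, rng.colonoscopy

    events: list[tuple] = []
    invitations_seen = 0
    diagnosed = False

    contact: tuple[float, str] | None = None
    if ind.first_invitation_year is not None:
        contact = (float(ind.first_invitation_year - ind.birth_year), "fit")

    def next_fit(age: float):
        return (age, "fit") if age <= program.age_max else None

    def death_now():
        from .natural_history import _resolve_death
        return _resolve_death(ind.death_age_other, res.fates())

    while not diagnosed:
        death, _cause = death_now()
        pending = [(c.symptomatic_dx_age, i) for i, c in res.active_cancers()
                   if c.symptomatic_dx_age is not None]
        next_sym = min(pending) if pending else None
        t_contact = contact[0] if contact is not None else math.inf
        if next_sym is not None and next_sym[0] <= t_contact and next_sym[0] < death:
            break  # clinical diagnosis pre-empts screening
        if contact is None or t_contact >= death:
            break
        age, kind = contact
        contact = None

        if kind == "fit":
            events.append((age, "invitation", None))
            first = invitations_seen == 0
            invitations_seen += 1
            if r_part.random() >= participation.fit_participation(age, first):
                contact = next_fit(age + program.screening_interval)
                continue
            events.append((age, "fit", None))
            lesions = res.lesions_at(age, sfn)
            positive = perform_fit([(k, m) for _, k, m in lesions], chars, r_fit)
            if not positive:
                contact = next_fit(age + program.screening_interval)
                continue
            events.append((age, "fit_positive", None))
            if r_part.random() >= participation.colonoscopy_compliance:
                contact = next_fit(age + program.screening_interval)
                continue
            purpose = "diagnostic"
        else:
            purpose = "surveillance"
            lesions = res.lesions_at(age, sfn)

        if purpose == "diagnostic":
            lesions = res.lesions_at(age, sfn)
        sizes = {i: res.adenomas[i].size_mm_at(age)
                 for i, k, _m in lesions if k != "crc"}
        det_ad, det_ca, findings = perform_colonoscopy(lesions, chars, r_colo,
                                                       sizes_mm=sizes)
        events.append((age, "colonoscopy", (purpose, findings.polypectomy)))
        if findings.complication:
            events.append((age, "complication", None))
        for i in det_ad:
            res.excision_age[i] = age

        if det_ca:
            # diagnose the most advanced detected cancer at its current stage
            det_ca.sort(key=lambda i: (-res.adenomas[i].cancer.stage_at(age),
                                       res.adenomas[i].cancer.onset_age))
            lead = det_ca[0]
            c = res.adenomas[lead].cancer
            stage = c.stage_at(age)
            _surv, cd = redraw_survival(c, stage, age, nh_params)
            res.screen_fate[lead] = (age, stage, cd)
            for i in det_ca[1:]:
                res.suppressed.add(i)  # managed within the same episode
            diagnosed = True
            continue

        disposition = next_disposition(findings, rules)
        if disposition == "colonoscopy_in_1y":
            nxt = (age + 1.0, "surveillance")
        elif disposition == "colonoscopy_in_3y":
            nxt = (age + 3.0, "surveillance")
        elif disposition == "fit_in_5y":
            nxt = next_fit(age + 5.0)
            contact = nxt
            continue
        else:
            contact = next_fit(age + program.screening_interval)
            continue
        if nxt[0] - 1e-9 > program.age_max and not program.surveillance_after_69:
            contact = None
        else:
            contact = nxt

    # settle final death and collect every diagnosis that precedes it
    from .natural_history import _resolve_death
    death, cause = _resolve_death(ind.death_age_other, res.fates())
    dx_records = []
    for i, ad in enumerate(res.adenomas):
        if ad.cancer is None or res.cancelled(i) or i in res.suppressed:
            continue
        if i in res.screen_fate:
            dx_age, stage, _cd = res.screen_fate[i]
            if dx_age < death:
                dx_records.append((dx_age, stage, ad.cancer.location, True))
        else:
            c = ad.cancer
            if c.symptomatic_dx_age is not None and c.symptomatic_dx_age < death:
                dx_records.append((c.symptomatic_dx_age, c.dx_stage,
                                   c.location, False))
                events.append((c.symptomatic_dx_age, "colonoscopy",
                               ("clinical", False)))
    dx_records.sort(key=lambda r: r[0])
    events.sort(key=lambda e: e[0])
    events = [e for e in events if e[0] <= death]
    excisions = tuple(a for a in res.excision_age if a is not None)
    return PersonOutcome(ind, death, cause, events, dx_records, excisions)
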