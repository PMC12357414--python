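"""Synthetic CPRD-GOLD-shaped cohort generator with planted ground truth.

The licensed source data cannot be redistributed, so every test and example
runs on cohorts from this generator. It emits the five input tables
(patient, practice, therapy, clinical, HES ethnicity) in the package's CSV
dialect together with a :class:`GroundTruth` computed by exhaustive
day-level enumeration of the *true* prescription durations — a target the
interval-based pipeline can be checked against, derived by an independent
route.

What it emulates
----------------
* demographics with the seven analysis age bands, a five-group ethnicity
  mix with two-stage missingness (primary-care record missing, hospital
  record recovering part of it), and person-level deprivation quintiles
  with a missing fraction that exercises the practice-level fallback;
* prescribing as per-person *episodes*: an initiation process (annual rate)
  starts a run of repeat scripts whose lengths come from a mixture over
  standard UK script durations, with a continuation probability and a
  small issue-date jitter that creates the overlap/gap structure a drug-era
  estimator must handle;
* a co-prescribing propensity: the opioid initiation hazard is multiplied
  while the person is covered by an antidepressant, which concentrates
  overlap within persons the way comorbid pain and depression do;
* censoring morbidity (cancer, terminal illness, heart failure, opioid
  misuse) as per-category annual hazards from the lookback start, so some
  events precede study entry (exclusions) and some interrupt follow-up;
* quantity/daily-dose bookkeeping: ``quantity = daily_dose x true days``
  always holds; a configurable fraction of scripts has the daily dose
  blanked (half of those carry a stated duration) to exercise the
  estimator's fallback chain.

Identical parameters and seed reproduce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd

from .cohort import StudyWindow
from .io import (CENSOR_CATEGORIES, ETHNIC_GROUPS, INDICATION_CATEGORIES,
                 Codelists, Tables)
from .oracle import DayEnumerationResult, enumerate_reference

REGIONS = (
    "North East", "North West", "Yorkshire & The Humber", "East Midlands",
    "West Midlands", "East of England", "London", "South East", "South West",
)

_OPIOIDS = {
    "codeine": 0.45, "tramadol": 0.20, "morphine": 0.10, "oxycodone": 0.08,
    "dihydrocodeine": 0.08, "buprenorphine": 0.04, "fentanyl": 0.03,
    "methadone": 0.02,
}
_ANTIDEPRESSANTS = {
    "amitriptyline": 0.30, "citalopram": 0.20, "sertraline": 0.15,
    "fluoxetine": 0.12, "mirtazapine": 0.08, "venlafaxine": 0.06,
    "duloxetine": 0.05, "paroxetine": 0.02, "phenelzine": 0.01,
    "tranylcypromine": 0.01,
}
_DAILY_DOSE = {  # tablets/day, fixed per drug
    "codeine": 4, "tramadol": 4, "morphine": 2, "oxycodone": 2,
    "dihydrocodeine": 4, "buprenorphine": 1, "fentanyl": 1, "methadone": 1,
    "amitriptyline": 1, "citalopram": 1, "sertraline": 1, "fluoxetine": 1,
    "mirtazapine": 1, "venlafaxine": 2, "duloxetine": 1, "paroxetine": 1,
    "phenelzine": 3, "tranylcypromine": 2,
}
_CONTRAINDICATED = (
    ("tramadol", "phenelzine"),
    ("tramadol", "tranylcypromine"),
    ("methadone", "citalopram"),
    ("morphine", "phenelzine"),
)
_CLINICAL_CODES = {
    "C10": "cancer", "C11": "cancer",
    "T20": "terminal_illness",
    "H30": "heart_failure",
    "M40": "opioid_misuse",
    "D50": "depression", "D51": "depression",
    "A60": "anxiety_phobia",
    "N70": "neuropathic_pain",
}


def default_codelists() -> Codelists:
    """Built-in synthetic codelists: drug classes, contraindicated pairs, codes."""
    drug_map = {d: "opioid" for d in _OPIOIDS}
    drug_map.update({d: "antidepressant" for d in _ANTIDEPRESSANTS})
    return Codelists(drug_map, frozenset(_CONTRAINDICATED), dict(_CLINICAL_CODES))


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic cohort.

    Rates are annual per-person probabilities/hazards; weights are
    normalised internally. Defaults are the "typical" scenario: a cohort
    whose co-prescribing prevalence lands in the tens per 1000 person-years.
    """

    n_patients: int = 2000
    seed: int = 1
    window: StudyWindow = StudyWindow()
    lookback_start: dt.date = dt.date(2008, 1, 1)
    n_practices: int = 20

    sex_female: float = 0.51
    #: weights over the seven analysis age bands (18-34 ... 85-100), age at window start
    age_band_weights: tuple = (0.365, 0.185, 0.162, 0.126, 0.086, 0.052, 0.024)
    ethnicity_weights: tuple = (0.057, 0.028, 0.011, 0.024, 0.880)  # ETHNIC_GROUPS order
    p_ethnicity_cprd_missing: float = 0.409
    p_ethnicity_hes_given_missing: float = 0.535
    townsend_weights: tuple = (0.179, 0.216, 0.205, 0.226, 0.174)
    p_townsend_person_missing: float = 0.30

    registration_start: dt.date = dt.date(1995, 1, 1)
    registration_end: dt.date = dt.date(2018, 6, 30)
    p_death_annual: float = 0.009
    p_transfer_annual: float = 0.030
    #: fraction of practices whose last collection predates the window end
    p_practice_early_stop: float = 0.30
    #: fraction of practices with an up-to-standard date inside the window
    p_practice_late_uts: float = 0.15

    opioid_rate: float = 0.22          # episode initiations per person-year
    antidepressant_rate: float = 0.16
    co_propensity: float = 4.5         # opioid-hazard multiplier under antidepressant cover
    script_days: tuple = (7, 14, 28, 56, 84)
    script_days_weights: tuple = (0.10, 0.20, 0.55, 0.10, 0.05)
    continuation_prob_opioid: float = 0.55
    continuation_prob_antidepressant: float = 0.72
    issue_jitter_days: int = 5         # renewal date jitter around seamless refill
    p_missing_daily_dose: float = 0.05
    p_stated_given_missing: float = 0.50
    exclusive_classes: bool = False    # structural zero for co-prescribing

    censor_hazards: tuple = (          # CENSOR_CATEGORIES order, annual
        ("cancer", 0.004), ("terminal_illness", 0.001),
        ("heart_failure", 0.002), ("opioid_misuse", 0.0005),
    )
    indication_probs: tuple = (        # given any antidepressant use
        ("depression", 0.60), ("anxiety_phobia", 0.30), ("neuropathic_pain", 0.25),
    )

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.lookback_start > self.window.start:
            raise ValueError("lookback must start no later than the study window")
        for name in ("sex_female", "p_ethnicity_cprd_missing",
                     "p_ethnicity_hes_given_missing", "p_townsend_person_missing",
                     "p_missing_daily_dose", "p_stated_given_missing",
                     "continuation_prob_opioid", "continuation_prob_antidepressant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


#: frozen parameter sets used throughout the test suite
_SCENARIOS = {
    # planted structural zero: each person may receive at most one drug
    # class, so opioid and antidepressant coverage can never meet; all
    # morbidity and mobility hazards are off and demographics are arranged
    # so that every person has eligible follow-up
    "null": dict(
        exclusive_classes=True,
        censor_hazards=tuple((c, 0.0) for c in CENSOR_CATEGORIES),
        p_death_annual=0.0, p_transfer_annual=0.0,
        p_practice_early_stop=0.0, p_practice_late_uts=0.0,
        age_band_weights=(0.40, 0.20, 0.16, 0.12, 0.08, 0.04, 0.0),
        registration_end=dt.date(2017, 12, 31),
    ),
    # the defaults, calibrated once so the cohort's overall co-prescribing
    # prevalence is of the order of tens per 1000 person-years
    "typical": dict(),
    # strong within-person coupling of the two classes
    "heavy_overlap": dict(opioid_rate=0.5, antidepressant_rate=0.35, co_propensity=12.0),
    # high cancer hazard: a third or more of persons lose follow-up to
    # censoring (or are excluded) before the window ends
    "censor_heavy": dict(censor_hazards=(
        ("cancer", 0.045), ("terminal_illness", 0.008),
        ("heart_failure", 0.012), ("opioid_misuse", 0.002),
    )),
}


def scenario_library(name: str, **overrides) -> SimulationParams:
    """Fixed, documented parameter sets used by the test suite.

    ``overrides`` (e.g. ``n_patients``, ``seed``) are applied on top.
    """
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")
    return SimulationParams(**{**_SCENARIOS[name], **overrides})


@dataclasses.dataclass
class GroundTruth:
    """Planted truth for one generated cohort.

    ``reference`` is the day-enumeration result over the *true* durations
    (follow-up, co-prescribed day sets, per-year prevalent/incident persons
    and person-days); ``true_durations`` holds the scripts with their true
    covered days, aligned row-for-row with the emitted therapy table.
    """

    reference: DayEnumerationResult
    true_durations: pd.DataFrame

    def prevalence_per_1000py(self, year=None) -> float:
        ref = self.reference
        if year is None:
            n = sum(len(s) for s in ref.prevalent_by_year.values())
            days = sum(ref.person_days_by_year.values())
        else:
            n = len(ref.prevalent_by_year.get(year, ()))
            days = ref.person_days_by_year.get(year, 0)
        return 1000.0 * n / (days / 365.25) if days else float("nan")

    def incidence_per_1000py(self, year=None) -> float:
        """First-event rate over day-enumerated at-risk time (prior
        co-prescribers removed; time truncated at the first event day)."""
        ref = self.reference
        inc = ref.incident_by_year()
        if year is None:
            n = sum(len(s) for s in inc.values())
            days = sum(ref.at_risk_days_by_year.values())
        else:
            n = len(inc.get(year, ()))
            days = ref.at_risk_days_by_year.get(year, 0)
        return 1000.0 * n / (days / 365.25) if days else float("nan")


def _weighted_choice(rng, items, weights):
    w = np.asarray(weights, dtype=float)
    return items[rng.choice(len(items), p=w / w.sum())]


def _simulate_episodes(rng, params: SimulationParams, cls: str, period_start: dt.date,
                       period_end: dt.date, rate: float, ad_cover=None):
    """Episode-structured scripts for one person and one drug class.

    Returns a list of (drug, issue_date, true_days). ``ad_cover`` is a
    sorted list of (start_ord, end_ord) antidepressant coverage used to
    modulate the opioid hazard (thinning of a bounded-rate process).
    """
    drugs = _OPIOIDS if cls == "opioid" else _ANTIDEPRESSANTS
    cont = (params.continuation_prob_opioid if cls == "opioid"
            else params.continuation_prob_antidepressant)
    boost = params.co_propensity if ad_cover is not None else 1.0
    max_rate = rate * max(1.0, boost)
    if max_rate <= 0:
        return []

    def covered(o: int) -> bool:
        if not ad_cover:
            return False
        for s, e in ad_cover:
            if s <= o <= e:
                return True
            if s > o:
                break
        return False

    out = []
    t = period_start.toordinal()
    end = period_end.toordinal()
    while True:
        t += max(1, int(round(rng.exponential(365.25 / max_rate))))
        if t > end:
            break
        # thinning: accept candidate with prob rate(t)/max_rate
        local = rate * (boost if covered(t) else 1.0)
        if rng.random() >= local / max_rate:
            continue
        drug = _weighted_choice(rng, list(drugs), list(drugs.values()))
        issue = t
        while issue <= end:
            days = int(_weighted_choice(rng, list(params.script_days),
                                        list(params.script_days_weights)))
            out.append((drug, dt.date.fromordinal(issue), days))
            if rng.random() >= cont:
                issue += days
                break
            jitter = int(rng.integers(-params.issue_jitter_days,
                                      params.issue_jitter_days + 1))
            issue = issue + days + jitter
            issue = max(issue, out[-1][1].toordinal() + 1)
        t = max(t, issue)
    return out


def generate(params: SimulationParams):
    """Generate one cohort: returns ``(tables, truth)``.

    ``tables`` is an :class:`coprescribe.io.Tables` with typed frames in the
    exact shape ``read_tables`` produces; ``truth`` the planted
    :class:`GroundTruth`. Deterministic in ``params`` (incl. ``seed``).
    """
    rng = np.random.default_rng(params.seed)
    window = params.window
    wstart, wend = window.start, window.end

    # practices -----------------------------------------------------------
    prac_rows = []
    for i in range(params.n_practices):
        pid = f"pr{i:03d}"
        late = rng.random() < params.p_practice_late_uts
        uts = (wstart + dt.timedelta(days=int(rng.integers(365, 4 * 365)))
               if late else
               dt.date(2000, 1, 1) + dt.timedelta(days=int(rng.integers(0, 8 * 365))))
        early = rng.random() < params.p_practice_early_stop
        lcd = (wstart + dt.timedelta(days=int(rng.integers(4 * 365, 10 * 365 - 30)))
               if early else wend)
        prac_rows.append((pid, REGIONS[i % len(REGIONS)], uts, max(uts, lcd),
                          int(rng.integers(1, 6))))
    practices = pd.DataFrame(prac_rows, columns=[
        "practice_id", "region", "uts_date", "last_collection_date", "townsend_practice"])
    for c in ("uts_date", "last_collection_date"):
        practices[c] = pd.to_datetime(practices[c])
    practices["townsend_practice"] = practices["townsend_practice"].astype("Int64")

    band_edges = ((18, 34), (35, 44), (45, 54), (55, 64), (65, 74), (75, 84), (85, 100))
    pat_rows, ther_rows, clin_rows, hes_rows, true_rows = [], [], [], [], []

    reg_span = (params.registration_end - params.registration_start).days
    for i in range(params.n_patients):
        pid = f"p{i:06d}"
        practice = practices.iloc[int(rng.integers(params.n_practices))]
        sex = "female" if rng.random() < params.sex_female else "male"
        lo, hi = band_edges[int(rng.choice(7, p=np.asarray(params.age_band_weights)
                                           / sum(params.age_band_weights)))]
        age0 = int(rng.integers(lo, hi + 1))
        birth_year = wstart.year - age0

        registration = params.registration_start + dt.timedelta(
            days=int(rng.integers(0, reg_span + 1)))
        registration = max(registration, dt.date(birth_year + 1, 1, 1))

        death = transfer = None
        if params.p_death_annual > 0:
            yrs = rng.exponential(1.0 / params.p_death_annual)
            if yrs < 12:
                death = wstart + dt.timedelta(days=int(yrs * 365.25))
        if params.p_transfer_annual > 0:
            yrs = rng.exponential(1.0 / params.p_transfer_annual)
            if yrs < 12:
                transfer = wstart + dt.timedelta(days=int(yrs * 365.25))
        # a death or transfer predating registration is incoherent (the
        # person was never in the panel): drop the marker instead
        if death is not None and death < registration:
            death = None
        if transfer is not None and transfer < registration:
            transfer = None
        if death is not None and transfer is not None and transfer > death:
            transfer = None
        horizon = min(d for d in (death, transfer, wend) if d is not None)

        # ethnicity: a true group, recorded in primary care or hospital data
        true_eth = ETHNIC_GROUPS[int(rng.choice(5, p=np.asarray(params.ethnicity_weights)
                                                / sum(params.ethnicity_weights)))]
        cprd_eth = None if rng.random() < params.p_ethnicity_cprd_missing else true_eth
        hes_eth = None
        if cprd_eth is None:
            if rng.random() < params.p_ethnicity_hes_given_missing:
                hes_eth = true_eth
        elif rng.random() < 0.5:     # hospital record often duplicates primary care
            hes_eth = true_eth
        townsend = None if rng.random() < params.p_townsend_person_missing else \
            int(rng.choice(5, p=np.asarray(params.townsend_weights)
                           / sum(params.townsend_weights))) + 1

        # censoring morbidity from the lookback start (some precede entry)
        for cat, hazard in params.censor_hazards:
            if hazard <= 0:
                continue
            days_off = rng.exponential(1.0 / hazard) * 365.25
            if days_off <= (wend - params.lookback_start).days:
                d = params.lookback_start + dt.timedelta(days=int(days_off))
                codes = [c for c, k in _CLINICAL_CODES.items() if k == cat]
                clin_rows.append((pid, d, codes[int(rng.integers(len(codes)))]))

        # prescribing ------------------------------------------------------
        rx_start = max(params.lookback_start, registration)
        if rx_start <= horizon:
            if params.exclusive_classes:
                p_op = params.opioid_rate / (params.opioid_rate
                                             + params.antidepressant_rate)
                allow_op = rng.random() < p_op
                allow_ad = not allow_op
            else:
                allow_op = allow_ad = True
            ad_scripts = _simulate_episodes(
                rng, params, "antidepressant", rx_start, horizon,
                params.antidepressant_rate if allow_ad else 0.0)
            ad_cover = sorted(
                (s.toordinal(), s.toordinal() + d - 1) for _, s, d in ad_scripts)
            op_scripts = _simulate_episodes(
                rng, params, "opioid", rx_start, horizon,
                params.opioid_rate if allow_op else 0.0, ad_cover=ad_cover)
        else:
            ad_scripts, op_scripts = [], []

        for cls, scripts in (("antidepressant", ad_scripts), ("opioid", op_scripts)):
            for drug, issue, days in scripts:
                dose = _DAILY_DOSE[drug]
                quantity = dose * days
                if rng.random() < params.p_missing_daily_dose:
                    emit_dose = None
                    stated = days if rng.random() < params.p_stated_given_missing else None
                else:
                    emit_dose = dose
                    stated = None
                ther_rows.append((pid, drug, issue, quantity, emit_dose, stated))
                true_rows.append((pid, drug, cls, issue, days))

        if ad_scripts:
            first_ad = min(s for _, s, _ in ad_scripts)
            for cat, prob in params.indication_probs:
                if rng.random() < prob:
                    offset = int(rng.integers(-730, 61))
                    d = max(params.lookback_start,
                            first_ad + dt.timedelta(days=offset))
                    codes = [c for c, k in _CLINICAL_CODES.items() if k == cat]
                    clin_rows.append((pid, d, codes[int(rng.integers(len(codes)))]))

        pat_rows.append((pid, sex, birth_year, registration, transfer, death,
                         practice["practice_id"], cprd_eth, townsend))
        if hes_eth is not None:
            hes_rows.append((pid, hes_eth))

    patients = pd.DataFrame(pat_rows, columns=[
        "patient_id", "sex", "birth_year", "registration_date", "transfer_out_date",
        "death_date", "practice_id", "ethnicity", "townsend_person"])
    for c in ("registration_date", "transfer_out_date", "death_date"):
        patients[c] = pd.to_datetime(patients[c])
    patients["townsend_person"] = patients["townsend_person"].astype("Int64")
    # normalise missing markers to pandas NA, matching what read_tables yields
    patients["ethnicity"] = patients["ethnicity"].where(
        patients["ethnicity"].notna(), pd.NA)

    codelists = default_codelists()
    therapy = pd.DataFrame(ther_rows, columns=[
        "patient_id", "drug_name", "issue_date", "quantity", "daily_dose",
        "stated_duration_days"])
    therapy["drug_class"] = therapy["drug_name"].map(codelists.drug_class_map)
    therapy = therapy[["patient_id", "drug_name", "drug_class", "issue_date",
                       "quantity", "daily_dose", "stated_duration_days"]]
    therapy["issue_date"] = pd.to_datetime(therapy["issue_date"])
    therapy["quantity"] = therapy["quantity"].astype(float)
    therapy["daily_dose"] = therapy["daily_dose"].astype(float)
    therapy["stated_duration_days"] = therapy["stated_duration_days"].astype("Int64")

    clinical = pd.DataFrame(clin_rows, columns=["patient_id", "event_date", "code"])
    clinical["event_date"] = pd.to_datetime(clinical["event_date"])
    clinical["category"] = clinical["code"].map(codelists.clinical_map)
    clinical = clinical.sort_values(["patient_id", "event_date", "code"],
                                    kind="stable").reset_index(drop=True)

    hes = pd.DataFrame(hes_rows, columns=["patient_id", "ethnicity"])

    tables = Tables(patients, practices, therapy, clinical, hes,
                    log={"generator": dataclasses.asdict(params) | {
                        "window": (str(window.start), str(window.end)),
                        "lookback_start": str(params.lookback_start),
                        "registration_start": str(params.registration_start),
                        "registration_end": str(params.registration_end),
                    }})

    true_durations = pd.DataFrame(true_rows, columns=[
        "patient_id", "drug_name", "drug_class", "issue_date", "duration_days"])
    true_durations["issue_date"] = pd.to_datetime(true_durations["issue_date"])
    reference = enumerate_reference(patients, practices, clinical,
                                    true_durations, window)
    return tables, GroundTruth(reference, true_durations)
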