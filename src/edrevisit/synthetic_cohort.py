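"""Synthetic ED-visit cohorts with plantable predictive signal.

The real study population — child/youth mental-health outpatients with ED
visits — cannot be shared, so this generator emulates its printed summary
statistics (visit counts with mean 5 / SD 5 truncated to >= 1, ages with
mean 12.4 / SD 3.9 clipped to [4, 18], roughly 17% 30-day revisit
prevalence, skewed categorical code frequencies) and, crucially, lets tests
*plant* predictive signal of two known shapes:

* **sequential** (``beta_seq``): high acuity (CTAS 1 or 2) at the final
  input visit raises the revisit hazard — learnable from the last visit's
  features alone;
* **relational** (``beta_rel``): the presence of a designated
  service-diagnosis co-occurrence pair anywhere in the (capped) input
  window raises the hazard — an AND over two feature slots within one
  visit, which the patient graph represents explicitly as a
  service-diagnosis edge.

The final inter-visit gap is drawn from one of two ranges (1..30 days vs
31..365 days) conditioned on a Bernoulli draw from the logistic hazard
``h = sigmoid(base + beta_seq*x_seq + beta_rel*x_rel)``; the intercept
``base`` is calibrated by bisection so expected prevalence over the
generated covariates matches the target.

Single-visit patients are structurally label-0 (there is no following
visit), yet their instances are observationally identical to those of
two-visit patients (one input visit each).  Left uncorrected this makes
input length predictive even with zero betas, so the generator boosts the
hazard of two-visit patients by exactly the factor that keeps the label
rate conditional on *observable* input features equal across input
lengths.  With ``beta_seq = beta_rel = 0`` the cohort is then genuinely
null — no function of the inputs beats AUROC 0.5 in expectation — and the
Bayes-optimal score reported by :func:`planted_signal_report` is the
observable posterior ``sigmoid(base + beta·x)``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .ehr_data import Cohort, PatientHistory, VisitRecord

__all__ = [
    "CohortSpec",
    "PatientTruth",
    "GroundTruth",
    "SignalReport",
    "CalibrationError",
    "generate_cohort",
    "planted_signal_report",
    "write_ground_truth",
]

HIGH_ACUITY = (1, 2)
_TRIAGE_FREQ_ORDER = (3, 4, 2, 5, 1, 9)  # mid-acuity most common in practice
_MAX_HAZARD = 0.999


class CalibrationError(ValueError):
    """Target prevalence unreachable under the chosen betas / visit mix."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the generator; defaults are the desk-scale conditions.

    Vocabulary sizes default to a small desk scale (the full reference
    sizes — 1377 diagnoses, 61 services — are reachable by config).
    ``beta_seq`` and ``beta_rel`` default to 0: a pure-noise cohort whose
    labels carry no learnable signal.  ``visit_cap`` must match the
    preprocessing cap so the relational signal lives entirely inside the
    window models actually see.
    """

    n_patients: int = 1000
    visit_count_mean: float = 5.0
    visit_count_sd: float = 5.0
    age_mean: float = 12.4
    age_sd: float = 3.9
    age_range: tuple[float, float] = (4.0, 18.0)
    n_disposition: int = 20
    n_diagnosis: int = 30
    n_service: int = 15
    services_per_visit: tuple[int, int] = (1, 3)
    target_prevalence: float = 0.17
    beta_seq: float = 0.0
    beta_rel: float = 0.0
    n_signal_pairs: int = 4
    category_decay: float = 0.9  # geometric frequency decay across code ranks
    window_days: int = 30
    max_gap_days: int = 365
    visit_cap: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0.0 < self.target_prevalence < 1.0):
            raise ValueError("target_prevalence must lie in (0, 1)")
        for name, size in (("n_disposition", self.n_disposition),
                           ("n_diagnosis", self.n_diagnosis),
                           ("n_service", self.n_service)):
            if size < 2:
                raise ValueError(f"{name} must be >= 2")
        lo, hi = self.services_per_visit
        if not (1 <= lo <= hi):
            raise ValueError("services_per_visit must be a range with lower bound >= 1")
        if not (0.0 < self.category_decay <= 1.0):
            raise ValueError("category_decay must lie in (0, 1]")
        if self.visit_cap < 1:
            raise ValueError("visit_cap must be >= 1")


@dataclass(frozen=True)
class PatientTruth:
    """Per-patient planted-signal record.

    ``hazard`` is the generative revisit probability used for the label
    draw (0 for single-visit patients, boosted for two-visit patients);
    ``x_seq``/``x_rel`` are the observable signal covariates.
    """

    patient_id: str
    hazard: float
    x_seq: int
    x_rel: int
    label: int


@dataclass
class GroundTruth:
    patients: dict[str, PatientTruth]
    base_intercept: float
    beta_seq: float
    beta_rel: float
    signal_pairs: tuple[tuple[str, str], ...]  # (service_code, diagnosis_code)


@dataclass(frozen=True)
class SignalReport:
    bayes_auroc: float
    prevalence: float
    n_positive: int
    n_patients: int


def _calibrated_count_location(mean: float, sd: float) -> float:
    """Location mu such that E[max(1, round(N(mu, sd)))] equals *mean*.

    Truncating N(5, 5) at 1 by clipping pushes the realized mean well above
    5, so the pre-truncation location is solved by bisection on the exact
    discretized expectation.
    """
    if sd <= 0:
        return mean
    ks = np.arange(0, int(mean + 10 * sd) + 2)
    vals = np.maximum(ks, 1)

    def realized(mu: float) -> float:
        upper = norm.cdf(ks + 0.5, loc=mu, scale=sd)
        lower = norm.cdf(ks - 0.5, loc=mu, scale=sd)
        p = upper - lower
        p[0] = norm.cdf(0.5, loc=mu, scale=sd)  # all mass below 0.5 maps to 1
        return float(np.sum(vals * p))

    lo, hi = mean - 6 * sd, mean + sd
    if realized(lo) > mean or realized(hi) < mean:
        raise CalibrationError(f"cannot calibrate visit counts to mean {mean}")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if realized(mid) < mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _skewed_probs(n: int, decay: float) -> np.ndarray:
    w = decay ** np.arange(n)
    return w / w.sum()


def generate_cohort(spec: CohortSpec) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort and its ground truth, fully determined by the seed."""
    rng = np.random.default_rng(spec.seed)
    lo_age, hi_age = spec.age_range

    mu_count = _calibrated_count_location(spec.visit_count_mean, spec.visit_count_sd)
    counts = np.maximum(
        np.rint(rng.normal(mu_count, spec.visit_count_sd, spec.n_patients)).astype(int), 1
    )
    base_ages = np.clip(rng.normal(spec.age_mean, spec.age_sd, spec.n_patients),
                        lo_age, hi_age)

    disp_codes = [f"DISP{i:02d}" for i in range(spec.n_disposition)]
    diag_codes = [f"DX{i:04d}" for i in range(spec.n_diagnosis)]
    svc_codes = [f"SVC{i:02d}" for i in range(spec.n_service)]
    p_triage = _skewed_probs(len(_TRIAGE_FREQ_ORDER), spec.category_decay)
    p_disp = _skewed_probs(spec.n_disposition, spec.category_decay)
    p_diag = _skewed_probs(spec.n_diagnosis, spec.category_decay)
    p_svc = _skewed_probs(spec.n_service, spec.category_decay)

    n_pairs = min(spec.n_signal_pairs, spec.n_service, spec.n_diagnosis)
    signal_pairs = tuple((svc_codes[i], diag_codes[i]) for i in range(n_pairs))
    pair_set = set(signal_pairs)

    svc_lo, svc_hi = spec.services_per_visit
    epoch = _dt.date(2015, 1, 1)

    # Draw every visit's covariates and all non-final gaps first, so the
    # hazard covariates exist before the intercept is calibrated.
    patients = []
    for p in range(spec.n_patients):
        n_visits = int(counts[p])
        triage = rng.choice(_TRIAGE_FREQ_ORDER, size=n_visits, p=p_triage)
        disp = rng.choice(disp_codes, size=n_visits, p=p_disp)
        diag = rng.choice(diag_codes, size=n_visits, p=p_diag)
        services = []
        for _ in range(n_visits):
            k = min(int(rng.integers(svc_lo, svc_hi + 1)), spec.n_service)
            services.append(frozenset(rng.choice(svc_codes, size=k, replace=False, p=p_svc)))
        gaps = rng.integers(5, spec.max_gap_days + 1, size=max(n_visits - 2, 0))
        first_offset = int(rng.integers(0, 1500))
        # observable signal covariates, computed on the capped input window
        # models actually see (for n=1 the input is the single visit itself)
        last_input = max(n_visits - 2, 0)
        window_lo = max(n_visits - 1 - spec.visit_cap, 0)
        window_hi = max(n_visits - 1, 1)
        x_seq = int(triage[last_input] in HIGH_ACUITY)
        x_rel = int(any(
            (s, diag[t]) in pair_set
            for t in range(window_lo, window_hi)
            for s in services[t]
        ))
        patients.append({
            "id": f"P{p:06d}", "n": n_visits, "triage": triage, "disp": disp,
            "diag": diag, "services": services, "gaps": gaps,
            "first_offset": first_offset, "x_seq": x_seq, "x_rel": x_rel,
        })

    # Equalization factor: two-visit patients absorb the structural zeros of
    # single-visit patients so that the label rate conditional on a
    # one-visit input window matches the multi-visit rate.
    n_single = sum(1 for pt in patients if pt["n"] == 1)
    n_two = sum(1 for pt in patients if pt["n"] == 2)
    boost = 1.0 + n_single / n_two if n_two else 1.0

    scores = {pt["id"]: spec.beta_seq * pt["x_seq"] + spec.beta_rel * pt["x_rel"]
              for pt in patients}

    def hazard_at(b: float, pt: dict) -> float:
        if pt["n"] == 1:
            return 0.0
        h = float(expit(b + scores[pt["id"]]))
        if pt["n"] == 2:
            h = min(boost * h, _MAX_HAZARD)
        return h

    n_multi = sum(1 for pt in patients if pt["n"] > 1)
    if n_multi == 0 or n_multi / spec.n_patients < spec.target_prevalence:
        raise CalibrationError(
            f"target prevalence {spec.target_prevalence} exceeds the multi-visit "
            f"fraction {n_multi / spec.n_patients:.3f}; no intercept can reach it"
        )
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        realized = sum(hazard_at(mid, pt) for pt in patients) / spec.n_patients
        if realized < spec.target_prevalence:
            lo = mid
        else:
            hi = mid
    base = 0.5 * (lo + hi)

    histories = []
    truths: dict[str, PatientTruth] = {}
    for idx, pt in enumerate(patients):
        hazard = hazard_at(base, pt)
        if pt["n"] > 1:
            label = int(rng.random() < hazard)
            final_gap = (int(rng.integers(1, spec.window_days + 1)) if label
                         else int(rng.integers(spec.window_days + 1, spec.max_gap_days + 1)))
            all_gaps = list(pt["gaps"]) + [final_gap]
            offsets = np.concatenate([[0], np.cumsum(all_gaps)])
        else:
            label = 0
            offsets = np.array([0])
        visits = []
        for t in range(pt["n"]):
            date = epoch + _dt.timedelta(days=pt["first_offset"] + int(offsets[t]))
            age = min(float(base_ages[idx]) + offsets[t] / 365.25, hi_age)
            visits.append(VisitRecord(
                patient_id=pt["id"], visit_date=date, age_years=round(age, 2),
                triage_level=int(pt["triage"][t]), disposition_code=str(pt["disp"][t]),
                diagnosis_code=str(pt["diag"][t]), service_codes=pt["services"][t],
            ))
        histories.append(PatientHistory(pt["id"], tuple(visits)))
        truths[pt["id"]] = PatientTruth(pt["id"], hazard, pt["x_seq"], pt["x_rel"], label)

    return Cohort(histories), GroundTruth(truths, base, spec.beta_seq, spec.beta_rel,
                                          signal_pairs)


def planted_signal_report(truth: GroundTruth, cohort: Cohort) -> SignalReport:
    """Bayes-optimal AUROC implied by the planted signal.

    The score is the observable posterior ``sigmoid(base + beta·x)`` — the
    best any model restricted to the input window can do — and the AUROC is
    its exact concordance probability against the realized labels, computed
    over the few distinct score values with ties counted 1/2.  With zero
    betas every score is identical and the AUROC is exactly 0.5.
    """
    ids = [h.patient_id for h in cohort.histories]
    missing = [i for i in ids if i not in truth.patients]
    if missing:
        raise ValueError(f"ground truth missing patients, e.g. {missing[0]}")
    scores = np.array([
        expit(truth.base_intercept
              + truth.beta_seq * truth.patients[i].x_seq
              + truth.beta_rel * truth.patients[i].x_rel)
        for i in ids
    ])
    labels = np.array([truth.patients[i].label for i in ids])
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return SignalReport(0.5, n_pos / len(labels), n_pos, len(labels))
    values = np.unique(scores)
    pos_counts = np.array([np.sum((scores == v) & (labels == 1)) for v in values])
    neg_counts = np.array([np.sum((scores == v) & (labels == 0)) for v in values])
    neg_below = np.concatenate([[0], np.cumsum(neg_counts)[:-1]])
    concordant = float(np.sum(pos_counts * neg_below))
    ties = float(np.sum(pos_counts * neg_counts))
    auroc = (concordant + 0.5 * ties) / (n_pos * n_neg)
    return SignalReport(float(auroc), n_pos / len(labels), n_pos, len(labels))


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Sidecar CSV with the planted per-patient signal and realized label."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "hazard", "x_seq", "x_rel", "label"])
        for pid in sorted(truth.patients):
            t = truth.patients[pid]
            writer.writerow([pid, repr(t.hazard), t.x_seq, t.x_rel, t.label])
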