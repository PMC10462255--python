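"""Trial-style response summarization: BOR, response rates, Kaplan-Meier.

Subjects carry a best percent change in target-lesion size from
baseline (negative = shrinkage), confirmation flags for RECIST v1.1
and irRECIST responses, a clinical-benefit duration in months, and a
flag for transition to new therapy within one year.  The module
classifies best overall response at the printed thresholds (partial
response at <= -30%, progression at >= +20%, complete response at
-100%), computes response and benefit rates over evaluable subjects,
prepares waterfall tables, and estimates right-censored survival with
the Kaplan-Meier product-limit estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

PR_THRESHOLD = -30.0   # percent change at or below -> partial response
PD_THRESHOLD = 20.0    # percent change at or above -> progressive disease
BENEFIT_CUTOFF_MONTHS = 6.0

BOR_ORDER = ("CR", "PR", "SD", "PD")


@dataclass
class SubjectResponse:
    subject_id: str
    best_pct_change: float
    confirmed_recist: bool = False
    confirmed_irrecist: bool = False
    benefit_months: float = 0.0
    new_therapy_within_1yr: bool = True
    evaluable: bool = True

    def __post_init__(self) -> None:
        if self.best_pct_change < -100:
            raise ValueError("best_pct_change cannot be below -100")
        if self.benefit_months < 0:
            raise ValueError("benefit_months must be nonnegative")


@dataclass
class SurvivalRecord:
    time: float
    event: bool  # True = event observed; False = right-censored

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be nonnegative")


@dataclass
class KMEstimate:
    """Product-limit survival curve: S(t) just after each event time."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) after each event time
    n_at_risk: np.ndarray   # risk-set size just before each event time


def classify_bor(pct_change: float) -> str:
    """Best overall response category at the printed thresholds.

    -100% is complete response; at or below -30% partial response; at
    or above +20% progressive disease; otherwise stable disease.
    Boundaries are inclusive per RECIST convention.
    """
    if pct_change < -100:
        raise ValueError("percent change cannot be below -100")
    if pct_change == -100:
        return "CR"
    if pct_change <= PR_THRESHOLD:
        return "PR"
    if pct_change >= PD_THRESHOLD:
        return "PD"
    return "SD"


def round_pct(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, matching printed clinical percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_trial(rows: Sequence[SubjectResponse],
                    benefit_cutoff_months: float = BENEFIT_CUTOFF_MONTHS,
                    ) -> dict[str, float]:
    """Response and benefit rates over evaluable subjects.

    Clinical benefit is strict: ``benefit_months > cutoff``.  The
    no-new-therapy rate counts subjects who had not transitioned to a
    new therapy within one year.  Percentages are rounded to one
    decimal, half away from zero.
    """
    ev = [r for r in rows if r.evaluable]
    if not ev:
        raise ValueError("no evaluable subjects")
    n = len(ev)

    def pct(count: int) -> float:
        return round_pct(100.0 * count / n)

    return {
        "n_evaluable": n,
        "orr_confirmed_recist_pct": pct(sum(r.confirmed_recist for r in ev)),
        "orr_confirmed_irrecist_pct": pct(sum(r.confirmed_irrecist for r in ev)),
        "cbr_pct": pct(sum(r.benefit_months > benefit_cutoff_months
                           for r in ev)),
        "no_new_therapy_1yr_pct": pct(sum(not r.new_therapy_within_1yr
                                          for r in ev)),
    }


def kaplan_meier(records: Sequence[SurvivalRecord]) -> KMEstimate:
    """Kaplan-Meier product-limit estimate with right censoring.

    Censored observations reduce the risk set without producing a
    step in the survival curve.
    """
    if not records:
        raise ValueError("no survival records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.unique(times[events])
    if event_times.size == 0:
        return KMEstimate(times=event_times,
                          survival=np.array([]), n_at_risk=np.array([]))
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    n_at_risk = np.array([(times >= t).sum() for t in event_times])
    return KMEstimate(times=event_times, survival=surv, n_at_risk=n_at_risk)


def waterfall_table(rows: Sequence[SubjectResponse],
                    benefit_cutoff_months: float = BENEFIT_CUTOFF_MONTHS,
                    ) -> pd.DataFrame:
    """Evaluable subjects sorted for a waterfall plot.

    Rows are sorted descending by best percent change (worst first),
    stable by subject id on ties, with the BOR category and a
    clinical-benefit flag attached.
    """
    ev = [r for r in rows if r.evaluable]
    df = pd.DataFrame([{
        "subject_id": r.subject_id,
        "best_pct_change": r.best_pct_change,
        "bor": classify_bor(r.best_pct_change),
        "clinical_benefit": r.benefit_months > benefit_cutoff_months,
    } for r in ev])
    if df.empty:
        return df
    df = df.sort_values("subject_id", kind="mergesort")
    df = df.sort_values("best_pct_change", ascending=False, kind="mergesort")
    return df.reset_index(drop=True)


def read_response_csv(path: str | Path) -> list[SubjectResponse]:
    """Load a subject response table from CSV (one row per subject)."""
    df = pd.read_csv(path)
    required = {"subject_id", "best_pct_change"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"response CSV missing columns: {sorted(missing)}")
    rows = []
    for _, rec in df.iterrows():
        rows.append(SubjectResponse(
            subject_id=str(rec["subject_id"]),
            best_pct_change=float(rec["best_pct_change"]),
            confirmed_recist=bool(rec.get("confirmed_recist", False)),
            confirmed_irrecist=bool(rec.get("confirmed_irrecist", False)),
            benefit_months=float(rec.get("benefit_months", 0.0)),
            new_therapy_within_1yr=bool(rec.get("new_therapy_within_1yr", True)),
            evaluable=bool(rec.get("evaluable", True)),
        ))
    return rows


def write_response_csv(rows: Sequence[SubjectResponse],
                       path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in rows]).to_csv(path, index=False)


def example_trial_narrative() -> list[SubjectResponse]:
    """Synthetic stand-in table encoding the reported trial counts.

    The published per-subject table is not printed, so this fixture
    reconstructs a minimal 14-subject cohort consistent with the
    narrative counts: 3 irRECIST-confirmed responders (2 also RECIST
    confirmed), 6 subjects with clinical benefit beyond six months,
    and 5 of those not starting a new therapy within one year.
    """
    rows: list[SubjectResponse] = []
    # three confirmed responders (PR-range shrinkage), two RECIST-confirmed
    for i, (recist, no_new) in enumerate(
            [(True, True), (True, True), (False, True)], start=1):
        rows.append(SubjectResponse(
            subject_id=f"R{i}", best_pct_change=-50.0,
            confirmed_recist=recist, confirmed_irrecist=True,
            benefit_months=12.0, new_therapy_within_1yr=not no_new))
    # three further subjects with durable benefit but no confirmed response
    for i, no_new in enumerate([True, True, False], start=1):
        rows.append(SubjectResponse(
            subject_id=f"B{i}", best_pct_change=-10.0,
            benefit_months=8.0, new_therapy_within_1yr=not no_new))
    # eight subjects without clinical benefit
    for i in range(1, 9):
        rows.append(SubjectResponse(
            subject_id=f"P{i}", best_pct_change=25.0,
            benefit_months=2.0, new_therapy_within_1yr=True))
    return rows
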