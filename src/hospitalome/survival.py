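"""Bloodstream-infection risk after intestinal domination.

Intestinal domination — a genus exceeding a relative-abundance threshold in
stool — is encoded as an absorbing time-dependent covariate on a day axis
relative to the nearest HCT, restricted to the peri-transplant window
(day -15 to day +35).  Risk of a genus-matched bloodstream infection (BSI) is
modeled with a Cox proportional-hazards model in counting-process form:
per-patient rows (start, stop, covariate, event) with half-open intervals
(start, stop].  The partial likelihood uses the Efron correction for the many
same-day ties produced by an integer day axis and is maximized by
Newton-Raphson.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import composition
from .schema import BSI_GENERA, Cohort

__all__ = [
    "CoxFit",
    "ConvergenceError",
    "build_counting_process",
    "fit_cox_td",
    "threshold_sweep",
    "infection_timeline",
    "DominationRiskModel",
    "DominationRiskResults",
]

DEFAULT_WINDOW = (-15, 35)


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge (typically a monotone likelihood)."""


@dataclass
class CoxFit:
    """Wald summary of the time-dependent domination covariate."""

    beta: float
    se: float
    n_patients: int
    n_events: int
    n_dominated: int
    loglik: float = np.nan
    n_iter: int = 0

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - 1.96 * self.se)),
            float(np.exp(self.beta + 1.96 * self.se)),
        )

    @property
    def p_value(self) -> float:
        z = self.beta / self.se
        return float(2 * stats.norm.sf(abs(z)))

    def summary(self) -> str:
        lo, hi = self.ci95
        return (
            f"HR {self.hr:.2f} [{lo:.2f}-{hi:.2f}] 95% CI, p={self.p_value:.3g} "
            f"(beta={self.beta:.4f}, se={self.se:.4f}; {self.n_events} events, "
            f"{self.n_dominated} dominated of {self.n_patients} patients)"
        )


def _patient_windows(hct_days: list[int], window: tuple[int, int]) -> list[tuple[int, int, int]]:
    """(hct_day, entry_rel, exit_rel) per HCT; overlapping windows truncated.

    A patient with several transplants contributes one observation anchored to
    each HCT, but a window overlapping the previous one starts where that one
    ended so no patient-day is counted twice.
    """
    lo, hi = window
    out = []
    prev_end_abs = None
    for h in sorted(hct_days):
        entry = lo
        if prev_end_abs is not None and h + lo < prev_end_abs:
            entry = prev_end_abs - h
        if entry < hi:
            out.append((h, entry, hi))
            prev_end_abs = h + hi
    return out


def build_counting_process(
    cohort: Cohort,
    genus: str,
    threshold: float = 0.30,
    window: tuple[int, int] = DEFAULT_WINDOW,
    censor_genera: frozenset = BSI_GENERA,
) -> pd.DataFrame:
    """Counting-process rows for the domination covariate of one genus.

    Per patient (and HCT window): entry at the window start, exit at the first
    tracked-genus blood culture or the window end, whichever is earlier; the
    event flag is set only when the culture matches ``genus`` (a BSI by
    another tracked genus censors).  The covariate starts at 0 and switches to
    1 the day after the first stool sample whose genus-level relative
    abundance strictly exceeds ``threshold``; it never reverts.  Patients with
    a matching BSI before entry are excluded; patients without samples
    contribute covariate-0 follow-up (flagged in ``attrs``).

    Returns a frame with columns PatientID, start, stop, dominated, event,
    intervals half-open (start, stop] on the day-relative-to-HCT axis.
    """
    rel = composition.genus_relative_abundance(cohort)
    have_genus = genus in rel.data.columns or genus in set(
        cohort.taxonomy.get("Genus", pd.Series(dtype="string")).dropna()
    )
    if not have_genus:
        raise KeyError(f"genus {genus!r} absent from the cohort taxonomy")
    fracs = rel.data[genus] if genus in rel.data.columns else pd.Series(dtype=float)

    samples = cohort.samples.dropna(subset=["SampleID", "PatientID", "Timepoint"])
    sample_meta = samples.set_index("SampleID")[["PatientID", "Timepoint"]]
    infections = cohort.infections.dropna(subset=["PatientID", "Timepoint"])

    rows = []
    flags: list[str] = []
    excluded: list[str] = []
    hct_map = (
        cohort.hct.dropna(subset=["TimepointOfTransplant"])
        .groupby("PatientID")["TimepointOfTransplant"]
        .apply(lambda v: sorted(int(x) for x in v))
    )
    for pid, hct_days in hct_map.items():
        pat_samples = sample_meta[sample_meta["PatientID"] == pid]
        pat_inf = infections[infections["PatientID"] == pid]
        for h, entry, win_end in _patient_windows(hct_days, window):
            # domination state from sampled stool, absorbing
            day_rel = pat_samples["Timepoint"].astype(int) - h
            obs = day_rel[day_rel <= win_end]
            dom_day = None
            if len(obs):
                f = fracs.reindex(obs.index).fillna(0.0)
                hits = obs[(f > threshold).to_numpy()]
                if len(hits):
                    dom_day = int(hits.min())
            else:
                flags.append(f"patient {pid}: no stool sample in window; covariate-0 follow-up only")
            inf_days = pat_inf["Timepoint"].astype(int) - h
            agents = pat_inf["InfectiousAgent"].astype(str)
            tracked = inf_days[agents.isin(censor_genera).to_numpy()]
            matching = inf_days[(agents == genus).to_numpy()]
            if len(matching) and int(matching.min()) <= entry:
                excluded.append(str(pid))
                continue
            exit_day = win_end
            event = False
            upcoming = tracked[tracked > entry]
            if len(upcoming):
                first = int(upcoming.min())
                if first <= win_end:
                    exit_day = first
                    event = bool(len(matching) and int(matching.min()) == first)
            if exit_day <= entry:
                flags.append(f"patient {pid}: zero-length follow-up, skipped")
                continue
            if dom_day is None or dom_day >= exit_day:
                rows.append((pid, entry, exit_day, 0, event))
            elif dom_day <= entry:
                rows.append((pid, entry, exit_day, 1, event))
            else:
                rows.append((pid, entry, dom_day, 0, False))
                rows.append((pid, dom_day, exit_day, 1, event))
    out = pd.DataFrame(rows, columns=["PatientID", "start", "stop", "dominated", "event"])
    out.attrs["flags"] = flags
    out.attrs["excluded_patients"] = excluded
    out.attrs["genus"] = genus
    out.attrs["threshold"] = threshold
    out.attrs["window"] = window
    return out


def _efron_quantities(beta: float, start, stop, x, event):
    """Log partial likelihood, score and information at beta (Efron ties)."""
    ll = 0.0
    score = 0.0
    info = 0.0
    for t in np.unique(stop[event]):
        at_risk = (start < t) & (t <= stop)
        deaths = at_risk & event & (stop == t)
        d = int(deaths.sum())
        xr = x[at_risk]
        xd = x[deaths]
        wr = np.exp(beta * xr)
        wd = np.exp(beta * xd)
        s0r, s1r, s2r = wr.sum(), (wr * xr).sum(), (wr * xr * xr).sum()
        s0d, s1d, s2d = wd.sum(), (wd * xd).sum(), (wd * xd * xd).sum()
        ll += beta * xd.sum()
        for l in range(d):
            frac = l / d
            phi = s0r - frac * s0d
            a = s1r - frac * s1d
            b = s2r - frac * s2d
            ll -= np.log(phi)
            score -= a / phi
            info += b / phi - (a / phi) ** 2
        score += xd.sum()
    return ll, score, info


def fit_cox_td(
    intervals: pd.DataFrame,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Maximize the Cox partial likelihood over counting-process rows.

    Single binary (or continuous) covariate ``dominated``; Efron correction
    for tied event days (Breslow available via ``ties="breslow"``);
    Newton-Raphson iterated to |delta beta| < ``tol``.  Raises
    :class:`ConvergenceError` on a monotone likelihood (e.g. all events in one
    covariate stratum) and ``ValueError`` when no contrast exists.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie correction {ties!r}")
    df = intervals
    start = df["start"].to_numpy(dtype=float)
    stop = df["stop"].to_numpy(dtype=float)
    x = df["dominated"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=bool)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events: Cox model cannot be fitted")
    if np.allclose(x, x[0]):
        raise ValueError("covariate has no contrast (constant across all rows)")

    if ties == "breslow":
        quantities = _breslow_quantities
    else:
        quantities = _efron_quantities

    beta = 0.0
    for it in range(1, max_iter + 1):
        ll, score, info = quantities(beta, start, stop, x, event)
        if info <= 0 or not np.isfinite(info):
            raise ConvergenceError(
                f"singular information at beta={beta:.3g}; events by stratum: "
                f"{_events_by_stratum(x, event)}"
            )
        step = score / info
        beta += step
        if abs(beta) > 30:
            raise ConvergenceError(
                "monotone partial likelihood (beta diverging); events by stratum: "
                f"{_events_by_stratum(x, event)}"
            )
        if abs(step) < tol:
            break
    else:
        raise ConvergenceError(f"no convergence in {max_iter} Newton-Raphson iterations")
    ll, _, info = quantities(beta, start, stop, x, event)
    se = float(1.0 / np.sqrt(info))
    dominated_patients = df.loc[df["dominated"] > 0, "PatientID"].nunique()
    return CoxFit(
        beta=float(beta),
        se=se,
        n_patients=int(df["PatientID"].nunique()),
        n_events=n_events,
        n_dominated=int(dominated_patients),
        loglik=float(ll),
        n_iter=it,
    )


def _breslow_quantities(beta: float, start, stop, x, event):
    ll = 0.0
    score = 0.0
    info = 0.0
    for t in np.unique(stop[event]):
        at_risk = (start < t) & (t <= stop)
        deaths = at_risk & event & (stop == t)
        d = int(deaths.sum())
        xr = x[at_risk]
        xd = x[deaths]
        wr = np.exp(beta * xr)
        s0 = wr.sum()
        s1 = (wr * xr).sum()
        s2 = (wr * xr * xr).sum()
        ll += beta * xd.sum() - d * np.log(s0)
        score += xd.sum() - d * s1 / s0
        info += d * (s2 / s0 - (s1 / s0) ** 2)
    return ll, score, info


def _events_by_stratum(x, event) -> dict:
    return {
        "covariate=0": int(event[x == 0].sum()),
        "covariate=1": int(event[x > 0].sum()),
    }


def threshold_sweep(
    cohort: Cohort,
    genus: str,
    thresholds: tuple = (0.30, 0.10, 0.01, 0.001),
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Repeat the domination Cox analysis across abundance thresholds.

    One fit per threshold; a threshold whose fit fails is reported with its
    error and the sweep continues.  The repeated fits are not adjusted for
    multiplicity.  ``n_dominated`` is monotone non-increasing in threshold.
    """
    rows = []
    for thr in thresholds:
        rec = {
            "genus": genus,
            "threshold": float(thr),
            "hr": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
            "n_patients": 0,
            "n_events": 0,
            "n_dominated": 0,
            "error": "",
        }
        try:
            cp = build_counting_process(cohort, genus, thr, window)
        except (ValueError, KeyError) as err:
            rec["error"] = str(err)
            rows.append(rec)
            continue
        rec.update(
            n_patients=int(cp["PatientID"].nunique()) if len(cp) else 0,
            n_events=int(cp["event"].sum()) if len(cp) else 0,
            n_dominated=int(cp.loc[cp["dominated"] > 0, "PatientID"].nunique()) if len(cp) else 0,
        )
        try:
            fit = fit_cox_td(cp)
            lo, hi = fit.ci95
            rec.update(hr=fit.hr, ci_low=lo, ci_high=hi, p=fit.p_value)
        except (ValueError, ConvergenceError) as err:
            rec["error"] = str(err)
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["note"] = "per-threshold fits are not multiplicity-adjusted"
    return out


def infection_timeline(
    infections: pd.DataFrame, window: tuple[int, int] = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Positive blood cultures per day-relative-to-HCT per genus (for plotting)."""
    lo, hi = window
    days = range(lo, hi + 1)
    genera = sorted(infections["InfectiousAgent"].dropna().unique()) if len(infections) else []
    out = pd.DataFrame(0, index=pd.Index(days, name="DayRelativeToNearestHCT"), columns=genera)
    if len(infections):
        sub = infections.dropna(subset=["DayRelativeToNearestHCT"])
        for _, row in sub.iterrows():
            d = int(row["DayRelativeToNearestHCT"])
            if lo <= d <= hi:
                out.loc[d, row["InfectiousAgent"]] += 1
    return out


class DominationRiskModel:
    """Model object: BSI risk of a genus after intestinal domination.

    ``fit()`` builds the counting process at one threshold and fits the Cox
    model; ``threshold_sweep`` repeats the analysis over a threshold grid.
    """

    def __init__(
        self,
        cohort: Cohort,
        genus: str,
        threshold: float = 0.30,
        window: tuple[int, int] = DEFAULT_WINDOW,
    ):
        self.cohort = cohort
        self.genus = genus
        self.threshold = threshold
        self.window = window

    def counting_process(self, threshold: float | None = None) -> pd.DataFrame:
        thr = self.threshold if threshold is None else threshold
        return build_counting_process(self.cohort, self.genus, thr, self.window)

    def fit(self, ties: str = "efron") -> "DominationRiskResults":
        cp = self.counting_process()
        fit = fit_cox_td(cp, ties=ties)
        return DominationRiskResults(self, fit, cp)

    def threshold_sweep(self, thresholds: tuple = (0.30, 0.10, 0.01, 0.001)) -> pd.DataFrame:
        return threshold_sweep(self.cohort, self.genus, thresholds, self.window)


class DominationRiskResults:
    """Fitted hazard ratio for the domination covariate."""

    def __init__(self, model: DominationRiskModel, fit: CoxFit, counting_process: pd.DataFrame):
        self.model = model
        self.fit_ = fit
        self.counting_process = counting_process

    @property
    def hr(self) -> float:
        return self.fit_.hr

    @property
    def ci95(self) -> tuple[float, float]:
        return self.fit_.ci95

    @property
    def p_value(self) -> float:
        return self.fit_.p_value

    def summary(self) -> str:
        head = (
            f"Domination -> BSI risk: genus {self.model.genus}, threshold "
            f"{self.model.threshold:g}, window {self.model.window}"
        )
        return head + "\n  " + self.fit_.summary()
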