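"""Synthetic hospitalome cohorts with known ground truth.

The generator runs the same forward model the inference assumes — daily
log-linear growth of each taxon's absolute abundance, perturbed additively by
binary antibiotic exposures — and then observes it the way the real deposit
was observed: multinomial read counts at a finite sequencing depth, a noisy
qPCR total 16S load, stool sampled every 1-4 days, interval-coded drug
courses, and genus-matched bloodstream-infection events whose discrete-day
hazard is multiplied by exp(beta) while the patient's stool is (observably)
dominated by the target genus.  The output is a drop-in replacement for the
deposit's CSV layout, so every downstream stage can be tested against known
parameters without downloading anything.

Conventions shared with the inference:

* the increment of log-abundance arriving at day d uses the exposure u_j(d),
  so the integral of u over a sample pair (t_i, t_f) equals the count of
  exposed days in the half-open window (t_i, t_f];
* the BSI hazard covariate is the absorbing, sample-detected domination
  state — 1 strictly after the first stool sample above the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import composition
from .schema import Cohort, empty_table

__all__ = [
    "SimConfig",
    "GroundTruth",
    "draw_ground_truth",
    "simulate_dynamics",
    "observe_sample",
    "simulate_drug_courses",
    "simulate_bsi",
    "generate_cohort",
]

#: genera assigned to synthetic ASVs, first two matching the BSI analyses
GENERA = (
    "Enterococcus",
    "Escherichia",
    "Blautia",
    "Lactobacillus",
    "Streptococcus",
    "Bacteroides",
    "Ruminococcus",
    "Erysipelatoclostridium",
    "Akkermansia",
    "Klebsiella",
    "Veillonella",
    "Faecalibacterium",
)

_LINEAGE = {
    "Enterococcus": ("Firmicutes", "Bacilli", "Lactobacillales", "Enterococcaceae"),
    "Escherichia": ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae"),
    "Blautia": ("Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae"),
    "Lactobacillus": ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae"),
    "Streptococcus": ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae"),
    "Bacteroides": ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Bacteroidaceae"),
    "Ruminococcus": ("Firmicutes", "Clostridia", "Oscillospirales", "Oscillospiraceae"),
    "Erysipelatoclostridium": ("Firmicutes", "Bacilli", "Erysipelotrichales", "Erysipelotrichaceae"),
    "Akkermansia": ("Verrucomicrobiota", "Verrucomicrobiae", "Verrucomicrobiales", "Akkermansiaceae"),
    "Klebsiella": ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae"),
    "Veillonella": ("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae"),
    "Faecalibacterium": ("Firmicutes", "Clostridia", "Oscillospirales", "Oscillospiraceae"),
}

#: synthetic antibacterial drug classes, each with a canonical route
DRUG_CLASSES = (
    ("penicillins", "intravenous"),
    ("glycopeptide antibiotics", "oral"),
    ("quinolones", "intravenous"),
    ("macrolides", "oral"),
    ("cephalosporins", "intravenous"),
    ("carbapenems", "intravenous"),
    ("sulfonamides", "oral"),
    ("tetracyclines", "oral"),
)

#: non-antibacterial nuisance drugs the grouping rules must discard
NUISANCE_DRUGS = (
    ("atovaquone", "miscellaneous", True),
    ("fluconazole", "antifungals", True),
    ("acyclovir", "antivirals", True),
    ("ondansetron", "antiemetics", False),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated cohort.

    Defaults emulate the real deposit's regime: stool every 1-4 days over the
    peri-transplant window, sequencing depth around 5e4 reads, total 16S load
    near 1e9 copies/g with 0.1 log10 qPCR noise, day-scale process noise of
    0.2 on log abundance, about three antibacterial courses per patient, and
    BSI hazard multiplied by 4 during domination of the target genus.
    """

    n_patients: int = 50
    n_taxa: int = 10
    n_drug_groups: int = 4
    day_window: tuple[int, int] = (-15, 35)
    sampling_interval: tuple[int, int] = (1, 4)  # uniform integer days
    read_depth: float | None = 5e4  # mean reads; None = exact (rounded latent) counts
    read_depth_dispersion: float = 5.0  # gamma shape of the depth mixture
    qpcr_noise_sd_log10: float = 0.1
    dynamics_noise_sd: float = 0.2  # per sqrt(day), log scale
    drug_course_rate: float = 3.0  # antibacterial courses per patient
    course_duration: tuple[int, int] = (3, 7)  # uniform integer days
    nuisance_drug_rate: float = 1.0
    bsi_beta: float = math.log(4.0)
    bsi_baseline_hazard: float = 0.0015  # events per patient-day (~8% of patients over the window)
    domination_threshold: float = 0.30
    bsi_genus: str = "Enterococcus"
    extinction_floor: float = 1.0  # copies/g below which a taxon reads as absent
    qpcr_fraction: float = 1.0
    multi_hct_fraction: float = 0.0
    total_load_log10: float = 9.5  # mean initial log10 total 16S copies/g
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_taxa <= 0 or self.n_drug_groups <= 0:
            raise ValueError("n_patients, n_taxa and n_drug_groups must be positive")
        if self.n_drug_groups > len(DRUG_CLASSES):
            raise ValueError(f"at most {len(DRUG_CLASSES)} drug groups supported")
        if self.day_window[0] >= self.day_window[1]:
            raise ValueError("day_window must be increasing")
        for name in (
            "qpcr_noise_sd_log10",
            "dynamics_noise_sd",
            "drug_course_rate",
            "nuisance_drug_rate",
            "bsi_baseline_hazard",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.domination_threshold < 1):
            raise ValueError("domination_threshold must lie in (0, 1)")
        if not (0 <= self.qpcr_fraction <= 1):
            raise ValueError("qpcr_fraction must lie in [0, 1]")

    @classmethod
    def noiseless(cls, **overrides) -> "SimConfig":
        """Deterministic observation: no process, sequencing or qPCR noise."""
        base = dict(dynamics_noise_sd=0.0, qpcr_noise_sd_log10=0.0, read_depth=None)
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """The parameters the generator drew and the latent states it produced."""

    g: np.ndarray  # (n_taxa,) drug-free growth rates, 1/day
    epsilon: np.ndarray  # (n_taxa, n_groups) susceptibilities, 1/day
    covariates: list  # [(group, route)] aligned with epsilon columns
    taxa: list  # ASV identifiers aligned with rows
    bsi_beta: float
    bsi_baseline_hazard: float
    trajectories: dict = field(default_factory=dict)  # pid -> (days, log_n matrix)
    domination_day: dict = field(default_factory=dict)  # pid -> observed first day or None
    hct_day: dict = field(default_factory=dict)  # pid -> absolute transplant Timepoint

    def epsilon_frame(self) -> pd.DataFrame:
        cols = [f"{g} [{r}]" for g, r in self.covariates]
        return pd.DataFrame(self.epsilon, index=self.taxa, columns=cols)

    def align_estimate(
        self, params: pd.DataFrame, include_growth: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """Paired (true, estimated) vectors over the parameters present in ``params``.

        ``params`` is a susceptibility-estimate coefficient table (taxa rows,
        ``growth_rate`` plus one column per (group, route) covariate).
        """
        te = self.epsilon_frame()
        true_vals, est_vals = [], []
        for i, taxon in enumerate(self.taxa):
            if taxon not in params.index:
                continue
            if include_growth and "growth_rate" in params.columns:
                true_vals.append(float(self.g[i]))
                est_vals.append(float(params.loc[taxon, "growth_rate"]))
            for col in te.columns:
                if col in params.columns:
                    true_vals.append(float(te.loc[taxon, col]))
                    est_vals.append(float(params.loc[taxon, col]))
        return np.asarray(true_vals), np.asarray(est_vals)


def draw_ground_truth(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    """Draw growth rates and susceptibilities.

    Most taxa are antibiotic-susceptible (negative effects dominate); the BSI
    target taxon gets a non-negative profile, the resistant Enterococcus-like
    phenotype that blooms under antibiotic pressure and drives domination.
    """
    k, m = config.n_taxa, config.n_drug_groups
    g = rng.uniform(-0.15, 0.25, size=k)
    magnitude = rng.uniform(0.25, 1.0, size=(k, m))
    sign = np.where(rng.random((k, m)) < 0.8, -1.0, 1.0)
    nonzero = rng.random((k, m)) < 0.7
    eps = magnitude * sign * nonzero
    # resistant target taxon: mildly positive, never inhibited
    eps[0] = rng.uniform(0.1, 0.35, size=m) * (rng.random(m) < 0.7)
    g[0] = abs(g[0])
    covs = [(DRUG_CLASSES[j][0], DRUG_CLASSES[j][1]) for j in range(m)]
    taxa = [f"ASV_{i + 1:04d}" for i in range(k)]
    return GroundTruth(
        g=g,
        epsilon=eps,
        covariates=covs,
        taxa=taxa,
        bsi_beta=config.bsi_beta,
        bsi_baseline_hazard=config.bsi_baseline_hazard,
    )


def simulate_dynamics(
    g: np.ndarray,
    epsilon: np.ndarray,
    exposure_u: np.ndarray,
    log_n0: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Daily Euler integration of the log-linear growth model.

    ``exposure_u`` has shape (n_days, n_groups): row t is the exposure acting
    on the increment that arrives at day t+1 (see module docstring).  Returns
    log abundances of shape (n_days + 1, n_taxa); with ``noise_sd=0`` the
    update is exact.
    """
    g = np.asarray(g, dtype=float)
    epsilon = np.atleast_2d(np.asarray(epsilon, dtype=float))
    exposure_u = np.atleast_2d(np.asarray(exposure_u, dtype=float))
    log_n0 = np.asarray(log_n0, dtype=float)
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(epsilon)) and np.all(np.isfinite(log_n0))):
        raise ValueError("non-finite inputs to simulate_dynamics")
    n_days = exposure_u.shape[0]
    out = np.empty((n_days + 1, len(g)))
    out[0] = log_n0
    drift = g + exposure_u @ epsilon.T  # (n_days, n_taxa)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires a random generator")
        drift = drift + rng.normal(0.0, noise_sd, size=drift.shape)
    out[1:] = log_n0 + np.cumsum(drift, axis=0)
    return out


def observe_sample(
    abundances: np.ndarray,
    depth: int | None,
    qpcr_noise_sd_log10: float,
    rng: np.random.Generator,
    detection_limit: float = 1e-9,
) -> tuple[np.ndarray, float]:
    """Observe one stool sample: read counts and a qPCR total load.

    With a finite ``depth``, counts are multinomial over the relative
    abundances and sum exactly to ``depth``; with ``depth=None`` the counts
    carry the latent composition essentially exactly: taxa below the relative
    ``detection_limit`` read as 0 (any assay, however deep, has one), the rest
    become integers proportional to the abundances at the largest scale int64
    allows, so the rounding error in any observable log-abundance is below
    ~1e-9.  The qPCR value is the true total times ``10**Normal(0, sd^2)``;
    with zero noise it equals the total abundance exactly.
    """
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("negative abundance")
    total = a.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector: nothing to sequence")
    if depth is None:
        kept = np.where(a < detection_limit * total, 0.0, a)
        scale = 4.0e18 / kept.max()
        counts = np.round(kept * scale).astype(np.int64)
    else:
        counts = rng.multinomial(int(depth), a / total)
    qpcr = float(total)
    if qpcr_noise_sd_log10 > 0:
        qpcr *= 10.0 ** rng.normal(0.0, qpcr_noise_sd_log10)
    return counts, qpcr


def simulate_drug_courses(
    config: SimConfig,
    rng: np.random.Generator,
    patient_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Closed-interval drug courses on the day-relative-to-HCT axis.

    Antibacterial courses draw a class uniformly from the configured groups
    (each class keeps its canonical route); non-antibacterial nuisance drugs
    are added at their own rate to exercise the selection rules downstream.
    Columns: PatientID, Start, Stop (relative days), Factor, Category,
    AntiInfective, Route.
    """
    if patient_ids is None:
        patient_ids = [f"syn{i:04d}" for i in range(config.n_patients)]
    lo, hi = config.day_window
    dlo, dhi = config.course_duration
    rows = []
    for pid in patient_ids:
        for _ in range(rng.poisson(config.drug_course_rate)):
            j = int(rng.integers(config.n_drug_groups))
            category, route = DRUG_CLASSES[j]
            start = int(rng.integers(lo, hi + 1))
            stop = min(start + int(rng.integers(dlo, dhi + 1)) - 1, hi)
            factor = f"{category.split()[0]}_drug{1 + int(rng.integers(2))}"
            rows.append((pid, start, stop, factor, category, True, route))
        for _ in range(rng.poisson(config.nuisance_drug_rate)):
            factor, category, anti = NUISANCE_DRUGS[int(rng.integers(len(NUISANCE_DRUGS)))]
            start = int(rng.integers(lo, hi + 1))
            stop = min(start + int(rng.integers(dlo, dhi + 1)) - 1, hi)
            route = ["oral", "intravenous"][int(rng.integers(2))]
            rows.append((pid, start, stop, factor, category, anti, route))
    return pd.DataFrame(
        rows,
        columns=["PatientID", "Start", "Stop", "Factor", "Category", "AntiInfective", "Route"],
    )


def simulate_bsi(
    domination_indicator: dict,
    beta: float,
    baseline_hazard: float,
    window: tuple[int, int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Discrete-day bloodstream-infection events.

    ``domination_indicator`` maps patient -> binary array over the days
    ``window[0]+1 .. window[1]`` (the days an event can arrive).  The daily
    event probability is ``baseline_hazard * exp(beta * indicator)``; at most
    one event per patient is retained (the first).  A hazard above 1 on any
    day is a configuration error.
    """
    lo, hi = window
    days = np.arange(lo + 1, hi + 1)
    hazard1 = baseline_hazard * math.exp(beta)
    if baseline_hazard > 1 or hazard1 > 1:
        raise ValueError("daily hazard exceeds 1: lower baseline_hazard or beta")
    rows = []
    for pid, ind in domination_indicator.items():
        ind = np.asarray(ind, dtype=float)
        if len(ind) != len(days):
            raise ValueError("indicator length must match the event window")
        haz = baseline_hazard * np.exp(beta * ind)
        hits = np.flatnonzero(rng.random(len(days)) < haz)
        if len(hits):
            rows.append((pid, int(days[hits[0]])))
    return pd.DataFrame(rows, columns=["PatientID", "Day"])


def _random_sequences(rng: np.random.Generator, n: int, length: int = 120) -> list[str]:
    return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]


def _make_taxonomy(config: SimConfig, taxa: list[str], rng: np.random.Generator) -> pd.DataFrame:
    from matplotlib import colormaps

    cmap = colormaps["tab20"]
    rows = []
    for i, asv in enumerate(taxa):
        genus = GENERA[i % len(GENERA)] if i < len(GENERA) else f"Genus{i:03d}"
        phylum, cls, order, family = _LINEAGE.get(
            genus, ("Firmicutes", "Clostridia", f"Order{i:03d}", f"Family{i:03d}")
        )
        r, g_, b, _ = cmap(i % 20)
        rows.append(
            {
                "ASV": asv,
                "Sequence": "",
                "Kingdom": "Bacteria",
                "Phylum": phylum,
                "Class": cls,
                "Order": order,
                "Family": family,
                "Genus": genus,
                **{f"Confidence{r_}": round(float(rng.uniform(80, 100)), 2)
                   for r_ in ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus")},
                "HexColor": "#{:02X}{:02X}{:02X}".format(int(r * 255), int(g_ * 255), int(b * 255)),
                "ColorOrder": i,
            }
        )
    frame = pd.DataFrame(rows)
    frame["Sequence"] = _random_sequences(rng, len(taxa))
    return frame


def generate_cohort(config: SimConfig, seed: int | None = None) -> tuple[Cohort, GroundTruth]:
    """Generate a full synthetic cohort plus its ground truth.

    Emits every deposit table (samples, melted ASV counts, genus-level wide
    counts, qPCR, HCT, drugs, infections, temperature, blood counts, vanA,
    taxonomy) with internally consistent keys and day axes.  Byte-identical
    under a fixed seed.
    """
    config.validate()
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    truth = draw_ground_truth(config, rng)
    lo, hi = config.day_window
    n_days = hi - lo
    pids = [f"syn{i:04d}" for i in range(config.n_patients)]

    # transplant anchoring on the deidentified Timepoint axis
    hct_rows = []
    for pid in pids:
        h = int(rng.integers(500, 3000))
        truth.hct_day[pid] = h
        source = ["BM_unmodified", "PBSC_unmodified", "TCD", "cord"][int(rng.integers(4))]
        disease = ["Leukemia", "Lymphoma", "Myeloma", "MDS"][int(rng.integers(4))]
        hct_rows.append((pid, h, source, disease))
        if rng.random() < config.multi_hct_fraction:
            h2 = h + int(rng.integers(150, 400))
            hct_rows.append((pid, h2, source, disease))

    drugs_rel = simulate_drug_courses(config, rng, pids)

    # latent dynamics per patient
    day_grid = np.arange(lo, hi + 1)
    covs = truth.covariates
    exposure_by_patient: dict[str, np.ndarray] = {}
    for pid in pids:
        u = np.zeros((n_days, len(covs)))
        sub = drugs_rel[(drugs_rel["PatientID"] == pid) & drugs_rel["AntiInfective"]]
        for _, row in sub.iterrows():
            key = (str(row["Category"]).lower(), str(row["Route"]).lower())
            if key not in covs:
                continue  # nuisance drug: no effect on bacterial dynamics
            j = covs.index(key)
            # u row t drives the increment arriving at day lo+1+t; exposure on
            # day d therefore fills row d-lo-1
            for d in range(int(row["Start"]), int(row["Stop"]) + 1):
                t = d - lo - 1
                if 0 <= t < n_days:
                    u[t, j] = 1.0
        exposure_by_patient[pid] = u

    sample_rows, count_rows, qpcr_rows, vana_rows = [], [], [], []
    dom_indicator: dict[str, np.ndarray] = {}
    event_days = np.arange(lo + 1, hi + 1)
    genus_of = {asv: (GENERA[i % len(GENERA)] if i < len(GENERA) else f"Genus{i:03d}")
                for i, asv in enumerate(truth.taxa)}
    target_idx = [i for i, asv in enumerate(truth.taxa) if genus_of[asv] == config.bsi_genus]
    consistencies = ["formed", "semi-formed", "liquid"]
    for pid in pids:
        log_n0 = (
            math.log(10.0) * config.total_load_log10
            - math.log(config.n_taxa)
            + rng.normal(0.0, 1.0, size=config.n_taxa)
        )
        traj = simulate_dynamics(
            truth.g, truth.epsilon, exposure_by_patient[pid],
            log_n0, config.dynamics_noise_sd, rng,
        )
        truth.trajectories[pid] = (day_grid.copy(), traj)
        # stool sampling days
        slo, shi = config.sampling_interval
        day = lo + int(rng.integers(0, shi))
        sdays = []
        while day <= hi:
            sdays.append(day)
            day += int(rng.integers(slo, shi + 1))
        h = truth.hct_day[pid]
        dom_day = None
        for si, d in enumerate(sdays):
            latent = np.exp(traj[d - lo])
            latent = np.where(latent < config.extinction_floor, 0.0, latent)
            if latent.sum() <= 0:
                continue
            if config.read_depth is None:
                depth = None
            else:
                depth = max(
                    1000,
                    int(rng.gamma(config.read_depth_dispersion,
                                  config.read_depth / config.read_depth_dispersion)),
                )
            counts, qpcr = observe_sample(latent, depth, config.qpcr_noise_sd_log10, rng)
            sid = f"{pid}.{si:03d}"
            consistency = (
                consistencies[int(rng.integers(3))] if rng.random() < 0.8 else None
            )
            sample_rows.append((sid, pid, h + d, consistency, None, None, d))
            nz = np.flatnonzero(counts > 0)
            for i in nz:
                count_rows.append((sid, truth.taxa[i], int(counts[i])))
            if rng.random() < config.qpcr_fraction:
                qpcr_rows.append((sid, qpcr))
            total_reads = counts.sum()
            target_frac = counts[target_idx].sum() / total_reads if total_reads > 0 else 0.0
            if dom_day is None and target_frac > config.domination_threshold:
                dom_day = d
            vana_rows.append((sid, bool(target_frac > 0.3) if rng.random() < 0.8 else bool(rng.random() < 0.05)))
        truth.domination_day[pid] = dom_day
        dom_indicator[pid] = (
            (event_days > dom_day).astype(float) if dom_day is not None else np.zeros(len(event_days))
        )

    infections_rel = simulate_bsi(
        dom_indicator, config.bsi_beta, config.bsi_baseline_hazard, config.day_window, rng
    )

    # vitals: daily max temperature with occasional neutropenic fevers
    temp_rows, blood_rows = [], []
    for pid in pids:
        h = truth.hct_day[pid]
        base = rng.normal(98.2, 0.3)
        for d in day_grid:
            fever = rng.random() < (0.10 if 0 <= d <= 14 else 0.02)
            t = base + rng.normal(0, 0.4) + (rng.uniform(2.0, 4.0) if fever else 0.0)
            temp_rows.append((pid, h + d, round(float(np.clip(t, 95, 106)), 1), int(d)))
            # neutrophils crash after conditioning, engraft ~ day +14
            if d < -7:
                neut = rng.uniform(2.0, 6.0)
            elif d < 14:
                neut = rng.uniform(0.0, 0.4)
            else:
                neut = rng.uniform(0.5, 4.0)
            blood_rows.append((pid, h + d, "Neutrophils", round(float(neut), 3), "K_per_uL", int(d)))
            blood_rows.append((pid, h + d, "WBCtotal", round(float(neut * rng.uniform(1.2, 2.5)), 3), "K_per_uL", int(d)))

    cohort = Cohort()
    cohort.samples = pd.DataFrame(
        sample_rows,
        columns=["SampleID", "PatientID", "Timepoint", "Consistency", "Accession", "BioProject", "DayRelativeToNearestHCT"],
    )
    cohort.counts = pd.DataFrame(count_rows, columns=["SampleID", "ASV", "Count"])
    cohort.qpcr = pd.DataFrame(qpcr_rows, columns=["SampleID", "qPCR16S"])
    cohort.hct = pd.DataFrame(hct_rows, columns=["PatientID", "TimepointOfTransplant", "HCTSource", "Disease"])
    drugs = drugs_rel.copy()
    hct_of = {pid: truth.hct_day[pid] for pid in pids}
    drugs["StartTimepoint"] = drugs["PatientID"].map(hct_of) + drugs["Start"]
    drugs["StopTimepoint"] = drugs["PatientID"].map(hct_of) + drugs["Stop"]
    drugs["StartDayRelativeToNearestHCT"] = drugs["Start"]
    drugs["StopDayRelativeToNearestHCT"] = drugs["Stop"]
    cohort.drugs = drugs[
        ["PatientID", "StartTimepoint", "StopTimepoint", "Factor", "Category",
         "AntiInfective", "Route", "StartDayRelativeToNearestHCT", "StopDayRelativeToNearestHCT"]
    ]
    inf = infections_rel.copy()
    if len(inf):
        inf["Timepoint"] = inf["PatientID"].map(hct_of) + inf["Day"]
        inf["InfectiousAgent"] = config.bsi_genus
        inf["DayRelativeToNearestHCT"] = inf["Day"]
        cohort.infections = inf[["PatientID", "Timepoint", "InfectiousAgent", "DayRelativeToNearestHCT"]]
    cohort.temperature = pd.DataFrame(
        temp_rows, columns=["PatientID", "Timepoint", "MaxTemperature", "DayRelativeToNearestHCT"]
    )
    cohort.blood_counts = pd.DataFrame(
        blood_rows, columns=["PatientID", "Day", "BloodCellType", "Value", "Unit", "DayRelativeToNearestHCT"]
    )
    cohort.vana = pd.DataFrame(vana_rows, columns=["SampleID", "VanA"])
    cohort.taxonomy = _make_taxonomy(config, truth.taxa, rng)
    # retype through the schema coercion path so dtypes match a loaded deposit
    _retype(cohort)
    genus_wide = composition.aggregate_to_level(cohort.counts, cohort.taxonomy, "genus")
    cohort.counts_wide["genus"] = genus_wide.astype(int).reset_index()
    cohort.provenance = {
        "generator": "hospitalome.synthetic",
        "seed": seed,
        "config": asdict(config),
    }
    return cohort, truth


def _retype(cohort: Cohort) -> None:
    from .schema import TABLE_COLUMNS, _DTYPE_MAP

    for name, spec in TABLE_COLUMNS.items():
        frame = cohort.table(name).copy()
        if frame.empty:
            setattr(cohort, name, empty_table(name))
            continue
        for col, kind in spec.items():
            if col not in frame.columns:
                frame[col] = pd.Series([pd.NA] * len(frame), dtype=_DTYPE_MAP[kind])
            else:
                frame[col] = frame[col].astype(_DTYPE_MAP[kind])
        setattr(cohort, name, frame[list(spec)].reset_index(drop=True))
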