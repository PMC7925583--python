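"""Inference of per-antibiotic effects on gut-microbe growth rates.

The model: antibiotics act independently and additively on the exponential
growth rate of each taxon,

    d log N_k / dt = g_k + sum_j eps_{k,j} u_j(t),

where N_k is the absolute abundance of taxon k (relative abundance times the
qPCR 16S load), g_k its drug-free growth rate, u_j(t) the daily presence of
antibiotic group j, and eps_{k,j} the susceptibility of k to j (1/day;
negative = inhibition).  Integrating between two consecutive stool samples of
a pair p gives a linear model in the time gap dt_p and the per-group exposure
day-counts C_{p,j}; stacking all pairs yields one regression problem per
taxon, solved by ridge regression with the penalty chosen by 3-fold
cross-validation repeated over random partitions.

Drugs are grouped by antibacterial category, split by administration route.
Oral and intravenous exposures enter the regression as separate covariates of
a single joint fit (one intercept g_k per taxon), and results are reported per
route.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import composition
from .schema import Cohort

__all__ = [
    "DrugGroupingSpec",
    "RidgeConfig",
    "ExposureMatrix",
    "RegressionProblem",
    "SusceptibilityEstimate",
    "assign_groups",
    "drug_frequency",
    "build_exposure_matrix",
    "make_pairs",
    "pair_covariates",
    "select_taxa",
    "assemble_problem",
    "fit_ridge",
    "select_lambda",
    "infer_susceptibilities",
    "AntibioticImpactModel",
    "AntibioticImpactResults",
]

log = logging.getLogger(__name__)

#: drug categories treated as antibacterial classes (matched case-insensitively)
DEFAULT_ANTIBACTERIAL_CATEGORIES = frozenset(
    {
        "aminoglycosides",
        "carbapenems",
        "cephalosporins",
        "glycopeptide antibiotics",
        "glycopeptides",
        "lincosamides",
        "macrolides",
        "miscellaneous",
        "miscellaneous antibiotics",
        "monobactams",
        "oxazolidinones",
        "penicillins",
        "quinolones",
        "rifamycins",
        "sulfonamides",
        "tetracyclines",
    }
)


@dataclass(frozen=True)
class DrugGroupingSpec:
    """Selection and grouping rules for antibacterial exposures.

    Only drugs of antibacterial categories are analyzed; atovaquone (an
    antiparasitic prophylactic) is excluded by name.  Within the miscellaneous
    class, metronidazole and aztreonam are promoted to their own groups and
    the remaining miscellaneous drugs are removed.  Everything else is grouped
    by its drug category, split by administration route.
    """

    antibacterial_categories: frozenset = DEFAULT_ANTIBACTERIAL_CATEGORIES
    excluded_drugs: frozenset = frozenset({"atovaquone"})
    promoted_drugs: frozenset = frozenset({"metronidazole", "aztreonam"})
    residual_categories: frozenset = frozenset({"miscellaneous", "miscellaneous antibiotics"})
    routes: tuple = ("oral", "intravenous")


def assign_groups(drugs: pd.DataFrame, spec: DrugGroupingSpec | None = None) -> pd.DataFrame:
    """Apply the grouping rules; returns retained rows with a ``Group`` column.

    Every retained exposure maps to exactly one (Group, Route).
    """
    spec = spec or DrugGroupingSpec()
    if drugs.empty:
        out = drugs.copy()
        out["Group"] = pd.Series(dtype="string")
        return out
    d = drugs.copy()
    cat = d["Category"].astype("string").str.strip().str.lower()
    factor = d["Factor"].astype("string").str.strip().str.lower()
    route = d["Route"].astype("string").str.strip().str.lower()
    keep = cat.isin(spec.antibacterial_categories)
    keep &= ~factor.isin(spec.excluded_drugs)
    keep &= route.isin(spec.routes)
    residual = cat.isin(spec.residual_categories)
    keep &= ~residual | factor.isin(spec.promoted_drugs)
    out = d[keep.fillna(False)].copy()
    out["Group"] = np.where(
        residual[keep.fillna(False)], factor[keep.fillna(False)], cat[keep.fillna(False)]
    )
    out["Group"] = out["Group"].astype("string")
    out["Route"] = route[keep.fillna(False)].astype("string")
    return out


def drug_frequency(
    drugs: pd.DataFrame,
    hct: pd.DataFrame,
    by: str = "Factor",
    spec: DrugGroupingSpec | None = None,
) -> pd.DataFrame:
    """Fraction of all patients ever exposed to each drug, per route.

    The denominator is the number of distinct patients in the HCT table; a
    patient with several courses of the same drug counts once.  When ``spec``
    is given, only exposures retained by the grouping rules are counted and
    ``by="Group"`` becomes available.
    """
    n_patients = hct["PatientID"].nunique()
    if n_patients == 0:
        raise ValueError("empty patient table")
    d = assign_groups(drugs, spec) if spec is not None else drugs
    if d.empty:
        return pd.DataFrame(columns=[by, "Route", "Category", "n_patients", "fraction"])
    grp = (
        d.groupby([by, "Route"], observed=True)
        .agg(Category=("Category", "first"), n_patients=("PatientID", "nunique"))
        .reset_index()
    )
    grp["fraction"] = grp["n_patients"] / n_patients
    return grp.sort_values("fraction", ascending=False).reset_index(drop=True)


class ExposureMatrix:
    """Binary daily presence u_j(t) of each (drug group, route) per patient.

    Built from closed administration intervals [start, stop]; overlapping
    courses of the same group are OR-ed, never double-counted.  Days are on
    the deidentified ``Timepoint`` axis, the same axis as sample collection.
    """

    def __init__(self, grouped_drugs: pd.DataFrame):
        self.covariates: list[tuple[str, str]] = sorted(
            {
                (str(g), str(r))
                for g, r in zip(grouped_drugs["Group"], grouped_drugs["Route"])
            }
        )
        self._days: dict[tuple[str, str, str], np.ndarray] = {}
        for (pid, grp, route), rows in grouped_drugs.groupby(
            ["PatientID", "Group", "Route"], observed=True
        ):
            days: set[int] = set()
            for start, stop in zip(rows["StartTimepoint"], rows["StopTimepoint"]):
                if pd.isna(start) or pd.isna(stop):
                    continue
                days.update(range(int(start), int(stop) + 1))
            self._days[(str(pid), str(grp), str(route))] = np.array(sorted(days), dtype=int)

    def exposed_days(self, patient_id: str, covariate: tuple[str, str]) -> np.ndarray:
        return self._days.get((str(patient_id), covariate[0], covariate[1]), np.empty(0, dtype=int))

    def count_in_window(self, patient_id: str, covariate: tuple[str, str], start: int, stop: int) -> int:
        """Number of exposed days in the half-open window (start, stop]."""
        days = self.exposed_days(patient_id, covariate)
        return int(np.searchsorted(days, stop, side="right") - np.searchsorted(days, start, side="right"))

    def indicator(self, patient_id: str, covariate: tuple[str, str], days: np.ndarray) -> np.ndarray:
        exposed = self.exposed_days(patient_id, covariate)
        return np.isin(np.asarray(days, dtype=int), exposed).astype(float)


def build_exposure_matrix(
    drugs: pd.DataFrame, grouping: DrugGroupingSpec | None = None
) -> ExposureMatrix:
    """Daily binary exposure matrix from an (optionally pre-grouped) drug table."""
    grouped = drugs if "Group" in drugs.columns else assign_groups(drugs, grouping)
    return ExposureMatrix(grouped)


def make_pairs(samples: pd.DataFrame, qpcr: pd.DataFrame, max_gap_days: int = 3) -> pd.DataFrame:
    """Consecutive same-patient stool-sample pairs usable for the regression.

    "Consecutive" means adjacent in the per-patient day-sorted sample sequence
    (an intermediate sample is never skipped to form a pair).  A pair is
    retained only when the gap is at most ``max_gap_days`` and both endpoints
    have a qPCR measurement.  Multiple samples on the same patient-day keep the
    first by SampleID sort order (logged).
    """
    s = samples.dropna(subset=["SampleID", "PatientID", "Timepoint"]).copy()
    s["Timepoint"] = s["Timepoint"].astype(int)
    s = s.sort_values(["PatientID", "Timepoint", "SampleID"])
    dup = s.duplicated(subset=["PatientID", "Timepoint"])
    if dup.any():
        log.info("make_pairs: dropping %d duplicate same-day samples (kept first by SampleID)", int(dup.sum()))
        s = s[~dup]
    has_qpcr = set(qpcr.dropna(subset=["qPCR16S"])["SampleID"])
    rows = []
    for pid, grp in s.groupby("PatientID", sort=False):
        sid = grp["SampleID"].to_numpy()
        tp = grp["Timepoint"].to_numpy()
        for i in range(len(grp) - 1):
            dt = int(tp[i + 1] - tp[i])
            if 0 < dt <= max_gap_days and sid[i] in has_qpcr and sid[i + 1] in has_qpcr:
                rows.append((pid, sid[i], sid[i + 1], int(tp[i]), int(tp[i + 1]), dt))
    return pd.DataFrame(
        rows, columns=["PatientID", "SampleID_i", "SampleID_f", "t_i", "t_f", "dt"]
    )


def pair_covariates(pair, exposure: ExposureMatrix) -> tuple[int, np.ndarray]:
    """(dt_p, C_p) for one sample pair.

    C_{p,j} counts exposed days in the half-open window (t_i, t_f]: a course
    active only on the day of the initial sample does not contribute, because
    that sample reflects the abundance before the day's subsequent dosing.
    Always 0 <= C_{p,j} <= dt_p.
    """
    dt = int(pair["dt"])
    c = np.array(
        [
            exposure.count_in_window(pair["PatientID"], cov, int(pair["t_i"]), int(pair["t_f"]))
            for cov in exposure.covariates
        ],
        dtype=float,
    )
    return dt, c


def build_design(pairs: pd.DataFrame, exposure: ExposureMatrix) -> np.ndarray:
    """Stacked design matrix [dt_p, C_{p,1} ... C_{p,Ma}] over all pairs."""
    design = np.zeros((len(pairs), 1 + len(exposure.covariates)))
    for r, (_, pair) in enumerate(pairs.iterrows()):
        dt, c = pair_covariates(pair, exposure)
        design[r, 0] = dt
        design[r, 1:] = c
    return design


def select_taxa(counts: pd.DataFrame, pairs: pd.DataFrame, k: int = 20) -> list[str]:
    """The ``k`` most abundant taxa among samples participating in retained pairs.

    Ranked by mean relative abundance over the unique endpoint samples
    (absent taxon = 0); ties break by taxon identifier.
    """
    sample_ids = pd.unique(pd.concat([pairs["SampleID_i"], pairs["SampleID_f"]]))
    rel = composition.relative_abundance(counts[counts["SampleID"].isin(sample_ids)])
    means = rel.data.mean(axis=0)
    ranked = means.sort_index().sort_values(ascending=False, kind="stable")
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} taxa available; requested top {k}", stacklevel=2
        )
    return ranked.index[:k].tolist()


@dataclass
class RegressionProblem:
    """One taxon's stacked linear system Y = D X.

    ``y``: log-ratio of absolute abundance across each retained pair (natural
    log); ``design``: rows [dt_p, C_{p,1..Ma}] aligned with ``y``;
    ``pair_index``: positional indices of the retained pairs.  Pairs where the
    taxon's abundance is zero at either endpoint are discarded before
    construction.
    """

    taxon: str
    y: np.ndarray
    design: np.ndarray
    pair_index: np.ndarray
    covariates: list[tuple[str, str]]

    @property
    def n_pairs(self) -> int:
        return len(self.y)


def assemble_problem(
    taxon: str,
    pairs: pd.DataFrame,
    absolute: "composition.AbundanceTable",
    design: np.ndarray,
    covariates: list[tuple[str, str]],
) -> RegressionProblem:
    """Build the per-taxon regression rows, applying the zero-discard rule."""
    if taxon in absolute.data.columns:
        vals = absolute.data[taxon]
    else:
        vals = pd.Series(0.0, index=absolute.data.index)
    n_i = vals.reindex(pairs["SampleID_i"]).to_numpy(dtype=float)
    n_f = vals.reindex(pairs["SampleID_f"]).to_numpy(dtype=float)
    ok = np.isfinite(n_i) & np.isfinite(n_f) & (n_i > 0) & (n_f > 0)
    if not ok.any():
        raise ValueError(f"taxon {taxon!r} not estimable: no pair has nonzero abundance at both endpoints")
    y = np.log(n_f[ok]) - np.log(n_i[ok])
    return RegressionProblem(
        taxon=taxon,
        y=y,
        design=design[ok],
        pair_index=np.flatnonzero(ok),
        covariates=list(covariates),
    )


@dataclass(frozen=True)
class RidgeConfig:
    """Penalty grid and cross-validation layout for the ridge solve."""

    lambda_grid: tuple = tuple(np.logspace(-4, 4, 25))
    folds: int = 3
    monte_carlo_reps: int = 10
    seed: int = 0
    penalize_intercept: bool = True

    def __post_init__(self):
        if any(l < 0 for l in self.lambda_grid):
            raise ValueError("lambda grid must be non-negative")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")


def _penalty_matrix(p: int, penalize_intercept: bool) -> np.ndarray:
    pen = np.eye(p)
    if not penalize_intercept:
        pen[0, 0] = 0.0
    return pen


def fit_ridge(
    design: np.ndarray,
    y: np.ndarray,
    lam: float,
    penalize_intercept: bool = True,
) -> np.ndarray:
    """Closed-form ridge solution argmin ||y - D x||^2 + lam ||x||^2.

    The penalty includes the growth-rate intercept by default (the objective
    penalizes the full coefficient vector); ``penalize_intercept=False``
    exempts the first column.  At ``lam=0`` with a rank-deficient design the
    minimum-norm least-squares solution is returned with a warning.
    """
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    p = design.shape[1]
    if lam == 0:
        if np.linalg.matrix_rank(design) < p:
            warnings.warn("rank-deficient design at lambda=0: returning minimum-norm solution", stacklevel=2)
        return np.linalg.lstsq(design, y, rcond=None)[0]
    pen = _penalty_matrix(p, penalize_intercept)
    return np.linalg.solve(design.T @ design + lam * pen, design.T @ y)


def select_lambda(
    problem: RegressionProblem, config: RidgeConfig
) -> tuple[float, pd.DataFrame, np.ndarray]:
    """Cross-validated penalty choice and final refit.

    For every lambda in the grid, the held-out sum of squared errors is
    accumulated over ``folds`` folds of ``monte_carlo_reps`` independent random
    row partitions; the minimizing lambda is then applied to the entire
    dataset.  Deterministic under a fixed config seed.
    """
    n = problem.n_pairs
    if n < config.folds:
        raise ValueError(f"{n} rows < {config.folds} folds: cannot cross-validate")
    grid = np.asarray(sorted(config.lambda_grid), dtype=float)
    rng = np.random.default_rng(config.seed)
    sse = np.zeros(len(grid))
    for _ in range(config.monte_carlo_reps):
        perm = rng.permutation(n)
        for fold in np.array_split(perm, config.folds):
            train = np.setdiff1d(perm, fold, assume_unique=True)
            d_tr, y_tr = problem.design[train], problem.y[train]
            d_te, y_te = problem.design[fold], problem.y[fold]
            gram = d_tr.T @ d_tr
            rhs = d_tr.T @ y_tr
            pen = _penalty_matrix(d_tr.shape[1], config.penalize_intercept)
            for i, lam in enumerate(grid):
                if lam == 0:
                    coef = np.linalg.lstsq(d_tr, y_tr, rcond=None)[0]
                else:
                    coef = np.linalg.solve(gram + lam * pen, rhs)
                resid = y_te - d_te @ coef
                sse[i] += float(resid @ resid)
    best = int(np.argmin(sse))
    curve = pd.DataFrame({"lambda": grid, "cv_sse": sse})
    lam_star = float(grid[best])
    coef = fit_ridge(problem.design, problem.y, lam_star, config.penalize_intercept)
    return lam_star, curve, coef


@dataclass
class SusceptibilityEstimate:
    """Estimated growth rates and antibiotic susceptibilities.

    ``params``: DataFrame indexed by taxon; first column ``growth_rate`` (g_k,
    1/day), remaining columns one per (group, route) covariate (eps_{k,j},
    1/day).  ``chosen_lambda`` and ``n_pairs`` are per-taxon diagnostics;
    ``n_patients`` counts distinct patients contributing retained pairs.
    """

    params: pd.DataFrame
    covariates: list[tuple[str, str]]
    chosen_lambda: pd.Series
    n_pairs: pd.Series
    n_patients: int
    cv_curves: dict = field(default_factory=dict)
    dropped_taxa: dict = field(default_factory=dict)
    convention: str = "exposure days counted in (t_i, t_f]"

    def route_view(self, route: str) -> pd.DataFrame:
        cols = [c for c in self.params.columns if c.endswith(f"[{route}]")]
        return self.params[cols]

    def to_long(self) -> pd.DataFrame:
        rows = []
        for taxon, row in self.params.iterrows():
            for (grp, route) in self.covariates:
                col = f"{grp} [{route}]"
                if col in row:
                    rows.append(
                        {
                            "taxon": taxon,
                            "drug_group": grp,
                            "route": route,
                            "coefficient": row[col],
                            "growth_rate": row["growth_rate"],
                            "lambda": self.chosen_lambda.get(taxon, np.nan),
                            "n_pairs": self.n_pairs.get(taxon, 0),
                        }
                    )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Antibiotic impact inference (log-linear growth model, ridge + 3-fold CV)",
            f"  taxa fitted: {len(self.params)}   covariates: {len(self.covariates)}"
            f"   patients contributing pairs: {self.n_patients}",
            f"  exposure convention: {self.convention}",
            "",
            self.params.round(4).to_string(),
        ]
        return "\n".join(lines)


def infer_susceptibilities(
    cohort: Cohort,
    grouping: DrugGroupingSpec | None = None,
    ridge_config: RidgeConfig | None = None,
    k: int = 20,
    max_gap_days: int = 3,
    taxa: list[str] | None = None,
) -> SusceptibilityEstimate:
    """End-to-end antibiotic-impact inference on a cohort.

    Chain: drug grouping -> daily exposure matrix -> consecutive sample pairs
    (gap <= 3 days, qPCR at both endpoints) -> absolute abundances -> top-k
    taxa -> per-taxon cross-validated ridge regression.  When the penalty grid
    has a single value, the cross-validation is skipped and that penalty is
    applied directly.
    """
    grouping = grouping or DrugGroupingSpec()
    ridge_config = ridge_config or RidgeConfig()
    grouped = assign_groups(cohort.drugs, grouping)
    exposure = ExposureMatrix(grouped)
    pairs = make_pairs(cohort.samples, cohort.qpcr, max_gap_days)
    if pairs.empty:
        raise ValueError("no usable sample pairs (gap filter + qPCR requirement left nothing)")
    design = build_design(pairs, exposure)
    sample_ids = pd.unique(pd.concat([pairs["SampleID_i"], pairs["SampleID_f"]]))
    counts = cohort.counts[cohort.counts["SampleID"].isin(sample_ids)]
    rel = composition.relative_abundance(counts)
    absolute = composition.absolute_abundance(rel, cohort.qpcr)
    if taxa is None:
        taxa = select_taxa(cohort.counts, pairs, k=k)
    columns = ["growth_rate"] + [f"{g} [{r}]" for g, r in exposure.covariates]
    params, lam_chosen, n_pairs_used, curves, dropped = {}, {}, {}, {}, {}
    single_lambda = len(set(ridge_config.lambda_grid)) == 1
    for i, taxon in enumerate(taxa):
        try:
            problem = assemble_problem(taxon, pairs, absolute, design, exposure.covariates)
        except ValueError as err:
            dropped[taxon] = str(err)
            continue
        cfg = replace(ridge_config, seed=int(ridge_config.seed) + i)
        if single_lambda or problem.n_pairs < cfg.folds:
            if not single_lambda:
                dropped[taxon] = f"only {problem.n_pairs} rows: fitted at smallest grid lambda without CV"
            lam = float(min(ridge_config.lambda_grid))
            coef = fit_ridge(problem.design, problem.y, lam, cfg.penalize_intercept)
        else:
            lam, curve, coef = select_lambda(problem, cfg)
            curves[taxon] = curve
        params[taxon] = coef
        lam_chosen[taxon] = lam
        n_pairs_used[taxon] = problem.n_pairs
    if not params:
        raise ValueError("no taxon was estimable")
    frame = pd.DataFrame.from_dict(params, orient="index")
    frame.columns = columns
    return SusceptibilityEstimate(
        params=frame,
        covariates=exposure.covariates,
        chosen_lambda=pd.Series(lam_chosen, dtype=float),
        n_pairs=pd.Series(n_pairs_used, dtype=int),
        n_patients=int(pairs["PatientID"].nunique()),
        cv_curves=curves,
        dropped_taxa=dropped,
    )


class AntibioticImpactModel:
    """Model object for the antibiotic-impact analysis of a cohort.

    Parameters mirror :func:`infer_susceptibilities`; ``fit()`` returns an
    :class:`AntibioticImpactResults` carrying the coefficient table,
    per-taxon penalties and diagnostics.
    """

    def __init__(
        self,
        cohort: Cohort,
        grouping: DrugGroupingSpec | None = None,
        ridge_config: RidgeConfig | None = None,
        top_k: int = 20,
        max_gap_days: int = 3,
    ):
        self.cohort = cohort
        self.grouping = grouping or DrugGroupingSpec()
        self.ridge_config = ridge_config or RidgeConfig()
        self.top_k = top_k
        self.max_gap_days = max_gap_days

    def fit(self, taxa: list[str] | None = None) -> "AntibioticImpactResults":
        est = infer_susceptibilities(
            self.cohort,
            grouping=self.grouping,
            ridge_config=self.ridge_config,
            k=self.top_k,
            max_gap_days=self.max_gap_days,
            taxa=taxa,
        )
        return AntibioticImpactResults(self, est)


class AntibioticImpactResults:
    """Fitted susceptibilities with statsmodels-style accessors."""

    def __init__(self, model: AntibioticImpactModel, estimate: SusceptibilityEstimate):
        self.model = model
        self.estimate = estimate

    @property
    def params(self) -> pd.DataFrame:
        return self.estimate.params

    @property
    def growth_rates(self) -> pd.Series:
        return self.estimate.params["growth_rate"]

    @property
    def n_patients(self) -> int:
        return self.estimate.n_patients

    def susceptibilities(self, route: str | None = None) -> pd.DataFrame:
        if route is None:
            return self.estimate.params.drop(columns=["growth_rate"])
        return self.estimate.route_view(route)

    def summary(self) -> str:
        return self.estimate.summary()

    def to_csv(self, path) -> None:
        self.estimate.to_long().to_csv(path, index=False)
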