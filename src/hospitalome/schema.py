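"""Table schemas and I/O for the hospitalome CSV deposit.

The deposit is a set of comma-separated tables sharing two keys — ``PatientID``
and ``SampleID`` — on a deidentified integer day axis: every ``Timepoint`` is an
offset from a secret per-patient reference date, so only day differences are
meaningful and no calendar date appears anywhere.  ``DayRelativeToNearestHCT``
columns re-express the same days relative to the nearest hematopoietic cell
transplant (HCT) of the patient.

This module defines the expected columns and dtypes of each table, a
:class:`Cohort` container holding them as pandas DataFrames, and the
load / validate / write operations with a round-trip guarantee.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SchemaError",
    "NoHctError",
    "Violation",
    "ValidationReport",
    "Cohort",
    "TABLE_FILES",
    "TABLE_COLUMNS",
    "WIDE_LEVELS",
    "day_relative_to_nearest_hct",
    "load_cohort",
    "validate_cohort",
    "write_cohort",
    "empty_table",
]


class SchemaError(ValueError):
    """A table violates the deposit schema (missing column, bad cell, invariant)."""


class NoHctError(ValueError):
    """Raised when a day-relative-to-HCT is requested for a patient with no HCT."""


#: canonical file name of each table inside a deposit directory
TABLE_FILES: dict[str, str] = {
    "samples": "tblASVsamples.csv",
    "counts": "tblcounts_asv_melt.csv",
    "qpcr": "tblqpcr.csv",
    "hct": "tblhctmeta.csv",
    "drugs": "tbldrug.csv",
    "infections": "tblInfectionsCidPapers.csv",
    "temperature": "tbltemperature.csv",
    "blood_counts": "tblbc.csv",
    "vana": "tblVanA.csv",
    "taxonomy": "tblASVtaxonomy_silva_v4v5_filter.csv",
}

#: taxonomic levels for which a wide counts table may exist
WIDE_LEVELS = ("asv", "genus", "family", "order", "class", "phylum")

TAXONOMY_RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus")

# dtype codes: "str", "int" (nullable Int64), "float", "bool" (nullable boolean)
TABLE_COLUMNS: dict[str, dict[str, str]] = {
    "samples": {
        "SampleID": "str",
        "PatientID": "str",
        "Timepoint": "int",
        "Consistency": "str",
        "Accession": "str",
        "BioProject": "str",
        "DayRelativeToNearestHCT": "int",
    },
    "counts": {"SampleID": "str", "ASV": "str", "Count": "int"},
    "qpcr": {"SampleID": "str", "qPCR16S": "float"},
    "hct": {
        "PatientID": "str",
        "TimepointOfTransplant": "int",
        "HCTSource": "str",
        "Disease": "str",
    },
    "drugs": {
        "PatientID": "str",
        "StartTimepoint": "int",
        "StopTimepoint": "int",
        "Factor": "str",
        "Category": "str",
        "AntiInfective": "bool",
        "Route": "str",
        "StartDayRelativeToNearestHCT": "int",
        "StopDayRelativeToNearestHCT": "int",
    },
    "infections": {
        "PatientID": "str",
        "Timepoint": "int",
        "InfectiousAgent": "str",
        "DayRelativeToNearestHCT": "int",
    },
    "temperature": {
        "PatientID": "str",
        "Timepoint": "int",
        "MaxTemperature": "float",
        "DayRelativeToNearestHCT": "int",
    },
    "blood_counts": {
        "PatientID": "str",
        "Day": "int",
        "BloodCellType": "str",
        "Value": "float",
        "Unit": "str",
        "DayRelativeToNearestHCT": "int",
    },
    "vana": {"SampleID": "str", "VanA": "bool"},
    "taxonomy": {
        "ASV": "str",
        "Sequence": "str",
        **{rank: "str" for rank in TAXONOMY_RANKS},
        **{f"Confidence{rank}": "float" for rank in TAXONOMY_RANKS},
        "HexColor": "str",
        "ColorOrder": "int",
    },
}

#: columns that may legitimately be empty (mapped to pandas NA, never 0)
NULLABLE_COLUMNS: dict[str, set[str]] = {
    "samples": {"Consistency", "Accession", "BioProject", "DayRelativeToNearestHCT"},
    "drugs": {"StartDayRelativeToNearestHCT", "StopDayRelativeToNearestHCT"},
    "taxonomy": set(TAXONOMY_RANKS) | {f"Confidence{r}" for r in TAXONOMY_RANKS},
    "temperature": {"DayRelativeToNearestHCT"},
    "blood_counts": {"DayRelativeToNearestHCT"},
    "infections": {"DayRelativeToNearestHCT"},
}

BSI_GENERA = frozenset(
    {
        "Enterococcus",
        "Escherichia",
        "Klebsiella",
        "Enterobacter",
        "Pseudomonas",
        "Stenotrophomonas",
        "Citrobacter",
    }
)

_HEX_COLOR_RE = re.compile(r"^#?[0-9A-Fa-f]{6}$")
_DTYPE_MAP = {"str": "string", "int": "Int64", "float": "Float64", "bool": "boolean"}
_BOOL_STRINGS = {
    "true": True,
    "false": False,
    "1": True,
    "0": False,
    "yes": True,
    "no": False,
}


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def empty_table(name: str) -> pd.DataFrame:
    """Return an empty, correctly typed DataFrame for a named table."""
    spec = TABLE_COLUMNS[name]
    return pd.DataFrame({c: pd.Series(dtype=_DTYPE_MAP[t]) for c, t in spec.items()})


def day_relative_to_nearest_hct(timepoint: int, hct_days: Iterable[int]) -> int:
    """Day of an event relative to the patient's nearest HCT day.

    Ties between two equidistant HCTs are broken toward the *earlier* HCT,
    which is deterministic and reproducible.

    Raises
    ------
    NoHctError
        If ``hct_days`` is empty (the patient has no recorded transplant).
    """
    hct_days = sorted(int(h) for h in hct_days)
    if not hct_days:
        raise NoHctError("patient has no HCT: cannot compute day relative to nearest HCT")
    # sorted + strict '<' keeps the earlier HCT on ties
    nearest = min(hct_days, key=lambda h: abs(int(timepoint) - h))
    return int(timepoint) - nearest


@dataclass
class Violation:
    table: str
    rule: str
    message: str
    n_rows: int = 1
    examples: list = field(default_factory=list)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        ex = f" e.g. {self.examples[:3]}" if self.examples else ""
        return f"[{self.table}] {self.rule}: {self.message} ({self.n_rows} rows){ex}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, table: str, rule: str, message: str, rows=None) -> None:
        rows = list(rows) if rows is not None else []
        self.violations.append(
            Violation(table, rule, message, n_rows=max(1, len(rows)), examples=rows[:5])
        )

    def summary(self) -> str:
        if self.ok:
            out = "cohort validation: OK, no violations"
        else:
            out = "\n".join(str(v) for v in self.violations)
        if self.flags:
            out += "\nflags:\n" + "\n".join(f"  - {f}" for f in self.flags)
        return out


@dataclass
class Cohort:
    """Container for the validated hospitalome tables.

    All tables are pandas DataFrames typed per :data:`TABLE_COLUMNS`; absent
    tables are present as empty frames so downstream code never branches on
    ``None``.  ``counts_wide`` holds any wide-format taxa-by-sample counts
    tables keyed by taxonomic level.
    """

    samples: pd.DataFrame = field(default_factory=lambda: empty_table("samples"))
    counts: pd.DataFrame = field(default_factory=lambda: empty_table("counts"))
    qpcr: pd.DataFrame = field(default_factory=lambda: empty_table("qpcr"))
    hct: pd.DataFrame = field(default_factory=lambda: empty_table("hct"))
    drugs: pd.DataFrame = field(default_factory=lambda: empty_table("drugs"))
    infections: pd.DataFrame = field(default_factory=lambda: empty_table("infections"))
    temperature: pd.DataFrame = field(default_factory=lambda: empty_table("temperature"))
    blood_counts: pd.DataFrame = field(default_factory=lambda: empty_table("blood_counts"))
    vana: pd.DataFrame = field(default_factory=lambda: empty_table("vana"))
    taxonomy: pd.DataFrame = field(default_factory=lambda: empty_table("taxonomy"))
    counts_wide: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    validation: ValidationReport | None = None

    TABLE_NAMES = tuple(TABLE_FILES)

    def table(self, name: str) -> pd.DataFrame:
        if name not in TABLE_FILES:
            raise KeyError(f"unknown table {name!r}")
        return getattr(self, name)

    @property
    def patients(self) -> pd.Index:
        """Distinct patient identifiers appearing in the sample table."""
        return pd.Index(self.samples["PatientID"].dropna().unique())

    def hct_days(self, patient_id: str) -> list[int]:
        rows = self.hct.loc[self.hct["PatientID"] == patient_id, "TimepointOfTransplant"]
        return sorted(int(v) for v in rows.dropna())

    def equals(self, other: "Cohort") -> bool:
        for name in self.TABLE_NAMES:
            a = self.table(name).reset_index(drop=True)
            b = other.table(name).reset_index(drop=True)
            if not a.equals(b):
                return False
        if set(self.counts_wide) != set(other.counts_wide):
            return False
        return all(
            self.counts_wide[k].reset_index(drop=True).equals(
                other.counts_wide[k].reset_index(drop=True)
            )
            for k in self.counts_wide
        )


def _coerce_table(name: str, raw: pd.DataFrame, strict: bool) -> tuple[pd.DataFrame, list[Violation]]:
    spec = TABLE_COLUMNS[name]
    problems: list[Violation] = []
    missing = [c for c in spec if c not in raw.columns]
    if missing:
        raise SchemaError(f"table {name!r}: missing mandatory column(s) {missing}")
    out = {}
    for col, kind in spec.items():
        s = raw[col]
        if kind == "str":
            out[col] = s.astype("string")
            continue
        if kind == "bool":
            lowered = s.astype("string").str.strip().str.lower()
            mapped = lowered.map(_BOOL_STRINGS)
            bad = lowered.notna() & mapped.isna()
            if bad.any():
                msg = f"unparseable boolean in {name}.{col}"
                if strict:
                    raise SchemaError(f"{msg} at rows {list(raw.index[bad][:5])}")
                problems.append(Violation(name, "parse", msg, int(bad.sum()), list(raw.index[bad][:5])))
            out[col] = mapped.astype("boolean")
            continue
        stripped = s.astype("string").str.strip()
        nonempty = stripped.notna() & (stripped != "")
        # float() round-trips the shortest decimal repr exactly; pandas' fast
        # CSV float parser does not, which would break the round-trip guarantee
        numeric = pd.Series(
            [float(v) if ok and _is_number(v) else None for v, ok in zip(stripped, nonempty)],
            index=s.index,
            dtype="Float64",
        )
        bad = nonempty & numeric.isna()
        if bad.any():
            msg = f"unparseable {kind} in {name}.{col}"
            if strict:
                raise SchemaError(f"{msg} at rows {list(raw.index[bad][:5])}")
            problems.append(Violation(name, "parse", msg, int(bad.sum()), list(raw.index[bad][:5])))
        if kind == "int":
            frac = numeric.notna() & (numeric != numeric.round())
            if frac.any():
                msg = f"non-integer day/count in {name}.{col}"
                if strict:
                    raise SchemaError(f"{msg} at rows {list(raw.index[frac][:5])}")
                problems.append(Violation(name, "parse", msg, int(frac.sum()), list(raw.index[frac][:5])))
                numeric = numeric.where(~frac)
            out[col] = numeric.round().astype("Int64")
        else:
            out[col] = numeric.astype("Float64")
    frame = pd.DataFrame(out)
    # keep any extra deposited columns (e.g. wbcPatientId) as opaque strings
    for col in raw.columns:
        if col not in spec:
            frame[col] = raw[col].astype("string")
    return frame, problems


def load_cohort(directory: str | Path, strict: bool = True) -> Cohort:
    """Load a deposit directory into a typed :class:`Cohort`.

    Any of the canonical CSV files may be absent; present files must carry the
    documented header.  In strict mode the first invariant violation raises
    :class:`SchemaError`; in lenient mode all violations are collected into the
    cohort's validation report.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(directory)
    cohort = Cohort()
    parse_problems: list[Violation] = []
    loaded = []
    for name, fname in TABLE_FILES.items():
        path = directory / fname
        if not path.exists():
            continue
        raw = pd.read_csv(path, dtype="string", keep_default_na=True)
        frame, problems = _coerce_table(name, raw, strict)
        setattr(cohort, name, frame)
        parse_problems.extend(problems)
        loaded.append(fname)
    for level in WIDE_LEVELS:
        path = directory / f"tblcounts_{level}_wide.csv"
        if path.exists():
            wide = pd.read_csv(path)
            wide = wide.rename(columns={wide.columns[0]: "SampleID"})
            wide["SampleID"] = wide["SampleID"].astype("string")
            cohort.counts_wide[level] = wide
            loaded.append(path.name)
    cohort.provenance = {
        "source": str(directory),
        "loaded_files": loaded,
        "loaded_at": datetime.datetime.now().isoformat(timespec="seconds"),
        "confidence_scale": _detect_confidence_scale(cohort.taxonomy),
    }
    report = validate_cohort(cohort)
    report.violations = parse_problems + report.violations
    cohort.validation = report
    if strict and not report.ok:
        raise SchemaError("cohort failed validation:\n" + report.summary())
    return cohort


def _detect_confidence_scale(taxonomy: pd.DataFrame) -> str | None:
    cols = [c for c in taxonomy.columns if c.startswith("Confidence")]
    if taxonomy.empty or not cols:
        return None
    vals = pd.concat([taxonomy[c] for c in cols]).dropna().astype(float)
    if vals.empty:
        return None
    return "percent" if vals.max() > 1.0 else "fraction"


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Check every table invariant and cross-table key; report, never raise."""
    rep = ValidationReport()
    s, c, q, t = cohort.samples, cohort.counts, cohort.qpcr, cohort.taxonomy

    dup = s["SampleID"][s["SampleID"].duplicated()]
    if len(dup):
        rep.add("samples", "unique-sample-id", "duplicate SampleID", dup.tolist())
    if len(c):
        neg = (c["Count"] < 0).fillna(False)
        if neg.any():
            rep.add("counts", "non-negative", "negative read count", c.loc[neg, "SampleID"].tolist())
        dupc = c.duplicated(subset=["SampleID", "ASV"])
        if dupc.any():
            rep.add("counts", "unique-key", "duplicate (SampleID, ASV)", c.loc[dupc, "SampleID"].tolist())
        if len(s):
            orphans = set(c["SampleID"].dropna()) - set(s["SampleID"].dropna())
            if orphans:
                rep.add("counts", "orphan-sample", "count rows whose SampleID is absent from samples", sorted(orphans))
        if len(t):
            unknown = set(c["ASV"].dropna()) - set(t["ASV"].dropna())
            if unknown:
                rep.add("counts", "unknown-asv", "ASVs absent from taxonomy", sorted(unknown))
    if len(q):
        nonpos = (q["qPCR16S"] <= 0).fillna(False)
        if nonpos.any():
            rep.add("qpcr", "positive", "qPCR16S must be > 0", q.loc[nonpos, "SampleID"].tolist())
        dupq = q["SampleID"][q["SampleID"].duplicated()]
        if len(dupq):
            rep.add("qpcr", "unique-sample-id", "duplicate SampleID", dupq.tolist())
        if len(s):
            orphans = set(q["SampleID"].dropna()) - set(s["SampleID"].dropna())
            if orphans:
                rep.add("qpcr", "orphan-sample", "qPCR rows whose SampleID is absent from samples", sorted(orphans))
    if len(cohort.vana) and len(s):
        orphans = set(cohort.vana["SampleID"].dropna()) - set(s["SampleID"].dropna())
        if orphans:
            rep.add("vana", "orphan-sample", "vanA rows whose SampleID is absent from samples", sorted(orphans))
    d = cohort.drugs
    if len(d):
        bad = (d["StopTimepoint"] < d["StartTimepoint"]).fillna(False)
        if bad.any():
            rep.add("drugs", "closed-interval", "StopTimepoint < StartTimepoint", d.index[bad].tolist())
    h = cohort.hct
    if len(h):
        per = h.groupby("PatientID").size()
        toomany = per[per > 3]
        if len(toomany):
            rep.add("hct", "max-3-hct", "patients with more than 3 HCT rows", toomany.index.tolist())
    inf = cohort.infections
    if len(inf):
        bad = ~inf["InfectiousAgent"].isin(list(BSI_GENERA))
        if bad.any():
            rep.add("infections", "known-genus", "InfectiousAgent outside the analyzed genera", inf.loc[bad, "InfectiousAgent"].unique().tolist())
    tt = cohort.temperature
    if len(tt):
        v = tt["MaxTemperature"].dropna().astype(float)
        bad = (v < 90) | (v > 110)
        if bad.any():
            rep.add("temperature", "plausible-range", "MaxTemperature outside [90, 110] degF", v.index[bad].tolist())
    b = cohort.blood_counts
    if len(b):
        if (b["Value"].dropna() < 0).any():
            rep.add("blood_counts", "non-negative", "negative blood cell value")
        bad = b["Unit"].notna() & ~b["Unit"].isin(["K_per_uL", "M_per_uL", "K_per_μL", "M_per_μL"])
        if bad.any():
            rep.add("blood_counts", "unit", "unknown Unit", b.loc[bad, "Unit"].unique().tolist())
    if len(t):
        dupt = t["ASV"][t["ASV"].duplicated()]
        if len(dupt):
            rep.add("taxonomy", "unique-asv", "duplicate ASV", dupt.tolist())
        hexcol = t["HexColor"].dropna()
        bad = ~hexcol.map(lambda x: bool(_HEX_COLOR_RE.match(str(x))))
        if bad.any():
            rep.add("taxonomy", "hex-color", "malformed HexColor", hexcol[bad].tolist())
    # recompute DayRelativeToNearestHCT where both sides are present
    if len(s) and len(h):
        hct_map = h.dropna(subset=["TimepointOfTransplant"]).groupby("PatientID")["TimepointOfTransplant"].apply(list)
        sub = s.dropna(subset=["Timepoint", "DayRelativeToNearestHCT"])
        sub = sub[sub["PatientID"].isin(hct_map.index)]
        if len(sub):
            expected = [
                day_relative_to_nearest_hct(tp, hct_map[pid])
                for pid, tp in zip(sub["PatientID"], sub["Timepoint"])
            ]
            mismatch = sub["DayRelativeToNearestHCT"].astype(int).to_numpy() != expected
            if mismatch.any():
                rep.add(
                    "samples",
                    "day-relative-consistency",
                    "DayRelativeToNearestHCT disagrees with recomputation from the HCT table",
                    sub.loc[mismatch, "SampleID"].tolist(),
                )
        multi = hct_map[hct_map.map(len) > 1]
        for pid, days in multi.items():
            days = sorted(days)
            mids = {(a + b) for a, b in zip(days, days[1:]) if (a + b) % 2 == 0}
            if mids:
                rep.flags.append(
                    f"patient {pid}: equidistant-HCT ties possible; broken toward the earlier HCT"
                )
    return rep


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write a cohort to a deposit directory (RFC-4180 CSV, UTF-8, header row).

    Empty cells encode nulls; ``load_cohort`` on the result reproduces the
    cohort field-for-field.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, fname in TABLE_FILES.items():
        frame = cohort.table(name)
        frame.to_csv(directory / fname, index=False, na_rep="")
    for level, wide in cohort.counts_wide.items():
        wide.to_csv(directory / f"tblcounts_{level}_wide.csv", index=False, na_rep="")
    return directory
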