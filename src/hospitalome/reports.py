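"""Descriptive figures: patient timeline, embedding map, drug frequencies.

All renders are deterministic given identical inputs (and embedding seed) and
never mutate the cohort.  Figures are written to SVG or PNG via matplotlib's
non-interactive backend.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import composition
from .schema import Cohort

__all__ = [
    "TimelineSpec",
    "filter_patient_window",
    "fever_days",
    "neutropenic_days",
    "render_timeline",
    "render_embedding_map",
    "render_drug_frequency",
]

FEVER_THRESHOLD_F = 100.4  # = 38.0 degC, the febrile-neutropenia convention
NEUTROPENIA_CELLS_PER_UL = 500.0

_UNIT_TO_CELLS_PER_UL = {
    "K_per_uL": 1e3,
    "K_per_μL": 1e3,
    "M_per_uL": 1e6,
    "M_per_μL": 1e6,
}


@dataclass
class TimelineSpec:
    """Layout of the four-panel patient timeline."""

    patient_id: str
    window: tuple[int, int] = (-5, 21)
    fever_threshold_f: float = FEVER_THRESHOLD_F
    neutropenia_cells_per_ul: float = NEUTROPENIA_CELLS_PER_UL
    min_abundance_legend: float = 0.01  # taxa below this mean fraction pool into "other"

    def __post_init__(self):
        if self.window[0] > self.window[1]:
            raise ValueError("window start must not exceed end")
        if self.fever_threshold_f <= 0 or self.neutropenia_cells_per_ul <= 0:
            raise ValueError("thresholds must be positive")


def filter_patient_window(cohort: Cohort, patient_id: str, window: tuple[int, int]) -> Cohort:
    """Restrict every table to one patient and an inclusive day window.

    Days are relative to the nearest HCT; drug courses overlapping the window
    are retained.  Raises ``KeyError`` for an unknown patient.
    """
    lo, hi = window
    known = set(cohort.samples["PatientID"].dropna()) | set(cohort.hct["PatientID"].dropna())
    if patient_id not in known:
        raise KeyError(f"unknown patient {patient_id!r}")
    out = Cohort()

    def _day_slice(frame, day_col):
        sub = frame[frame["PatientID"] == patient_id]
        days = sub[day_col]
        return sub[(days >= lo) & (days <= hi) & days.notna()]

    out.samples = _day_slice(cohort.samples, "DayRelativeToNearestHCT").copy()
    keep_sids = set(out.samples["SampleID"])
    out.counts = cohort.counts[cohort.counts["SampleID"].isin(keep_sids)].copy()
    out.qpcr = cohort.qpcr[cohort.qpcr["SampleID"].isin(keep_sids)].copy()
    out.vana = cohort.vana[cohort.vana["SampleID"].isin(keep_sids)].copy()
    out.hct = cohort.hct[cohort.hct["PatientID"] == patient_id].copy()
    d = cohort.drugs[cohort.drugs["PatientID"] == patient_id]
    overlap = (d["StartDayRelativeToNearestHCT"] <= hi) & (d["StopDayRelativeToNearestHCT"] >= lo)
    out.drugs = d[overlap.fillna(False)].copy()
    out.infections = _day_slice(cohort.infections, "DayRelativeToNearestHCT").copy()
    out.temperature = _day_slice(cohort.temperature, "DayRelativeToNearestHCT").copy()
    out.blood_counts = _day_slice(cohort.blood_counts, "DayRelativeToNearestHCT").copy()
    out.taxonomy = cohort.taxonomy.copy()
    out.provenance = {
        "parent": cohort.provenance,
        "filter": {"patient_id": patient_id, "window": [lo, hi]},
    }
    return out


def fever_days(temperature: pd.DataFrame, threshold_f: float = FEVER_THRESHOLD_F) -> list[int]:
    """Days (relative to HCT) whose maximum temperature strictly exceeds the threshold."""
    t = temperature.dropna(subset=["MaxTemperature", "DayRelativeToNearestHCT"])
    hit = t[t["MaxTemperature"].astype(float) > threshold_f]
    return sorted(int(d) for d in hit["DayRelativeToNearestHCT"].unique())


def neutropenic_days(
    blood_counts: pd.DataFrame, threshold_cells_per_ul: float = NEUTROPENIA_CELLS_PER_UL
) -> list[int]:
    """Days with an absolute neutrophil count strictly below the threshold (cells/uL)."""
    b = blood_counts[blood_counts["BloodCellType"] == "Neutrophils"].dropna(
        subset=["Value", "Unit", "DayRelativeToNearestHCT"]
    )
    scale = b["Unit"].map(_UNIT_TO_CELLS_PER_UL)
    cells = b["Value"].astype(float) * scale.astype(float)
    hit = b[(cells < threshold_cells_per_ul).to_numpy()]
    return sorted(int(d) for d in hit["DayRelativeToNearestHCT"].unique())


def render_timeline(cohort_slice: Cohort, spec: TimelineSpec, path) -> "plt.Figure":
    """Four aligned panels: temperature, anti-infectives, neutrophils, composition."""
    lo, hi = spec.window
    fig, axes = plt.subplots(4, 1, figsize=(10, 9), sharex=True,
                             gridspec_kw={"height_ratios": [1, 1.2, 1, 1.6]})
    ax_t, ax_d, ax_n, ax_c = axes

    temp = cohort_slice.temperature.dropna(subset=["MaxTemperature", "DayRelativeToNearestHCT"])
    if len(temp):
        days = temp["DayRelativeToNearestHCT"].astype(int)
        vals = temp["MaxTemperature"].astype(float)
        febrile = vals > spec.fever_threshold_f
        ax_t.plot(days, vals, "k.", ms=4)
        ax_t.plot(days[febrile], vals[febrile], "r.", ms=7)
        ax_t.axhline(spec.fever_threshold_f, color="r", lw=0.5, ls="--")
    else:
        ax_t.text(0.5, 0.5, "no temperature data", transform=ax_t.transAxes, ha="center")
    ax_t.set_ylabel("max temp (F)")

    drugs = cohort_slice.drugs[cohort_slice.drugs["AntiInfective"].fillna(False)]
    if len(drugs):
        labels = (drugs["Factor"].astype(str) + " (" + drugs["Route"].astype(str) + ")")
        for y, (label, sub) in enumerate(drugs.assign(label=labels).groupby("label")):
            for _, row in sub.iterrows():
                ax_d.plot(
                    [row["StartDayRelativeToNearestHCT"], row["StopDayRelativeToNearestHCT"]],
                    [y, y], lw=5, solid_capstyle="butt",
                )
            ax_d.text(lo - 0.3, y, label, ha="right", va="center", fontsize=7)
        ax_d.set_ylim(-1, y + 1)
    else:
        ax_d.text(0.5, 0.5, "no anti-infectives", transform=ax_d.transAxes, ha="center")
    ax_d.set_yticks([])
    ax_d.set_ylabel("anti-infectives")

    blood = cohort_slice.blood_counts
    neut = blood[blood["BloodCellType"] == "Neutrophils"].dropna(subset=["Value", "DayRelativeToNearestHCT"])
    if len(neut):
        days = neut["DayRelativeToNearestHCT"].astype(int)
        cells = neut["Value"].astype(float) * neut["Unit"].map(_UNIT_TO_CELLS_PER_UL).astype(float)
        low = cells < spec.neutropenia_cells_per_ul
        ax_n.semilogy(days, cells.clip(lower=1), "k.", ms=4)
        ax_n.semilogy(days[low], cells[low].clip(lower=1), "r.", ms=7)
        ax_n.axhline(spec.neutropenia_cells_per_ul, color="r", lw=0.5, ls="--")
    else:
        ax_n.text(0.5, 0.5, "no blood counts", transform=ax_n.transAxes, ha="center")
    ax_n.set_ylabel("neutrophils (/uL)")

    rel = composition.relative_abundance(cohort_slice.counts)
    meta = cohort_slice.samples.set_index("SampleID")
    if len(rel.data):
        order_color = {}
        if len(cohort_slice.taxonomy):
            tx = cohort_slice.taxonomy.set_index("ASV")
            order_color = {
                asv: (int(tx.loc[asv, "ColorOrder"]) if pd.notna(tx.loc[asv, "ColorOrder"]) else 0,
                      str(tx.loc[asv, "HexColor"]))
                for asv in rel.data.columns if asv in tx.index
            }
        cols = sorted(rel.data.columns, key=lambda a: order_color.get(a, (0, ""))[0])
        days = meta.loc[rel.data.index, "DayRelativeToNearestHCT"].astype(int)
        bottom = np.zeros(len(rel.data))
        for asv in cols:
            h = rel.data[asv].to_numpy()
            color = order_color.get(asv, (0, None))[1]
            if color and not str(color).startswith("#"):
                color = "#" + str(color)
            ax_c.bar(days, h, bottom=bottom, width=0.8, color=color)
            bottom += h
        ax_c.set_ylim(0, 1)
    else:
        ax_c.text(0.5, 0.5, "no samples in window", transform=ax_c.transAxes, ha="center")
    ax_c.set_ylabel("relative abundance")
    ax_c.set_xlabel("day relative to HCT")
    ax_c.set_xlim(lo - 0.7, hi + 0.7)
    fig.suptitle(f"Patient {spec.patient_id}: day {lo} to {hi}")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def render_embedding_map(
    coords: pd.DataFrame,
    samples: pd.DataFrame,
    trajectory_patient: str | None,
    window: tuple[int, int],
    path,
) -> "plt.Figure":
    """Scatter of all compositions; one patient's time-ordered trajectory overlaid."""
    fig, ax = plt.subplots(figsize=(8, 7))
    colors = coords["hex_color"].fillna("#999999") if "hex_color" in coords else "#999999"
    if isinstance(colors, pd.Series):
        colors = ["#" + c.lstrip("#") for c in colors.astype(str)]
    ax.scatter(coords["x"], coords["y"], s=8, c=colors, lw=0)
    n_arrows = 0
    if trajectory_patient is not None:
        lo, hi = window
        meta = samples.dropna(subset=["DayRelativeToNearestHCT"])
        sub = meta[
            (meta["PatientID"] == trajectory_patient)
            & (meta["DayRelativeToNearestHCT"] >= lo)
            & (meta["DayRelativeToNearestHCT"] <= hi)
        ].sort_values(["DayRelativeToNearestHCT", "SampleID"])
        pts = coords.reindex(sub["SampleID"]).dropna(subset=["x", "y"])
        if len(pts) >= 2:
            xy = pts[["x", "y"]].to_numpy()
            for a, b in zip(xy[:-1], xy[1:]):
                ax.annotate(
                    "", xy=b, xytext=a,
                    arrowprops=dict(arrowstyle="->", color="white", lw=1.8),
                )
                n_arrows += 1
        elif len(pts) == 1:
            ax.plot(*pts.iloc[0][["x", "y"]], "w*", ms=12)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.set_facecolor("#222222")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    fig.n_arrows = n_arrows
    return fig


def render_drug_frequency(frequencies: pd.DataFrame, path) -> "plt.Figure":
    """Two panels (oral, intravenous) of per-drug exposure fractions by category."""
    routes = ["oral", "intravenous"]
    fig, axes = plt.subplots(1, 2, figsize=(12, 5), sharey=True)
    categories = sorted(frequencies["Category"].dropna().astype(str).unique())
    cmap = plt.get_cmap("tab20")
    cat_color = {c: cmap(i % 20) for i, c in enumerate(categories)}
    name_col = frequencies.columns[0]
    for ax, route in zip(axes, routes):
        sub = frequencies[frequencies["Route"].astype(str).str.lower() == route]
        sub = sub.sort_values(["Category", "fraction"], ascending=[True, False])
        ax.bar(
            np.arange(len(sub)),
            sub["fraction"],
            color=[cat_color.get(str(c), "#888888") for c in sub["Category"]],
        )
        ax.set_xticks(np.arange(len(sub)))
        ax.set_xticklabels(sub[name_col], rotation=90, fontsize=7)
        ax.set_title(route)
        ax.set_ylabel("fraction of patients ever exposed")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig
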