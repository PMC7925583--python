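"""Compositional transforms of the 16S count tables.

Relative abundances divide each ASV's reads by the sample's total depth;
absolute abundances (16S copies per gram of stool) rescale those fractions by
the sample's qPCR total 16S load.  Counts can be aggregated to any taxonomic
rank, genus-level abundances support intestinal-domination calls, and the
whole dataset can be projected to 2-D with a stochastic neighbor embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import TAXONOMY_RANKS, Cohort

__all__ = [
    "AbundanceTable",
    "relative_abundance",
    "absolute_abundance",
    "aggregate_to_level",
    "genus_relative_abundance",
    "call_domination",
    "embed_2d",
    "counts_to_wide",
]

#: rank names accepted by :func:`aggregate_to_level` (lowercase)
LEVELS = ("asv",) + tuple(r.lower() for r in TAXONOMY_RANKS[1:])

_UNCLASSIFIED_TOKENS = {"", "unclassified", "na", "nan", "none", "<not present>"}


@dataclass
class AbundanceTable:
    """Sample-by-taxon abundance matrix.

    ``data`` is indexed by SampleID with one column per taxon.  ``kind`` is
    ``"relative"`` (rows sum to 1) or ``"absolute"`` (16S copies per gram);
    ``level`` names the taxonomic rank of the columns.  ``excluded`` lists
    samples dropped during the transform (zero depth, missing qPCR).
    """

    data: pd.DataFrame
    level: str = "asv"
    kind: str = "relative"
    excluded: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def taxa(self) -> pd.Index:
        return self.data.columns

    def fractions_of(self, taxon: str) -> pd.Series:
        if taxon not in self.data.columns:
            raise KeyError(f"taxon {taxon!r} not present at level {self.level!r}")
        return self.data[taxon]


def counts_to_wide(counts: pd.DataFrame) -> pd.DataFrame:
    """Pivot a melted counts table (SampleID, ASV/taxon, Count) to sample x taxon."""
    taxon_col = "ASV" if "ASV" in counts.columns else counts.columns[1]
    wide = counts.pivot_table(
        index="SampleID", columns=taxon_col, values="Count", aggfunc="sum", fill_value=0
    )
    wide.columns.name = None
    return wide.astype(float)


def _as_wide(counts: pd.DataFrame) -> pd.DataFrame:
    if {"SampleID", "Count"}.issubset(counts.columns):
        return counts_to_wide(counts)
    wide = counts.copy()
    if "SampleID" in wide.columns:
        wide = wide.set_index("SampleID")
    return wide.astype(float)


def relative_abundance(counts: pd.DataFrame, level: str = "asv") -> AbundanceTable:
    """Per-sample fractions: reads of a taxon over the sample's total depth.

    Accepts either the melted counts table or a wide sample-by-taxon matrix.
    Samples with zero total depth cannot be normalized; they are excluded and
    listed in ``excluded``.
    """
    wide = _as_wide(counts)
    depth = wide.sum(axis=1)
    zero = depth[depth <= 0].index.tolist()
    wide = wide.drop(index=zero)
    rel = wide.div(wide.sum(axis=1), axis=0)
    return AbundanceTable(rel, level=level, kind="relative", excluded=zero)


def absolute_abundance(rel: AbundanceTable, qpcr: pd.DataFrame) -> AbundanceTable:
    """Scale relative abundances by the qPCR total 16S load (copies per gram)."""
    if rel.kind != "relative":
        raise ValueError("absolute_abundance expects a relative AbundanceTable")
    load = qpcr.dropna(subset=["qPCR16S"]).set_index("SampleID")["qPCR16S"].astype(float)
    have = rel.data.index.intersection(load.index)
    missing = rel.data.index.difference(load.index).tolist()
    absolute = rel.data.loc[have].mul(load.loc[have], axis=0)
    return AbundanceTable(absolute, level=rel.level, kind="absolute", excluded=missing)


def _rank_labels(taxonomy: pd.DataFrame, level: str) -> pd.Series:
    """Label each ASV at a rank; unclassified ASVs get a per-parent bucket.

    Unclassified labels are never merged across parents: an ASV whose genus is
    unknown but whose family is Lachnospiraceae maps to
    ``"unclassified Lachnospiraceae"``, distinct from unclassified members of
    any other family.
    """
    rank = level.capitalize()
    if rank not in TAXONOMY_RANKS:
        raise ValueError(f"unknown rank {level!r}; expected one of {LEVELS}")
    ranks_up = list(TAXONOMY_RANKS[: TAXONOMY_RANKS.index(rank) + 1])[::-1]

    def label(row) -> str:
        for i, r in enumerate(ranks_up):
            v = row[r]
            v = "" if pd.isna(v) else str(v).strip()
            if v.lower() not in _UNCLASSIFIED_TOKENS:
                return v if i == 0 else f"unclassified {v}"
        return "unclassified"

    return pd.Series(
        taxonomy.apply(label, axis=1).to_numpy(), index=taxonomy["ASV"].to_numpy()
    )


def aggregate_to_level(
    counts: pd.DataFrame, taxonomy: pd.DataFrame, level: str
) -> pd.DataFrame:
    """Sum ASV counts over all ASVs sharing the taxon label at ``level``.

    Returns a wide sample-by-taxon matrix.  Per-sample totals are conserved:
    ASVs missing from the taxonomy table are kept under their own identifier.
    """
    level = level.lower()
    wide = _as_wide(counts)
    if level == "asv":
        return wide
    labels = _rank_labels(taxonomy, level)
    mapped = wide.columns.to_series().map(labels)
    mapped = mapped.fillna(pd.Series(wide.columns, index=wide.columns))
    return wide.T.groupby(mapped.to_numpy()).sum().T


def genus_relative_abundance(cohort: Cohort) -> AbundanceTable:
    """Genus-level relative abundances for every sample with nonzero depth."""
    genus_counts = aggregate_to_level(cohort.counts, cohort.taxonomy, "genus")
    return relative_abundance(genus_counts, level="genus")


def call_domination(
    rel: AbundanceTable,
    samples: pd.DataFrame,
    genus: str,
    threshold: float = 0.30,
) -> pd.DataFrame:
    """First day each patient's stool is dominated by ``genus``.

    Domination is a *strict* exceedance: the genus' relative abundance in a
    sample must be greater than ``threshold``.  Days are reported relative to
    the nearest HCT.  Patients never exceeding the threshold get a null
    ``FirstDominationDay``.
    """
    if rel.level != "genus":
        raise ValueError("call_domination expects a genus-level table")
    fracs = rel.fractions_of(genus)  # raises KeyError when genus unknown
    meta = samples.dropna(subset=["DayRelativeToNearestHCT"]).set_index("SampleID")
    meta = meta.loc[meta.index.intersection(fracs.index)]
    dominated = fracs.loc[meta.index] > threshold
    days = meta["DayRelativeToNearestHCT"].astype(int)
    rows = []
    for pid, grp in meta.groupby("PatientID"):
        hit_days = days.loc[grp.index][dominated.loc[grp.index]]
        first = int(hit_days.min()) if len(hit_days) else pd.NA
        rows.append({"PatientID": pid, "Genus": genus, "Threshold": threshold, "FirstDominationDay": first})
    out = pd.DataFrame(rows, columns=["PatientID", "Genus", "Threshold", "FirstDominationDay"])
    out["FirstDominationDay"] = out["FirstDominationDay"].astype("Int64")
    return out


def embed_2d(
    rel: AbundanceTable,
    seed: int = 0,
    taxonomy: pd.DataFrame | None = None,
    perplexity: float | None = None,
) -> pd.DataFrame:
    """Project all compositions to 2-D with t-SNE (off-the-shelf, seeded).

    Returns a frame indexed by SampleID with columns ``x``, ``y``,
    ``dominant_taxon`` and, when a taxonomy with colors is supplied,
    ``hex_color`` of the dominant taxon for plotting.
    """
    from sklearn.manifold import TSNE

    n = len(rel.data)
    if n < 3:
        raise ValueError("embedding needs at least 3 samples")
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    tsne = TSNE(
        n_components=2,
        random_state=int(seed),
        perplexity=float(perplexity),
        init="pca",
    )
    xy = tsne.fit_transform(rel.data.to_numpy())
    out = pd.DataFrame(xy, columns=["x", "y"], index=rel.data.index)
    out["dominant_taxon"] = rel.data.idxmax(axis=1)
    if taxonomy is not None and len(taxonomy):
        key = "ASV" if rel.level == "asv" else rel.level.capitalize()
        if key in taxonomy.columns:
            colors = (
                taxonomy.dropna(subset=[key, "HexColor"])
                .drop_duplicates(subset=[key])
                .set_index(key)["HexColor"]
            )
            out["hex_color"] = out["dominant_taxon"].map(colors)
    return out
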