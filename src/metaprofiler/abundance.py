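"""Read-to-OTU mapping, the abundance table with its low-count cell filter,
rank-abundance curves, and community richness/abundance profiles.

Reads (the full quality-filtered set, including the low-abundance sequences
removed by denoising) are mapped back to core OTU centroids at a global
identity threshold.  The resulting OTU × sample count table then has cells
with fewer than 3 reads zeroed — per-sample counts of 1–2 are
indistinguishable from tag jumps and index errors — and totals are
recomputed; the removed reads are reported as the "corrected" delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .otucluster import OTU
from .readproc import MergedRead
from .seqcore import RANKS, UNRESOLVED, TaxonLineage, global_identity

__all__ = ["AbundanceTable", "CommunityProfile", "map_reads",
           "rank_abundance", "community_profile"]


@dataclass
class AbundanceTable:
    """An OTU × sample integer count matrix plus mapping bookkeeping.

    ``counts`` rows are OTU ids, columns sample names.  ``unmapped`` counts
    reads below the mapping threshold; ``corrected`` counts reads removed by
    the <``cell_floor`` cell filter.
    """

    counts: pd.DataFrame
    unmapped: int = 0
    corrected: int = 0

    @property
    def mapped(self) -> int:
        return int(self.counts.values.sum())

    def otu_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="otu")


def map_reads(
    reads: Sequence[MergedRead],
    otus: Sequence[OTU],
    threshold: float = 97.0,
    cell_floor: int = 3,
) -> AbundanceTable:
    """Map sample-labelled reads to OTU centroids at an identity threshold.

    Each read goes to the best-identity centroid with identity ≥
    ``threshold`` (ties to the more abundant OTU); unmatched reads are
    tallied as unmapped.  Cells with count < ``cell_floor`` are then zeroed
    and their reads added to the corrected tally.
    """
    if not otus:
        raise ValueError("map_reads requires at least one OTU")
    order = sorted(otus, key=lambda o: (-o.total_count, o.centroid))
    samples = sorted({r.sample for r in reads if r.sample is not None})
    counts = {otu.id: {s: 0 for s in samples} for otu in order}
    unmapped = 0
    cache: dict[str, str | None] = {}
    for read in reads:
        if read.sample is None:
            raise ValueError(f"read {read.id!r}: sample label required")
        target = cache.get(read.bases, "?")
        if target == "?":
            best_id, best_ident = None, -1.0
            for otu in order:
                ident = global_identity(read.bases, otu.centroid)
                if ident >= threshold and ident > best_ident:
                    best_id, best_ident = otu.id, ident
            target = best_id
            cache[read.bases] = target
        if target is None:
            unmapped += 1
        else:
            counts[target][read.sample] += 1
    frame = pd.DataFrame.from_dict(counts, orient="index", dtype=int)
    frame = frame.reindex(index=[o.id for o in order], columns=samples, fill_value=0)
    low = (frame > 0) & (frame < cell_floor)
    corrected = int(frame.values[low.values].sum())
    frame = frame.mask(low, 0)
    return AbundanceTable(frame, unmapped=unmapped, corrected=corrected)


def rank_abundance(
    table: AbundanceTable,
    sample: str,
    cumulative: bool = False,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Rank-abundance curve for one sample.

    OTUs are sorted by descending count (ties by OTU id); the non-cumulative
    curve carries raw counts and per-OTU shares of mapped reads, the
    cumulative one the running share.  ``top_n`` truncates the curve.
    """
    if sample not in table.counts.columns:
        raise ValueError(f"unknown sample {sample!r}")
    col = table.counts[sample]
    col = col.iloc[sorted(range(len(col)), key=lambda i: (-col.iloc[i], col.index[i]))]
    total = int(col.sum())
    share = 100.0 * col / total if total else col.astype(float)
    frame = pd.DataFrame({
        "otu": col.index,
        "rank": range(1, len(col) + 1),
        "count": col.values,
        "share": share.values,
    })
    if cumulative:
        frame["cumulative_share"] = frame["share"].cumsum()
    if top_n is not None:
        frame = frame.head(top_n)
    return frame.reset_index(drop=True)


@dataclass
class CommunityProfile:
    """Per-taxon richness (% of OTUs) and abundance (% of mapped reads)
    shares, per sample and overall."""

    rank: str
    richness: pd.DataFrame    # taxa × (samples..., overall)
    abundance: pd.DataFrame


def community_profile(
    table: AbundanceTable,
    annotations: Mapping[str, TaxonLineage],
    rank: str = "phylum",
    phototroph_split: Mapping[str, bool] | None = None,
    others_floor: float | None = None,
) -> CommunityProfile:
    """Aggregate OTU richness and read abundance per taxon at one rank.

    OTUs missing from ``annotations`` are reported under ``UNRESOLVED``,
    never dropped.  With ``rank="trophic"`` and a ``phototroph_split`` map,
    taxa are the two labels Phototrophs/Heterotrophs.  Taxa whose mean
    abundance share across samples is below ``others_floor`` (percent) are
    pooled into "Others".
    """
    if rank != "trophic" and rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")

    def taxon_of(otu_id: str) -> str:
        if rank == "trophic":
            if phototroph_split is None:
                raise ValueError("trophic profile requires a phototroph_split map")
            flag = phototroph_split.get(otu_id)
            if flag is None:
                return UNRESOLVED
            return "Phototrophs" if flag else "Heterotrophs"
        lin = annotations.get(otu_id)
        return lin.get(rank) if lin is not None else UNRESOLVED

    taxa = pd.Series({otu: taxon_of(otu) for otu in table.counts.index})
    samples = list(table.counts.columns)

    grouped_counts = table.counts.groupby(taxa).sum()
    richness_counts = taxa.groupby(taxa).size()

    abundance = pd.DataFrame(index=grouped_counts.index)
    for s in samples:
        tot = grouped_counts[s].sum()
        abundance[s] = 100.0 * grouped_counts[s] / tot if tot else 0.0
    overall_tot = grouped_counts.values.sum()
    abundance["overall"] = (
        100.0 * grouped_counts.sum(axis=1) / overall_tot if overall_tot else 0.0
    )

    richness = pd.DataFrame(index=grouped_counts.index)
    present = table.counts > 0
    for s in samples:
        per_sample = taxa[present[s]].groupby(taxa[present[s]]).size()
        n = per_sample.sum()
        richness[s] = (
            100.0 * per_sample.reindex(grouped_counts.index, fill_value=0) / n
            if n else 0.0
        )
    richness["overall"] = 100.0 * richness_counts / richness_counts.sum()
    richness = richness.fillna(0.0)

    if others_floor is not None:
        mean_share = abundance[samples].mean(axis=1) if samples else abundance["overall"]
        pooled = mean_share < others_floor
        if pooled.any():
            keep = abundance.index[~pooled]
            others_ab = abundance.loc[pooled].sum()
            others_ri = richness.loc[pooled].sum()
            abundance = abundance.loc[keep]
            richness = richness.loc[keep]
            abundance.loc["Others"] = others_ab
            richness.loc["Others"] = others_ri

    return CommunityProfile(rank=rank, richness=richness, abundance=abundance)
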