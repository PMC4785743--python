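"""Calibration of per-rank percent-identity annotation thresholds from a
taxonomy-annotated reference alignment, and database-performance profiling.

Two threshold families are derived over the metabarcode window:

*Conservative (clade-based).*  For a rank, every record pair resolvable at
that rank is classified intra- or inter-clade and the raw threshold is the
**maximum inter-clade identity** — the worst-case similarity between members
of different clades.  A best hit at or above its integer ceiling therefore
guarantees the hit's clade at that rank.

*Relaxed (best-hit).*  Each reference is queried against the rest of the
database (leave-one-out best hit by identity); the hit is scored correct
when its label at the rank equals the query's.  The raw threshold is the
maximum identity among *incorrect* hits: above it, no best hit was ever
misclassified on this database.

Raw values are rounded **up** to the next integer.  High ranks and low ranks
may be calibrated on different record subsets (e.g. low ranks within a
single class), and thresholds at a high rank can legitimately exceed those
at a lower one — rank monotonicity is a property of the data, not of the
method, and is never enforced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .otucluster import OTU
from .seqcore import (
    RANKS,
    UNRESOLVED,
    IdentityMatrix,
    ReferenceRecord,
    TaxonLineage,
    global_identity,
    identity_matrix,
)

__all__ = [
    "RankDivergence",
    "ThresholdSet",
    "Annotation",
    "round_up_threshold",
    "rank_divergence",
    "conservative_threshold",
    "relaxed_threshold",
    "calibrate_thresholds",
    "annotate_otu",
    "db_performance",
]

#: Species-band floor for species-rank assignment, as percent identity over
#: a 375 bp metabarcode (8 substitutions).
DEFAULT_SPECIES_IDENTITY = 97.87


def round_up_threshold(raw: float) -> int:
    """Annotation thresholds are rounded up: smallest integer ≥ raw.

    Raw values are snapped to 6 dp first so that float representations of
    exact percentages (e.g. 342/375 = 91.2) do not ceil one integer too
    high.
    """
    return math.ceil(round(raw, 6))


def _five_number(values: np.ndarray) -> dict[str, float]:
    if values.size == 0:
        return {}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "min": float(values.min()), "q1": float(q1), "median": float(med),
        "q3": float(q3), "max": float(values.max()),
    }


@dataclass
class RankDivergence:
    """Intra- and inter-clade identity distributions at one rank.

    The two pair sets partition all comparable pairs of records resolved at
    the rank.  ``intra_pairs``/``inter_pairs`` carry (id_a, id_b, identity)
    for provenance.
    """

    rank: str
    intra: np.ndarray
    inter: np.ndarray
    intra_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    inter_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    n_clades: int = 0
    single_clade: bool = False

    def summary(self) -> dict[str, dict[str, float]]:
        return {"intra": _five_number(self.intra), "inter": _five_number(self.inter)}


def rank_divergence(
    records: Sequence[ReferenceRecord],
    rank: str,
    max_end_missing: int = 20,
    matrix: IdentityMatrix | None = None,
) -> RankDivergence:
    """Classify every resolvable record pair at ``rank`` as intra- or
    inter-clade and return both identity distributions.

    Records unresolved at the rank are excluded from this rank's
    computation.  A precomputed :class:`IdentityMatrix` may be passed to
    share the all-pairs work across ranks.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if matrix is None:
        matrix = identity_matrix(records, max_end_missing=max_end_missing)
    by_id = {r.id: r for r in records}
    ids = [i for i in matrix.ids if by_id[i].lineage.is_resolved(rank)]
    labels = {i: by_id[i].lineage.get(rank) for i in ids}
    index = {rid: k for k, rid in enumerate(matrix.ids)}
    intra_pairs, inter_pairs = [], []
    for a_pos in range(len(ids)):
        for b_pos in range(a_pos + 1, len(ids)):
            a, b = ids[a_pos], ids[b_pos]
            ident = float(matrix.matrix[index[a], index[b]])
            if labels[a] == labels[b]:
                intra_pairs.append((a, b, ident))
            else:
                inter_pairs.append((a, b, ident))
    clades = set(labels.values())
    return RankDivergence(
        rank=rank,
        intra=np.array([p[2] for p in intra_pairs]),
        inter=np.array([p[2] for p in inter_pairs]),
        intra_pairs=intra_pairs,
        inter_pairs=inter_pairs,
        n_clades=len(clades),
        single_clade=len(clades) < 2,
    )


@dataclass
class ThresholdEntry:
    """One rank's calibrated cutoffs; ``raw`` is the unrounded value and
    ``provenance`` the pair or hit that set it.  A relaxed threshold with no
    incorrect hit anywhere is *unbounded below*: ``raw`` is None and
    ``min_correct_identity`` reports the weakest correct hit instead."""

    rank: str
    mode: str                      # conservative | relaxed
    raw: float | None
    rounded: int | None
    provenance: str = ""
    min_correct_identity: float | None = None

    @property
    def unbounded_below(self) -> bool:
        return self.raw is None


@dataclass
class ThresholdSet:
    """Per-rank conservative and relaxed cutoffs."""

    conservative: dict[str, ThresholdEntry] = field(default_factory=dict)
    relaxed: dict[str, ThresholdEntry] = field(default_factory=dict)
    species_identity: float = DEFAULT_SPECIES_IDENTITY

    def get(self, rank: str, mode: str) -> ThresholdEntry | None:
        table = self.conservative if mode == "conservative" else self.relaxed
        return table.get(rank)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tmode\traw\trounded\tprovenance\n")
            for table in (self.conservative, self.relaxed):
                for entry in table.values():
                    raw = "unbounded_below" if entry.raw is None else f"{entry.raw:.2f}"
                    rounded = "" if entry.rounded is None else str(entry.rounded)
                    fh.write(
                        f"{entry.rank}\t{entry.mode}\t{raw}\t{rounded}\t"
                        f"{entry.provenance}\n"
                    )


def conservative_threshold(div: RankDivergence) -> ThresholdEntry:
    """Clade-based threshold: ceiling of the maximum inter-clade identity."""
    if div.inter.size == 0:
        raise ValueError(
            f"rank {div.rank!r}: no inter-clade pairs "
            f"({div.n_clades} clade(s)); conservative threshold undefined"
        )
    k = int(np.argmax(div.inter))
    a, b, raw = div.inter_pairs[k]
    return ThresholdEntry(
        rank=div.rank,
        mode="conservative",
        raw=raw,
        rounded=round_up_threshold(raw),
        provenance=f"{a}|{b}",
    )


def _best_hits(
    matrix: IdentityMatrix, query_ids: Sequence[str], tol: float = 1e-9
) -> dict[str, tuple[list[str], float]]:
    """Leave-one-out best hit(s) per query: all co-maximal refs and the
    identity."""
    index = {rid: k for k, rid in enumerate(matrix.ids)}
    out = {}
    for q in query_ids:
        row = matrix.matrix[index[q]].copy()
        row[index[q]] = -np.inf
        best = float(row.max())
        hits = [matrix.ids[j] for j in range(len(row)) if row[j] >= best - tol]
        out[q] = (hits, best)
    return out


def relaxed_threshold(
    records: Sequence[ReferenceRecord],
    rank: str,
    max_end_missing: int = 20,
    matrix: IdentityMatrix | None = None,
) -> tuple[ThresholdEntry, pd.DataFrame]:
    """Best-hit threshold from leave-one-out self-classification.

    Returns the threshold entry and the full per-query hit table
    (query, hit, identity, correct) — the histogram data behind the
    correct/incorrect hit distributions.
    """
    if matrix is None:
        matrix = identity_matrix(records, max_end_missing=max_end_missing)
    by_id = {r.id: r for r in records}
    queries = [i for i in matrix.ids if by_id[i].lineage.is_resolved(rank)]
    hits = _best_hits(matrix, queries)
    rows = []
    for q in queries:
        hit_ids, ident = hits[q]
        labels = {by_id[h].lineage.get(rank) for h in hit_ids}
        # Majority label among tied hits; an unresolved or split vote is a
        # discrepancy (the hit cannot confirm the query's clade).
        counts: dict[str, int] = {}
        for h in hit_ids:
            lab = by_id[h].lineage.get(rank)
            counts[lab] = counts.get(lab, 0) + 1
        top = max(counts.values())
        winners = sorted(lab for lab, n in counts.items() if n == top)
        hit_label = winners[0] if len(winners) == 1 else UNRESOLVED
        correct = (
            hit_label != UNRESOLVED and hit_label == by_id[q].lineage.get(rank)
        )
        rows.append({
            "query": q,
            "hit": hit_ids[0],
            "identity": ident,
            "hit_label": hit_label,
            "true_label": by_id[q].lineage.get(rank),
            "correct": correct,
        })
    table = pd.DataFrame(rows)
    incorrect = table[~table["correct"]]
    if incorrect.empty:
        correct_ids = table["identity"]
        entry = ThresholdEntry(
            rank=rank, mode="relaxed", raw=None, rounded=None,
            provenance="no incorrect best hit",
            min_correct_identity=(
                float(correct_ids.min()) if not correct_ids.empty else None
            ),
        )
    else:
        k = incorrect["identity"].idxmax()
        raw = float(incorrect.loc[k, "identity"])
        entry = ThresholdEntry(
            rank=rank, mode="relaxed", raw=raw,
            rounded=round_up_threshold(raw),
            provenance=f"{incorrect.loc[k, 'query']}|{incorrect.loc[k, 'hit']}",
        )
    return entry, table


def calibrate_thresholds(
    records: Sequence[ReferenceRecord],
    ranks: Sequence[str] = ("domain", "phylum", "class", "order", "suborder", "family"),
    subsets: Mapping[str, Sequence[ReferenceRecord]] | None = None,
    max_end_missing: int = 20,
    species_identity: float = DEFAULT_SPECIES_IDENTITY,
) -> tuple[ThresholdSet, dict[str, RankDivergence]]:
    """Calibrate both threshold families at every requested rank.

    ``subsets`` optionally restricts individual ranks to a record subset
    (e.g. low ranks calibrated within one class only); other ranks use the
    full record list.
    """
    thresholds = ThresholdSet(species_identity=species_identity)
    divergences: dict[str, RankDivergence] = {}
    full_matrix = identity_matrix(records, max_end_missing=max_end_missing)
    subset_matrices: dict[int, tuple[Sequence[ReferenceRecord], IdentityMatrix]] = {}
    for rank in ranks:
        subset = list(subsets[rank]) if subsets and rank in subsets else list(records)
        if subsets and rank in subsets:
            key = id(subsets[rank])
            if key not in subset_matrices:
                subset_matrices[key] = (
                    subset, identity_matrix(subset, max_end_missing=max_end_missing)
                )
            subset, matrix = subset_matrices[key]
        else:
            matrix = full_matrix
        div = rank_divergence(subset, rank, matrix=matrix)
        divergences[rank] = div
        if div.inter.size:
            thresholds.conservative[rank] = conservative_threshold(div)
        entry, _ = relaxed_threshold(subset, rank, matrix=matrix)
        thresholds.relaxed[rank] = entry
    return thresholds, divergences


# ---------------------------------------------------------------------------
# OTU annotation
# ---------------------------------------------------------------------------

@dataclass
class Annotation:
    """A per-rank taxonomy with the best hit that produced it."""

    lineage: TaxonLineage
    best_hit: str
    identity: float
    assigned_rank: str | None    # deepest rank assigned, None if fully unresolved


def _best_reference_hits(
    query: str, references: Sequence[ReferenceRecord], tol: float = 1e-9
) -> tuple[list[ReferenceRecord], float]:
    best, best_ident = [], -1.0
    for ref in references:
        ident = global_identity(query, ref.seq.bases)
        if ident > best_ident + tol:
            best, best_ident = [ref], ident
        elif ident >= best_ident - tol:
            best.append(ref)
    return best, best_ident


def _consensus_lineage(hits: Sequence[ReferenceRecord]) -> TaxonLineage:
    """Majority label per rank among tied hits; conflicts become UNRESOLVED."""
    labels = []
    for rank in RANKS:
        counts: dict[str, int] = {}
        for h in hits:
            lab = h.lineage.get(rank)
            counts[lab] = counts.get(lab, 0) + 1
        top = max(counts.values())
        winners = sorted(lab for lab, n in counts.items() if n == top)
        labels.append(winners[0] if len(winners) == 1 else UNRESOLVED)
    return TaxonLineage(tuple(labels))


def annotate_otu(
    otu: OTU | str,
    references: Sequence[ReferenceRecord],
    thresholds: ThresholdSet,
    mode: str = "conservative",
) -> Annotation:
    """Annotate an OTU centroid from its best database hit.

    The hit's labels are copied down to the deepest rank whose calibrated
    threshold the best-hit identity reaches; deeper ranks stay UNRESOLVED.
    Species is assigned only within the species band
    (identity ≥ ``thresholds.species_identity``).  Ties at equal identity
    resolve to the majority lineage of the tied hits, UNRESOLVED where they
    conflict.
    """
    if mode not in ("conservative", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    if not references:
        raise ValueError("annotate_otu requires a non-empty reference set")
    query = otu.centroid if isinstance(otu, OTU) else otu
    hits, identity = _best_reference_hits(query, references)
    hit_lineage = _consensus_lineage(hits)

    deepest: str | None = None
    for rank in RANKS:                       # domain → species, shallow first
        if rank == "species":
            passes = identity >= thresholds.species_identity
        else:
            entry = thresholds.get(rank, mode)
            if entry is None:
                continue
            if entry.unbounded_below:
                passes = True
            else:
                passes = identity >= entry.rounded
        if passes:
            deepest = rank
    labels = []
    cutoff = RANKS.index(deepest) if deepest is not None else -1
    for k, rank in enumerate(RANKS):
        labels.append(hit_lineage.get(rank) if k <= cutoff else UNRESOLVED)
    return Annotation(
        lineage=TaxonLineage(tuple(labels)),
        best_hit=hits[0].id,
        identity=identity,
        assigned_rank=deepest,
    )


def db_performance(
    otus: Sequence[OTU],
    references: Sequence[ReferenceRecord],
    table=None,
    abundant_share: float = 1.0,
) -> pd.DataFrame:
    """Best-hit identity per OTU, flagged for the high-abundance subset.

    An OTU is *abundant* when it holds ≥ ``abundant_share`` percent of the
    mapped reads of at least one sample in the abundance table (all False
    when no table is given).
    """
    abundant: set[str] = set()
    if table is not None:
        sample_totals = table.sample_totals()
        for sample in table.counts.columns:
            tot = sample_totals[sample]
            if tot == 0:
                continue
            share = 100.0 * table.counts[sample] / tot
            abundant.update(share[share >= abundant_share].index)
    rows = []
    for otu in otus:
        hits, ident = _best_reference_hits(otu.centroid, references)
        rows.append({
            "otu": otu.id,
            "best_hit": hits[0].id,
            "identity": ident,
            "abundant": otu.id in abundant,
        })
    return pd.DataFrame(rows)
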