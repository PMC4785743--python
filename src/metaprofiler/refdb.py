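"""Reference-database curation: identity dereplication, maximally distant
representative selection ("framing" of large clades), lineage-based
exclusion rules, and composition summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .seqcore import RANKS, UNRESOLVED, ReferenceRecord, global_identity

__all__ = ["dereplicate_db", "select_distant_representatives", "db_summary",
           "exclude_lineages", "DBSummary"]


def _lineages_compatible(a: ReferenceRecord, b: ReferenceRecord) -> bool:
    """True when no rank resolved in both lineages conflicts."""
    for rank in RANKS:
        agree = a.lineage.agree_at(b.lineage, rank)
        if agree is False:
            return False
    return True


def _derep_identity(shorter: str, longer: str) -> float:
    """Identity of the shorter sequence inside the longer one (infix
    alignment), so exact-substring duplicates score 100."""
    if len(shorter) > len(longer):
        shorter, longer = longer, shorter
    res = edlib.align(shorter, longer, mode="HW", task="distance")
    return 100.0 * (len(shorter) - res["editDistance"]) / len(shorter)


def dereplicate_db(
    records: Sequence[ReferenceRecord],
    identity: float = 100.0,
) -> tuple[list[ReferenceRecord], dict[str, str]]:
    """Greedy longest-first dereplication at an identity threshold.

    A record joins the first representative reaching the threshold whose
    lineage does not conflict with its own at any rank resolved in both
    (dereplication never merges records with contradictory taxonomy);
    otherwise it becomes a representative.  At 100 % only exact duplicates
    and exact substrings collapse.  Returns (representatives, member→rep id
    map).  Ordering rule: longest sequence first, ties lexicographic.
    """
    if not 50.0 < identity <= 100.0:
        raise ValueError(f"identity must be in (50, 100], got {identity}")
    ordered = sorted(records, key=lambda r: (-r.seq.length(), r.seq.bases, r.id))
    reps: list[ReferenceRecord] = []
    member_map: dict[str, str] = {}
    for rec in ordered:
        home = None
        for rep in reps:
            if not _lineages_compatible(rec, rep):
                continue
            if _derep_identity(rec.seq.degapped().bases, rep.seq.degapped().bases) >= identity:
                home = rep
                break
        if home is None:
            reps.append(rec)
            member_map[rec.id] = rec.id
        else:
            member_map[rec.id] = home.id
    return reps, member_map


def select_distant_representatives(
    records: Sequence[ReferenceRecord], k: int
) -> list[ReferenceRecord]:
    """Farthest-point selection of ``k`` maximally distant records.

    Greedy phase: start from the globally most divergent pair, then
    repeatedly add the record whose minimum distance (100 − identity) to
    the chosen set is largest; ties break lexicographically by id.  A
    1-swap refinement pass then exchanges chosen for unchosen records while
    any swap improves the set's minimum pairwise distance, so the result is
    1-swap locally optimal.  Used to "frame" large clades with a few
    representatives spanning their diversity.
    """
    if not 2 <= k <= len(records):
        raise ValueError(f"k must be in [2, {len(records)}], got {k}")
    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 100.0 - global_identity(records[i].seq.bases, records[j].seq.bases)
            dist[i, j] = dist[j, i] = d
    # most divergent pair, ties lexicographic by the pair's ids
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    start = min(
        pairs,
        key=lambda p: (-dist[p], tuple(sorted((records[p[0]].id, records[p[1]].id)))),
    )
    chosen = list(start)
    while len(chosen) < k:
        remaining = [i for i in range(n) if i not in chosen]
        best = min(
            remaining,
            key=lambda i: (-min(dist[i, c] for c in chosen), records[i].id),
        )
        chosen.append(best)

    def min_pair(indices: list[int]) -> float:
        return min(
            dist[a, b] for x, a in enumerate(indices) for b in indices[x + 1:]
        ) if len(indices) > 1 else 0.0

    improved = True
    while improved:
        improved = False
        current = min_pair(chosen)
        best_swap = None   # (gain, out_id, in_id, out, cand)
        for out in chosen:
            rest = [c for c in chosen if c != out]
            for cand in range(n):
                if cand in chosen:
                    continue
                score = min_pair(rest + [cand])
                if score > current + 1e-12:
                    key = (-score, records[out].id, records[cand].id)
                    if best_swap is None or key < best_swap[0]:
                        best_swap = (key, out, cand)
        if best_swap is not None:
            _, out, cand = best_swap
            chosen = [c for c in chosen if c != out] + [cand]
            improved = True
    return [records[i] for i in sorted(chosen)]


def exclude_lineages(
    records: Sequence[ReferenceRecord],
    rules: Sequence[Mapping[str, str]],
) -> tuple[list[ReferenceRecord], list[ReferenceRecord]]:
    """Apply lineage-based exclusion rules (e.g. drop a whole order).

    Each rule is a {rank: label} mapping; a record matching every pair of
    some rule is excluded.  Returns (kept, excluded).
    """
    kept, excluded = [], []
    for rec in records:
        hit = any(
            all(rec.lineage.get(rank) == label for rank, label in rule.items())
            for rule in rules
        )
        (excluded if hit else kept).append(rec)
    return kept, excluded


@dataclass
class DBSummary:
    """Composition tallies of a reference database."""

    total: int
    phototrophs: int
    heterotrophs: int
    per_domain: pd.Series
    per_phylum: pd.Series
    per_class: pd.Series


def db_summary(records: Sequence[ReferenceRecord]) -> DBSummary:
    """Exact composition tallies; phototrophs + heterotrophs = total."""
    photo = sum(1 for r in records if r.is_phototroph)
    frame = pd.DataFrame({
        "domain": [r.lineage.get("domain") for r in records],
        "phylum": [r.lineage.get("phylum") for r in records],
        "class": [r.lineage.get("class") for r in records],
    })
    empty = pd.Series(dtype=int)
    return DBSummary(
        total=len(records),
        phototrophs=photo,
        heterotrophs=len(records) - photo,
        per_domain=frame["domain"].value_counts().sort_index() if len(frame) else empty,
        per_phylum=frame["phylum"].value_counts().sort_index() if len(frame) else empty,
        per_class=frame["class"].value_counts().sort_index() if len(frame) else empty,
    )
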