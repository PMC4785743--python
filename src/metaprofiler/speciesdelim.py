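"""Substitution↔identity conversion over the metabarcode and a simplified
barcode-gap species partitioner.

The partitioner is an explicitly simplified take on automatic barcode-gap
discovery: it sweeps intraspecific-distance priors over a log grid, looks
for the first gap in the pairwise-distance distribution above each prior
that is wide enough relative to it, splits by single-linkage at the gap's
lower edge, and recurses within groups.  It consumes plain p-distances
((100 − identity)/100); no model correction.  All outputs label it
"barcode-gap (simplified)".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = ["SpeciesPartition", "subs_to_identity", "identity_to_subs",
           "barcode_gap_partition"]

METHOD_LABEL = "barcode-gap (simplified)"


def subs_to_identity(k: int, L: int = 375) -> float:
    """Percent identity of ``k`` substitutions over an ``L``-column
    metabarcode, rounded half-up to 2 dp."""
    if L <= 0:
        raise ValueError(f"alignment length must be positive, got {L}")
    if not 0 <= k <= L:
        raise ValueError(f"substitution count {k} outside [0, {L}]")
    value = 100.0 * (L - k) / L
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def identity_to_subs(percent: float, L: int = 375) -> int:
    """Inverse conversion: substitution count implied by a percent identity."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent identity {percent} outside [0, 100]")
    return round(L * (100.0 - percent) / 100.0)


@dataclass
class SpeciesPartition:
    """A species assignment with the barcode gap that produced it.

    ``gap`` is the (lower, upper) distance edge of the first split's gap (as
    p-distances), or None when no qualifying gap exists and everything is
    one group.
    """

    assignment: dict[str, int]
    gap: tuple[float, float] | None
    n_species: int
    method: str = METHOD_LABEL
    prior_range: tuple[float, float] | None = None


def _single_linkage(dist: np.ndarray, threshold: float) -> list[list[int]]:
    """Connected components of the ≤ threshold graph."""
    n = dist.shape[0]
    seen = [False] * n
    groups = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in range(n):
                if not seen[j] and dist[i, j] <= threshold:
                    seen[j] = True
                    stack.append(j)
        groups.append(sorted(comp))
    return groups


def _first_gap(
    values: np.ndarray, prior: float, relative_gap_width: float
) -> tuple[float, float] | None:
    """First gap between consecutive distinct distances that reaches above
    the prior (distances ≤ prior are presumed intraspecific) and is at
    least relative_gap_width × prior wide."""
    uniq = np.unique(values)
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        if hi > prior and (hi - lo) >= relative_gap_width * prior:
            return float(lo), float(hi)
    return None


def _partition_at_prior(
    dist: np.ndarray,
    members: list[int],
    prior: float,
    relative_gap_width: float,
    first_gap_out: list[tuple[float, float]],
) -> list[list[int]]:
    if len(members) < 2:
        return [members]
    sub = dist[np.ix_(members, members)]
    tri = sub[np.triu_indices(len(members), k=1)]
    gap = _first_gap(tri, prior, relative_gap_width)
    if gap is None:
        return [members]
    first_gap_out.append(gap)
    groups = _single_linkage(sub, gap[0])
    if len(groups) == 1:
        return [members]
    out = []
    for g in groups:
        out.extend(
            _partition_at_prior(
                dist, [members[i] for i in g], prior, relative_gap_width,
                first_gap_out,
            )
        )
    return out


def barcode_gap_partition(
    distances: np.ndarray,
    ids: list[str] | None = None,
    pmin: float = 0.001,
    pmax: float = 1.0,
    steps: int = 100,
    relative_gap_width: float = 0.5,
) -> SpeciesPartition:
    """Partition records into species groups at the barcode gap.

    ``distances`` is a symmetric zero-diagonal p-distance matrix.  Priors
    are swept over a log grid from ``pmin`` to ``pmax`` in ``steps`` steps;
    the returned partition is the one stable over the widest contiguous
    prior range (ties to the lower-prior range).  Group numbering follows
    the first member's input order, so the partition is invariant to record
    order.
    """
    distances = np.asarray(distances, dtype=float)
    n = distances.shape[0]
    if distances.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(distances, distances.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(distances), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if ids is None:
        ids = [str(i) for i in range(n)]

    priors = np.logspace(np.log10(pmin), np.log10(pmax), steps)
    results = []   # (prior, groups-as-tuple-of-tuples, first gap)
    for prior in priors:
        gaps: list[tuple[float, float]] = []
        groups = _partition_at_prior(
            distances, list(range(n)), prior, relative_gap_width, gaps
        )
        key = tuple(sorted(tuple(g) for g in groups))
        results.append((float(prior), key, gaps[0] if gaps else None))

    # widest contiguous run of priors yielding one identical partition;
    # runs that found a barcode gap take precedence over the trivial
    # single-group outcome, which is only the no-gap fallback
    best = None   # (has_gap, run length, -start) maximized
    start = 0
    for i in range(1, len(results) + 1):
        if i < len(results) and results[i][1] == results[start][1]:
            continue
        has_gap = results[start][2] is not None
        key = (has_gap, i - start, -start)
        if best is None or key > best[0]:
            best = (key, start, i - start)
        start = i
    _, best_start, best_len = best
    chosen = results[best_start]
    groups = chosen[1]

    assignment: dict[str, int] = {}
    ordered = sorted(groups, key=lambda g: g[0])
    for gid, group in enumerate(ordered, start=1):
        for i in group:
            assignment[ids[i]] = gid
    return SpeciesPartition(
        assignment=assignment,
        gap=chosen[2],
        n_species=len(groups),
        prior_range=(chosen[0], results[best_start + best_len - 1][0]),
    )
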