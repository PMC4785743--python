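"""Dual OTU clustering: greedy global-threshold centroid clustering, local
d-step agglomeration, their core-OTU consensus, and the d-scan.

Two complementary clustering strategies are implemented.  The *global*
algorithm assigns amplicons, in decreasing abundance order, to the existing
centroid of best global-alignment identity provided it reaches the threshold
(default 97 %), else founds a new OTU.  The *local* algorithm grows swarms:
starting from the most abundant unassigned amplicon, any amplicon within d
edit-distance steps (Levenshtein) of a current member joins, generation by
generation, until closure.  OTUs produced concordantly by both — the global
centroid sequence also being the seed of a local swarm — are the *core*
OTUs carried into downstream profiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .readproc import UniqueAmplicon
from .seqcore import global_identity, levenshtein

__all__ = ["OTU", "ClusterScan", "cluster_global", "cluster_local",
           "core_consensus", "d_scan"]


@dataclass
class OTU:
    """A centroid sequence with its member amplicons and summed counts."""

    centroid: str
    members: list[UniqueAmplicon]
    source: str = "global"          # global | local | core
    id: str = ""

    @property
    def total_count(self) -> int:
        return sum(m.total_count for m in self.members)

    @property
    def per_sample_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.members:
            for sample, n in m.per_sample_counts.items():
                counts[sample] = counts.get(sample, 0) + n
        return counts


def _sorted_amplicons(amplicons: Sequence[UniqueAmplicon]) -> list[UniqueAmplicon]:
    return sorted(amplicons, key=lambda a: (-a.total_count, a.bases))


def _label(otus: list[OTU], prefix: str) -> list[OTU]:
    for i, otu in enumerate(otus, 1):
        otu.id = f"{prefix}{i:04d}"
    return otus


def cluster_global(
    amplicons: Sequence[UniqueAmplicon], threshold: float = 97.0
) -> list[OTU]:
    """Greedy abundance-ordered centroid clustering at a global identity
    threshold.

    Each amplicon joins the qualifying centroid of highest identity (ties to
    the more abundant, i.e. earlier-founded, centroid), else founds a new
    OTU whose centroid it becomes.  Fully deterministic.
    """
    if not 50.0 < threshold <= 100.0:
        raise ValueError(f"threshold must be in (50, 100], got {threshold}")
    otus: list[OTU] = []
    for amp in _sorted_amplicons(amplicons):
        best_i, best_ident = -1, -1.0
        for i, otu in enumerate(otus):
            ident = global_identity(amp.bases, otu.centroid)
            if ident >= threshold and ident > best_ident:
                best_i, best_ident = i, ident
        if best_i >= 0:
            otus[best_i].members.append(amp)
        else:
            otus.append(OTU(centroid=amp.bases, members=[amp], source="global"))
    return _label(otus, "OTU_G")


def cluster_local(amplicons: Sequence[UniqueAmplicon], d: int = 10) -> list[OTU]:
    """Swarm-style local clustering: transitive closure of the ≤d
    edit-distance relation, seeded in decreasing abundance order."""
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    pool = _sorted_amplicons(amplicons)
    unassigned = list(range(len(pool)))
    otus: list[OTU] = []
    while unassigned:
        seed = unassigned.pop(0)
        members = [seed]
        frontier = [seed]
        while frontier:
            new_frontier = []
            remaining = []
            for j in unassigned:
                joined = False
                for i in frontier:
                    dist = levenshtein(pool[i].bases, pool[j].bases, max_distance=d)
                    if 0 <= dist <= d:
                        joined = True
                        break
                if joined:
                    members.append(j)
                    new_frontier.append(j)
                else:
                    remaining.append(j)
            unassigned = remaining
            frontier = new_frontier
        otus.append(OTU(
            centroid=pool[seed].bases,
            members=[pool[i] for i in members],
            source="local",
        ))
    return _label(otus, "OTU_L")


def core_consensus(
    global_otus: Sequence[OTU],
    local_otus: Sequence[OTU],
    criterion: str = "centroid",
    min_jaccard: float = 0.5,
) -> list[OTU]:
    """Robust core OTUs produced concordantly by both algorithms.

    ``criterion="centroid"`` (default): a global OTU is core iff its
    centroid sequence is exactly the seed sequence of some local OTU.
    ``criterion="jaccard"``: core iff some local OTU shares ≥ ``min_jaccard``
    of member sequences (Jaccard on member base-strings).  The core OTU
    inherits the global OTU's membership.
    """
    if criterion == "centroid":
        seeds = {otu.centroid for otu in local_otus}
        core = [otu for otu in global_otus if otu.centroid in seeds]
    elif criterion == "jaccard":
        local_sets = [{m.bases for m in otu.members} for otu in local_otus]
        core = []
        for otu in global_otus:
            gset = {m.bases for m in otu.members}
            for lset in local_sets:
                union = len(gset | lset)
                if union and len(gset & lset) / union >= min_jaccard:
                    core.append(otu)
                    break
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    out = [OTU(o.centroid, list(o.members), source="core") for o in core]
    return _label(out, "OTU")


@dataclass
class ClusterScan:
    """d-scan result: per-d local OTU count and core count against a fixed
    global clustering, plus the widest plateau of constant core count."""

    rows: list[tuple[int, int, int]] = field(default_factory=list)  # (d, local, core)
    optimum: tuple[int, int] | None = None                          # inclusive d range

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("d\tlocal_otus\tcore_otus\n")
            for d, local, core in self.rows:
                fh.write(f"{d}\t{local}\t{core}\n")


def d_scan(
    amplicons: Sequence[UniqueAmplicon],
    global_otus: Sequence[OTU],
    d_values: Iterable[int] = range(1, 17),
) -> ClusterScan:
    """Scan local clustering resolutions against a fixed global clustering.

    For each d the local OTU count and the core count (centroid criterion)
    are recorded; the *optimum* is the widest run of consecutive d values
    with constant core count (ties to the first such run).
    """
    scan = ClusterScan()
    for d in d_values:
        local = cluster_local(amplicons, d)
        core = core_consensus(global_otus, local)
        scan.rows.append((d, len(local), len(core)))
    if scan.rows:
        best_start = best_len = 0
        start = 0
        for i in range(1, len(scan.rows) + 1):
            contiguous = (
                i < len(scan.rows)
                and scan.rows[i][0] == scan.rows[i - 1][0] + 1
                and scan.rows[i][2] == scan.rows[start][2]
            )
            if not contiguous:
                if i - start > best_len:
                    best_start, best_len = start, i - start
                start = i
        scan.optimum = (scan.rows[best_start][0],
                        scan.rows[best_start + best_len - 1][0])
    return scan


def write_otu_fasta(otus: Sequence[OTU], path) -> None:
    """Centroid FASTA with ``;size=`` abundance annotations in headers."""
    with open(path, "w") as fh:
        for otu in otus:
            fh.write(f">{otu.id};size={otu.total_count}\n{otu.centroid}\n")


def write_membership_tsv(otus: Sequence[OTU], path) -> None:
    with open(path, "w") as fh:
        fh.write("amplicon_rank\totu\tidentity\n")
        for otu in otus:
            for i, m in enumerate(otu.members):
                ident = global_identity(m.bases, otu.centroid)
                fh.write(f"{otu.id}.m{i}\t{otu.id}\t{ident:.2f}\n")
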