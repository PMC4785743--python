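"""Amplicon read processing: merge, demultiplex, filter, trim, dereplicate,
denoise, chimera- and contaminant-screen.

The chain mirrors a standard amplicon pipeline: paired-end overlap merging,
exact-index demultiplexing with forward-primer stripping, expected-error
quality filtering (E = Σ 10^(−Q/10), keep E ≤ 0.5), inclusive length
filtering with fixed 5'/3' cropping, exact dereplication with per-sample
counts, abundance denoising (unique sequences of dataset-wide count ≤ 3
dropped), reference-based bimera flagging and non-marker decontamination.
Every stage is deterministic and reports its survivor count to a
:class:`PipelineLedger`.

Boundary semantics are deliberate and tested: quality keep is E ≤ maxee
(exclusion is E > maxee), length bounds are inclusive, and denoising
removes totals strictly below ``min_total``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np

from .primertools import DegeneratePrimer, primer_match
from .seqcore import ReferenceRecord, reverse_complement

__all__ = [
    "ReadPair",
    "MergedRead",
    "UniqueAmplicon",
    "PipelineLedger",
    "merge_pairs",
    "demultiplex",
    "quality_filter",
    "size_filter_and_trim",
    "dereplicate",
    "denoise_by_abundance",
    "chimera_screen",
    "decontaminate",
    "read_fastq_pairs",
    "write_fastq",
]

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass(frozen=True)
class ReadPair:
    """A raw paired-end read; qualities are Phred scores (offset 33 on disk)."""

    id: str
    bases1: str
    quals1: tuple[int, ...]
    bases2: str
    quals2: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases1) != len(self.quals1) or len(self.bases2) != len(self.quals2):
            raise ValueError(f"read {self.id!r}: bases/quality length mismatch")


@dataclass(frozen=True)
class MergedRead:
    """An overlap-merged read; ``sample`` is set only by demultiplexing and
    ``quals`` is dropped by trimming."""

    id: str
    bases: str
    quals: tuple[int, ...] | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.id!r}: empty bases")
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(f"read {self.id!r}: bases/quality length mismatch")


@dataclass
class UniqueAmplicon:
    """A dereplicated sequence with total and per-sample abundances."""

    bases: str
    total_count: int
    per_sample_counts: dict[str, int]
    read_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_count != sum(self.per_sample_counts.values()):
            raise ValueError("total_count != sum of per-sample counts")


@dataclass
class PipelineLedger:
    """Per-stage survivor counts as counts and integer percent of raw."""

    rows: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, stage: str, remaining: int) -> None:
        raw = self.rows[0][1] if self.rows else remaining
        pct = 100 if raw == 0 else round(100 * remaining / raw)
        if self.rows and remaining > self.rows[-1][1]:
            raise ValueError(f"stage {stage!r}: counts must be non-increasing")
        self.rows.append((stage, remaining, pct))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\treads\tpercent_of_raw\n")
            for stage, count, pct in self.rows:
                fh.write(f"{stage}\t{count}\t{pct}\n")


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------

def _merge_one(
    pair: ReadPair, min_overlap: int, max_mismatch_frac: float
) -> MergedRead | None:
    b1, q1 = pair.bases1, pair.quals1
    b2 = reverse_complement(pair.bases2)
    q2 = pair.quals2[::-1]
    a1 = np.frombuffer(b1.encode("ascii"), dtype=np.uint8)
    a2 = np.frombuffer(b2.encode("ascii"), dtype=np.uint8)
    best = None  # (matches, overlap)
    max_o = min(len(b1), len(b2))
    for o in range(min_overlap, max_o + 1):
        matches = int((a1[-o:] == a2[:o]).sum())
        if (o - matches) / o > max_mismatch_frac:
            continue
        if best is None or (matches, o) > best[:2]:
            best = (matches, o)
    if best is None:
        return None
    _, o = best
    merged_bases = []
    merged_quals = []
    for i in range(o):
        x, y = b1[len(b1) - o + i], b2[i]
        qx, qy = q1[len(b1) - o + i], q2[i]
        if x == y:
            merged_bases.append(x)
            merged_quals.append(max(qx, qy))
        elif qx >= qy:          # tie keeps read 1's call
            merged_bases.append(x)
            merged_quals.append(qx)
        else:
            merged_bases.append(y)
            merged_quals.append(qy)
    bases = b1[:-o] + "".join(merged_bases) + b2[o:]
    quals = q1[:-o] + tuple(merged_quals) + q2[o:]
    return MergedRead(pair.id, bases, quals)


def merge_pairs(
    pairs: Sequence[ReadPair],
    min_overlap: int = 16,
    max_overlap_mismatch_frac: float = 0.25,
) -> tuple[list[MergedRead], int]:
    """Overlap-merge read pairs; returns (merged reads, n failed).

    Read 2 is reverse-complemented, the best ungapped overlap ≥
    ``min_overlap`` is chosen by maximum matches (ties to the longer
    overlap), and within the overlap the higher-quality base wins (agreement
    keeps the maximum quality).  Pairs without an acceptable overlap are
    dropped and tallied.
    """
    merged, failed = [], 0
    for pair in pairs:
        m = _merge_one(pair, min_overlap, max_overlap_mismatch_frac)
        if m is None:
            failed += 1
        else:
            merged.append(m)
    return merged, failed


# ---------------------------------------------------------------------------
# Demultiplex
# ---------------------------------------------------------------------------

def demultiplex(
    reads: Sequence[MergedRead],
    index_table: dict[str, str],
    fwd_primer: DegeneratePrimer,
    primer_mismatch: int = 2,
) -> tuple[list[MergedRead], int]:
    """Assign reads to samples by exact 5' index match, then strip index and
    forward primer.

    The index must match with zero mismatches; the window following it must
    match ``fwd_primer`` within ``primer_mismatch``.  Everything else is
    discarded and tallied.  Returns (assigned reads, n discarded).
    """
    if not index_table:
        raise ValueError("empty index table")
    lengths = {len(ix) for ix in index_table.values()}
    if len(lengths) != 1:
        raise ValueError("indexes must share one length")
    if len(set(index_table.values())) != len(index_table):
        raise ValueError("duplicate index sequences in table")
    ilen = lengths.pop()
    by_index = {ix.upper(): sample for sample, ix in index_table.items()}
    plen = len(fwd_primer)
    assigned, discarded = [], 0
    for read in reads:
        sample = by_index.get(read.bases[:ilen])
        if sample is None or len(read.bases) < ilen + plen + 1:
            discarded += 1
            continue
        ok, _ = primer_match(fwd_primer, read.bases[ilen:ilen + plen], primer_mismatch)
        if not ok:
            discarded += 1
            continue
        quals = read.quals[ilen + plen:] if read.quals is not None else None
        assigned.append(MergedRead(read.id, read.bases[ilen + plen:], quals, sample))
    return assigned, discarded


# ---------------------------------------------------------------------------
# Quality / size filters
# ---------------------------------------------------------------------------

def expected_errors(quals: Sequence[int]) -> float:
    """Expected number of errors: Σ 10^(−Q/10)."""
    return float(sum(10.0 ** (-q / 10.0) for q in quals))


def quality_filter(
    reads: Sequence[MergedRead], max_expected_error: float = 0.5
) -> tuple[list[MergedRead], int]:
    """Keep reads with expected error E ≤ ``max_expected_error`` (inclusive)."""
    kept, dropped = [], 0
    for read in reads:
        if read.quals is None:
            raise ValueError(f"read {read.id!r}: qualities required")
        # tiny tolerance keeps the inclusive boundary exact under float
        # accumulation (50 bases at Q20 must sum to exactly 0.5)
        if expected_errors(read.quals) <= max_expected_error + 1e-9:
            kept.append(read)
        else:
            dropped += 1
    return kept, dropped


def size_filter_and_trim(
    reads: Sequence[MergedRead],
    min_len: int = 400,
    max_len: int = 440,
    crop5: int = 20,
    crop3: int = 50,
) -> tuple[list[MergedRead], int]:
    """Drop reads outside [min_len, max_len] (inclusive), then crop fixed
    5'/3' stretches from the survivors.  Qualities are dropped at trimming."""
    if crop5 + crop3 >= min_len:
        raise ValueError(f"crop5+crop3 ({crop5 + crop3}) must be < min_len ({min_len})")
    kept, dropped = [], 0
    for read in reads:
        n = len(read.bases)
        if n < min_len or n > max_len:
            dropped += 1
            continue
        bases = read.bases[crop5: n - crop3] if crop3 else read.bases[crop5:]
        kept.append(MergedRead(read.id, bases, None, read.sample))
    return kept, dropped


# ---------------------------------------------------------------------------
# Dereplicate / denoise
# ---------------------------------------------------------------------------

def dereplicate(reads: Sequence[MergedRead]) -> list[UniqueAmplicon]:
    """Collapse exact duplicate sequences, keeping per-sample counts.

    Output order is deterministic: decreasing total count, ties broken by
    sequence lexicographic order.
    """
    groups: dict[str, UniqueAmplicon] = {}
    for read in reads:
        if read.sample is None:
            raise ValueError(f"read {read.id!r}: sample label required")
        amp = groups.get(read.bases)
        if amp is None:
            groups[read.bases] = UniqueAmplicon(
                read.bases, 1, {read.sample: 1}, [read.id]
            )
        else:
            amp.total_count += 1
            amp.per_sample_counts[read.sample] = (
                amp.per_sample_counts.get(read.sample, 0) + 1
            )
            amp.read_ids.append(read.id)
    return sorted(groups.values(), key=lambda a: (-a.total_count, a.bases))


def denoise_by_abundance(
    amplicons: Sequence[UniqueAmplicon], min_total: int = 4
) -> tuple[list[UniqueAmplicon], int]:
    """Remove unique sequences with dataset-wide total below ``min_total``
    (default drops singletons, doubletons and tripletons)."""
    kept = [a for a in amplicons if a.total_count >= min_total]
    return kept, len(amplicons) - len(kept)


# ---------------------------------------------------------------------------
# Chimera screen
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _match_profile(query: str, parent: str) -> np.ndarray:
    """Boolean per-query-position match vector from a global alignment."""
    if len(query) == len(parent):
        return np.fromiter(
            (a == b for a, b in zip(query, parent)), dtype=bool, count=len(query)
        )
    res = edlib.align(query, parent, mode="NW", task="path")
    profile = np.zeros(len(query), dtype=bool)
    qpos = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        if op == "=":
            profile[qpos:qpos + n] = True
            qpos += n
        elif op in ("X", "I"):   # I: base present in query, absent in parent
            qpos += n
    return profile


def chimera_screen(
    amplicons: Sequence[UniqueAmplicon],
    references: Sequence[ReferenceRecord],
    min_parent_gain: float = 3.0,
    min_two_parent_identity: float = 99.0,
    kmer_size: int = 8,
) -> tuple[list[UniqueAmplicon], list[UniqueAmplicon]]:
    """Reference-based bimera screen; returns (clean, flagged).

    For each amplicon the best single-parent identity is compared with the
    best two-parent split model (left prefix explained by parent A, right
    suffix by parent B, maximized over all crossover points and parent
    pairs).  The amplicon is flagged iff the two-parent model gains at least
    ``min_parent_gain`` percentage points over the best single parent *and*
    reaches ``min_two_parent_identity``.  Parents are pre-screened by shared
    k-mers; a parent sharing no k-mer cannot support the near-identity
    two-parent model, so the prescreen never changes the decision.
    """
    if not references:
        raise ValueError("chimera_screen requires a non-empty reference set")
    ref_seqs = [r.seq.degapped().bases for r in references]
    ref_kmers = [_kmers(s, kmer_size) for s in ref_seqs]
    clean, flagged = [], []
    for amp in amplicons:
        qk = _kmers(amp.bases, kmer_size)
        candidates = [i for i, rk in enumerate(ref_kmers) if qk & rk]
        if len(candidates) < 2:
            clean.append(amp)
            continue
        L = len(amp.bases)
        profiles = {i: _match_profile(amp.bases, ref_seqs[i]) for i in candidates}
        totals = {i: int(p.sum()) for i, p in profiles.items()}
        best_single = 100.0 * max(totals.values()) / L
        prefix = {i: np.concatenate(([0], np.cumsum(p))) for i, p in profiles.items()}
        best_two = 0.0
        for ia in candidates:
            for ib in candidates:
                if ia == ib:
                    continue
                # matches = prefix A up to crossover + suffix B after it
                combo = prefix[ia][1:L] + (totals[ib] - prefix[ib][1:L])
                best_two = max(best_two, 100.0 * int(combo.max()) / L)
        if (
            best_two - best_single >= min_parent_gain
            and best_two >= min_two_parent_identity
        ):
            flagged.append(amp)
        else:
            clean.append(amp)
    return clean, flagged


# ---------------------------------------------------------------------------
# Decontaminate
# ---------------------------------------------------------------------------

def _local_identity(query: str, target: str) -> tuple[float, float]:
    """Best infix alignment of ``query`` in ``target``: (identity, coverage).

    Identity is matches over alignment columns; coverage is the fraction of
    the query inside substitution columns (insertions to the target reduce
    it).
    """
    if len(query) > len(target):
        query, target = target, query
    res = edlib.align(query, target, mode="HW", task="path")
    ops = {"=": 0, "X": 0, "I": 0, "D": 0}
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        ops[op] += int(n)
    cols = sum(ops.values())
    if cols == 0:
        return 0.0, 0.0
    identity = 100.0 * ops["="] / cols
    coverage = (ops["="] + ops["X"]) / len(query)
    return identity, coverage


def decontaminate(
    amplicons: Sequence[UniqueAmplicon],
    references: Sequence[ReferenceRecord],
    min_identity: float = 60.0,
    min_coverage: float = 0.5,
) -> tuple[list[UniqueAmplicon], list[UniqueAmplicon]]:
    """Split amplicons into (on_target, off_target) by best local alignment
    against the reference set.

    An amplicon is on-target iff some reference aligns at identity ≥
    ``min_identity`` with query coverage ≥ ``min_coverage``.  Unrelated
    (non-marker) sequences align near the ~55 % identity noise floor of
    edit-distance alignment and fall below the default 60 % cutoff.
    """
    if not references:
        raise ValueError("decontaminate requires a non-empty reference set")
    ref_seqs = [r.seq.degapped().bases for r in references]
    on_target, off_target = [], []
    for amp in amplicons:
        hit = False
        for rs in ref_seqs:
            ident, cov = _local_identity(amp.bases, rs)
            if ident >= min_identity and cov >= min_coverage:
                hit = True
                break
        (on_target if hit else off_target).append(amp)
    return on_target, off_target


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33)
# ---------------------------------------------------------------------------

def _read_fastq(path: str | Path) -> list[tuple[str, str, tuple[int, ...]]]:
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                break
            bases = fh.readline().rstrip("\n")
            fh.readline()
            quals = fh.readline().rstrip("\n")
            if not header.startswith("@") or len(bases) != len(quals):
                raise ValueError(f"{path}: malformed FASTQ near {header!r}")
            out.append(
                (header[1:].split()[0], bases.upper(),
                 tuple(ord(c) - 33 for c in quals))
            )
    return out


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    r1 = _read_fastq(r1_path)
    r2 = _read_fastq(r2_path)
    if len(r1) != len(r2):
        raise ValueError("R1/R2 read counts differ")
    pairs = []
    for (id1, b1, q1), (id2, b2, q2) in zip(r1, r2):
        if id1 != id2:
            raise ValueError(f"R1/R2 id mismatch: {id1!r} vs {id2!r}")
        pairs.append(ReadPair(id1, b1, q1, b2, q2))
    return pairs


def write_fastq(reads: Iterable[MergedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            quals = read.quals if read.quals is not None else (40,) * len(read.bases)
            fh.write(
                f"@{read.id}\n{read.bases}\n+\n"
                + "".join(chr(q + 33) for q in quals) + "\n"
            )
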