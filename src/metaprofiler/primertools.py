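"""Degenerate-primer metrics, matching, in-silico PCR and conservation profiling.

Degenerate primers are written 5'→3' in IUPAC code.  GC content of a
degenerate primer is computed under *fractional ambiguity weighting*: each
position contributes the fraction of its ambiguity set that is G or C
(so ``S`` → 1, ``W`` → 0, ``N`` → 0.5, ``B``/``V`` → 2/3, ``D``/``H`` → 1/3),
which equals the mean GC over all non-degenerate expansions of the primer.

Melting temperature is offered only as an informational output
(:func:`primer_tm_wallace`, the Wallace 2(A+T)+4(G+C) rule with the same
fractional weighting); it is not a validated metric of this package.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterator, Sequence

import numpy as np

from .seqcore import IUPAC_MASK, IUPAC_SET, NucSequence, reverse_complement

__all__ = [
    "DegeneratePrimer",
    "ConservationProfile",
    "Amplicon",
    "primer_gc_percent",
    "primer_tm_wallace",
    "primer_match",
    "in_silico_pcr",
    "conservation_profile",
]


def _round_half_up(value: float, digits: int) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(10) ** -digits, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DegeneratePrimer:
    """A PCR primer over the IUPAC alphabet, stored as written 5'→3'.

    Reverse primers anneal to the coding strand via their reverse
    complement; :func:`in_silico_pcr` handles that orientation flip.
    """

    name: str
    bases: str
    orientation: str = "forward"

    def __post_init__(self) -> None:
        norm = self.bases.upper().replace("U", "T")
        if not norm:
            raise ValueError(f"primer {self.name!r}: empty sequence")
        bad = set(norm) - (set(IUPAC_MASK) - {"-", "."})
        if bad:
            raise ValueError(f"primer {self.name!r}: invalid characters {sorted(bad)!r}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name!r}: orientation must be forward|reverse")
        object.__setattr__(self, "bases", norm)

    def __len__(self) -> int:
        return len(self.bases)

    def degeneracy(self) -> int:
        """Product of per-position ambiguity-set sizes (1 for a plain primer)."""
        d = 1
        for c in self.bases:
            d *= len(IUPAC_SET[c])
        return d

    def expand(self, limit: int = 65536) -> Iterator[str]:
        """All non-degenerate variants (raises if degeneracy exceeds ``limit``)."""
        if self.degeneracy() > limit:
            raise ValueError(f"primer {self.name!r}: degeneracy {self.degeneracy()} > {limit}")
        pools = [sorted(IUPAC_SET[c]) for c in self.bases]
        for combo in itertools.product(*pools):
            yield "".join(combo)


def primer_gc_percent(primer: DegeneratePrimer) -> float:
    """Fractionally weighted GC percentage, rounded half-up to 1 dp."""
    total = 0.0
    for c in primer.bases:
        s = IUPAC_SET[c]
        total += sum(1 for b in s if b in "GC") / len(s)
    return _round_half_up(100.0 * total / len(primer), 1)


def primer_tm_wallace(primer: DegeneratePrimer) -> float:
    """Informational Wallace-rule Tm: 2·(A+T) + 4·(G+C), fractional weights."""
    gc = at = 0.0
    for c in primer.bases:
        s = IUPAC_SET[c]
        frac_gc = sum(1 for b in s if b in "GC") / len(s)
        gc += frac_gc
        at += 1.0 - frac_gc
    return 2.0 * at + 4.0 * gc


def primer_match(
    primer: DegeneratePrimer,
    window: NucSequence | str,
    max_mismatch: int = 0,
) -> tuple[bool, int]:
    """Match a primer against an equal-length template window.

    A position mismatches when the window base is outside the primer's
    ambiguity set (set intersection for ambiguous window bases).  Returns
    ``(matched, mismatch_count)``.
    """
    bases = window.bases if isinstance(window, NucSequence) else window.upper()
    if len(bases) != len(primer):
        raise ValueError(
            f"window length {len(bases)} != primer length {len(primer)}"
        )
    mism = sum(
        1 for p, w in zip(primer.bases, bases)
        if not (IUPAC_MASK[p] & IUPAC_MASK.get(w, 0))
    )
    return mism <= max_mismatch, mism


@dataclass(frozen=True)
class Amplicon:
    """One in-silico PCR product on the forward strand (0-based half-open)."""

    start: int            # first base of the forward priming site
    end: int              # one past the last base of the reverse priming site
    insert_start: int
    insert_end: int
    full_sequence: str
    insert_sequence: str

    @property
    def full_length(self) -> int:
        return self.end - self.start

    @property
    def insert_length(self) -> int:
        return self.insert_end - self.insert_start


def _scan_sites(primer_bases: str, template: str, max_mismatch: int) -> list[int]:
    plen = len(primer_bases)
    p = DegeneratePrimer("site", primer_bases)
    hits = []
    for i in range(len(template) - plen + 1):
        ok, _ = primer_match(p, template[i:i + plen], max_mismatch)
        if ok:
            hits.append(i)
    return hits


def in_silico_pcr(
    template: NucSequence | str,
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    max_mismatch: int = 0,
    both_strands: bool = False,
) -> list[Amplicon]:
    """Enumerate amplicons a forward/reverse primer pair would produce.

    Scans the forward strand for the forward priming site and, downstream of
    it, for the reverse complement of the reverse primer.  Every valid
    (forward site, reverse site) pair yields one amplicon, reported with its
    full length and insert length (full − both primer lengths).  With
    ``both_strands=True`` the reverse-complemented template is scanned too.
    """
    bases = template.bases if isinstance(template, NucSequence) else template.upper()
    if "-" in bases or "." in bases:
        raise ValueError("template must be gap-free")
    rev_site = reverse_complement(rev.bases)
    products = []
    fwd_hits = _scan_sites(fwd.bases, bases, max_mismatch)
    rev_hits = _scan_sites(rev_site, bases, max_mismatch)
    for f in fwd_hits:
        insert_start = f + len(fwd)
        for r in rev_hits:
            if r < insert_start:
                continue
            end = r + len(rev)
            products.append(Amplicon(
                start=f,
                end=end,
                insert_start=insert_start,
                insert_end=r,
                full_sequence=bases[f:end],
                insert_sequence=bases[insert_start:r],
            ))
    if both_strands:
        rc = reverse_complement(bases)
        for amp in in_silico_pcr(rc, fwd, rev, max_mismatch, both_strands=False):
            products.append(amp)
    return products


@dataclass
class ConservationProfile:
    """Per-column entropy profile of an alignment.

    ``entropy`` is the Shannon entropy (bits) of the column's A/C/G/T
    frequencies, ``percent_of_max`` is 100·H/2, and ``smoothed`` its
    centered moving average.  Fully conserved columns are flagged with
    their A/T vs G/C class.
    """

    entropy: np.ndarray
    percent_of_max: np.ndarray
    smoothed: np.ndarray
    window: int
    conserved_class: list[str | None]   # "A/T", "G/C" or None per column


def conservation_profile(
    alignment: Sequence[NucSequence],
    window: int = 11,
) -> ConservationProfile:
    """Column-wise conservation of an alignment as percent of maximum entropy."""
    if not alignment:
        raise ValueError("empty alignment")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    lengths = {s.raw_length for s in alignment}
    if len(lengths) > 1:
        raise ValueError("alignment rows must have equal raw length")
    ncol = lengths.pop()
    entropy = np.zeros(ncol)
    conserved: list[str | None] = []
    for j in range(ncol):
        counts = {"A": 0, "C": 0, "G": 0, "T": 0}
        for s in alignment:
            c = s.bases[j]
            if c in counts:
                counts[c] += 1
        total = sum(counts.values())
        if total == 0:
            entropy[j] = 0.0
            conserved.append(None)
            continue
        h = 0.0
        for n in counts.values():
            if n:
                p = n / total
                h -= p * math.log2(p)
        entropy[j] = h
        nonzero = [b for b, n in counts.items() if n]
        if len(nonzero) == 1:
            conserved.append("A/T" if nonzero[0] in "AT" else "G/C")
        else:
            conserved.append(None)
    percent = entropy / 2.0 * 100.0
    half = window // 2
    smoothed = np.array([
        percent[max(0, j - half): j + half + 1].mean() for j in range(ncol)
    ])
    return ConservationProfile(entropy, percent, smoothed, window, conserved)


def read_primer_tsv(path) -> list[DegeneratePrimer]:
    """Primer table: name <TAB> sequence <TAB> orientation."""
    primers = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: expected 3 columns")
            primers.append(DegeneratePrimer(parts[0], parts[1], parts[2]))
    return primers
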