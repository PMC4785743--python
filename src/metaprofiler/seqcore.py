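"""Core sequence, taxonomy and pairwise-identity primitives.

Every other module builds on the three domain objects defined here — a
nucleotide sequence over the IUPAC alphabet (:class:`NucSequence`), a ranked
taxonomy lineage (:class:`TaxonLineage`) and their combination into a
reference-database record (:class:`ReferenceRecord`) — plus the two identity
computations used throughout: column-wise percent identity on pre-aligned
sequences and global-alignment percent identity on unaligned ones.

Identity conventions
--------------------
* The comparable-column denominator excludes columns where either sequence
  carries a gap (``-``) or missing-data (``.``) mark (pairwise deletion).
  ``gap_as_mismatch=True`` switches internal gap columns to counting as
  mismatches instead.
* IUPAC ambiguity codes match whenever their base sets intersect
  (``W`` matches ``A``); ``strict=True`` demands identical concrete bases.
* Identities are percentages in [0, 100]; reports print them to 2 dp.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# Alphabet
# ---------------------------------------------------------------------------

#: 4-bit base-set encoding: A=1, C=2, G=4, T=8; ambiguity codes are unions.
IUPAC_MASK: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 4 | 2, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
    "-": 0, ".": 0,
}

#: Expansion of each code into its concrete base set.
IUPAC_SET: dict[str, frozenset[str]] = {
    code: frozenset(b for b, m in (("A", 1), ("C", 2), ("G", 4), ("T", 8)) if mask & m)
    for code, mask in IUPAC_MASK.items()
}

_COMPLEMENT_TABLE = str.maketrans(
    "ACGTRYSWKMBDHVN-.", "TGCAYRSWMKVHDBN-."
)

#: Pairs of distinct symbols whose base sets intersect, for alignment engines
#: that take an explicit equality relation.
AMBIGUITY_EQUALITIES: list[tuple[str, str]] = [
    (a, b)
    for a in IUPAC_MASK
    for b in IUPAC_MASK
    if a < b and IUPAC_MASK[a] & IUPAC_MASK[b]
]

_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _c, _m in IUPAC_MASK.items():
    _MASK_LUT[ord(_c)] = _m
    _MASK_LUT[ord(_c.lower())] = _m

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def reverse_complement(bases: str) -> str:
    """Reverse complement preserving ambiguity codes and gap marks."""
    return bases.translate(_COMPLEMENT_TABLE)[::-1]


def base_masks(bases: str) -> np.ndarray:
    """Encode a sequence as a uint8 vector of 4-bit base-set masks."""
    return _MASK_LUT[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "suborder", "family", "species",
)

UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class NucSequence:
    """A labelled nucleotide sequence over the IUPAC alphabet.

    ``bases`` may contain alignment gaps (``-``) and missing-end marks
    (``.``); input is case-normalized to upper case and ``U`` mapped to
    ``T``.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        norm = self.bases.upper().replace("U", "T")
        if not norm:
            raise ValueError(f"sequence {self.id!r}: empty bases")
        bad = set(norm) - set(IUPAC_MASK)
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: invalid characters {sorted(bad)!r}"
            )
        object.__setattr__(self, "bases", norm)

    def length(self) -> int:
        """Number of non-gap, non-missing characters."""
        return sum(1 for c in self.bases if c not in "-.")

    @property
    def raw_length(self) -> int:
        """Number of characters including gaps/missing marks."""
        return len(self.bases)

    def degapped(self) -> "NucSequence":
        return NucSequence(self.id, self.bases.replace("-", "").replace(".", ""))

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id, reverse_complement(self.bases))


@dataclass(frozen=True)
class TaxonLineage:
    """An ordered lineage over the fixed rank system ``RANKS``.

    Labels may carry the reserved token :data:`UNRESOLVED`.  Two lineages
    *agree* at a rank iff both labels are resolved and equal; a comparison
    involving an unresolved label is undefined (``None``), not a mismatch.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(RANKS):
            raise ValueError(
                f"lineage needs {len(RANKS)} labels ({', '.join(RANKS)}), "
                f"got {len(self.labels)}"
            )

    @classmethod
    def from_string(cls, text: str, sep: str = ";") -> "TaxonLineage":
        """Parse a separator-joined lineage, padding missing tail ranks."""
        parts = [p.strip() or UNRESOLVED for p in text.split(sep)]
        if len(parts) > len(RANKS):
            raise ValueError(f"lineage {text!r} has more than {len(RANKS)} ranks")
        parts += [UNRESOLVED] * (len(RANKS) - len(parts))
        return cls(tuple(parts))

    def to_string(self, sep: str = ";") -> str:
        return sep.join(self.labels)

    def get(self, rank: str) -> str:
        return self.labels[RANKS.index(rank)]

    def is_resolved(self, rank: str) -> bool:
        return self.get(rank) != UNRESOLVED

    def agree_at(self, other: "TaxonLineage", rank: str) -> bool | None:
        """True/False when both resolved at ``rank``; None otherwise."""
        a, b = self.get(rank), other.get(rank)
        if a == UNRESOLVED or b == UNRESOLVED:
            return None
        return a == b


@dataclass(frozen=True)
class ReferenceRecord:
    """A marker sequence with its taxonomy; the unit of the reference DB."""

    seq: NucSequence
    lineage: TaxonLineage
    is_phototroph: bool = True

    @property
    def id(self) -> str:
        return self.seq.id


# ---------------------------------------------------------------------------
# Percent identity
# ---------------------------------------------------------------------------

def _cigar_ops(cigar: str) -> dict[str, int]:
    ops = {"=": 0, "X": 0, "I": 0, "D": 0}
    for n, op in _CIGAR_RE.findall(cigar):
        ops[op] += int(n)
    return ops


def aligned_identity(
    a: str,
    b: str,
    strict: bool = False,
    gap_as_mismatch: bool = False,
) -> float:
    """Column-wise percent identity of two equal-length alignment rows."""
    if len(a) != len(b):
        raise ValueError(
            f"aligned mode requires equal raw lengths ({len(a)} vs {len(b)})"
        )
    ma, mb = base_masks(a), base_masks(b)
    both = (ma > 0) & (mb > 0)
    if strict:
        concrete = np.isin(ma, (1, 2, 4, 8)) & np.isin(mb, (1, 2, 4, 8))
        matches = both & concrete & (ma == mb)
    else:
        matches = (ma & mb) > 0
    n_match = int(matches.sum())
    if gap_as_mismatch:
        comparable = int(((ma > 0) | (mb > 0)).sum())
    else:
        comparable = int(both.sum())
    if comparable == 0:
        raise ValueError("no overlap: zero comparable columns")
    return 100.0 * n_match / comparable


def global_identity(a: str, b: str, strict: bool = False) -> float:
    """Percent identity after an end-to-end (Needleman–Wunsch, unit-cost)
    alignment; indel columns are excluded from the denominator."""
    a = a.replace("-", "").replace(".", "")
    b = b.replace("-", "").replace(".", "")
    if not a or not b:
        raise ValueError("no overlap: empty sequence in global mode")
    eq = None if strict else AMBIGUITY_EQUALITIES
    res = edlib.align(a, b, mode="NW", task="path", additionalEqualities=eq)
    ops = _cigar_ops(res["cigar"])
    comparable = ops["="] + ops["X"]
    if comparable == 0:
        raise ValueError("no overlap: alignment has no substitution columns")
    return 100.0 * ops["="] / comparable


def percent_identity(
    a: NucSequence | str,
    b: NucSequence | str,
    mode: str = "aligned",
    strict: bool = False,
    gap_as_mismatch: bool = False,
) -> float:
    """Percent identity between two sequences.

    ``mode="aligned"`` treats the inputs as rows of one alignment (equal raw
    length required); ``mode="global-align"`` computes an end-to-end
    alignment first.  Symmetric in its arguments.
    """
    sa = a.bases if isinstance(a, NucSequence) else a
    sb = b.bases if isinstance(b, NucSequence) else b
    if mode == "aligned":
        return aligned_identity(sa, sb, strict=strict, gap_as_mismatch=gap_as_mismatch)
    if mode == "global-align":
        return global_identity(sa, sb, strict=strict)
    raise ValueError(f"unknown mode {mode!r}")


def levenshtein(a: str, b: str, max_distance: int | None = None) -> int:
    """Unit-cost edit distance; -1 if ``max_distance`` is set and exceeded."""
    k = -1 if max_distance is None else max_distance
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


# ---------------------------------------------------------------------------
# Identity matrix over an alignment window
# ---------------------------------------------------------------------------

@dataclass
class IdentityMatrix:
    """Pairwise identity matrix over the surviving records of an alignment."""

    ids: list[str]
    matrix: np.ndarray
    excluded: list[str] = field(default_factory=list)

    def identity(self, id_a: str, id_b: str) -> float:
        return float(self.matrix[self.ids.index(id_a), self.ids.index(id_b)])


def _end_missing(bases: str) -> tuple[int, int]:
    lead = len(bases) - len(bases.lstrip("-."))
    trail = len(bases) - len(bases.rstrip("-."))
    return lead, trail


def identity_matrix(
    records: Sequence[ReferenceRecord] | Sequence[NucSequence],
    max_end_missing: int = 20,
    strict: bool = False,
    gap_as_mismatch: bool = False,
) -> IdentityMatrix:
    """All-pairs aligned identity over one alignment window.

    Records with more than ``max_end_missing`` gap/missing characters at
    either end are excluded (they would inflate identities computed under
    pairwise deletion) and reported in ``excluded``.
    """
    seqs = [r.seq if isinstance(r, ReferenceRecord) else r for r in records]
    lengths = {s.raw_length for s in seqs}
    if len(lengths) > 1:
        raise ValueError("records must share one alignment coordinate system")
    kept, excluded = [], []
    for s in seqs:
        lead, trail = _end_missing(s.bases)
        if lead > max_end_missing or trail > max_end_missing:
            excluded.append(s.id)
        else:
            kept.append(s)
    if len(kept) < 2:
        raise ValueError(
            f"fewer than 2 records survive the end-missing filter "
            f"({len(kept)} kept, {len(excluded)} excluded)"
        )
    masks = np.stack([base_masks(s.bases) for s in kept])
    present = masks > 0
    n = len(kept)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        inter = masks[i] & masks[i + 1:]
        both = present[i] & present[i + 1:]
        if strict:
            concrete_i = np.isin(masks[i], (1, 2, 4, 8))
            concrete_j = np.isin(masks[i + 1:], (1, 2, 4, 8))
            match = both & concrete_i & concrete_j & (masks[i] == masks[i + 1:])
        else:
            match = inter > 0
        n_match = match.sum(axis=1)
        if gap_as_mismatch:
            denom = (present[i] | present[i + 1:]).sum(axis=1)
        else:
            denom = both.sum(axis=1)
        if np.any(denom == 0):
            j = int(np.argmax(denom == 0)) + i + 1
            raise ValueError(
                f"no overlap between records {kept[i].id!r} and {kept[j].id!r}"
            )
        mat[i, i + 1:] = mat[i + 1:, i] = 100.0 * n_match / denom
    return IdentityMatrix([s.id for s in kept], mat, excluded)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[NucSequence]:
    return [NucSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[NucSequence], path: str | Path, wrap: int | None = None) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        if wrap is None:
            for rec in records:
                fh.write(f">{rec.id}\n{rec.seq}\n")
        else:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
            writer.write_file(records)


def read_taxonomy_tsv(path: str | Path) -> dict[str, tuple[TaxonLineage, bool]]:
    """Read the taxonomy sidecar: id <TAB> lineage <TAB> phototroph{0,1}."""
    table: dict[str, tuple[TaxonLineage, bool]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected at least 2 columns")
            seq_id, lineage = parts[0], TaxonLineage.from_string(parts[1])
            photo = bool(int(parts[2])) if len(parts) > 2 and parts[2] != "" else True
            if seq_id in table:
                raise ValueError(f"{path}:{line_no}: duplicate id {seq_id!r}")
            table[seq_id] = (lineage, photo)
    return table


def write_taxonomy_tsv(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.id}\t{rec.lineage.to_string()}\t{int(rec.is_phototroph)}\n")


def load_reference_db(fasta_path: str | Path, taxonomy_path: str | Path) -> list[ReferenceRecord]:
    """Pair an alignment/sequence FASTA with its taxonomy TSV.

    Raises with the offending ids listed on any mismatch between the files.
    """
    seqs = read_fasta(fasta_path)
    taxa = read_taxonomy_tsv(taxonomy_path)
    missing = [s.id for s in seqs if s.id not in taxa]
    if missing:
        raise ValueError(f"ids missing from taxonomy table: {missing}")
    return [
        ReferenceRecord(seq=s, lineage=taxa[s.id][0], is_phototroph=taxa[s.id][1])
        for s in seqs
    ]
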