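"""Synthetic fixture generation: taxonomy-structured reference databases and
amplicon sequencing runs with controlled, fully logged ground truth.

The generator emulates the data a metabarcoding study consumes without any
download.  A root metabarcode sequence evolves down the rank hierarchy by
copy-with-substitutions: sibling clades at a rank are separated by a planned
number of substitutions, so per-rank identity bands are controllable.  Reads
are then drawn from a per-sample species multinomial, wrapped in index +
forward-primer + conserved flanks, split into overlapping paired-end reads,
and corrupted with per-base substitution errors; two-parent chimeras and
random off-target contaminants are injected at configurable rates.

Everything is substitution-only by default (so Hamming and Levenshtein
coincide on fixtures); an indel knob exists to exercise alignment paths.
Every stochastic event is recorded in a :class:`SimManifest`, and all
sampling derives from one seed, so identical configs reproduce identical
files bit for bit.  Tests compare against *realized* divergences from the
manifest, not the nominal plan, because substitution positions can collide.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .readproc import ReadPair
from .seqcore import (
    RANKS,
    NucSequence,
    ReferenceRecord,
    TaxonLineage,
    aligned_identity,
    reverse_complement,
)

__all__ = ["SimConfig", "SimManifest", "simulate_reference_db", "simulate_reads"]

_BASES = "ACGT"

#: Fixed synthetic metabarcoding primer pair (forward as sequenced, reverse
#: as written 5'→3' on its own strand).
DEFAULT_FWD_PRIMER = "TGGGTAGAGAAGATTTACAACTTG"
DEFAULT_REV_PRIMER = "TTACATCAGTTGTTCGTACATAGA"


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    ``rank_subs`` holds the target substitution separation between sibling
    clades at each rank (each child branch receives half), over a
    ``marker_length`` bp metabarcode; the plan must increase strictly with
    rank height so identity bands are separable.  ``children`` gives the
    number of child clades per node at each rank below domain (the domain
    count is the length of ``domains``).  Defaults are desk-scale: a
    two-domain, 48-species database and two samples of 400 reads each with a
    MiSeq-like 0.1 % per-base substitution error rate.
    """

    seed: int = 1
    marker_length: int = 375
    domains: tuple[str, ...] = ("Eukaryota", "Bacteria")
    children: dict = field(default_factory=lambda: {
        "phylum": 2, "class": 2, "order": 2, "suborder": 1,
        "family": 2, "species": 2,
    })
    records_per_species: int = 1
    haplotype_subs: int = 1
    rank_subs: dict = field(default_factory=lambda: {
        "domain": 100, "phylum": 76, "class": 62, "order": 50,
        "suborder": 40, "family": 30, "species": 20,
    })
    indel_rate: float = 0.0

    # read simulation
    samples: dict = field(default_factory=lambda: {
        "S1": {"fraction_of_species": 0.25, "reads": 600},
        "S2": {"fraction_of_species": 0.25, "reads": 600},
    })
    community_alpha: float = 5.0
    index_length: int = 8
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER
    pad5_length: int = 20        # conserved 5' stretch cropped by trimming
    pad3_length: int = 50        # conserved 3' stretch (incl. reverse primer)
    read_length: int = 250
    base_quality: int = 38
    error_rate: float = 0.001
    chimera_rate: float = 0.0
    contaminant_rate: float = 0.0

    def validate(self) -> None:
        order = [r for r in RANKS if r in self.rank_subs]
        values = [self.rank_subs[r] for r in order]
        all_zero = all(v == 0 for v in values)   # degenerate: no divergence at all
        if not all_zero and any(a <= b for a, b in zip(values, values[1:])):
            raise ValueError(
                "rank_subs must strictly decrease from domain to species "
                f"(got {self.rank_subs})"
            )
        for rate in (self.error_rate, self.chimera_rate, self.contaminant_rate,
                     self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rates must lie in [0, 1], got {rate}")
        if self.pad3_length < len(self.rev_primer):
            raise ValueError("pad3_length must cover the reverse primer")


@dataclass
class SimManifest:
    """Ground truth for every generated record and read."""

    config: dict
    root_sequence: str = ""
    lineages: dict = field(default_factory=dict)        # record id -> lineage str
    species_sequences: dict = field(default_factory=dict)
    record_sequences: dict = field(default_factory=dict)
    band_warning: bool = False
    sample_indexes: dict = field(default_factory=dict)  # sample -> index
    community: dict = field(default_factory=dict)       # sample -> {species: prob}
    reads: dict = field(default_factory=dict)           # read id -> event dict
    chimeras: list = field(default_factory=list)
    contaminants: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    # -- realized divergence oracles -------------------------------------

    def realized_rank_identities(self, rank: str) -> tuple[list[float], list[float]]:
        """(intra, inter) identity lists at ``rank`` from the generated
        record sequences — the oracle for threshold recovery tests."""
        ids = sorted(self.record_sequences)
        rank_pos = RANKS.index(rank)
        intra, inter = [], []
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                ident = aligned_identity(
                    self.record_sequences[a], self.record_sequences[b]
                )
                same = (
                    self.lineages[a].split(";")[rank_pos]
                    == self.lineages[b].split(";")[rank_pos]
                )
                (intra if same else inter).append(ident)
        return intra, inter

    def realized_max_inter_identity(self, rank: str) -> float:
        _, inter = self.realized_rank_identities(rank)
        if not inter:
            raise ValueError(f"no inter-clade pair at rank {rank!r}")
        return max(inter)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _mutate(
    rng: np.random.Generator,
    seq: str,
    n_subs: int,
    forbidden: set[int] | None = None,
) -> tuple[str, list[int]]:
    """Copy with ``n_subs`` substitutions at distinct positions (avoiding
    ``forbidden`` when possible)."""
    pool = [i for i in range(len(seq)) if not forbidden or i not in forbidden]
    if len(pool) < n_subs:
        pool = list(range(len(seq)))
    positions = sorted(rng.choice(len(pool), size=n_subs, replace=False))
    chars = list(seq)
    hit = []
    for p in positions:
        i = pool[p]
        chars[i] = rng.choice([b for b in _BASES if b != chars[i]])
        hit.append(i)
    return "".join(chars), hit


def simulate_reference_db(
    cfg: SimConfig,
) -> tuple[list[ReferenceRecord], SimManifest]:
    """Generate a taxonomy-structured reference database.

    A root metabarcode evolves down domain → species; each child clade at a
    rank receives ``rank_subs[rank] // 2`` substitutions from its parent
    consensus, and each record ``haplotype_subs`` more from its species
    consensus.  Records in the domain ``"Bacteria"`` are heterotrophs, all
    others phototrophs.  The manifest flags plans whose realized bands
    overlap (species band overlapping the family band) instead of failing.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    root = _random_sequence(rng, cfg.marker_length)
    manifest = SimManifest(config=dataclasses.asdict(cfg), root_sequence=root)

    records: list[ReferenceRecord] = []
    lower_ranks = RANKS[1:]

    def recurse(
        rank_idx: int, consensus: str, labels: list[str], lineage_hits: set[int]
    ) -> None:
        if rank_idx == len(RANKS):
            species_label = labels[-1]
            manifest.species_sequences[species_label] = consensus
            for h in range(cfg.records_per_species):
                bases, _ = (
                    _mutate(rng, consensus, cfg.haplotype_subs, lineage_hits)
                    if cfg.haplotype_subs else (consensus, [])
                )
                rec_id = f"{species_label}_h{h + 1}"
                lineage = TaxonLineage(tuple(labels))
                records.append(ReferenceRecord(
                    seq=NucSequence(rec_id, bases),
                    lineage=lineage,
                    is_phototroph=labels[0] != "Bacteria",
                ))
                manifest.lineages[rec_id] = lineage.to_string()
                manifest.record_sequences[rec_id] = bases
            return
        rank = RANKS[rank_idx]
        n_children = cfg.children.get(rank, 1)
        per_branch = -(-cfg.rank_subs[rank] // 2)   # ceil(k/2); 0 stays 0
        for c in range(n_children):
            # substitutions avoid positions already hit along this lineage,
            # so planned separations are not eroded by back-substitutions
            child_seq, hit = _mutate(rng, consensus, per_branch, lineage_hits)
            prefix = labels[-1] if labels else "root"
            label = f"{prefix}.{rank[:3]}{c + 1}" if labels else f"{rank[:3]}{c + 1}"
            recurse(rank_idx + 1, child_seq, labels + [label], lineage_hits | set(hit))

    for d, domain in enumerate(cfg.domains):
        per_branch = -(-cfg.rank_subs["domain"] // 2)
        domain_seq, hit = _mutate(rng, root, per_branch)
        recurse(1, domain_seq, [domain], set(hit))

    # band-separation check: species band must stay above the family band
    try:
        intra_sp, _ = manifest.realized_rank_identities("species")
        _, inter_fam = manifest.realized_rank_identities("family")
        if intra_sp and inter_fam and min(intra_sp) <= max(inter_fam):
            manifest.band_warning = True
    except ValueError:
        pass
    return records, manifest


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _apply_errors(
    rng: np.random.Generator, bases: str, rate: float
) -> tuple[str, list[int]]:
    if rate <= 0.0:
        return bases, []
    chars = list(bases)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        chars[i] = rng.choice([b for b in _BASES if b != chars[i]])
    return "".join(chars), [int(i) for i in hits]


def _distinct_indexes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    while len(seen) < n:
        seen.add(_random_sequence(rng, length))
    return sorted(seen)


def simulate_reads(
    manifest: SimManifest,
    cfg: SimConfig,
) -> tuple[list[ReadPair], dict[str, str]]:
    """Simulate a paired-end metabarcoding run from a generated database.

    Each sample draws reads from a multinomial over a seeded subset of the
    database's species (``fraction_of_species`` of them, with Dirichlet
    weights).  A read's template is
    ``index + forward primer + 5' pad + species metabarcode + 3' pad``
    (the 3' pad starts with the reverse-complemented reverse primer); the
    paired reads are the template's first ``read_length`` bases and the
    reverse complement of its last ``read_length``.  Substitution errors
    are applied per read; chimeric and off-target templates replace normal
    ones at the configured rates.  Returns (pairs, sample→index table); all
    events land in the manifest.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 7_919)
    species = sorted(manifest.species_sequences)
    if not species:
        raise ValueError("manifest holds no species sequences")
    indexes = _distinct_indexes(rng, len(cfg.samples), cfg.index_length)
    manifest.sample_indexes = dict(zip(sorted(cfg.samples), indexes))

    pad5 = _random_sequence(rng, cfg.pad5_length)
    pad3 = reverse_complement(cfg.rev_primer) + _random_sequence(
        rng, cfg.pad3_length - len(cfg.rev_primer)
    )

    for sample in sorted(cfg.samples):
        spec = cfg.samples[sample]
        n_pick = max(1, round(spec.get("fraction_of_species", 1.0) * len(species)))
        picked = sorted(rng.choice(species, size=n_pick, replace=False))
        weights = rng.dirichlet(np.full(n_pick, cfg.community_alpha))
        manifest.community[sample] = {
            s: float(w) for s, w in zip(picked, weights)
        }

    pairs: list[ReadPair] = []
    for sample in sorted(cfg.samples):
        spec = cfg.samples[sample]
        index = manifest.sample_indexes[sample]
        comm = manifest.community[sample]
        picked = sorted(comm)
        probs = np.array([comm[s] for s in picked])
        n_reads = int(spec.get("reads", 400))
        draws = rng.choice(len(picked), size=n_reads, p=probs)
        for r, k in enumerate(draws):
            read_id = f"{sample}_r{r + 1}"
            event: dict = {"sample": sample, "kind": "normal",
                           "species": picked[int(k)]}
            u = rng.random()
            if u < cfg.chimera_rate:
                a, b = rng.choice(len(picked), size=2, replace=False)
                cross = int(rng.integers(80, cfg.marker_length - 80))
                core = (
                    manifest.species_sequences[picked[int(a)]][:cross]
                    + manifest.species_sequences[picked[int(b)]][cross:]
                )
                event = {"sample": sample, "kind": "chimera",
                         "parents": [picked[int(a)], picked[int(b)]],
                         "crossover": cross}
                manifest.chimeras.append(read_id)
            elif u < cfg.chimera_rate + cfg.contaminant_rate:
                core = _random_sequence(rng, cfg.marker_length)
                event = {"sample": sample, "kind": "contaminant"}
                manifest.contaminants.append(read_id)
            else:
                core = manifest.species_sequences[picked[int(k)]]
            template = index + cfg.fwd_primer + pad5 + core + pad3
            b1 = template[: cfg.read_length]
            b2 = reverse_complement(template[-cfg.read_length:])
            b1, err1 = _apply_errors(rng, b1, cfg.error_rate)
            b2, err2 = _apply_errors(rng, b2, cfg.error_rate)
            event["errors_r1"], event["errors_r2"] = err1, err2
            manifest.reads[read_id] = event
            q = (cfg.base_quality,) * cfg.read_length
            pairs.append(ReadPair(read_id, b1, q, b2, q))
    return pairs, dict(manifest.sample_indexes)


def write_run_files(
    records: Sequence[ReferenceRecord],
    manifest: SimManifest,
    pairs: Sequence[ReadPair],
    index_table: dict[str, str],
    outdir: str | Path,
) -> None:
    """Write the standard file set a real run would start from."""
    from .seqcore import write_fasta, write_taxonomy_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta((r.seq for r in records), outdir / "reference.fasta")
    write_taxonomy_tsv(records, outdir / "taxonomy.tsv")
    with open(outdir / "indexes.tsv", "w") as fh:
        for sample, index in sorted(index_table.items()):
            fh.write(f"{sample}\t{index}\n")
    with open(outdir / "reads_R1.fastq", "w") as fh1, \
            open(outdir / "reads_R2.fastq", "w") as fh2:
        for p in pairs:
            q1 = "".join(chr(q + 33) for q in p.quals1)
            q2 = "".join(chr(q + 33) for q in p.quals2)
            fh1.write(f"@{p.id}\n{p.bases1}\n+\n{q1}\n")
            fh2.write(f"@{p.id}\n{p.bases2}\n+\n{q2}\n")
    manifest.to_json(outdir / "manifest.json")
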