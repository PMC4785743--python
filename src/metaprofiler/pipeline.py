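"""Orchestration of the two workflows: a full metabarcoding run
(merge → demultiplex → filter → trim → dereplicate → denoise → chimera →
decontaminate → dual-cluster → core consensus → map → annotate) and
threshold calibration from a reference alignment.

Stage parameters live in :class:`PipelineConfig`; the defaults are the
canonical published pipeline settings (97 % global threshold, d = 10 local
threshold, expected error ≤ 0.5, 400–440 bp size window, 20/50 bp crops,
minimum abundance 4, abundance-cell floor 3).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import abundance as _abundance
from . import calibrate as _calibrate
from . import otucluster, readproc
from .otucluster import OTU, ClusterScan
from .primertools import DegeneratePrimer
from .readproc import MergedRead, PipelineLedger, ReadPair, UniqueAmplicon
from .seqcore import ReferenceRecord

__all__ = ["PipelineConfig", "RunResult", "CalibrationResult",
           "run_metabarcoding", "run_calibration"]

log = logging.getLogger("metaprofiler")


@dataclass
class PipelineConfig:
    """All stage parameters of the metabarcoding workflow."""

    merge_min_overlap: int = 16
    merge_max_mismatch_frac: float = 0.25
    primer_mismatch: int = 2
    max_expected_error: float = 0.5
    min_len: int = 400
    max_len: int = 440
    crop5: int = 20
    crop3: int = 50
    denoise_min_total: int = 4
    chimera_min_parent_gain: float = 3.0
    chimera_min_two_parent_identity: float = 99.0
    chimera_kmer_size: int = 8
    decontam_min_identity: float = 60.0
    decontam_min_coverage: float = 0.5
    global_threshold: float = 97.0
    local_d: int = 10
    map_threshold: float = 97.0
    cell_floor: int = 3
    run_d_scan: bool = False
    d_scan_values: tuple[int, ...] = tuple(range(1, 17))
    annotation_mode: str = "conservative"

    def validate(self) -> None:
        if self.crop5 + self.crop3 >= self.min_len:
            raise ValueError(
                f"crop5+crop3 ({self.crop5 + self.crop3}) must be < "
                f"min_len ({self.min_len})"
            )
        if not 50.0 < self.global_threshold <= 100.0:
            raise ValueError("global_threshold must lie in (50, 100]")
        if self.local_d < 1:
            raise ValueError("local_d must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "d_scan_values" in data:
            data["d_scan_values"] = tuple(data["d_scan_values"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class RunResult:
    """Everything a metabarcoding run produces."""

    ledger: PipelineLedger
    core_otus: list[OTU]
    global_otus: list[OTU]
    local_otus: list[OTU]
    table: _abundance.AbundanceTable | None
    annotations: dict[str, _calibrate.Annotation] = field(default_factory=dict)
    scan: ClusterScan | None = None
    amplicons: list[UniqueAmplicon] = field(default_factory=list)
    mapped_reads: list[MergedRead] = field(default_factory=list)


def run_metabarcoding(
    pairs: Sequence[ReadPair],
    index_table: Mapping[str, str],
    fwd_primer: DegeneratePrimer | str,
    references: Sequence[ReferenceRecord],
    config: PipelineConfig | None = None,
    thresholds: _calibrate.ThresholdSet | None = None,
) -> RunResult:
    """Execute the full read-to-annotated-OTU workflow.

    Reads surviving the quality filter (including the low-abundance
    sequences later removed by denoising) are kept aside for abundance
    mapping against the core OTUs.  Annotation runs only when a calibrated
    :class:`~metaprofiler.calibrate.ThresholdSet` is supplied.  An empty
    read set yields a ledger of zeros, no OTUs and no table.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    if isinstance(fwd_primer, str):
        fwd_primer = DegeneratePrimer("fwd", fwd_primer)

    ledger = PipelineLedger()
    ledger.add("raw", len(pairs))

    merged, _ = readproc.merge_pairs(
        pairs, cfg.merge_min_overlap, cfg.merge_max_mismatch_frac
    )
    ledger.add("paired_end_merging", len(merged))
    log.info("merged %d/%d pairs", len(merged), len(pairs))

    demuxed, _ = readproc.demultiplex(
        merged, dict(index_table), fwd_primer, cfg.primer_mismatch
    )
    ledger.add("demultiplexing", len(demuxed))

    hq, _ = readproc.quality_filter(demuxed, cfg.max_expected_error)
    ledger.add("quality_filter", len(hq))

    trimmed, _ = readproc.size_filter_and_trim(
        hq, cfg.min_len, cfg.max_len, cfg.crop5, cfg.crop3
    )
    ledger.add("size_filter", len(trimmed))

    amplicons = readproc.dereplicate(trimmed) if trimmed else []
    denoised, _ = readproc.denoise_by_abundance(amplicons, cfg.denoise_min_total)
    ledger.add("denoising", sum(a.total_count for a in denoised))

    if references and denoised:
        no_chim, _ = readproc.chimera_screen(
            denoised, references,
            cfg.chimera_min_parent_gain,
            cfg.chimera_min_two_parent_identity,
            cfg.chimera_kmer_size,
        )
        clean, _ = readproc.decontaminate(
            no_chim, references,
            cfg.decontam_min_identity, cfg.decontam_min_coverage,
        )
    else:
        clean = denoised
    ledger.add("decontamination", sum(a.total_count for a in clean))

    if not clean:
        return RunResult(
            ledger=ledger, core_otus=[], global_otus=[], local_otus=[],
            table=None, amplicons=[], mapped_reads=list(trimmed),
        )

    global_otus = otucluster.cluster_global(clean, cfg.global_threshold)
    local_otus = otucluster.cluster_local(clean, cfg.local_d)
    core = otucluster.core_consensus(global_otus, local_otus)
    log.info(
        "clustering: %d global, %d local, %d core OTUs",
        len(global_otus), len(local_otus), len(core),
    )

    scan = None
    if cfg.run_d_scan:
        scan = otucluster.d_scan(clean, global_otus, cfg.d_scan_values)

    table = _abundance.map_reads(
        trimmed, core, cfg.map_threshold, cfg.cell_floor
    ) if core else None

    annotations: dict[str, _calibrate.Annotation] = {}
    if thresholds is not None and core:
        for otu in core:
            annotations[otu.id] = _calibrate.annotate_otu(
                otu, references, thresholds, cfg.annotation_mode
            )

    return RunResult(
        ledger=ledger,
        core_otus=core,
        global_otus=global_otus,
        local_otus=local_otus,
        table=table,
        annotations=annotations,
        scan=scan,
        amplicons=clean,
        mapped_reads=list(trimmed),
    )


@dataclass
class CalibrationResult:
    thresholds: _calibrate.ThresholdSet
    divergences: dict[str, _calibrate.RankDivergence]
    hit_tables: dict[str, "object"]   # rank -> per-query best-hit DataFrame


def run_calibration(
    records: Sequence[ReferenceRecord],
    ranks: Sequence[str] = ("domain", "phylum", "class", "order", "suborder", "family"),
    low_rank_class: str | None = None,
    low_ranks: Sequence[str] = ("order", "suborder", "family"),
    max_end_missing: int = 20,
) -> CalibrationResult:
    """Calibrate thresholds from a reference alignment.

    With ``low_rank_class`` set, the low ranks are calibrated only within
    records of that class (the usual split: high ranks on all phototrophs,
    low ranks within one well-sampled class); other ranks use all records.
    """
    subsets = None
    if low_rank_class is not None:
        subset = [r for r in records if r.lineage.get("class") == low_rank_class]
        if len(subset) < 2:
            raise ValueError(
                f"class {low_rank_class!r} has {len(subset)} record(s); "
                "cannot calibrate low ranks on it"
            )
        subsets = {rank: subset for rank in low_ranks}
    thresholds, divergences = _calibrate.calibrate_thresholds(
        records, ranks=ranks, subsets=subsets, max_end_missing=max_end_missing
    )
    hit_tables = {}
    for rank in ranks:
        source = subsets[rank] if subsets and rank in subsets else records
        _, table = _calibrate.relaxed_threshold(
            source, rank, max_end_missing=max_end_missing
        )
        hit_tables[rank] = table
    return CalibrationResult(thresholds, divergences, hit_tables)
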