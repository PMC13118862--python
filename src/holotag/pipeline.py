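"""End-to-end orchestration of the holobiont tag workflow.

These functions chain the per-module operations into the three runs a
study needs -- database construction, per-sample processing, and cohort
analysis -- and are shared by the command-line interface, the test
suite and the reproduction script.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import fastpath
from .enzyme import BCGI, EnzymeSpec, digest_genome
from .errors import InputError
from .holodb import (
    GenomeEntry,
    RemovalReport,
    TagDatabase,
    TaxonLineage,
    assign_specificity,
    build_host_tagset,
    cross_deredundancy,
    db_statistics,
    genome_entry_from_digest,
    single_copy_tags,
)
from .genotyper import GenotypeCall, assign_to_loci, call_sample
from .profiler import (
    AbundanceProfile,
    ClassifiedSample,
    classify_observations,
    relative_abundance,
    species_evidence,
)
from .reads import (
    DropReport,
    ReadRecord,
    TagObservations,
    extract_read_tags,
    quality_filter,
)

__all__ = [
    "BuildResult",
    "SampleResult",
    "build_database",
    "process_reads",
    "process_read_matrix",
    "run_sample",
]


@dataclass
class BuildResult:
    db: TagDatabase
    entries: list[GenomeEntry]
    removal: RemovalReport
    statistics: dict


def build_database(
    genomes: Sequence[tuple[str, Sequence[tuple[str, str]]]],
    lineages: Mapping[str, TaxonLineage],
    host_records: Sequence[tuple[str, str]],
    enzyme: EnzymeSpec = BCGI,
    host_id: str = "host",
) -> BuildResult:
    """Digest -> single-copy -> specificity -> host set -> cross
    de-redundancy, with full genome accounting."""
    genome_tags: dict[str, set[str]] = {}
    entries: list[GenomeEntry] = []
    for gid, records in genomes:
        if gid not in lineages:
            raise InputError(f"genome {gid!r} has no lineage")
        summary = digest_genome(records, gid, enzyme)
        entry = genome_entry_from_digest(summary, lineages[gid])
        entries.append(entry)
        if entry.status == "included":
            genome_tags[gid] = single_copy_tags(summary)
    db = assign_specificity(genome_tags, lineages, enzyme)

    host_summary = digest_genome(host_records, host_id, enzyme)
    host_tags, host_stats = build_host_tagset(host_summary)
    entries.append(
        GenomeEntry(
            genome_id=host_id,
            lineage=None,
            source="host",
            n_total_tags=host_summary.total,
            n_single_copy_tags=len(host_tags),
        )
    )
    db, removal = cross_deredundancy(db, host_tags)
    for entry in entries:
        if entry.genome_id in removal.genomes_removed:
            entry.status = "removed_by_deredundancy"
    stats = db_statistics(db, entries)
    stats["host_tags_before_deredundancy"] = removal.host_tags_before
    stats["host_tags_after_deredundancy"] = removal.host_tags_retained
    stats.update({f"host_{k}": v for k, v in host_stats.items()})
    return BuildResult(db=db, entries=entries, removal=removal,
                       statistics=stats)


@dataclass
class SampleResult:
    """Everything one sample yields: QC, routing, profile, genotypes."""

    sample_id: str
    n_raw_reads: int
    drop_report: DropReport | dict
    observations: TagObservations
    classified: ClassifiedSample
    profile: AbundanceProfile
    genotype_calls: dict[str, GenotypeCall]
    n_ambiguous_host_obs: int = 0

    def qc_summary(self) -> dict:
        """Per-sample sequencing summary (raw reads, high-quality reads
        and rate, site-bearing tags, host/microbial mapping rates)."""
        dropped = (
            self.drop_report.total
            if isinstance(self.drop_report, DropReport)
            else sum(self.drop_report.values())
        )
        hq = self.n_raw_reads - dropped
        return {
            "sample_id": self.sample_id,
            "raw_reads": self.n_raw_reads,
            "high_quality_reads": hq,
            "high_quality_rate": hq / self.n_raw_reads
            if self.n_raw_reads
            else 0.0,
            "tags_with_site": self.observations.n_reads_with_site,
            "mapping_rate_host": self.classified.mapping_rate_host,
            "mapping_rate_microbial": self.classified.mapping_rate_microbial,
        }


def process_reads(
    reads: Sequence[ReadRecord],
    enzyme: EnzymeSpec,
    low_q: int = 10,
    max_low_frac: float = 0.20,
    max_homopolymer: int = 10,
) -> tuple[int, DropReport, TagObservations]:
    """String-path QC + tag extraction."""
    reads = list(reads)
    kept, report = quality_filter(reads, low_q, max_low_frac,
                                  max_homopolymer)
    obs = extract_read_tags(kept, enzyme)
    return len(reads), report, obs


def process_read_matrix(
    seqs: np.ndarray,
    quals: np.ndarray,
    enzyme: EnzymeSpec,
    low_q: int = 10,
    max_low_frac: float = 0.20,
    max_homopolymer: int = 10,
) -> tuple[int, dict, TagObservations]:
    """Vectorized QC + tag extraction over a fixed-length read matrix
    (same semantics as :func:`process_reads`)."""
    keep, report = fastpath.quality_filter_matrix(
        seqs, quals, low_q, max_low_frac, max_homopolymer
    )
    kept = seqs[keep]
    windows, found = fastpath.extract_tags_matrix(kept, enzyme)
    obs = TagObservations(
        counts=fastpath.tag_counts_from_matrix(windows),
        n_reads_with_site=int(found.sum()),
        n_reads_without_site=int((~found).sum()),
        enzyme=enzyme,
    )
    return seqs.shape[0], report, obs


def run_sample(
    n_raw: int,
    drop_report,
    obs: TagObservations,
    db: TagDatabase,
    sample_id: str = "sample",
    g_threshold: float = 5.0,
    min_depth: int = 4,
    err: float = 0.01,
    max_mismatch: int = 2,
) -> SampleResult:
    """Classify extracted observations and run both analysis streams."""
    classified = classify_observations(obs.counts, db, sample_id)
    evidence = species_evidence(classified.microbial_obs, db)
    profile = relative_abundance(
        evidence, db.theoretical_counts, sample_id, g_threshold
    )
    # Genotyping also considers unassigned tags: a read carrying a host
    # SNP allele or a sequencing error is not an exact member of the
    # host set but still aligns to its locus within max_mismatch.
    host_stream = Counter(classified.host_obs)
    host_stream.update(classified.unassigned_obs)
    loci = sorted(db.host_tags)
    pileups, ambiguous = assign_to_loci(host_stream, loci, max_mismatch)
    calls = call_sample(pileups, loci, min_depth, err)
    return SampleResult(
        sample_id=sample_id,
        n_raw_reads=n_raw,
        drop_report=drop_report,
        observations=obs,
        classified=classified,
        profile=profile,
        genotype_calls=calls,
        n_ambiguous_host_obs=ambiguous,
    )
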