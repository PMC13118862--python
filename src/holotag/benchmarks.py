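"""Validation studies: parameter-recovery experiments on synthetic
holobiont data.

Each function sets up a study condition with the synthetic-data
generator, runs the full pipeline on it, and returns the measured
quantities (correlations, detection counts, genotype accuracies).
They back both the acceptance test suite and the reproduction script,
so the numbers those report are always recomputed from scratch.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .enzyme import BCGI, EnzymeSpec
from .genotyper import concordance
from .holodb import TagDatabase
from .pipeline import BuildResult, build_database, process_read_matrix, run_sample
from .profiler import replicate_concordance
from .reads import TagObservations
from .simulate import (
    HostTruth,
    MicrobialTruth,
    SimConfig,
    simulate_diploid_host,
    simulate_genomes,
    simulate_reads,
)

__all__ = [
    "build_world",
    "profile_simulated_sample",
    "abundance_recovery_study",
    "replicate_concordance_study",
    "genotype_recovery_study",
]


def build_world(
    cfg: SimConfig, enzyme: EnzymeSpec = BCGI
) -> tuple[MicrobialTruth, HostTruth, BuildResult]:
    """Simulate genomes + diploid host and build their holo-DB."""
    mic = simulate_genomes(cfg, enzyme)
    host = simulate_diploid_host(cfg, enzyme)
    build = build_database(
        [(gid, [(gid, seq)]) for gid, seq in mic.genomes],
        mic.lineages,
        [("host_reference", host.reference)],
        enzyme,
    )
    return mic, host, build


def profile_simulated_sample(
    mic: MicrobialTruth,
    host: HostTruth,
    build: BuildResult,
    cfg: SimConfig,
    read_seed: int,
    chunk_reads: int = 2_000_000,
    sample_id: str = "sample",
    genotype: bool = False,
):
    """Simulate ``cfg.total_reads`` reads in independent draws of at
    most *chunk_reads* (bounding memory) and run them through QC,
    extraction and classification as one sample."""
    merged = TagObservations(enzyme=BCGI)
    drop: dict[str, int] = {"n_base": 0, "homopolymer": 0,
                            "low_quality": 0}
    n_total = 0
    remaining = cfg.total_reads
    draw = 0
    while remaining > 0:
        take = min(chunk_reads, remaining)
        sub = dataclasses.replace(cfg, total_reads=take)
        sim = simulate_reads(mic, host, sub,
                             read_seed=read_seed + draw)
        n, rep, obs = process_read_matrix(sim.seqs, sim.quals, BCGI)
        n_total += n
        for k in drop:
            drop[k] += rep[k]
        merged.counts.update(obs.counts)
        merged.n_reads_with_site += obs.n_reads_with_site
        merged.n_reads_without_site += obs.n_reads_without_site
        remaining -= take
        draw += 1
    result = run_sample(n_total, drop, merged, build.db, sample_id)
    if not genotype:
        result.genotype_calls = {}
    return result


def abundance_recovery_study(
    seed: int,
    total_reads: int = 20_000_000,
    host_fraction: float = 0.99,
    chunk_reads: int = 2_000_000,
) -> dict:
    """The host-contamination recovery condition: a 20-species
    log-normal community hidden behind ~99% host reads at 0.5%
    sequencing error. Measures how well relative abundances and
    species presence are recovered."""
    cfg = SimConfig(seed=seed, total_reads=total_reads,
                    host_fraction=host_fraction)
    mic, host, build = build_world(cfg)
    result = profile_simulated_sample(
        mic, host, build, cfg, read_seed=seed + 1,
        chunk_reads=chunk_reads,
    )
    prof = result.profile
    est = np.array([prof.abundance.get(sp, 0.0)
                    for sp in mic.species_labels])
    r = float(np.corrcoef(mic.abundance, est)[0, 1])
    detected = set(prof.abundance)
    evidence = prof.evidence
    missed_with_evidence = [
        sp for sp, e in evidence.items()
        if e.reads >= 25 and e.tags_hit >= 1 and sp not in detected
    ]
    low_g = [sp for sp, e in evidence.items()
             if e.reads >= 25 and e.tags_hit >= 1 and e.g_score < 5.0]
    return {
        "pearson_r": r,
        "sum_abundance": float(sum(prof.abundance.values())),
        "n_species_true": cfg.n_species,
        "n_species_detected": len(detected),
        "n_false_species": len(detected - set(mic.species_labels)),
        "n_missed_with_evidence": len(missed_with_evidence),
        "n_low_g_with_evidence": len(low_g),
        "n_microbial_reads": result.classified.microbial_count,
        "mapping_rate_host": result.classified.mapping_rate_host,
        "mapping_rate_microbial": result.classified.mapping_rate_microbial,
    }


def replicate_concordance_study(
    seed: int,
    microbial_reads: int = 200_000,
    host_fraction: float = 0.5,
) -> dict:
    """Two technical replicates of one community truth (independent
    read draws): shared species and abundance correlation."""
    total = int(round(microbial_reads / (1 - host_fraction)))
    cfg = SimConfig(seed=seed, total_reads=total,
                    host_fraction=host_fraction)
    mic, host, build = build_world(cfg)
    profiles = []
    for rep in (1, 2):
        result = profile_simulated_sample(
            mic, host, build, cfg, read_seed=seed + 1000 * rep,
            sample_id=f"rep{rep}",
        )
        profiles.append(result.profile)
    out = replicate_concordance(profiles[0], profiles[1])
    out["identical_species_sets"] = (
        profiles[0].species == profiles[1].species
    )
    return out


def genotype_recovery_study(
    seed: int,
    n_pairs: int = 20,
    n_loci: int = 200,
    depth: int = 20,
    min_depth: int = 4,
) -> dict:
    """Diploid genotype recovery at ~*depth*x per locus over *n_pairs*
    technical replicate pairs.

    Reports called-genotype accuracy against the planted truth, the
    depth-gate check, and replicate concordance pooled over both
    comparison directions of every pair, stratified by genotype class.
    """
    cfg = SimConfig(
        seed=seed,
        total_reads=n_loci * depth,
        host_fraction=1.0,
        n_species=2,
        sites_per_genome=5,
        genome_length=2_000,
        n_host_sites=n_loci,
        n_host_snps=int(n_loci * 0.75),
        host_genome_length=n_loci * 200,
    )
    mic, host, build = build_world(cfg)
    truth = host.genotypes
    n_called = n_correct = 0
    min_called_depth = None
    strata = {
        "homozygote": {"genotyped": 0, "same": 0},
        "heterozygote": {"genotyped": 0, "same": 0},
    }
    for pair in range(n_pairs):
        calls = []
        for rep in (1, 2):
            result = profile_simulated_sample(
                mic, host, build, cfg,
                read_seed=seed + 10_000 + 100 * pair + rep,
                genotype=True,
            )
            calls.append(result.genotype_calls)
            for locus, call in result.genotype_calls.items():
                if call.status != "called":
                    continue
                n_called += 1
                if call.alleles == truth[locus]:
                    n_correct += 1
                if (min_called_depth is None
                        or call.depth < min_called_depth):
                    min_called_depth = call.depth
        # Pool both comparison directions: each discordant event then
        # contributes once to each stratum.
        for a, b in ((0, 1), (1, 0)):
            table = concordance(calls[a], calls[b])
            for name in strata:
                strata[name]["genotyped"] += table[name]["genotyped"]
                strata[name]["same"] += table[name]["same"]
    agreement = {
        name: (s["same"] / s["genotyped"] if s["genotyped"] else None)
        for name, s in strata.items()
    }
    return {
        "n_pairs": n_pairs,
        "n_called": n_called,
        "accuracy": n_correct / n_called if n_called else None,
        "min_called_depth": min_called_depth,
        "hom_agreement": agreement["homozygote"],
        "het_agreement": agreement["heterozygote"],
        "n_hom_comparisons": strata["homozygote"]["genotyped"],
        "n_het_comparisons": strata["heterozygote"]["genotyped"],
    }
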