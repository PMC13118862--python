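"""Dual-stream classification and microbial abundance profiling.

Observed canonical tags are routed against the holo-DB: host-unique
tags feed genotyping, microbial taxa-specific tags feed community
profiling, everything else is unassigned. Species presence is called
with the G score ``G_i = sqrt(reads_i * tags_hit_i)`` over
species-specific tags, and relative abundance normalizes read counts by
each species' theoretical (database) tag count:

    c_i = reads_i / theoretical_tags_i,   p_i = c_i / sum_j c_j

so that genome size and restriction-site density do not bias the
profile.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import InputError, InternalError
from .holodb import TagDatabase

__all__ = [
    "ClassifiedSample",
    "SpeciesEvidence",
    "AbundanceProfile",
    "classify_observations",
    "species_evidence",
    "species_presence",
    "relative_abundance",
    "replicate_concordance",
]


@dataclass
class ClassifiedSample:
    """Routing of one sample's tag observations against the holo-DB."""

    sample_id: str
    host_obs: Counter = field(default_factory=Counter)
    microbial_obs: Counter = field(default_factory=Counter)
    #: tags matching neither side exactly; kept (not just counted) so
    #: genotyping can still consider mismatch-bearing host tags.
    unassigned_obs: Counter = field(default_factory=Counter)

    @property
    def unassigned_count(self) -> int:
        return sum(self.unassigned_obs.values())

    @property
    def host_count(self) -> int:
        return sum(self.host_obs.values())

    @property
    def microbial_count(self) -> int:
        return sum(self.microbial_obs.values())

    @property
    def total(self) -> int:
        return self.host_count + self.microbial_count + self.unassigned_count

    @property
    def mapping_rate_host(self) -> float:
        return self.host_count / self.total if self.total else 0.0

    @property
    def mapping_rate_microbial(self) -> float:
        return self.microbial_count / self.total if self.total else 0.0


@dataclass
class SpeciesEvidence:
    """Read and distinct-tag evidence for one species."""

    reads: int = 0
    tags_hit: int = 0

    @property
    def g_score(self) -> float:
        return math.sqrt(self.reads * self.tags_hit)


@dataclass
class AbundanceProfile:
    """Per-sample species relative abundances with their evidence."""

    sample_id: str
    evidence: dict[str, SpeciesEvidence] = field(default_factory=dict)
    abundance: dict[str, float] = field(default_factory=dict)

    @property
    def species(self) -> set[str]:
        return set(self.abundance)


def classify_observations(
    observations: Mapping[str, int],
    db: TagDatabase,
    sample_id: str = "sample",
    enzyme=None,
) -> ClassifiedSample:
    """Route each canonical tag to host / microbial / unassigned."""
    if enzyme is not None and enzyme != db.enzyme:
        raise InputError(
            f"enzyme mismatch: observations {enzyme}, database {db.enzyme}"
        )
    out = ClassifiedSample(sample_id=sample_id)
    for tag, count in observations.items():
        if tag in db.host_tags:
            out.host_obs[tag] += count
        elif tag in db.microbial:
            out.microbial_obs[tag] += count
        else:
            out.unassigned_obs[tag] += count
    return out


def species_evidence(
    microbial_obs: Mapping[str, int], db: TagDatabase
) -> dict[str, SpeciesEvidence]:
    """Aggregate read/tag evidence per species over species-specific
    tags only (shallower-rank tags carry no species signal)."""
    ev: dict[str, SpeciesEvidence] = {}
    for tag, count in microbial_obs.items():
        sp = db.species_of_tag(tag)
        if sp is None:
            continue
        e = ev.setdefault(sp, SpeciesEvidence())
        e.reads += count
        e.tags_hit += 1
    return ev


def species_presence(
    evidence: Mapping[str, SpeciesEvidence], g_threshold: float = 5.0
) -> set[str]:
    """Species detected iff G >= g_threshold."""
    return {s for s, e in evidence.items() if e.g_score >= g_threshold}


def relative_abundance(
    evidence: Mapping[str, SpeciesEvidence],
    theoretical_counts: Mapping[str, int],
    sample_id: str = "sample",
    g_threshold: float = 5.0,
) -> AbundanceProfile:
    """Normalized abundances over the detected species set."""
    detected = species_presence(evidence, g_threshold)
    profile = AbundanceProfile(sample_id=sample_id, evidence=dict(evidence))
    if not detected:
        return profile
    coverage: dict[str, float] = {}
    for sp in detected:
        denom = theoretical_counts.get(sp, 0)
        if denom <= 0:
            raise InternalError(
                f"species {sp!r} detected but has theoretical tag count "
                f"{denom}; database is inconsistent"
            )
        coverage[sp] = evidence[sp].reads / denom
    total = sum(coverage.values())
    profile.abundance = {sp: c / total for sp, c in coverage.items()}
    return profile


def replicate_concordance(
    profile1: AbundanceProfile, profile2: AbundanceProfile
) -> dict:
    """Shared-species and abundance-correlation summary of two samples.

    Pearson r is computed over the union of detected species, absent
    species contributing 0; r is None when either profile is empty or a
    vector is constant.
    """
    s1, s2 = profile1.species, profile2.species
    union = sorted(s1 | s2)
    shared = s1 & s2
    out = {
        "n_species_1": len(s1),
        "n_species_2": len(s2),
        "n_shared": len(shared),
        "jaccard": len(shared) / len(union) if union else 0.0,
        "pearson_r": None,
    }
    if s1 and s2:
        x = np.array([profile1.abundance.get(s, 0.0) for s in union])
        y = np.array([profile2.abundance.get(s, 0.0) for s in union])
        if len(union) >= 2 and x.std() > 0 and y.std() > 0:
            out["pearson_r"] = float(np.corrcoef(x, y)[0, 1])
    return out
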