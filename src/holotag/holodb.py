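"""Hologenome tag-database construction.

The database maps every retained canonical tag either to the host
(host-unique single-copy tags) or to the most specific taxonomic rank
shared by all microbial genomes that carry it. Species-specific tags
double as the "theoretical tag" denominators used for abundance
normalization during profiling.

Build order: per-genome digestion -> single-copy filtering ->
rank-specificity assignment -> host tag set -> cross-redundancy removal
(any tag seen on both sides is deleted from both).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .enzyme import BCGI, DigestSummary, EnzymeSpec
from .errors import FormatError, InputError

__all__ = [
    "RANKS",
    "TaxonLineage",
    "GenomeEntry",
    "TagRecord",
    "TagDatabase",
    "RemovalReport",
    "single_copy_tags",
    "assign_specificity",
    "build_host_tagset",
    "cross_deredundancy",
    "db_statistics",
    "save_db",
    "load_db",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

DB_FORMAT_VERSION = "holotag-db/1"


@dataclass(frozen=True)
class TaxonLineage:
    """Seven-rank lineage. 'unresolved_<n>' labels are ordinary labels:
    two genomes share a rank only if the literal strings match."""

    kingdom: str
    phylum: str
    class_: str
    order: str
    family: str
    genus: str
    species: str

    def __post_init__(self) -> None:
        if any(not lbl for lbl in self.labels):
            raise InputError(f"lineage has an empty rank label: {self}")

    @property
    def labels(self) -> tuple[str, ...]:
        return (
            self.kingdom,
            self.phylum,
            self.class_,
            self.order,
            self.family,
            self.genus,
            self.species,
        )

    @classmethod
    def from_string(cls, text: str, sep: str = ";") -> "TaxonLineage":
        parts = [p.strip() for p in text.split(sep)]
        if len(parts) != 7:
            raise FormatError(
                f"lineage must have 7 ranks, got {len(parts)}: {text!r}"
            )
        return cls(*parts)

    def to_string(self, sep: str = ";") -> str:
        return sep.join(self.labels)


@dataclass
class GenomeEntry:
    """Bookkeeping for one input genome through the build."""

    genome_id: str
    lineage: TaxonLineage | None
    source: str  # reference | mag | host
    n_total_tags: int = 0
    n_single_copy_tags: int = 0
    status: str = "included"  # included | no_site | no_unique_tag |
    # removed_by_deredundancy


@dataclass(frozen=True)
class TagRecord:
    """Taxonomic specificity of one microbial canonical tag."""

    rank: str  # one of RANKS or "nonspecific"
    taxon: str  # label at that rank ("" when nonspecific)
    genome_ids: tuple[str, ...]


@dataclass
class TagDatabase:
    """The holo-DB: microbial specificity map + host-unique tag set."""

    enzyme: EnzymeSpec
    microbial: dict[str, TagRecord] = field(default_factory=dict)
    host_tags: set[str] = field(default_factory=set)
    theoretical_counts: dict[str, int] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)
    #: tags whose carrier genomes disagree even at kingdom; excluded
    #: from profiling but kept for statistics.
    n_nonspecific: int = 0

    def species_of_tag(self, tag: str) -> str | None:
        rec = self.microbial.get(tag)
        if rec is not None and rec.rank == "species":
            return rec.taxon
        return None


def single_copy_tags(summary: DigestSummary) -> set[str]:
    """Canonical tags occurring exactly once in the genome."""
    return {t for t, c in summary.counts.items() if c == 1}


def genome_entry_from_digest(
    summary: DigestSummary,
    lineage: TaxonLineage | None,
    source: str = "reference",
) -> GenomeEntry:
    single = single_copy_tags(summary)
    if summary.total == 0:
        status = "no_site"
    elif not single:
        status = "no_unique_tag"
    else:
        status = "included"
    return GenomeEntry(
        genome_id=summary.genome_id,
        lineage=lineage,
        source=source,
        n_total_tags=summary.total,
        n_single_copy_tags=len(single),
        status=status,
    )


def _lca_depth(lineages: list[TaxonLineage]) -> int:
    """Length of the longest common prefix of the rank-label tuples."""
    first = lineages[0].labels
    depth = 7
    for lin in lineages[1:]:
        labels = lin.labels
        d = 0
        while d < depth and labels[d] == first[d]:
            d += 1
        depth = d
        if depth == 0:
            break
    return depth


def assign_specificity(
    genome_tags: Mapping[str, Iterable[str]],
    lineages: Mapping[str, TaxonLineage],
    enzyme: EnzymeSpec = BCGI,
) -> TagDatabase:
    """Assign each single-copy tag its deepest shared taxonomic rank.

    Parameters
    ----------
    genome_tags : mapping genome_id -> iterable of single-copy canonical
        tags (a tag that is multi-copy in genome A but single-copy in B
        is treated as absent from A).
    lineages : mapping genome_id -> TaxonLineage.

    Tags whose carrier genomes disagree even at kingdom are counted as
    nonspecific and excluded from the profiling map.
    """
    for gid in genome_tags:
        if gid not in lineages:
            raise InputError(f"genome {gid!r} has no lineage")
    carriers: dict[str, list[str]] = {}
    for gid, tags in genome_tags.items():
        for tag in tags:
            carriers.setdefault(tag, []).append(gid)

    db = TagDatabase(enzyme=enzyme)
    for tag, gids in carriers.items():
        lins = [lineages[g] for g in gids]
        depth = _lca_depth(lins)
        if depth == 0:
            db.n_nonspecific += 1
            continue
        rank = RANKS[depth - 1]
        taxon = lins[0].labels[depth - 1]
        db.microbial[tag] = TagRecord(
            rank=rank, taxon=taxon, genome_ids=tuple(sorted(gids))
        )
        if rank == "species":
            db.theoretical_counts[taxon] = (
                db.theoretical_counts.get(taxon, 0) + 1
            )
    return db


def build_host_tagset(host_summary: DigestSummary) -> tuple[set[str], dict]:
    """Single-copy canonical tags of the host genome.

    Returns the tag set plus counts of all distinct and of unique
    (single-copy) tags.
    """
    unique = single_copy_tags(host_summary)
    stats = {
        "n_distinct_tags": len(host_summary.counts),
        "n_unique_tags": len(unique),
    }
    return unique, stats


@dataclass
class RemovalReport:
    """Accounting of the host<->microbe cross-redundancy removal."""

    host_tags_before: int
    host_tags_removed: int
    microbial_tags_before: int
    microbial_tags_removed: int
    genomes_removed: tuple[str, ...]
    species_before: int
    species_retained: int
    #: rank -> fraction of rank-specific tags retained (None if no tags
    #: at that rank before removal)
    retained_fraction_by_rank: dict[str, float | None] = field(
        default_factory=dict
    )

    @property
    def host_tags_retained(self) -> int:
        return self.host_tags_before - self.host_tags_removed

    @property
    def microbial_tags_retained(self) -> int:
        return self.microbial_tags_before - self.microbial_tags_removed


def cross_deredundancy(
    db: TagDatabase,
    host_tags: set[str],
    host_enzyme: EnzymeSpec | None = None,
) -> tuple[TagDatabase, RemovalReport]:
    """Delete every canonical tag present on both sides from BOTH sides.

    Microbial genomes (hence species) left without any species-specific
    tag are reported as removed. The returned database carries the
    surviving host set in ``host_tags``.
    """
    if host_enzyme is not None and host_enzyme != db.enzyme:
        raise InputError(
            f"enzyme mismatch: microbial side {db.enzyme}, "
            f"host side {host_enzyme}"
        )
    shared = host_tags & set(db.microbial)

    before_by_rank: dict[str, int] = {r: 0 for r in RANKS}
    for rec in db.microbial.values():
        before_by_rank[rec.rank] += 1

    new_microbial = {
        t: r for t, r in db.microbial.items() if t not in shared
    }
    new_host = host_tags - shared

    # Re-derive species-specific accounting from the surviving map.
    new_counts: dict[str, int] = {}
    species_genomes: dict[str, set[str]] = {}
    for rec in new_microbial.values():
        if rec.rank == "species":
            new_counts[rec.taxon] = new_counts.get(rec.taxon, 0) + 1
            species_genomes.setdefault(rec.taxon, set()).update(
                rec.genome_ids
            )

    genomes_with_specific_before: set[str] = set()
    species_before: set[str] = set()
    for tag, rec in db.microbial.items():
        if rec.rank == "species":
            species_before.add(rec.taxon)
            genomes_with_specific_before.update(rec.genome_ids)
    genomes_with_specific_after: set[str] = set()
    for gset in species_genomes.values():
        genomes_with_specific_after.update(gset)
    removed_genomes = tuple(
        sorted(genomes_with_specific_before - genomes_with_specific_after)
    )

    after_by_rank: dict[str, int] = {r: 0 for r in RANKS}
    for rec in new_microbial.values():
        after_by_rank[rec.rank] += 1
    retained_fraction = {
        r: (after_by_rank[r] / before_by_rank[r]) if before_by_rank[r] else None
        for r in RANKS
    }

    report = RemovalReport(
        host_tags_before=len(host_tags),
        host_tags_removed=len(shared),
        microbial_tags_before=len(db.microbial),
        microbial_tags_removed=len(shared),
        genomes_removed=removed_genomes,
        species_before=len(species_before),
        species_retained=len(new_counts),
        retained_fraction_by_rank=retained_fraction,
    )
    new_db = TagDatabase(
        enzyme=db.enzyme,
        microbial=new_microbial,
        host_tags=new_host,
        theoretical_counts=new_counts,
        metadata=dict(db.metadata),
        n_nonspecific=db.n_nonspecific,
    )
    return new_db, report


def db_statistics(
    db: TagDatabase, entries: Iterable[GenomeEntry] = ()
) -> dict:
    """Summary statistics of a built database.

    Fractions over zero denominators are reported as None.
    """
    entries = list(entries)
    microbial_entries = [e for e in entries if e.source != "host"]
    n_genomes = len(microbial_entries)
    mean_tags = (
        sum(e.n_total_tags for e in microbial_entries) / n_genomes
        if n_genomes
        else None
    )
    by_rank = {r: 0 for r in RANKS}
    for rec in db.microbial.values():
        by_rank[rec.rank] += 1
    n_map = len(db.microbial)
    total_assigned = n_map + db.n_nonspecific
    frac_by_rank = {
        r: (by_rank[r] / total_assigned) if total_assigned else None
        for r in RANKS
    }
    retained = [e for e in microbial_entries if e.status == "included"]
    return {
        "n_genomes": n_genomes,
        "n_genomes_retained": len(retained),
        "fraction_genomes_retained": (
            len(retained) / n_genomes if n_genomes else None
        ),
        "mean_tags_per_genome": mean_tags,
        "n_microbial_tags": n_map,
        "n_nonspecific_tags": db.n_nonspecific,
        "tags_by_rank": by_rank,
        "fraction_by_rank": frac_by_rank,
        "n_species": len(db.theoretical_counts),
        "n_host_tags": len(db.host_tags),
    }


# ---------------------------------------------------------------------------
# Persistence: versioned, sorted, gzip TSV (deterministic for diffing).


def save_db(db: TagDatabase, path: str, *, timestamp: str | None = None) -> None:
    """Write a database as versioned gzip TSV.

    Output is byte-deterministic for identical databases (sorted rows,
    zeroed gzip mtime); pass *timestamp* to record a build date.
    """
    import io as _io

    raw = _io.BytesIO()
    with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
        fh = _io.TextIOWrapper(gz, encoding="utf-8")
        fh.write(f"#FORMAT\t{DB_FORMAT_VERSION}\n")
        fh.write(f"#ENZYME\t{db.enzyme.name}\t{db.enzyme.recognition}"
                 f"\t{db.enzyme.left_flank}\t{db.enzyme.right_flank}\n")
        if timestamp is not None:
            fh.write(f"#BUILT\t{timestamp}\n")
        for k in sorted(db.metadata):
            fh.write(f"#META\t{k}\t{db.metadata[k]}\n")
        fh.write(f"#NONSPECIFIC\t{db.n_nonspecific}\n")
        fh.write("#SECTION\tMICROBIAL\n")
        for tag in sorted(db.microbial):
            rec = db.microbial[tag]
            fh.write(
                f"{tag}\t{rec.rank}\t{rec.taxon}\t{len(rec.genome_ids)}"
                f"\t{','.join(rec.genome_ids)}\n"
            )
        fh.write("#SECTION\tHOST\n")
        for tag in sorted(db.host_tags):
            fh.write(f"{tag}\n")
        fh.write("#END\n")
        fh.flush()
    with open(path, "wb") as out:
        out.write(raw.getvalue())


def load_db(path: str) -> TagDatabase:
    enzyme: EnzymeSpec | None = None
    metadata: dict[str, str] = {}
    microbial: dict[str, TagRecord] = {}
    host: set[str] = set()
    n_nonspecific = 0
    section = None
    saw_end = False
    with gzip.open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if lineno == 1:
                if line != f"#FORMAT\t{DB_FORMAT_VERSION}":
                    raise FormatError(
                        f"{path}: unsupported database format "
                        f"(line 1: {line!r})"
                    )
                continue
            if line.startswith("#"):
                fields = line.split("\t")
                key = fields[0]
                if key == "#ENZYME":
                    if len(fields) != 5:
                        raise FormatError(
                            f"{path}: malformed #ENZYME at line {lineno}"
                        )
                    enzyme = EnzymeSpec(
                        fields[1], fields[2], int(fields[3]), int(fields[4])
                    )
                elif key == "#META":
                    metadata[fields[1]] = fields[2]
                elif key == "#NONSPECIFIC":
                    n_nonspecific = int(fields[1])
                elif key == "#SECTION":
                    section = fields[1]
                elif key == "#END":
                    saw_end = True
                continue
            if section == "MICROBIAL":
                fields = line.split("\t")
                if len(fields) != 5:
                    raise FormatError(
                        f"{path}: corrupt MICROBIAL row at line {lineno}"
                    )
                tag, rank, taxon, _n, gids = fields
                microbial[tag] = TagRecord(
                    rank=rank,
                    taxon=taxon,
                    genome_ids=tuple(gids.split(",")) if gids else (),
                )
            elif section == "HOST":
                if "\t" in line:
                    raise FormatError(
                        f"{path}: corrupt HOST row at line {lineno}"
                    )
                host.add(line)
            else:
                raise FormatError(
                    f"{path}: data outside any section at line {lineno}"
                )
    if enzyme is None:
        raise FormatError(f"{path}: missing #ENZYME header")
    if not saw_end:
        raise FormatError(f"{path}: truncated file (missing #END)")
    counts: dict[str, int] = {}
    for rec in microbial.values():
        if rec.rank == "species":
            counts[rec.taxon] = counts.get(rec.taxon, 0) + 1
    return TagDatabase(
        enzyme=enzyme,
        microbial=microbial,
        host_tags=host,
        theoretical_counts=counts,
        metadata=metadata,
        n_nonspecific=n_nonspecific,
    )
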