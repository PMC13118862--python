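"""Synthetic holobiont data with exact truth tables.

The generator emulates the data regime of a type IIB RAD holobiont
library: a community of microbial genomes with known log-normal
abundances, a diploid host with SNPs planted inside tag windows, and a
read pool dominated by host DNA (~99% by default, the contamination
level typical of coral holobiont extractions).

Exactness is engineered, not approximate: background sequence is
rejection-sampled to be recognition-free, every planted tag carries
exactly one recognition site, and read fillers are sanitized so the
planted tag is always the leftmost extractable window. Truth tables
therefore state precisely which genome, tag and haplotype each read
came from, before sequencing error is applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .enzyme import BCGI, EnzymeSpec, find_sites
from .errors import InputError, InternalError
from .fastpath import _COMP_LUT, find_sites_matrix
from .holodb import TaxonLineage
from .reads import PHRED_OFFSET, ReadRecord
from .sequence import IUPAC_CODES, canonical, revcomp

__all__ = [
    "SimConfig",
    "MicrobialTruth",
    "HostTruth",
    "SimReads",
    "simulate_genomes",
    "simulate_diploid_host",
    "simulate_reads",
]

_BASES = "ACGT"
_MIN_SPACER = 8
#: reads are generated free of homopolymer runs exceeding this length,
#: matching the read-QC default, so that error-free libraries pass the
#: filter in full
_MAX_RUN = 10


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic holobiont experiment.

    Defaults encode the intended regime: 20 species with log-normal
    (sigma = 1) abundances, 99% host-derived reads, PE150-length reads,
    0.5% per-base substitution error with flat Q40 qualities, and a
    diploid host with 200 SNP loci at 50% heterozygosity.
    """

    seed: int = 0
    n_species: int = 20
    #: children per parent at (phylum/kingdom, class/phylum, order/class,
    #: family/order, genus/family, species/genus)
    lineage_fanout: tuple[int, ...] = (4, 2, 2, 2, 2, 2)
    genome_length: int = 20_000
    gc_fraction: float = 0.5
    sites_per_genome: int = 50
    abundance_sigma: float = 1.0
    host_genome_length: int = 60_000
    n_host_sites: int = 250
    n_host_snps: int = 200
    snp_heterozygosity: float = 0.5
    host_fraction: float = 0.99
    total_reads: int = 100_000
    read_length: int = 150
    base_error_rate: float = 0.005
    quality_model: str = "constant"  # "constant" | "two-tier"
    q_high: int = 40
    q_low: int = 8
    low_q_frac: float = 0.0  # two-tier: fraction of bases at q_low

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.total_reads < 0:
            raise InputError("counts must be positive")
        if not 0 <= self.host_fraction <= 1:
            raise InputError("host_fraction must lie in [0, 1]")
        if not 0 <= self.snp_heterozygosity <= 1:
            raise InputError("snp_heterozygosity must lie in [0, 1]")
        if self.n_host_snps > self.n_host_sites:
            raise InputError("cannot plant more SNPs than host tag loci")


@dataclass
class MicrobialTruth:
    """Planted community: genomes, lineages, tags and abundances."""

    genomes: list[tuple[str, str]]  # (genome_id, sequence)
    lineages: dict[str, TaxonLineage]
    planted_tags: dict[str, list[str]]  # genome_id -> canonical tags
    species_labels: list[str]
    abundance: np.ndarray  # true relative abundances, sums to 1


@dataclass
class HostTruth:
    """Diploid host: reference, haplotypes and per-locus genotypes."""

    reference: str
    hap1: str
    hap2: str
    loci: list[str]  # reference canonical tags, window order
    window_starts: list[int]
    #: locus -> lexicographically sorted (allele1, allele2) canonical tags
    genotypes: dict[str, tuple[str, str]]

    def het_loci(self) -> set[str]:
        return {
            loc for loc, (a, b) in self.genotypes.items() if a != b
        }


# ---------------------------------------------------------------------------
# Sequence construction helpers


def _constrained_positions(enzyme: EnzymeSpec) -> list[int]:
    return [
        i for i, code in enumerate(enzyme.recognition) if code != "N"
    ]


def _breaking_base(rng: np.random.Generator, code: str, current: str) -> str:
    choices = [
        b for b in _BASES if b not in IUPAC_CODES[code] and b != current
    ]
    if not choices:
        choices = [b for b in _BASES if b != current]
    return choices[rng.integers(len(choices))]


def _site_regexes(enzyme: EnzymeSpec) -> list[re.Pattern]:
    from .enzyme import _pattern_regex

    pats = [_pattern_regex(enzyme.recognition)]
    rc = revcomp(enzyme.recognition)
    if rc != enzyme.recognition:
        pats.append(_pattern_regex(rc))
    return pats


def _random_seq(
    rng: np.random.Generator, length: int, gc: float
) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return list(lut[idx].tobytes().decode("ascii"))


def _scrub_sites(
    seq: list[str],
    rng: np.random.Generator,
    enzyme: EnzymeSpec,
    protected: list[tuple[int, int]] | None = None,
) -> None:
    """Mutate *seq* in place until it contains no recognition site whose
    span is not fully inside a protected window. Sites inside protected
    windows are left alone."""
    protected = protected or []
    span = enzyme.recognition_length
    fwd_positions = _constrained_positions(enzyme)
    for _ in range(200):
        text = "".join(seq)
        dirty = False
        for pos, strand in find_sites(text, enzyme):
            if any(s <= pos and pos + span <= e for s, e in protected):
                continue
            dirty = True
            # Mutate a constrained position outside every protected
            # window.
            if strand == "+":
                cands = [(pos + p, enzyme.recognition[p])
                         for p in fwd_positions]
            else:
                rc = revcomp(enzyme.recognition)
                cands = [(pos + p, rc[p])
                         for p in range(span) if rc[p] != "N"]
            hit = None
            for gpos, code in cands:
                if not any(s <= gpos < e for s, e in protected):
                    hit = (gpos, code)
                    break
            if hit is None:
                raise InternalError(
                    "recognition site fully inside protected windows"
                )
            gpos, code = hit
            seq[gpos] = _breaking_base(rng, code, seq[gpos])
        if not dirty:
            return
    raise InternalError("site scrubbing failed to converge")


def _longest_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best


def _make_tag(
    rng: np.random.Generator, enzyme: EnzymeSpec, gc: float, used: set[str]
) -> str:
    """A tag window carrying exactly one recognition site, canonical
    form unseen so far."""
    for _ in range(1000):
        left = _random_seq(rng, enzyme.left_flank, gc)
        rec = []
        for code in enzyme.recognition:
            allowed = sorted(IUPAC_CODES[code])
            rec.append(allowed[rng.integers(len(allowed))])
        right = _random_seq(rng, enzyme.right_flank, gc)
        tag = "".join(left + rec + right)
        if find_sites(tag, enzyme) != [(enzyme.left_flank, "+")]:
            continue
        if _longest_run(tag) > _MAX_RUN:
            continue
        canon = canonical(tag)
        if canon in used:
            continue
        used.add(canon)
        return tag
    raise InternalError("could not sample a single-site tag")


def _assemble_genome(
    rng: np.random.Generator,
    tags: list[str],
    length: int,
    gc: float,
    enzyme: EnzymeSpec,
) -> tuple[str, list[int]]:
    """Concatenate site-free spacers and planted tag windows to exactly
    *length* bases; returns the sequence and plus-strand window starts."""
    tag_len = enzyme.tag_length
    n = len(tags)
    budget = length - n * tag_len - (n + 1) * _MIN_SPACER
    if budget < 0:
        raise InputError(
            f"genome_length {length} too short for {n} tag windows"
        )
    extra = rng.multinomial(budget, np.full(n + 1, 1 / (n + 1)))
    seq: list[str] = []
    starts: list[int] = []
    for i, tag in enumerate(tags):
        seq.extend(_random_seq(rng, _MIN_SPACER + int(extra[i]), gc))
        starts.append(len(seq))
        seq.extend(tag)
    seq.extend(_random_seq(rng, _MIN_SPACER + int(extra[n]), gc))
    protected = [(s, s + tag_len) for s in starts]
    _scrub_sites(seq, rng, enzyme, protected)
    genome = "".join(seq)
    # Planted windows must have survived scrubbing untouched.
    for s, tag in zip(starts, tags):
        if genome[s : s + tag_len] != tag:
            raise InternalError("planted window was altered by scrubbing")
    return genome, starts


def _make_lineages(
    n_species: int, fanout: tuple[int, ...]
) -> tuple[list[str], dict[int, TaxonLineage]]:
    """Nested lineages: species i gets genus i // f_genus etc."""
    if len(fanout) != 6:
        raise InputError("lineage_fanout must have 6 entries")
    f_phy, f_cls, f_ord, f_fam, f_gen, f_spe = fanout
    labels = []
    lineages: dict[int, TaxonLineage] = {}
    for i in range(n_species):
        genus = i // f_spe
        family = genus // f_gen
        order = family // f_fam
        cls = order // f_ord
        phylum = cls // f_cls
        lin = TaxonLineage(
            kingdom="k_Bacteria",
            phylum=f"p_{phylum}",
            class_=f"c_{cls}",
            order=f"o_{order}",
            family=f"f_{family}",
            genus=f"g_{genus}",
            species=f"s_{i}",
        )
        lineages[i] = lin
        labels.append(lin.species)
    return labels, lineages


def _seeds(cfg: SimConfig) -> tuple[int, int, int]:
    ss = np.random.SeedSequence(cfg.seed)
    g, h, r = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    return g, h, r


def simulate_genomes(
    cfg: SimConfig, enzyme: EnzymeSpec = BCGI
) -> MicrobialTruth:
    """One genome per species, each with exactly ``sites_per_genome``
    planted single-copy tag windows, plus the community abundance
    vector (log-normal, normalized)."""
    gseed, _, _ = _seeds(cfg)
    rng = np.random.default_rng(gseed)
    labels, lineage_by_idx = _make_lineages(
        cfg.n_species, cfg.lineage_fanout
    )
    used: set[str] = set()
    genomes: list[tuple[str, str]] = []
    lineages: dict[str, TaxonLineage] = {}
    planted: dict[str, list[str]] = {}
    for i in range(cfg.n_species):
        gid = f"genome_{i}"
        tags = [
            _make_tag(rng, enzyme, cfg.gc_fraction, used)
            for _ in range(cfg.sites_per_genome)
        ]
        seq, _starts = _assemble_genome(
            rng, tags, cfg.genome_length, cfg.gc_fraction, enzyme
        )
        genomes.append((gid, seq))
        lineages[gid] = lineage_by_idx[i]
        planted[gid] = [canonical(t) for t in tags]
    raw = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma,
                        size=cfg.n_species)
    return MicrobialTruth(
        genomes=genomes,
        lineages=lineages,
        planted_tags=planted,
        species_labels=labels,
        abundance=raw / raw.sum(),
    )


def _snp_positions(enzyme: EnzymeSpec) -> list[int]:
    """Window offsets where a substitution never breaks the site:
    flanks plus fully degenerate recognition positions."""
    offs = list(range(enzyme.left_flank))
    for p, code in enumerate(enzyme.recognition):
        if code == "N":
            offs.append(enzyme.left_flank + p)
    start = enzyme.left_flank + enzyme.recognition_length
    offs.extend(range(start, enzyme.tag_length))
    return offs


def simulate_diploid_host(
    cfg: SimConfig, enzyme: EnzymeSpec = BCGI
) -> HostTruth:
    """Reference host genome plus two haplotypes with SNPs planted
    strictly inside tag windows (never at constrained recognition
    bases)."""
    _, hseed, _ = _seeds(cfg)
    rng = np.random.default_rng(hseed)
    used: set[str] = set()
    tags = [
        _make_tag(rng, enzyme, cfg.gc_fraction, used)
        for _ in range(cfg.n_host_sites)
    ]
    reference, starts = _assemble_genome(
        rng, tags, cfg.host_genome_length, cfg.gc_fraction, enzyme
    )
    tag_len = enzyme.tag_length
    loci = [canonical(t) for t in tags]
    hap1 = list(reference)
    hap2 = list(reference)
    snp_loci = rng.choice(
        cfg.n_host_sites, size=cfg.n_host_snps, replace=False
    )
    allowed_offsets = _snp_positions(enzyme)
    for li in snp_loci:
        w0 = starts[li]
        for _ in range(100):
            off = allowed_offsets[rng.integers(len(allowed_offsets))]
            pos = w0 + off
            ref_base = reference[pos]
            alt = [b for b in _BASES if b != ref_base][rng.integers(3)]
            window = list(reference[w0 : w0 + tag_len])
            window[off] = alt
            alt_window = "".join(window)
            # The altered window must still carry exactly one site and
            # stay unambiguous among loci.
            if find_sites(alt_window, enzyme) != [
                (enzyme.left_flank, "+")
            ]:
                continue
            if canonical(alt_window) in used:
                continue
            break
        else:
            raise InternalError("SNP placement failed")
        if rng.random() < cfg.snp_heterozygosity:
            hap2[pos] = alt  # heterozygote
        else:
            hap1[pos] = alt  # homozygote for the alternate allele
            hap2[pos] = alt
    hap1_s = "".join(hap1)
    hap2_s = "".join(hap2)
    genotypes: dict[str, tuple[str, str]] = {}
    for li, (w0, locus) in enumerate(zip(starts, loci)):
        a1 = canonical(hap1_s[w0 : w0 + tag_len])
        a2 = canonical(hap2_s[w0 : w0 + tag_len])
        genotypes[locus] = tuple(sorted((a1, a2)))
    return HostTruth(
        reference=reference,
        hap1=hap1_s,
        hap2=hap2_s,
        loci=loci,
        window_starts=list(starts),
        genotypes=genotypes,
    )


# ---------------------------------------------------------------------------
# Read simulation (vectorized, chunked)

try:
    import numba as _numba

    @_numba.njit(cache=False, nogil=True)
    def _assemble_kernel(idxmat, lut, tag_table, tag_row, flip, offs,
                         comp, out):  # pragma: no cover
        m, length = idxmat.shape
        tl = tag_table.shape[1]
        for i in range(m):
            for j in range(length):
                out[i, j] = lut[idxmat[i, j]]
            r = tag_row[i]
            o = offs[i]
            if flip[i]:
                for p in range(tl):
                    out[i, o + p] = comp[tag_table[r, tl - 1 - p]]
            else:
                for p in range(tl):
                    out[i, o + p] = tag_table[r, p]

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _assemble_numpy(idxmat, lut, tag_table, tag_row, flip, offs, comp,
                    out) -> None:
    out[:] = lut[idxmat]
    tags = tag_table[tag_row]
    if flip.any():
        tags[flip] = comp[tags[flip]][:, ::-1]
    tl = tag_table.shape[1]
    cols = offs[:, None] + np.arange(tl, dtype=np.int32)[None, :]
    out[np.arange(out.shape[0], dtype=np.int32)[:, None], cols] = tags


@dataclass
class SimReads:
    """Simulated read pool with per-read truth.

    ``origin_species`` is -1 for host reads; ``locus_idx``/``hap_idx``
    are -1 for microbial reads; ``tag_idx`` indexes the species' planted
    tag list for microbial reads.
    """

    seqs: np.ndarray  # (n, L) uint8 ASCII
    #: (n, L) uint8 phred scores, or a single (1, L) row under the
    #: constant-quality model (broadcast to every read)
    quals: np.ndarray
    origin_species: np.ndarray
    locus_idx: np.ndarray
    hap_idx: np.ndarray
    tag_idx: np.ndarray
    config: SimConfig

    @property
    def n_reads(self) -> int:
        return self.seqs.shape[0]

    @property
    def n_host(self) -> int:
        return int((self.origin_species < 0).sum())

    def qual_row(self, i: int) -> np.ndarray:
        return self.quals[i if self.quals.shape[0] > 1 else 0]

    def read_records(self) -> Iterator[ReadRecord]:
        for i in range(self.n_reads):
            yield ReadRecord(
                read_id=f"read_{i}",
                sequence=self.seqs[i].tobytes().decode("ascii"),
                quality=(self.qual_row(i) + PHRED_OFFSET)
                .tobytes()
                .decode("ascii"),
            )

    def write_fastq(self, path: str) -> None:
        import gzip

        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            for rec in self.read_records():
                fh.write(
                    f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n"
                )


def _tag_matrix(tags: list[str]) -> np.ndarray:
    if not tags:
        return np.empty((0, 0), dtype=np.uint8)
    return np.frombuffer(
        "".join(tags).encode("ascii"), dtype=np.uint8
    ).reshape(len(tags), len(tags[0])).copy()


def _fix_spurious_sites(
    chunk: np.ndarray,
    offsets: np.ndarray,
    rng: np.random.Generator,
    enzyme: EnzymeSpec,
    rows: np.ndarray | None = None,
) -> None:
    """Mutate filler bases until the planted window (at *offsets*) is
    the leftmost extractable site of every read in *chunk* (or of the
    given *rows* only)."""
    tag_len = enzyme.tag_length
    regexes = _site_regexes(enzyme)
    patterns = [enzyme.recognition]
    rc = revcomp(enzyme.recognition)
    if rc != enzyme.recognition:
        patterns.append(rc)
    if rows is None:
        starts, _ = find_sites_matrix(chunk, enzyme)
        bad = np.nonzero(starts != offsets)[0]
    else:
        rows = np.asarray(rows)
        if rows.size == 0:
            return
        starts, _ = find_sites_matrix(chunk[rows], enzyme)
        bad = rows[starts != offsets[rows]]
    for r in bad:
        seq = bytearray(chunk[r].tobytes())
        w0 = int(offsets[r])
        for _ in range(100):
            text = seq.decode("ascii")
            # Sites before the planted window (any site at or after it
            # cannot outrank the planted leftmost match).
            spurious: list[tuple[int, int]] = []
            for pat_idx, regex in enumerate(regexes):
                for m in regex.finditer(text, 0, w0 + tag_len):
                    if m.start() != w0 + _site_offset(enzyme, pat_idx):
                        spurious.append((m.start(), pat_idx))
            if not spurious:
                break
            for pos, pat_idx in spurious:
                pat = patterns[pat_idx]
                fixed = False
                for p, code in enumerate(pat):
                    if code == "N":
                        continue
                    g = pos + p
                    if w0 <= g < w0 + tag_len or g >= len(seq):
                        continue
                    seq[g] = ord(
                        _breaking_base(rng, code, chr(seq[g]))
                    )
                    fixed = True
                    break
                if not fixed:
                    raise InternalError(
                        "read filler sanitization found no mutable base"
                    )
        else:
            raise InternalError("read sanitization failed to converge")
        chunk[r] = np.frombuffer(bytes(seq), dtype=np.uint8)


def _site_offset(enzyme: EnzymeSpec, pat_idx: int) -> int:
    """Recognition offset of the planted site within its window for the
    forward (0) / reverse-complement (1) pattern orientation."""
    return enzyme.left_flank if pat_idx == 0 else enzyme.right_flank


def _fix_homopolymers(
    chunk: np.ndarray,
    offsets: np.ndarray,
    rng: np.random.Generator,
    enzyme: EnzymeSpec,
    max_run: int = _MAX_RUN,
) -> np.ndarray:
    """Break filler homopolymer runs exceeding *max_run* by mutating a
    filler base inside each run; returns the affected row indices so
    the site sanitizer can re-check them. Planted tags themselves never
    exceed the run limit, so every offending run has a filler base."""
    from . import fastpath

    if fastpath._HAVE_NUMBA:
        _, has_run = fastpath._scan_reads_kernel(
            np.ascontiguousarray(chunk), max_run
        )
    else:
        _, has_run = fastpath._scan_reads_numpy(chunk, max_run)
    bad = np.nonzero(has_run)[0]
    tag_len = enzyme.tag_length
    for r in bad:
        seq = bytearray(chunk[r].tobytes())
        w0 = int(offsets[r])
        for _ in range(30):
            text = seq.decode("ascii")
            run_start, run_len = _find_long_run(text, max_run)
            if run_start is None:
                break
            cands = [
                p
                for p in range(run_start, run_start + run_len)
                if not w0 <= p < w0 + tag_len
            ]
            if not cands:
                raise InternalError(
                    "homopolymer run entirely inside a planted tag"
                )
            # Break near the middle so both pieces drop under the cap.
            pos = cands[len(cands) // 2]
            cur = text[pos]
            repl = [b for b in _BASES if b != cur]
            seq[pos] = ord(repl[rng.integers(3)])
        else:
            raise InternalError("homopolymer fixing failed to converge")
        chunk[r] = np.frombuffer(bytes(seq), dtype=np.uint8)
    return bad


def _find_long_run(text: str, max_run: int) -> tuple[int | None, int]:
    run = 1
    start = 0
    for i in range(1, len(text)):
        if text[i] == text[i - 1]:
            run += 1
            if run > max_run:
                # Extend to the full run before reporting.
                j = i + 1
                while j < len(text) and text[j] == text[i]:
                    j += 1
                return start, j - start
        else:
            run = 1
            start = i
    return None, 0


def simulate_reads(
    mic: MicrobialTruth,
    host: HostTruth,
    cfg: SimConfig,
    enzyme: EnzymeSpec = BCGI,
    read_seed: int | None = None,
    chunk_size: int = 1_000_000,
) -> SimReads:
    """Draw ``cfg.total_reads`` reads: host with probability
    ``host_fraction`` (haplotype-sampled at every locus), else a species
    by its true abundance; each read embeds one planted tag in random
    orientation at a random offset within site-free filler, then
    receives substitution errors at ``base_error_rate``."""
    if read_seed is None:
        _, _, read_seed = _seeds(cfg)
    rng = np.random.default_rng(read_seed)
    n, length = cfg.total_reads, cfg.read_length
    tag_len = enzyme.tag_length
    if length < tag_len:
        raise InputError("read_length shorter than the tag length")

    # Host allele windows per locus/haplotype, plus-strand orientation.
    n_loci = len(host.loci)
    host_alleles = np.empty((n_loci, 2, tag_len), dtype=np.uint8)
    for li, w0 in enumerate(host.window_starts):
        for h, hap in enumerate((host.hap1, host.hap2)):
            host_alleles[li, h] = np.frombuffer(
                hap[w0 : w0 + tag_len].encode("ascii"), dtype=np.uint8
            )
    # Microbial tags flattened with per-species offsets. Planted tag
    # lists are canonical; orientation is randomized per read anyway.
    species_tags = [
        _tag_matrix(mic.planted_tags[gid]) for gid, _ in mic.genomes
    ]
    tags_per_species = np.array([t.shape[0] for t in species_tags])
    mic_flat = (
        np.vstack(species_tags)
        if species_tags
        else np.empty((0, tag_len), dtype=np.uint8)
    )
    species_offset = np.concatenate(
        [[0], np.cumsum(tags_per_species)[:-1]]
    ) if len(tags_per_species) else np.array([], dtype=int)
    # One combined tag table: host alleles first (locus-major, two
    # haplotype rows each), then the flattened species tags.
    n_host_rows = n_loci * 2
    tag_table = np.vstack(
        [host_alleles.reshape(n_host_rows, tag_len), mic_flat]
    )

    constant_quality = not (
        cfg.quality_model == "two-tier" and cfg.low_q_frac > 0
    )
    seqs = np.empty((n, length), dtype=np.uint8)
    quals = (
        np.full((1, length), cfg.q_high, dtype=np.uint8)
        if constant_quality
        else np.empty((n, length), dtype=np.uint8)
    )
    origin = np.empty(n, dtype=np.int32)
    locus_idx = np.full(n, -1, dtype=np.int32)
    hap_idx = np.full(n, -1, dtype=np.int8)
    tag_idx = np.full(n, -1, dtype=np.int32)

    base_lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    code_of = np.zeros(256, dtype=np.uint8)
    for k, b in enumerate(b"ACGT"):
        code_of[b] = k

    for lo in range(0, n, chunk_size):
        hi = min(lo + chunk_size, n)
        m = hi - lo
        is_host = rng.random(m) < cfg.host_fraction
        sp = np.full(m, -1, dtype=np.int32)
        n_mic = int((~is_host).sum())
        if n_mic and cfg.n_species:
            sp[~is_host] = rng.choice(
                cfg.n_species, size=n_mic, p=mic.abundance
            )
        # Per-read tag choice (row into the combined tag table).
        li = np.full(m, -1, dtype=np.int32)
        hp = np.full(m, -1, dtype=np.int8)
        ti = np.full(m, -1, dtype=np.int32)
        tag_row = np.empty(m, dtype=np.int64)
        hmask = is_host
        nh = int(hmask.sum())
        if nh:
            li[hmask] = rng.integers(0, n_loci, size=nh)
            hp[hmask] = rng.integers(0, 2, size=nh)
            tag_row[hmask] = li[hmask].astype(np.int64) * 2 + hp[hmask]
        if n_mic:
            within = (
                rng.random(n_mic) * tags_per_species[sp[~hmask]]
            ).astype(np.int64)
            ti[~hmask] = within
            tag_row[~hmask] = (
                n_host_rows + species_offset[sp[~hmask]] + within
            )
        # Random orientation and placement; assemble filler + tag.
        flip = rng.random(m) < 0.5
        offs = rng.integers(
            0, length - tag_len + 1, size=m, dtype=np.int32
        )
        idxmat = rng.integers(0, 4, size=(m, length), dtype=np.uint8)
        block = np.empty((m, length), dtype=np.uint8)
        assemble = _assemble_kernel if _HAVE_NUMBA else _assemble_numpy
        assemble(idxmat, base_lut, tag_table, tag_row, flip, offs,
                 _COMP_LUT, block)
        _fix_spurious_sites(block, offs, rng, enzyme)
        # Keep reads QC-clean: break long filler homopolymer runs,
        # then re-verify the planted site on the touched rows (the two
        # fixes can interact, but each pass strictly shrinks the
        # offending set).
        for _ in range(20):
            touched = _fix_homopolymers(block, offs, rng, enzyme)
            if touched.size == 0:
                break
            _fix_spurious_sites(block, offs, rng, enzyme, rows=touched)
        else:
            raise InternalError(
                "read sanitization did not reach a fixed point"
            )
        # Substitution errors.
        if cfg.base_error_rate > 0:
            k = rng.binomial(m * length, cfg.base_error_rate)
            if k:
                flat = rng.integers(0, m * length, size=k)
                rows, colp = flat // length, flat % length
                old = code_of[block[rows, colp]]
                new = (old + rng.integers(1, 4, size=k).astype(np.uint8)) % 4
                block[rows, colp] = base_lut[new]
        # Qualities.
        if not constant_quality:
            q = np.full((m, length), cfg.q_high, dtype=np.uint8)
            low = rng.random((m, length)) < cfg.low_q_frac
            q[low] = cfg.q_low
            quals[lo:hi] = q
        seqs[lo:hi] = block
        origin[lo:hi] = sp
        locus_idx[lo:hi] = li
        hap_idx[lo:hi] = hp
        tag_idx[lo:hi] = ti

    return SimReads(
        seqs=seqs,
        quals=quals,
        origin_species=origin,
        locus_idx=locus_idx,
        hap_idx=hap_idx,
        tag_idx=tag_idx,
        config=cfg,
    )
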