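"""Database construction: specificity LCA, de-redundancy set algebra,
persistence round-trip."""

import itertools

import numpy as np
import pytest

from holotag.enzyme import BCGI, DigestSummary
from holotag.errors import FormatError, InputError
from holotag.holodb import (
    RANKS,
    TagDatabase,
    TagRecord,
    TaxonLineage,
    assign_specificity,
    build_host_tagset,
    cross_deredundancy,
    db_statistics,
    load_db,
    save_db,
    single_copy_tags,
)

from collections import Counter


def lineage(*, k="Bacteria", p="P1", c="C1", o="O1", f="F1", g="G1",
            s="S1"):
    return TaxonLineage(k, p, c, o, f, g, s)


def summary(genome_id, counts):
    return DigestSummary(genome_id=genome_id, counts=Counter(counts))


def oracle_lca_rank(lineages):
    """Exhaustive per-rank agreement check (independent of the
    implementation's prefix walk)."""
    deepest = None
    for depth, rank in enumerate(RANKS):
        labels = {lin.labels[depth] for lin in lineages}
        if len(labels) == 1:
            deepest = rank
        else:
            break
    return deepest


class TestSingleCopy:
    def test_multicopy_excluded(self):
        assert single_copy_tags(summary("g", {"t1": 1, "t2": 2})) == {"t1"}

    def test_empty_digest(self):
        assert single_copy_tags(summary("g", {})) == set()

    def test_matches_count_filter_oracle(self):
        rng = np.random.default_rng(0)
        counts = {f"t{i}": int(c) for i, c in
                  enumerate(rng.integers(1, 4, size=200))}
        expected = {t for t, c in counts.items() if c == 1}
        assert single_copy_tags(summary("g", counts)) == expected


class TestAssignSpecificity:
    def test_same_species_two_genomes(self):
        db = assign_specificity(
            {"g1": {"t"}, "g2": {"t"}},
            {"g1": lineage(), "g2": lineage()},
        )
        assert db.microbial["t"].rank == "species"
        assert db.theoretical_counts == {"S1": 1}

    def test_same_genus_different_species(self):
        db = assign_specificity(
            {"g1": {"t"}, "g2": {"t"}},
            {"g1": lineage(s="S1"), "g2": lineage(s="S2")},
        )
        assert db.microbial["t"].rank == "genus"
        assert db.microbial["t"].taxon == "G1"

    def test_kingdom_disagreement_nonspecific(self):
        db = assign_specificity(
            {"g1": {"t"}, "g2": {"t"}},
            {"g1": lineage(k="Bacteria"), "g2": lineage(k="Fungi")},
        )
        assert "t" not in db.microbial
        assert db.n_nonspecific == 1

    def test_missing_lineage_names_genome(self):
        with pytest.raises(InputError, match="g2"):
            assign_specificity({"g1": {"t"}, "g2": {"t"}},
                               {"g1": lineage()})

    def test_toy_taxonomy_matches_exhaustive_lca(self):
        # Six genomes over a small taxonomy; every subset of carriers
        # engineered via per-tag membership.
        lins = {
            "g0": lineage(p="P1", c="C1", o="O1", f="F1", g="G1", s="S1"),
            "g1": lineage(p="P1", c="C1", o="O1", f="F1", g="G1", s="S1"),
            "g2": lineage(p="P1", c="C1", o="O1", f="F1", g="G1", s="S2"),
            "g3": lineage(p="P1", c="C1", o="O2", f="F2", g="G2", s="S3"),
            "g4": lineage(p="P2", c="C2", o="O3", f="F3", g="G3", s="S4"),
            "g5": lineage(k="Fungi", p="P9", c="C9", o="O9", f="F9",
                          g="G9", s="S9"),
        }
        gids = sorted(lins)
        genome_tags = {g: set() for g in gids}
        tag_carriers = {}
        idx = 0
        for r in range(1, 4):
            for combo in itertools.combinations(gids, r):
                tag = f"tag{idx}"
                idx += 1
                tag_carriers[tag] = combo
                for g in combo:
                    genome_tags[g].add(tag)
        db = assign_specificity(genome_tags, lins)
        for tag, carriers in tag_carriers.items():
            expected = oracle_lca_rank([lins[g] for g in carriers])
            if expected is None:
                assert tag not in db.microbial
            else:
                rec = db.microbial[tag]
                assert rec.rank == expected
                depth = RANKS.index(expected)
                assert rec.taxon == lins[carriers[0]].labels[depth]
                assert rec.genome_ids == tuple(sorted(carriers))

    def test_monotonicity_adding_genome_never_deepens_rank(self):
        """A tag's specificity can only move toward shallower ranks (or
        nonspecific) as more genomes carry it."""
        rng = np.random.default_rng(1)
        pool = {
            f"g{i}": lineage(
                p=f"P{rng.integers(2)}", c="C", o="O",
                f=f"F{rng.integers(2)}", g=f"G{rng.integers(3)}",
                s=f"S{rng.integers(6)}",
            )
            for i in range(8)
        }
        gids = sorted(pool)
        order = {None: -1, **{r: i for i, r in enumerate(RANKS)}}
        for k in range(1, len(gids)):
            smaller = assign_specificity(
                {g: {"t"} for g in gids[:k]}, pool)
            larger = assign_specificity(
                {g: {"t"} for g in gids[: k + 1]}, pool)
            rank_small = (smaller.microbial["t"].rank
                          if "t" in smaller.microbial else None)
            rank_large = (larger.microbial["t"].rank
                          if "t" in larger.microbial else None)
            assert order[rank_large] <= order[rank_small]


class TestHostTagset:
    def test_single_site(self):
        tags, stats = build_host_tagset(summary("host", {"t": 1}))
        assert tags == {"t"} and stats["n_unique_tags"] == 1

    def test_duplicate_cassette_excluded(self):
        tags, stats = build_host_tagset(summary("host", {"t": 2, "u": 1}))
        assert tags == {"u"}
        assert stats["n_distinct_tags"] == 2


class TestCrossDeredundancy:
    def _toy_db(self, tags):
        db = TagDatabase(enzyme=BCGI)
        for t in tags:
            db.microbial[t] = TagRecord("species", "SX", ("g1",))
        db.theoretical_counts = {"SX": len(tags)}
        return db

    def test_disjoint_nothing_removed(self):
        db = self._toy_db(["m1", "m2"])
        new, report = cross_deredundancy(db, {"h1", "h2"})
        assert report.host_tags_removed == 0
        assert report.microbial_tags_removed == 0
        assert new.host_tags == {"h1", "h2"}
        assert set(new.microbial) == {"m1", "m2"}

    def test_sole_species_tag_removal_flags_species(self):
        db = self._toy_db(["shared"])
        new, report = cross_deredundancy(db, {"shared", "h"})
        assert "shared" not in new.microbial
        assert "shared" not in new.host_tags
        assert report.genomes_removed == ("g1",)
        assert report.species_retained == 0

    def test_enzyme_mismatch_rejected(self):
        from holotag.enzyme import EnzymeSpec

        db = self._toy_db(["m"])
        other = EnzymeSpec("X", "CGANNNNNNTGC", 9, 9)
        with pytest.raises(InputError):
            cross_deredundancy(db, {"h"}, host_enzyme=other)

    def test_randomized_overlap_equals_set_algebra(self):
        rng = np.random.default_rng(9)
        universe = [f"t{i}" for i in range(300)]
        mic = set(rng.choice(universe, 150, replace=False))
        host = set(rng.choice(universe, 150, replace=False))
        db = TagDatabase(enzyme=BCGI)
        for i, t in enumerate(sorted(mic)):
            db.microbial[t] = TagRecord("species", f"S{i % 20}",
                                        (f"g{i % 20}",))
        new, report = cross_deredundancy(db, host)
        shared = mic & host
        assert set(new.microbial) == mic - shared
        assert new.host_tags == host - shared
        assert report.microbial_tags_removed == len(shared)
        assert report.host_tags_removed == len(shared)
        # Partition property: no tag on both sides after removal.
        assert not (set(new.microbial) & new.host_tags)
        # Conservation.
        assert (report.host_tags_removed + len(new.host_tags)
                == report.host_tags_before)
        assert (report.microbial_tags_removed + len(new.microbial)
                == report.microbial_tags_before)
        # theoretical_counts sums to species-specific tags in the map.
        n_species_specific = sum(
            1 for r in new.microbial.values() if r.rank == "species"
        )
        assert sum(new.theoretical_counts.values()) == n_species_specific


class TestStatistics:
    def test_empty_db(self):
        stats = db_statistics(TagDatabase(enzyme=BCGI), [])
        assert stats["n_genomes"] == 0
        assert stats["mean_tags_per_genome"] is None
        assert stats["fraction_by_rank"]["species"] is None

    def test_single_genome_all_species_specific(self):
        db = assign_specificity({"g1": {"a", "b"}}, {"g1": lineage()})
        stats = db_statistics(db, [])
        assert stats["tags_by_rank"]["species"] == 2
        assert stats["fraction_by_rank"]["species"] == 1.0


class TestPersistence:
    def _build(self):
        db = assign_specificity(
            {"g1": {"ACGT", "TTTT"}, "g2": {"ACGT"}},
            {"g1": lineage(), "g2": lineage(s="S2")},
        )
        db.host_tags = {"CCCC"}
        db.metadata["note"] = "toy"
        return db

    def test_round_trip_identity(self, tmp_path):
        db = self._build()
        path = str(tmp_path / "db.tsv.gz")
        save_db(db, path)
        loaded = load_db(path)
        assert loaded.microbial == db.microbial
        assert loaded.host_tags == db.host_tags
        assert loaded.theoretical_counts == db.theoretical_counts
        assert loaded.enzyme == db.enzyme
        assert loaded.metadata == db.metadata
        assert loaded.n_nonspecific == db.n_nonspecific

    def test_save_is_deterministic(self, tmp_path):
        db = self._build()
        p1, p2 = str(tmp_path / "a.gz"), str(tmp_path / "b.gz")
        save_db(db, p1)
        save_db(db, p2)
        assert open(p1, "rb").read() == open(p2, "rb").read()

    def test_truncated_file_rejected(self, tmp_path):
        import gzip

        db = self._build()
        path = str(tmp_path / "db.tsv.gz")
        save_db(db, path)
        lines = gzip.open(path, "rt").read().splitlines()[:-1]
        trunc = str(tmp_path / "trunc.gz")
        with gzip.open(trunc, "wt") as fh:
            fh.write("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="truncated"):
            load_db(trunc)

    def test_corrupt_row_reports_line_number(self, tmp_path):
        import gzip

        db = self._build()
        path = str(tmp_path / "db.tsv.gz")
        save_db(db, path)
        lines = gzip.open(path, "rt").read().splitlines()
        i = next(k for k, ln in enumerate(lines)
                 if not ln.startswith("#"))
        lines[i] = "corrupt\trow"
        bad = str(tmp_path / "bad.gz")
        with gzip.open(bad, "wt") as fh:
            fh.write("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match=f"line {i + 1}"):
            load_db(bad)

    def test_wrong_format_version_rejected(self, tmp_path):
        import gzip

        path = str(tmp_path / "v.gz")
        with gzip.open(path, "wt") as fh:
            fh.write("#FORMAT\tother/9\n#END\n")
        with pytest.raises(FormatError):
            load_db(path)
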