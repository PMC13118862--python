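"""Locus assignment, codominant calling, distances, NJ and PCA."""

import io
from collections import Counter
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import binom

from holotag.errors import InputError
from holotag.genotyper import (
    GenotypeCall,
    GenotypeMatrix,
    LocusPileup,
    allele_sharing_distance,
    assign_to_loci,
    call_genotype,
    concordance,
    neighbor_joining,
    pca,
)
from holotag.sequence import revcomp

from conftest import random_seq


def _mutate(tag: str, positions, rng) -> str:
    out = list(tag)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestAssignToLoci:
    def _refs(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return [random_seq(rng, 32) for _ in range(n)], rng

    def test_exact_match(self):
        refs, _ = self._refs()
        piles, amb = assign_to_loci({refs[0]: 5}, refs)
        assert piles[refs[0]].alleles == {refs[0]: 5}
        assert amb == 0

    def test_three_mismatches_unassigned(self):
        refs, rng = self._refs()
        query = _mutate(refs[0], [1, 5, 9], rng)
        piles, amb = assign_to_loci({query: 1}, refs)
        assert piles == {} and amb == 0

    def test_revcomp_query_assigned(self):
        refs, rng = self._refs()
        query = revcomp(_mutate(refs[3], [2], rng))
        piles, _ = assign_to_loci({query: 2}, refs)
        assert refs[3] in piles

    def test_tie_discarded_as_ambiguous(self):
        base = "A" * 32
        ref1 = _mutate(base, [0], None.__class__ and np.random.default_rng(0)) \
            if False else "C" + "A" * 31
        ref2 = "A" * 31 + "C"
        query = "A" * 32  # distance 1 from both references
        piles, amb = assign_to_loci({query: 7}, [ref1, ref2])
        assert piles == {} and amb == 7

    def test_pigeonhole_index_matches_bruteforce(self):
        refs, rng = self._refs(n=40, seed=3)

        def brute(query):
            best, winners = 99, []
            rc = revcomp(query)
            for i, r in enumerate(refs):
                d = min(sum(a != b for a, b in zip(query, r)),
                        sum(a != b for a, b in zip(rc, r)))
                if d < best:
                    best, winners = d, [i]
                elif d == best:
                    winners.append(i)
            if best > 2 or len(winners) != 1:
                return None
            return winners[0]

        queries = []
        for _ in range(300):
            base = refs[int(rng.integers(len(refs)))]
            k = int(rng.integers(0, 4))
            pos = rng.choice(32, size=k, replace=False)
            q = _mutate(base, pos, rng)
            if rng.random() < 0.5:
                q = revcomp(q)
            queries.append(q)
        queries.extend(random_seq(rng, 32) for _ in range(50))
        for q in queries:
            piles, _ = assign_to_loci({q: 1}, refs)
            expected = brute(q)
            got = next(iter(piles)) if piles else None
            assert got == (refs[expected] if expected is not None
                           else None)


class TestCallGenotype:
    def _pile(self, counts):
        return LocusPileup("L", Counter(counts))

    def test_single_allele_homozygote(self):
        call = call_genotype(self._pile({"A" * 32: 10}))
        assert call.status == "called"
        assert call.alleles == ("A" * 32,) * 2
        assert call.depth == 10

    def test_balanced_heterozygote(self):
        call = call_genotype(self._pile({"A" * 32: 5, "C" * 32: 5}))
        assert call.is_het

    def test_below_min_depth_undetermined(self):
        call = call_genotype(self._pile({"A" * 32: 2, "C" * 32: 1}))
        assert call.status == "undetermined" and call.depth == 3

    def test_depth_gate_counts_all_alleles(self):
        # Top-two depth is 3 but total is 4: locus passes the gate.
        call = call_genotype(
            self._pile({"A" * 32: 2, "C" * 32: 1, "G" * 32: 1})
        )
        assert call.status == "called"

    def test_decision_boundary_matches_bruteforce(self):
        """Sweep n2 at fixed M = 20; the hom/het decision must follow
        the explicit binomial likelihood comparison."""
        err = 0.01
        m = 20
        for n2 in range(0, m // 2 + 1):
            n1 = m - n2
            call = call_genotype(
                self._pile({"A" * 32: n1, "C" * 32: n2}), err=err
            )
            expect_het = bool(binom.pmf(n2, m, 0.5)
                              > binom.pmf(n2, m, err))
            assert call.is_het is expect_het, f"n2={n2}"


class TestConcordance:
    def _calls(self, spec):
        out = {}
        for locus, alleles in spec.items():
            if alleles is None:
                out[locus] = GenotypeCall(locus, "undetermined", None, 1)
            else:
                out[locus] = GenotypeCall(
                    locus, "called", tuple(sorted(alleles)), 10
                )
        return out

    def test_identity_is_full_agreement(self):
        calls = self._calls(
            {f"L{i}": ("A", "A") if i % 2 else ("A", "B")
             for i in range(10)}
        )
        out = concordance(calls, calls)
        for stratum in ("overall", "homozygote", "heterozygote"):
            assert out[stratum]["agreement"] == 1.0

    def test_hand_counted_table(self):
        spec1 = {f"L{i}": ("A", "A") for i in range(6)}
        spec1.update({f"H{i}": ("A", "B") for i in range(4)})
        spec2 = dict(spec1)
        spec2["L0"] = ("A", "C")       # hom discordance
        spec2["H0"] = ("A", "A")       # het discordance
        out = concordance(self._calls(spec1), self._calls(spec2))
        assert out["homozygote"] == {
            "genotyped": 6, "same": 5, "different": 1,
            "agreement": pytest.approx(5 / 6),
        }
        assert out["heterozygote"] == {
            "genotyped": 4, "same": 3, "different": 1,
            "agreement": pytest.approx(3 / 4),
        }
        assert out["overall"]["genotyped"] == 10

    def test_disjoint_called_loci_undefined(self):
        c1 = self._calls({"L1": ("A", "A"), "L2": None})
        c2 = self._calls({"L1": None, "L2": ("A", "A")})
        out = concordance(c1, c2)
        assert out["overall"]["agreement"] is None


class TestAlleleSharingDistance:
    def _matrix(self, genotypes):
        samples = sorted(genotypes)
        loci = sorted(next(iter(genotypes.values())))
        calls = {
            s: {
                loc: (GenotypeCall(loc, "called",
                                   tuple(sorted(genotypes[s][loc])), 10)
                     if genotypes[s][loc] else
                     GenotypeCall(loc, "undetermined", None, 0))
                for loc in loci
            }
            for s in samples
        }
        return GenotypeMatrix(samples=samples, loci=loci, calls=calls)

    def test_duplicate_samples_distance_zero(self):
        g = {f"L{i}": ("A", "B") for i in range(5)}
        m = self._matrix({"s1": g, "s2": dict(g)})
        assert allele_sharing_distance(m)[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        m = self._matrix({
            "s1": {f"L{i}": ("A", "A") for i in range(5)},
            "s2": {f"L{i}": ("B", "B") for i in range(5)},
        })
        assert allele_sharing_distance(m)[0, 1] == 1.0

    def test_hom_vs_het_half(self):
        m = self._matrix({
            "s1": {f"L{i}": ("A", "A") for i in range(5)},
            "s2": {f"L{i}": ("A", "B") for i in range(5)},
        })
        assert allele_sharing_distance(m)[0, 1] == 0.5

    def test_no_shared_loci_is_error(self):
        m = self._matrix({
            "s1": {"L0": ("A", "A"), "L1": None},
            "s2": {"L0": None, "L1": ("A", "A")},
        })
        with pytest.raises(InputError):
            allele_sharing_distance(m)


def _tree_path_metric(newick: str, labels):
    """Tip-to-tip path lengths via scikit-bio (independent parser)."""
    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tree.find(labels[i]).distance(tree.find(labels[j]))
            out[i, j] = out[j, i] = d
    return out


def _additive_metric_from_random_tree(rng, labels):
    """Build an additive distance matrix from a random binary tree with
    known branch lengths (the generating truth)."""
    import dendropy

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
        num_extant_tips=len(labels),
        rng=__import__("random").Random(int(rng.integers(2**31))),
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            t1 = taxa.get_taxon(labels[i])
            t2 = taxa.get_taxon(labels[j])
            d[i, j] = d[j, i] = pdm.distance(t1, t2)
    return d


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        nwk = neighbor_joining(d, ["a", "b", "c"])
        la = (0.3 + 0.5 - 0.6) / 2
        lb = (0.3 + 0.6 - 0.5) / 2
        lc = (0.5 + 0.6 - 0.3) / 2
        assert nwk == f"(a:{la:.10g},b:{lb:.10g},c:{lc:.10g});"

    @pytest.mark.parametrize("n_taxa", [4, 6, 9])
    def test_additive_metric_recovered_exactly(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        labels = [f"t{i}" for i in range(n_taxa)]
        d = _additive_metric_from_random_tree(rng, labels)
        nwk = neighbor_joining(d, labels)
        recovered = _tree_path_metric(nwk, labels)
        assert np.allclose(recovered, d, atol=1e-9)

    def test_matches_skbio_nj_path_metric(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(77)
        labels = [f"t{i}" for i in range(7)]
        d = _additive_metric_from_random_tree(rng, labels)
        ours = _tree_path_metric(neighbor_joining(d, labels), labels)
        theirs_tree = skbio_nj(DistanceMatrix(d, labels))
        theirs = np.zeros_like(d)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                theirs[i, j] = theirs[j, i] = theirs_tree.find(
                    labels[i]).distance(theirs_tree.find(labels[j]))
        assert np.allclose(ours, theirs, atol=1e-9)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(InputError):
            neighbor_joining(d, list("abc"))

    def test_negative_entry_rejected(self):
        d = np.array([[0, -1, 2], [-1, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(InputError):
            neighbor_joining(d, list("abc"))


class TestPCA:
    def _matrix_from_codes(self, codes):
        """codes: (n_samples, n_loci) of 0/1/2 or None."""
        n, p = len(codes), len(codes[0])
        samples = [f"s{i}" for i in range(n)]
        loci = [f"L{j}" for j in range(p)]
        allele = {0: ("R", "R"), 1: ("A", "R"), 2: ("A", "A")}
        calls = {}
        for i, s in enumerate(samples):
            row = {}
            for j, loc in enumerate(loci):
                c = codes[i][j]
                if c is None:
                    row[loc] = GenotypeCall(loc, "undetermined", None, 0)
                else:
                    row[loc] = GenotypeCall(
                        loc, "called", tuple(sorted(allele[c])), 10)
            calls[s] = row
        return GenotypeMatrix(samples=samples, loci=loci, calls=calls)

    def test_duplicated_samples_identical_coordinates(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=20).tolist()
        other = rng.integers(0, 3, size=20).tolist()
        m = self._matrix_from_codes([base, base, other, other])
        coords, _ = pca(m)
        assert np.allclose(coords[0], coords[1])
        assert np.allclose(coords[2], coords[3])

    def test_two_populations_separate_on_pc1(self):
        rng = np.random.default_rng(5)
        pop1 = [(rng.integers(0, 2, size=50) * 0).tolist()
                for _ in range(6)]
        pop2 = [(2 - rng.integers(0, 2, size=50) * 0).tolist()
                for _ in range(6)]
        noise = rng.integers(0, 3, size=(12, 10)).tolist()
        codes = [p + n for p, n in zip(pop1 + pop2, noise)]
        coords, explained = pca(self._matrix_from_codes(codes))
        pc1 = coords[:, 0]
        assert (pc1[:6].max() < pc1[6:].min()
                or pc1[6:].max() < pc1[:6].min())
        assert explained[0] > 0.5

    def test_explained_variance_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(6)
        codes = rng.integers(0, 3, size=(8, 40)).tolist()
        _, explained = pca(self._matrix_from_codes(codes))
        assert np.all(np.diff(explained) <= 1e-12)
        assert explained.sum() <= 1.0 + 1e-9

    def test_too_few_informative_loci_rejected(self):
        m = self._matrix_from_codes([[0, 0], [0, 0], [0, 0]])
        with pytest.raises(InputError):
            pca(m)
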