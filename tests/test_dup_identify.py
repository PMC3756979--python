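"""Synteny, orthology, paralog pairing, classification, polarization."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from lineagedup import dup_identify as di
from lineagedup.types import GeneModel, HomologyHit, ParalogPair


def _gene(gid, start, end, contig="chr1", cds=""):
    return GeneModel(gid, contig, start, end, "+",
                     cds_intervals=[(start, end)], cds_sequence=cds)


class TestAlignProteins:
    def test_identical_sequences(self):
        ident, cov, _, score = di.align_proteins("MKVLAW" * 10, "MKVLAW" * 10)
        assert ident == 100.0 and cov == 100.0 and score > 0

    def test_short_vs_long_coverage_bound(self):
        ident, cov, _, _ = di.align_proteins("ACDE", "ACDE" + "FGHIKLMNPQ")
        assert cov <= 100.0 * 4 / 14 + 1e-9

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            di.align_proteins("MKV1", "MKVL")
        with pytest.raises(ValueError, match="empty"):
            di.align_proteins("", "MKVL")

    def test_score_matches_independent_gotoh_oracle(self, rng):
        """Local DP score equals a from-scratch quadratic-space Gotoh
        affine-gap oracle with the same scoring."""
        B = substitution_matrices.load("BLOSUM62")

        def gotoh_local(a, b, open_=-11.0, ext=-1.0):
            n, m = len(a), len(b)
            NEG = -1e9
            M = np.zeros((n + 1, m + 1))
            Ix = np.full((n + 1, m + 1), NEG)
            Iy = np.full((n + 1, m + 1), NEG)
            best = 0.0
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    Ix[i][j] = max(M[i - 1][j] + open_, Ix[i - 1][j] + ext)
                    Iy[i][j] = max(M[i][j - 1] + open_, Iy[i][j - 1] + ext)
                    s = B[a[i - 1], b[j - 1]]
                    M[i][j] = max(0.0, M[i - 1][j - 1] + s, Ix[i - 1][j - 1] + s,
                                  Iy[i - 1][j - 1] + s)
                    best = max(best, M[i][j])
            return best

        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(3):
            a = "".join(rng.choice(list(aa), 100))
            b = list(a)
            for i in range(len(b)):
                if rng.random() < 0.3:
                    b[i] = aa[rng.integers(20)]
            b = "".join(b[5:95])
            _, _, _, score = di.align_proteins(a, b, "local")
            assert score == gotoh_local(a, b)


class TestCallOrthologs:
    def _hit(self, q, s, score, e=1e-30):
        return HomologyHit(q, s, 90.0, e, score)

    def test_symmetric_unique_best_hits(self):
        ab = [self._hit("a1", "b1", 500), self._hit("a1", "b2", 100)]
        ba = [self._hit("b1", "a1", 500)]
        assert di.call_orthologs(ab, ba) == [("a1", "b1")]

    def test_evalue_cutoff_one_direction(self):
        ab = [self._hit("a1", "b1", 500)]
        ba = [self._hit("b1", "a1", 500, e=0.01)]
        assert di.call_orthologs(ab, ba) == []

    def test_tied_best_scores_no_call(self):
        ab = [self._hit("a1", "b1", 500), self._hit("a1", "b2", 500)]
        ba = [self._hit("b1", "a1", 500), self._hit("b2", "a1", 500)]
        assert di.call_orthologs(ab, ba) == []


class TestBuildSynteny:
    def _setup(self, order_a, order_b):
        genes_a = [_gene(g, 1000 * i, 1000 * i + 500) for i, g in enumerate(order_a)]
        genes_b = [_gene("B" + g, 1000 * i, 1000 * i + 500, contig="chrB")
                   for i, g in enumerate(order_b)]
        hits = []
        for g in order_a:
            hits.append(HomologyHit(g, "B" + g, 99.0, 1e-40, 500.0))
            hits.append(HomologyHit("B" + g, g, 99.0, 1e-40, 500.0))
        return genes_a, genes_b, hits

    def test_identical_order_single_block(self):
        genes_a, genes_b, hits = self._setup("abcdef", "abcdef")
        blocks = di.build_synteny(genes_a, genes_b, hits, min_anchors=3)
        assert len(blocks) == 1 and len(blocks[0]) == 6

    def test_swap_with_gap_limit_one_drops_one_gene(self):
        genes_a, genes_b, hits = self._setup("abcd", "acbd")
        blocks = di.build_synteny(genes_a, genes_b, hits, min_anchors=3, max_gap=1)
        assert len(blocks) == 1 and len(blocks[0]) == 3

    def test_chain_is_optimal_vs_exhaustive_enumeration(self, rng):
        """Greedy-extracted first chain matches the brute-force longest
        collinear chain over all anchor subsets (<= 12 anchors)."""
        for _ in range(5):
            perm = list(rng.permutation(10))
            order_b = ["g%d" % i for i in perm]
            order_a = ["g%d" % i for i in range(10)]
            genes_a, genes_b, hits = self._setup(order_a, order_b)
            blocks = di.build_synteny(genes_a, genes_b, hits, min_anchors=1, max_gap=2)
            found = max((len(b) for b in blocks), default=0)
            # oracle: brute force over all subsets
            pos_b = {g: i for i, g in enumerate(order_b)}
            best = 0
            items = [(i, pos_b[g]) for i, g in enumerate(order_a)]
            for r in range(1, 11):
                for sub in itertools.combinations(items, r):
                    for sign in (1, -1):
                        ok = all(0 < b[0] - a[0] <= 3 and 0 < sign * (b[1] - a[1]) <= 3
                                 for a, b in zip(sub, sub[1:]))
                        if ok:
                            best = max(best, r)
            assert found == best

    def test_unknown_gene_in_hits_rejected(self):
        genes_a, genes_b, hits = self._setup("ab", "ab")
        hits.append(HomologyHit("zz", "Ba", 90.0, 1e-30, 100.0))
        with pytest.raises(ValueError, match="unknown gene"):
            di.build_synteny(genes_a, genes_b, hits)


class TestFindLineageSpecific:
    def _blocks(self, genes, og="og1"):
        anchors = [(g.gene_id, "B" + g.gene_id) for g in genes]
        from lineagedup.types import SyntenyBlock
        return [SyntenyBlock("focal", og, anchors)]

    def test_ortholog_in_one_outgroup_excludes(self):
        genes = [_gene("a", 0, 300), _gene("x", 1000, 1300)]
        blocks = {"og1": [], "og2": []}
        orthos = {"og1": [("x", "y")], "og2": []}
        assert di.find_lineage_specific(genes, blocks, orthos) == ["a"]

    def test_inside_synteny_without_rbh_excluded(self):
        # gene "n" overlaps the anchor footprint of gene "a" but has no RBH
        a = _gene("a", 0, 3000)
        n = _gene("n", 1000, 2000)
        blocks = {"og1": self._blocks([a])}
        orthos = {"og1": [("a", "Ba")]}
        assert di.find_lineage_specific([a, n], blocks, orthos) == []

    def test_mismatched_outgroup_sets_rejected(self):
        with pytest.raises(ValueError, match="same outgroups"):
            di.find_lineage_specific([], {"og1": []}, {"og2": []})


class TestClassifyDuplication:
    def _order(self, n=40):
        return [_gene(f"g{i}", 1000 * i, 1000 * i + 500) for i in range(n)]

    def test_adjacent_copies_are_tandem(self):
        genes = self._order()
        p = ParalogPair("g5", "g6")
        assert di.classify_duplication(p, genes, [p]) == "tandem"

    def test_companion_pair_within_ten_genes_is_segmental(self):
        genes = self._order()
        p1 = ParalogPair("g5", "g25")
        p2 = ParalogPair("g10", "g30")  # 5 genes from both copies, same order
        assert di.classify_duplication(p1, genes, [p1, p2]) == "segmental"
        assert di.classify_duplication(p2, genes, [p1, p2]) == "segmental"

    def test_opposite_order_companion_is_not_segmental(self):
        genes = self._order()
        p1 = ParalogPair("g5", "g30")
        p2 = ParalogPair("g10", "g25")  # crossing, segments not collinear
        assert di.classify_duplication(p1, genes, [p1, p2]) == "dispersed"

    def test_lone_cross_contig_pair_is_dispersed(self):
        genes = self._order(20) + [_gene("h0", 0, 500, contig="chr2")]
        p = ParalogPair("g3", "h0")
        assert di.classify_duplication(p, genes, [p]) == "dispersed"

    def test_companion_beyond_ten_genes_is_dispersed(self):
        genes = self._order()
        p1 = ParalogPair("g0", "g20")
        p2 = ParalogPair("g12", "g32")  # 11 intervening genes: too far
        assert di.classify_duplication(p1, genes, [p1, p2]) == "dispersed"


class TestPolarize:
    def test_synteny_fraction_route(self, small_genomes):
        gset, truth = small_genomes
        pairs = di.identify_ndg_pairs(gset, seed=0)
        by_pair = {frozenset((p.gene_1, p.gene_2)): p for p in pairs if not p.chimera}
        for t in truth.pairs:
            p = by_pair[frozenset((t.parent_id, t.ndg_id))]
            assert p.ndg_id == t.ndg_id, t
            assert p.parent_id == t.parent_id

    def test_polarization_is_antisymmetric(self, small_genomes):
        """Swapping gene_1/gene_2 never changes which copy is the NDG."""
        gset, truth = small_genomes
        pairs = di.identify_ndg_pairs(gset, seed=0)
        genes_focal = gset.genes[gset.focal_species]
        t = truth.pairs[0]
        fwd = ParalogPair(t.parent_id, t.ndg_id, duplication_class="tandem")
        rev = ParalogPair(t.ndg_id, t.parent_id, duplication_class="tandem")
        # reuse only the synteny route (no outgroup cds supplied)
        blocks = {}
        proteins = {sp: {g.gene_id: g.protein for g in gl}
                    for sp, gl in gset.genes.items()}
        for og in [s for s in gset.genes if s != "focal"]:
            hab = di.all_vs_all_hits(proteins["focal"], proteins[og])
            hba = di.all_vs_all_hits(proteins[og], proteins["focal"])
            blocks[og] = di.build_synteny(genes_focal, gset.genes[og], hab + hba,
                                          species_a="focal", species_b=og)
        a = di.polarize(fwd, blocks, genes_focal)
        b = di.polarize(rev, blocks, genes_focal)
        assert a.ndg_id == b.ndg_id == t.ndg_id

    def test_no_outgroup_tie_is_undetermined(self):
        genes = [_gene("a", 0, 300), _gene("b", 1000, 1300)]
        p = di.polarize(ParalogPair("a", "b"), {"og": []}, genes)
        assert p.polarization_method == "undetermined"
        assert p.parent_id == "" and p.ndg_id == ""


class TestDetectChimera:
    def _hits(self):
        return [
            HomologyHit("q", "donor1", 90.0, 1e-40, 300.0, (0, 150), (0, 150)),
            HomologyHit("q", "donor2", 90.0, 1e-35, 250.0, (150, 300), (10, 160)),
        ]

    def test_two_disjoint_donors_is_chimera(self):
        rep = di.detect_chimera("q", self._hits())
        assert rep["chimera"] and set(rep["donors"]) == {"donor1", "donor2"}

    def test_single_full_length_donor_is_not(self):
        rep = di.detect_chimera("q", [self._hits()[0]])
        assert not rep["chimera"]

    def test_overlapping_donors_not_chimera(self):
        hits = [
            HomologyHit("q", "d1", 90.0, 1e-40, 300.0, (0, 150), (0, 150)),
            HomologyHit("q", "d2", 90.0, 1e-35, 250.0, (30, 170), (0, 140)),
        ]
        assert not di.detect_chimera("q", hits)["chimera"]

    def test_te_donor_makes_te_fusion(self):
        rep = di.detect_chimera("q", self._hits(), te_annotation=[("donor2", 0, 200)])
        assert rep["chimera"] and rep["te_fusion"]

    def test_planted_chimera_found_with_correct_donors(self, small_genomes):
        gset, truth = small_genomes
        found = di.find_chimeras(gset)
        assert set(found) == set(truth.chimera_donors)
        for gid, donors in truth.chimera_donors.items():
            assert set(found[gid]["donors"]) == set(donors)


class TestPresenceFixation:
    def test_present_everywhere_is_fixed(self):
        assert di.presence_fixation({f"acc{i}": "present" for i in range(18)}) == "fixed"

    def test_one_absent_is_segregating(self):
        calls = {f"acc{i}": "present" for i in range(17)}
        calls["acc17"] = "absent"
        assert di.presence_fixation(calls) == "segregating"

    def test_unannotated_hit_counts_as_present(self):
        assert di.presence_fixation({"a": "unannotated-hit"}) == "fixed"

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            di.presence_fixation({})
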