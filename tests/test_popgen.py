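"""Diversity statistics, neutrality tests, empirical nulls, MK tests."""

import math

import numpy as np
import pytest
from scipy import stats

from lineagedup import popgen, synthetic_data as sd
from lineagedup._codon import GENETIC_CODE, STOP_CODONS
from lineagedup.types import (
    EmpiricalNull,
    GeneModel,
    HaplotypeMatrix,
    NeutralityResult,
    SimConfig,
)


def _matrix(geno, positions=None, L=100, **kw):
    geno = np.asarray(geno, dtype=np.int8)
    if positions is None:
        positions = np.arange(geno.shape[1]) * 3 + 1
    return HaplotypeMatrix([f"s{i}" for i in range(geno.shape[0])],
                           np.asarray(positions), geno, locus_length=L, **kw)


# frozen toy matrix: n=6, S=4, L=100; Tajima's D verified against
# dendropy.calculate.popgenstat; Fu & Li D*/F* against a from-scratch
# constants script (Fu & Li 1993 with the Simonsen et al. 1995 forms)
_TOY = np.array([
    [0, 0, 1, 0],
    [0, 1, 1, 0],
    [1, 0, 0, 0],
    [0, 0, 0, 1],
    [1, 1, 0, 0],
    [0, 0, 0, 0]], dtype=np.int8)
_TOY_POS = np.array([5, 10, 20, 40])


class TestClassifySites:
    def _gene(self, cds):
        return GeneModel("g", "c", 0, len(cds), "+",
                         cds_intervals=[(0, len(cds))], cds_sequence=cds)

    def test_fourfold_site_counts_fully_synonymous(self):
        gene = self._gene("GGG")  # glycine: third position 4-fold
        hm = _matrix(np.array([[0], [1]]), positions=[2], L=3)
        hm.ref_alleles, hm.alt_alleles = ["G"], ["A"]
        sc = popgen.classify_sites(gene, hm)
        assert sc.l_syn == pytest.approx(1.0)
        assert sc.snp_classes[2] == "synonymous"

    def test_atg_is_fully_nonsynonymous(self):
        gene = self._gene("ATG")
        hm = _matrix(np.array([[0], [1]]), positions=[0], L=3)
        hm.ref_alleles, hm.alt_alleles = ["A"], ["G"]
        sc = popgen.classify_sites(gene, hm)
        assert sc.l_nonsyn == pytest.approx(3.0)
        assert sc.snp_classes[0] == "nonsynonymous"

    def test_totals_match_exhaustive_substitution_oracle(self, rng):
        """Site totals equal direct enumeration of all 9 x n_codon single
        substitutions on a 10-codon gene."""
        cds = sd.random_cds(10, rng)
        gene = self._gene(cds)
        hm = _matrix(np.array([[0], [1]]), positions=[1], L=len(cds))
        hm.ref_alleles, hm.alt_alleles = [cds[1]], ["T" if cds[1] != "T" else "A"]
        sc = popgen.classify_sites(gene, hm)
        syn = 0.0
        for k in range(0, len(cds), 3):
            codon = cds[k : k + 3]
            for pos in range(3):
                alts = [codon[:pos] + n + codon[pos + 1 :]
                        for n in "ACGT" if n != codon[pos]]
                alts = [a for a in alts if a not in STOP_CODONS]
                if alts:
                    syn += sum(GENETIC_CODE[a] == GENETIC_CODE[codon]
                               for a in alts) / len(alts)
        assert sc.l_syn == pytest.approx(syn)
        assert sc.l_syn + sc.l_nonsyn == pytest.approx(3.0 * len(cds) / 3, abs=1e-9)


class TestDiversity:
    def test_no_segregating_sites_all_zero(self):
        hm = _matrix(np.zeros((4, 0)), positions=[], L=100)
        d = popgen.diversity(hm)
        assert d["pi_a"] == 0.0 and d["theta_a"] == 0.0

    def test_watterson_formula_direct(self):
        # n=4, S=2, L=100: theta = 2 / ((11/6) * 100)
        hm = _matrix(np.array([[0, 0], [1, 0], [0, 1], [0, 0]]), L=100)
        d = popgen.diversity(hm)
        assert d["theta_a"] == pytest.approx(2 / ((11 / 6) * 100))

    def test_invariant_under_relabeling(self):
        hm1 = _matrix(_TOY, _TOY_POS)
        perm = np.array([3, 1, 5, 0, 2, 4])
        hm2 = _matrix(_TOY[perm], _TOY_POS)
        flipped = _TOY.copy()
        flipped[:, 2] = 1 - flipped[:, 2]  # allele relabeling at one site
        hm3 = _matrix(flipped, _TOY_POS)
        for key in ("pi_a", "theta_a"):
            assert popgen.diversity(hm1)[key] == pytest.approx(popgen.diversity(hm2)[key])
            assert popgen.diversity(hm1)[key] == pytest.approx(popgen.diversity(hm3)[key])


class TestTajimaD:
    def test_frozen_toy_value(self):
        # verified against dendropy popgenstat on the same matrix
        assert popgen.tajima_d(_matrix(_TOY, _TOY_POS)) == pytest.approx(
            0.561681986158284, abs=1e-12)

    def test_undefined_without_segregating_sites(self):
        assert math.isnan(popgen.tajima_d(_matrix(np.zeros((4, 0)), positions=[])))

    def test_sign_reflects_frequency_spectrum(self, rng):
        cfg_neutral = SimConfig(seed=0, n_haplotypes=20, theta=8.0)
        cfg_skew = SimConfig(seed=0, n_haplotypes=20, theta=8.0, spectrum_skew=-0.7)

        def mean_d(cfg):
            vals = []
            for _ in range(400):
                d = popgen.tajima_d(sd.simulate_haplotypes(cfg, rng=rng))
                if np.isfinite(d):
                    vals.append(d)
            return float(np.mean(vals))

        assert mean_d(cfg_skew) < -1.0 < mean_d(cfg_neutral)


class TestFuLi:
    def test_frozen_toy_starred_values(self):
        d, f, starred = popgen.fu_li(_matrix(_TOY, _TOY_POS))
        assert starred
        assert d == pytest.approx(0.7692451366495073, abs=1e-12)
        assert f == pytest.approx(0.5061765616117713, abs=1e-12)

    def test_unstarred_with_full_ancestral_map(self):
        hm = _matrix(_TOY, _TOY_POS)
        anc = {int(p): 0 for p in _TOY_POS}
        d, f, starred = popgen.fu_li(hm, ancestral=anc)
        assert not starred
        # independent computation from the published unstarred constants
        n, S = 6, 4
        an = sum(1 / i for i in range(1, n))
        bn = sum(1 / i**2 for i in range(1, n))
        an1 = an + 1 / n
        cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
        vd = 1 + (an**2 / (bn + an**2)) * (cn - (n + 1) / (n - 1))
        ud = an - 1 - vd
        vf = (cn + 2 * (n * n + n + 3) / (9 * n * (n - 1)) - 2 / (n - 1)) / (an**2 + bn)
        uf = (1 + (n + 1) / (3 * (n - 1))
              - 4 * ((n + 1) / ((n - 1) ** 2)) * (an1 - 2 * n / (n + 1))) / an - vf
        counts = _TOY.sum(axis=0)
        eta_e = int((counts == 1).sum())
        pi_tot = sum(2 * c * (n - c) / (n * (n - 1)) for c in counts)
        assert d == pytest.approx((S - an * eta_e) / math.sqrt(ud * S + vd * S * S))
        assert f == pytest.approx((pi_tot - eta_e) / math.sqrt(uf * S + vf * S * S))

    def test_sparse_ancestral_map_falls_back_to_starred(self):
        hm = _matrix(_TOY, _TOY_POS)
        _, _, starred = popgen.fu_li(hm, ancestral={5: 0})
        assert starred

    def test_excess_singletons_give_negative_d(self, rng):
        cfg = SimConfig(seed=0, n_haplotypes=20, theta=8.0, spectrum_skew=-0.7)
        vals = []
        for _ in range(300):
            d, _, _ = popgen.fu_li(sd.simulate_haplotypes(cfg, rng=rng))
            if np.isfinite(d):
                vals.append(d)
        assert np.mean(vals) < -1.0


class TestEmpiricalNull:
    def test_spacing_filter_keeps_one_per_cluster(self, rng):
        cfg = SimConfig(seed=0, n_haplotypes=10, theta=5.0)
        loci = [(("chr1", i * 1000), sd.simulate_haplotypes(cfg, rng=rng))
                for i in range(100)]  # all within 25 kb of the previous
        with pytest.raises(ValueError, match="spacing"):
            popgen.build_empirical_null(loci, "tajima_d")

    def test_well_spaced_loci_subsampled_to_target(self, rng):
        cfg = SimConfig(seed=0, n_haplotypes=10, theta=5.0)
        loci = [(("chr%d" % (i // 250), (i % 250) * 30_000),
                 sd.simulate_haplotypes(cfg, rng=rng)) for i in range(1000)]
        null = popgen.build_empirical_null(loci, "tajima_d", n_target=800, seed=3)
        assert len(null.values) == 800

    def test_deterministic_and_input_order_independent(self, rng):
        cfg = SimConfig(seed=0, n_haplotypes=10, theta=5.0)
        loci = [(("chr1", i * 30_000), sd.simulate_haplotypes(cfg, rng=rng))
                for i in range(120)]
        n1 = popgen.build_empirical_null(loci, "tajima_d", n_target=60, seed=5)
        shuffled = list(loci)
        np.random.default_rng(0).shuffle(shuffled)
        n2 = popgen.build_empirical_null(shuffled, "tajima_d", n_target=60, seed=5)
        assert np.array_equal(n1.values, n2.values)


class TestEmpiricalP:
    def _null(self):
        return EmpiricalNull("tajima_d", np.linspace(-2.0, 2.0, 800))

    def test_extreme_negative_raw_zero(self):
        assert popgen.empirical_p(-5.0, self._null()) == 0.0
        assert popgen.empirical_p(-5.0, self._null(), add_one_smoothing=True) > 0.0

    def test_median_negative_about_half(self):
        null = EmpiricalNull("tajima_d", np.linspace(-2.0, 0.0, 801))
        assert popgen.empirical_p(-1.0, null) == pytest.approx(0.5, abs=0.01)

    def test_fifth_percentile_order_statistic(self):
        null = EmpiricalNull("tajima_d", np.arange(1, 801, dtype=float) - 900)
        # observed equal to the 40th smallest of 800 values -> p = 40/800
        assert popgen.empirical_p(float(null.values[39]), null) == pytest.approx(0.05)


class TestCallSelection:
    def test_all_p_one_no_flags(self):
        results = [NeutralityResult(f"g{i}", "ndg", tajima_d=-1.0,
                                    empirical_p={"tajima_d": 1.0}) for i in range(10)]
        out = popgen.call_selection(results)
        assert out["flagged"] == []

    def test_negative_value_required(self):
        r = NeutralityResult("g", "ndg", tajima_d=2.0, empirical_p={"tajima_d": 1e-6})
        out = popgen.call_selection([r])
        assert out["flagged"] == []

    def test_bh_matches_brute_force_definition(self, rng):
        pvals = rng.uniform(0, 1, 40)
        pvals[:5] = rng.uniform(0, 1e-4, 5)
        results = [NeutralityResult(f"g{i}", "ndg", tajima_d=-1.0,
                                    empirical_p={"tajima_d": float(p)})
                   for i, p in enumerate(pvals)]
        popgen.call_selection(results)
        qs = np.array([r.fdr_q["tajima_d"] for r in results])
        # brute-force BH: q_i = min over j with p_j >= p_i of p_j * m / rank_j
        m = len(pvals)
        order = np.argsort(pvals)
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, pvals[i] * m / rank)
            brute[i] = running
        assert np.allclose(qs, brute)


class TestMKTest:
    def _gene(self, cds):
        return GeneModel("g", "c", 0, len(cds), "+",
                         cds_intervals=[(0, len(cds))], cds_sequence=cds)

    def test_identical_paralog_no_polymorphism_empty(self):
        cds = "ATGAAATTTGGG"
        hm = _matrix(np.zeros((4, 0)), positions=[], L=len(cds))
        t = popgen.mk_test(hm, self._gene(cds), cds)
        assert (t.fixed_nonsyn, t.fixed_syn, t.poly_nonsyn, t.poly_syn) == (0, 0, 0, 0)
        assert math.isnan(t.fisher_p)

    def test_counts_on_constructed_case(self):
        # gene AAA AAA; paralog differs at codon1 pos0 (nonsyn fixed);
        # polymorphism at codon2 pos2 syn (AAA->AAG Lys)
        cds = "AAAAAA"
        paralog = "GAAAAA"  # K->E nonsynonymous
        geno = np.array([[0], [1], [0], [1]], dtype=np.int8)
        hm = _matrix(geno, positions=[5], L=6)
        hm.ref_alleles, hm.alt_alleles = ["A"], ["G"]
        t = popgen.mk_test(hm, self._gene(cds), paralog)
        assert t.fixed_nonsyn == 1 and t.fixed_syn == 0
        assert t.poly_syn == 1 and t.poly_nonsyn == 0

    def test_fisher_p_matches_hypergeometric_enumeration(self, rng):
        """Two-sided Fisher p equals direct enumeration of all tables
        with the observed margins (sum of hypergeometric pmf <= observed)."""
        for _ in range(20):
            dn, ds_, pn, ps_ = (int(x) for x in rng.integers(0, 15, 4))
            if dn + ds_ + pn + ps_ == 0:
                continue
            _, p = stats.fisher_exact([[dn, ds_], [pn, ps_]])
            row1, col1, n = dn + ds_, dn + pn, dn + ds_ + pn + ps_
            obs = stats.hypergeom.pmf(dn, n, row1, col1)
            total = 0.0
            for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
                pk = stats.hypergeom.pmf(k, n, row1, col1)
                if pk <= obs * (1 + 1e-9):
                    total += pk
            assert p == pytest.approx(min(1.0, total), rel=1e-6)

    def test_neutral_calibration_rejection_not_inflated(self, rng):
        """Under neutral divergence (omega=1) and neutral polymorphism the
        MK Fisher test rejects at most around the nominal rate."""
        rej = n_done = 0
        cfg = SimConfig(seed=0, n_haplotypes=20, theta=6.0, locus_length=300)
        for _ in range(150):
            cds = sd.random_cds(100, rng)
            paralog = sd.evolve_codon_pair(cds, 0.4, 1.0, 2.0, rng)
            hm = sd.simulate_haplotypes(cfg, rng=rng, reference_seq=cds)
            gene = self._gene(cds)
            hm.gene = gene
            t = popgen.mk_test(hm, gene, paralog)
            if np.isfinite(t.fisher_p):
                n_done += 1
                rej += t.fisher_p < 0.05
        assert n_done > 100
        assert rej / n_done <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_done)
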