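"""Polymorphism statistics, empirical-null significance, and MK tests.

Per-gene nucleotide diversity (pi), Watterson's theta, Tajima's D and
Fu & Li's D/F (starred, outgroup-free variants by default; unstarred
with an ancestral-allele map), significance against an empirical
genome-wide null of well-spaced loci (>= 25 kb apart, ~800 loci),
Benjamini-Hochberg FDR over the pooled p-values, and McDonald-Kreitman
tests of polymorphism vs fixed paralog divergence with Fisher's exact
test.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._codon import GENETIC_CODE, STOP_CODONS, codons_of
from .molevol import pairwise_codon_alignment, _site_fractions
from .types import (
    EmpiricalNull,
    GeneModel,
    HaplotypeMatrix,
    MKTable,
    NeutralityResult,
    SiteClassCounts,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# site classification


def _classify_substitution(codon: str, pos_in_codon: int, alt: str) -> str:
    mutant = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1 :]
    if mutant in STOP_CODONS:
        return "nonsynonymous"  # premature stop counts as nonsynonymous
    return "synonymous" if GENETIC_CODE[mutant] == GENETIC_CODE[codon] else "nonsynonymous"


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def classify_sites(gene: GeneModel, variants: HaplotypeMatrix) -> SiteClassCounts:
    """Fractional syn/nonsyn site totals over the gene's CDS (NG86
    convention) and a per-SNP class for every variant in the gene span.

    Each coding SNP is classified by substituting its alternate allele
    alone into the reference codon.  A SNP creating a premature stop is
    nonsynonymous (flagged via log).  Non-CDS SNPs are 'noncoding'.
    """
    if not gene.cds_sequence:
        raise ValueError(f"{gene.gene_id} has no CDS sequence")
    l_syn = l_nonsyn = 0.0
    for codon in codons_of(gene.cds_sequence):
        if codon in STOP_CODONS:
            continue
        s, n = _site_fractions(codon)
        l_syn += s
        l_nonsyn += n
    classes: dict[int, str] = {}
    codons = codons_of(gene.cds_sequence)
    for j, pos in enumerate(variants.positions):
        abs_pos = variants.locus_start + int(pos)
        if not gene.start <= abs_pos < gene.end:
            raise ValueError(f"variant at {abs_pos} outside gene span")
        off = gene.cds_offset(abs_pos)
        if off is None:
            classes[int(pos)] = "noncoding"
            continue
        if variants.alt_alleles is None or variants.ref_alleles is None:
            raise ValueError("coding-site classification needs ref/alt alleles")
        alt = variants.alt_alleles[j]
        if gene.strand == "-":
            alt = _COMP[alt]
        codon = codons[off // 3]
        cls = _classify_substitution(codon, off % 3, alt)
        mutant = codon[: off % 3] + alt + codon[off % 3 + 1 :]
        if mutant in STOP_CODONS:
            logger.info("SNP at %d creates a premature stop in %s", abs_pos, gene.gene_id)
        classes[int(pos)] = cls
    return SiteClassCounts(float(gene.length), l_syn, l_nonsyn, classes)


# ---------------------------------------------------------------------------
# diversity statistics


def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


def _pairwise_diff_total(variants: HaplotypeMatrix, site_mask=None) -> float:
    """Mean number of pairwise differences over the selected sites."""
    n = variants.n_samples
    geno = variants.genotypes if site_mask is None else variants.genotypes[:, site_mask]
    counts = geno.sum(axis=0).astype(float)
    return float((2.0 * counts * (n - counts) / (n * (n - 1))).sum())


def diversity(variants: HaplotypeMatrix, sites: SiteClassCounts | None = None) -> dict:
    """pi and Watterson's theta per site, for all / synonymous /
    nonsynonymous partitions.

    All-sites values use the full locus length; syn/nonsyn use the
    fractional site totals of the CDS.  A partition with zero length is
    reported as NaN (undefined, not 0).
    """
    n = variants.n_samples
    a1 = _harmonic(n)
    out = {}
    L_all = float(sites.l_total if sites else variants.locus_length)

    def part(mask, L, suffix):
        if L <= 0:
            out[f"pi_{suffix}"] = out[f"theta_{suffix}"] = float("nan")
            return
        S = int(mask.sum()) if mask is not None else variants.n_sites
        out[f"pi_{suffix}"] = _pairwise_diff_total(variants, mask) / L
        out[f"theta_{suffix}"] = S / (a1 * L)

    part(None, L_all, "a")
    if sites is not None:
        cls = np.array([sites.snp_classes.get(int(p), "noncoding")
                        for p in variants.positions])
        part(cls == "synonymous", sites.l_syn, "s")
        part(cls == "nonsynonymous", sites.l_nonsyn, "n")
    else:
        out["pi_s"] = out["theta_s"] = out["pi_n"] = out["theta_n"] = float("nan")
    return out


def tajima_d(variants: HaplotypeMatrix) -> float:
    """Tajima's (1989) D; NaN when there are no segregating sites."""
    n = variants.n_samples
    S = variants.n_sites
    if S < 1:
        return float("nan")
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi_total = _pairwise_diff_total(variants)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((pi_total - S / a1) / math.sqrt(var))


def _fuli_constants(n: int) -> dict:
    an = _harmonic(n)
    bn = _harmonic(n, 2)
    an1 = an + 1.0 / n  # a_{n+1}
    if n > 2:
        cn = 2.0 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    else:
        cn = 1.0
    if n > 2:
        dn = cn + (n - 2) / ((n - 1) ** 2) + (2.0 / (n - 1)) * (
            1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
    else:
        dn = 2.0
    # unstarred (derived singletons via an outgroup)
    vd = 1 + (an**2 / (bn + an**2)) * (cn - (n + 1) / (n - 1))
    ud = an - 1 - vd
    vf = (cn + 2 * (n * n + n + 3) / (9 * n * (n - 1)) - 2 / (n - 1)) / (an**2 + bn)
    uf = (1 + (n + 1) / (3 * (n - 1))
          - 4 * ((n + 1) / ((n - 1) ** 2)) * (an1 - 2 * n / (n + 1))) / an - vf
    # starred (outgroup-free; Simonsen et al. 1995 corrections)
    vds = ((n / (n - 1)) ** 2 * bn + an**2 * dn
           - 2 * (n * an * (an + 1)) / ((n - 1) ** 2)) / (an**2 + bn)
    uds = (n / (n - 1)) * (an - n / (n - 1)) - vds
    vfs = (dn + 2 * (n * n + n + 3) / (9 * n * (n - 1))
           - (2.0 / (n - 1)) * (4 * bn - 6 + 8.0 / n)) / (an**2 + bn)
    ufs = (n / (n - 1) + (n + 1) / (3 * (n - 1)) - 4.0 / (n * (n - 1))
           + 2 * ((n + 1) / ((n - 1) ** 2)) * (an1 - 2 * n / (n + 1))) / an - vfs
    return {"an": an, "bn": bn, "ud": ud, "vd": vd, "uf": uf, "vf": vf,
            "uds": uds, "vds": vds, "ufs": ufs, "vfs": vfs}


def fu_li(variants: HaplotypeMatrix,
          ancestral: dict[int, int] | None = None) -> tuple[float, float, bool]:
    """Fu & Li's D and F.

    With an ancestral-allele map (position -> ancestral state 0/1)
    covering >= 90% of SNPs, the unstarred statistics are computed from
    derived singletons; otherwise (or on insufficient coverage, logged)
    the starred, outgroup-free variants use sample singletons.  Returns
    ``(D, F, starred)``; NaN/NaN when there are no segregating sites.
    """
    n = variants.n_samples
    S = variants.n_sites
    if S < 1:
        return float("nan"), float("nan"), ancestral is None
    counts = variants.genotypes.sum(axis=0).astype(int)
    k = _fuli_constants(n)
    pi_total = _pairwise_diff_total(variants)
    use_starred = True
    if ancestral is not None:
        covered = sum(int(p) in ancestral for p in variants.positions)
        if covered / S >= 0.9:
            use_starred = False
        else:
            logger.info("ancestral map covers %d/%d SNPs; using starred statistics",
                        covered, S)
    if not use_starred:
        eta_e = 0
        for j, p in enumerate(variants.positions):
            anc = ancestral.get(int(p))
            if anc is None:
                continue
            derived = counts[j] if anc == 0 else n - counts[j]
            if derived == 1:
                eta_e += 1
        var_d = k["ud"] * S + k["vd"] * S * S
        var_f = k["uf"] * S + k["vf"] * S * S
        d = (S - k["an"] * eta_e) / math.sqrt(var_d) if var_d > 0 else float("nan")
        f = (pi_total - eta_e) / math.sqrt(var_f) if var_f > 0 else float("nan")
        return float(d), float(f), False
    eta_s = int(((counts == 1) | (counts == n - 1)).sum())
    var_d = k["uds"] * S + k["vds"] * S * S
    var_f = k["ufs"] * S + k["vfs"] * S * S
    d = ((n / (n - 1)) * S - k["an"] * eta_s) / math.sqrt(var_d) if var_d > 0 else float("nan")
    f = (pi_total - ((n - 1) / n) * eta_s) / math.sqrt(var_f) if var_f > 0 else float("nan")
    return float(d), float(f), True


# ---------------------------------------------------------------------------
# empirical null


_STATISTICS = {
    "tajima_d": tajima_d,
    "fuli_d": lambda v: fu_li(v)[0],
    "fuli_f": lambda v: fu_li(v)[1],
}


def build_empirical_null(loci: list[tuple[tuple[str, int], HaplotypeMatrix]],
                         statistic: str, n_target: int = 800,
                         min_spacing: int = 25_000, seed: int = 0,
                         min_loci: int = 50) -> EmpiricalNull:
    """Genome-wide null distribution of a neutrality statistic.

    Loci are sorted by coordinate, thinned greedily left-to-right so
    retained loci are >= ``min_spacing`` apart per chromosome, then
    randomly subsampled (seeded) to ``n_target``.  Loci whose statistic
    is undefined (no segregating sites) are dropped.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    fn = _STATISTICS[statistic]
    loci_sorted = sorted(loci, key=lambda x: x[0])
    retained = []
    last: dict[str, int] = {}
    for (contig, pos), mat in loci_sorted:
        if contig in last and pos - last[contig] < min_spacing:
            continue
        last[contig] = pos
        retained.append(mat)
    values = np.array([fn(m) for m in retained], dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < min_loci:
        raise ValueError(
            f"only {len(values)} loci retained after spacing filter; "
            f"null too small to be meaningful")
    rng = np.random.default_rng(seed)
    if len(values) > n_target:
        values = rng.choice(values, size=n_target, replace=False)
    return EmpiricalNull(statistic, np.sort(values), min_spacing, len(loci))


def empirical_p(observed: float, null: EmpiricalNull,
                add_one_smoothing: bool = False) -> float:
    """Signed one-tail empirical p: lower tail for negative observations,
    upper tail otherwise, inclusive comparisons.  The raw proportion may
    be 0 unless ``add_one_smoothing`` is set."""
    if len(null.values) == 0:
        raise ValueError("empty null")
    v = null.values
    if observed < 0:
        count = int((v <= observed).sum())
    else:
        count = int((v >= observed).sum())
    if add_one_smoothing:
        return (count + 1) / (len(v) + 1)
    return count / len(v)


def call_selection(results: list[NeutralityResult], alpha: float = 0.05) -> dict:
    """FDR-corrected selection calls over the pooled NDG+parent tests.

    For each statistic the empirical p-values of all genes are pooled
    and Benjamini-Hochberg corrected; a gene is flagged when any
    statistic has q < alpha AND a negative observed value.  Returns the
    flagged ids and per-class counts/percentages (1 decimal).
    """
    if not results:
        raise ValueError("need at least one result")
    statistics = sorted({s for r in results for s in r.empirical_p})
    for stat in statistics:
        idx = [i for i, r in enumerate(results) if stat in r.empirical_p]
        pvals = [results[i].empirical_p[stat] for i in idx]
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for i, q in zip(idx, qvals):
            results[i].fdr_q[stat] = float(q)
    flagged = []
    for r in results:
        value_of = {"tajima_d": r.tajima_d, "fuli_d": r.fuli_d, "fuli_f": r.fuli_f}
        r.selection_flag = any(
            r.fdr_q.get(s, 1.0) < alpha and value_of.get(s, float("nan")) < 0
            for s in statistics)
        if r.selection_flag:
            flagged.append(r.gene_id)
    summary = {}
    for cls in sorted({r.gene_class for r in results if r.gene_class}):
        members = [r for r in results if r.gene_class == cls]
        k = sum(r.selection_flag for r in members)
        summary[cls] = {
            "flagged": k, "total": len(members),
            "percentage": round(100.0 * k / len(members), 1) if members else float("nan"),
        }
    return {"flagged": flagged, "summary": summary}


# ---------------------------------------------------------------------------
# McDonald-Kreitman


def mk_test(variants: HaplotypeMatrix, gene: GeneModel, paralog_cds: str) -> MKTable:
    """MK contrast of polymorphism within the focal sample against fixed
    divergence from the paralog.

    A coding site is a fixed difference when the focal sample is
    monomorphic and differs from the aligned paralog codon position; a
    polymorphic site is any segregating coding site (fixed-difference
    sites are by construction excluded from the polymorphism cells).
    Both kinds are classified syn/nonsyn by single substitution into the
    focal reference codon.  Two-sided Fisher's exact test on the 2x2.
    """
    if not gene.cds_sequence:
        raise ValueError("focal gene needs a CDS sequence")
    aln = pairwise_codon_alignment(gene.cds_sequence, paralog_cds)
    focal_aln, para_aln = aln.seqs
    # map focal CDS offset -> paralog nucleotide at the aligned position
    para_at: dict[int, str] = {}
    off = 0
    for a, b in zip(focal_aln, para_aln):
        if a != "-":
            if b != "-":
                para_at[off] = b
            off += 1

    codons = codons_of(gene.cds_sequence)
    n = variants.n_samples
    counts = variants.genotypes.sum(axis=0).astype(int)
    segregating_offsets = {}
    for j, p in enumerate(variants.positions):
        o = gene.cds_offset(variants.locus_start + int(p))
        if o is not None and 0 < counts[j] < n:
            segregating_offsets[o] = j

    pn = ps = dn = ds = 0
    for o in range(len(gene.cds_sequence)):
        codon = codons[o // 3]
        if codon in STOP_CODONS:
            continue
        if o in segregating_offsets:
            j = segregating_offsets[o]
            if variants.alt_alleles is None:
                raise ValueError("polymorphism classification needs alt alleles")
            alt = variants.alt_alleles[j]
            if gene.strand == "-":
                alt = _COMP[alt]
            cls = _classify_substitution(codon, o % 3, alt)
            if cls == "synonymous":
                ps += 1
            else:
                pn += 1
        else:
            para_nt = para_at.get(o)
            if para_nt is None or para_nt == gene.cds_sequence[o]:
                continue
            # monomorphic focal site differing from the paralog
            cls = _classify_substitution(codon, o % 3, para_nt)
            if cls == "synonymous":
                ds += 1
            else:
                dn += 1
    table = MKTable(dn, ds, pn, ps)
    if dn + ds + pn + ps > 0:
        _, p = stats.fisher_exact([[dn, ds], [pn, ps]], alternative="two-sided")
        table.fisher_p = float(p)
    return table


def neutrality_scan(genes: list[tuple[str, str, HaplotypeMatrix]],
                    nulls: dict[str, EmpiricalNull],
                    alpha: float = 0.05) -> tuple[list[NeutralityResult], dict]:
    """Convenience driver: per-gene statistics, empirical p-values
    against the supplied nulls, and pooled FDR selection calls.

    ``genes`` is a list of (gene_id, gene_class, haplotype matrix).
    """
    results = []
    for gid, cls, mat in genes:
        r = NeutralityResult(gid, cls)
        div = diversity(mat)
        r.pi, r.theta_w = div["pi_a"], div["theta_a"]
        r.tajima_d = tajima_d(mat)
        r.fuli_d, r.fuli_f, _ = fu_li(mat)
        for stat, val in (("tajima_d", r.tajima_d), ("fuli_d", r.fuli_d),
                          ("fuli_f", r.fuli_f)):
            if stat in nulls and np.isfinite(val):
                r.empirical_p[stat] = empirical_p(val, nulls[stat])
        results.append(r)
    calls = call_selection(results, alpha=alpha)
    return results, calls
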