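"""Codon-model divergence estimation and likelihood-ratio tests.

Pairwise Ka/Ks under a GY94-style 61-codon substitution model (kappa for
transitions, omega for the nonsynonymous rate, equal codon frequencies
by default with an F3x4 option), with likelihood-ratio tests of the free
omega against omega fixed at 0.5 and at 1 (chi-square, 1 df).  A
two-ratio branch model (foreground vs background omega) is fitted by the
pruning algorithm on small trees.  Nei-Gojobori (1986) counting with
pathway averaging and Jukes-Cantor correction serves as initializer and
independent cross-check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

from ._codon import (
    CODON_INDEX,
    GENETIC_CODE,
    N_CODONS,
    STOP_CODONS,
    codon_structure,
    codons_of,
    rate_matrix,
    transition_probabilities,
    translate,
)
from .types import BranchOmegaFit, OmegaFit

_T_BOUNDS = (1e-6, 50.0)
_KAPPA_BOUNDS = (0.1, 20.0)
_OMEGA_BOUNDS = (1e-4, 99.0)


# ---------------------------------------------------------------------------
# codon alignment


@dataclass
class CodonAlignment:
    """CDSs aligned codon-wise through their protein alignment."""

    ids: list[str]
    seqs: list[str]  # aligned CDS strings, gaps as '---'

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must have equal length")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("alignment length must be divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3 if self.seqs else 0

    def ungapped_codon_columns(self) -> list[tuple[str, ...]]:
        cols = []
        for k in range(self.n_codons):
            col = tuple(s[3 * k : 3 * k + 3] for s in self.seqs)
            if any("-" in c for c in col) or any(c in STOP_CODONS for c in col):
                continue
            cols.append(col)
        return cols


def align_protein_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global affine-gap protein alignment, returned as gapped strings."""
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    a.mode = "global"
    aln = a.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def codon_align(cds_list: list[str], protein_alignment: list[str],
                ids: list[str] | None = None) -> CodonAlignment:
    """Back-map a protein alignment onto the CDSs, gaps propagating 3:1.

    Each CDS must translate to its ungapped protein (a trailing stop
    codon on the CDS is tolerated and dropped).
    """
    if len(cds_list) != len(protein_alignment):
        raise ValueError("one aligned protein per CDS required")
    ids = ids or [f"seq{i}" for i in range(len(cds_list))]
    out = []
    for cds, prot_aln in zip(cds_list, protein_alignment):
        cds = cds.upper()
        codons = codons_of(cds)
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        prot = prot_aln.replace("-", "")
        expected = translate("".join(codons))
        if expected != prot:
            for i, (a, b) in enumerate(zip(expected, prot)):
                if a != b:
                    raise ValueError(
                        f"CDS does not translate to aligned protein at residue {i}: "
                        f"{a} vs {b}")
            raise ValueError("CDS/protein length mismatch")
        it = iter(codons)
        out.append("".join("---" if c == "-" else next(it) for c in prot_aln))
    return CodonAlignment(ids, out)


def pairwise_codon_alignment(cds_a: str, cds_b: str,
                             ids: tuple[str, str] = ("seq0", "seq1")) -> CodonAlignment:
    """Protein-guided codon alignment of two CDSs."""

    def _prot(cds):
        c = codons_of(cds.upper())
        if c and c[-1] in STOP_CODONS:
            c = c[:-1]
        return translate("".join(c))

    pa, pb = align_protein_pair(_prot(cds_a), _prot(cds_b))
    return codon_align([cds_a, cds_b], [pa, pb], list(ids))


# ---------------------------------------------------------------------------
# NG86 counting


def _site_fractions(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) sites of one codon; changes
    to stop codons are excluded from the opportunity count."""
    syn = nonsyn = 0.0
    for pos in range(3):
        alts = [codon[:pos] + n + codon[pos + 1 :] for n in "TCAG" if n != codon[pos]]
        alts = [a for a in alts if a not in STOP_CODONS]
        if not alts:
            continue
        s = sum(GENETIC_CODE[a] == GENETIC_CODE[codon] for a in alts)
        syn += s / len(alts)
        nonsyn += (len(alts) - s) / len(alts)
    return syn, nonsyn


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts
    between two codons, skipping pathways through stop codons."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    total_s = total_n = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        s = n = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            total_s += s
            total_n += n
            n_paths += 1
    if n_paths == 0:  # all pathways blocked; fall back to counting all
        for order in itertools.permutations(diff_pos):
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                total_s += GENETIC_CODE.get(cur, "*") == GENETIC_CODE.get(nxt, "*")
                total_n += GENETIC_CODE.get(cur, "*") != GENETIC_CODE.get(nxt, "*")
                cur = nxt
        n_paths = math.factorial(len(diff_pos))
    return total_s / n_paths, total_n / n_paths


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) if p > 0 else 0.0


def ng86_counts(aln: CodonAlignment) -> dict:
    """Nei-Gojobori (1986) Ka/Ks for a pairwise codon alignment.

    Returns a dict with fractional site counts (``s_sites``/``n_sites``),
    pathway-averaged differences, proportions, and the Jukes-Cantor
    corrected ``ka``/``ks`` (NaN with ``saturated=True`` when a corrected
    proportion is undefined).
    """
    if len(aln.seqs) != 2:
        raise ValueError("NG86 requires a pairwise alignment")
    s_sites = n_sites = sd = nd = 0.0
    for c1, c2 in aln.ungapped_codon_columns():
        s1, n1 = _site_fractions(c1)
        s2, n2 = _site_fractions(c2)
        s_sites += (s1 + s2) / 2
        n_sites += (n1 + n2) / 2
        ds, dn = _pathway_differences(c1, c2)
        sd += ds
        nd += dn
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks, ka = _jc_correct(ps), _jc_correct(pn)
    return {
        "s_sites": s_sites, "n_sites": n_sites, "syn_differences": sd,
        "nonsyn_differences": nd, "ps": ps, "pn": pn, "ks": ks, "ka": ka,
        "omega": (ka / ks) if ks and ks > 0 and not math.isnan(ka) else float("nan"),
        "saturated": math.isnan(ks) or math.isnan(ka),
    }


# ---------------------------------------------------------------------------
# pairwise ML fit


def _pair_count_matrix(aln: CodonAlignment) -> np.ndarray:
    counts = np.zeros((N_CODONS, N_CODONS))
    for c1, c2 in aln.ungapped_codon_columns():
        counts[CODON_INDEX[c1], CODON_INDEX[c2]] += 1
    return counts


def _pairwise_nll(params: np.ndarray, counts: np.ndarray, freqs: np.ndarray,
                  fixed_omega: float | None) -> float:
    t, kappa = np.exp(params[0]), np.exp(params[1])
    omega = fixed_omega if fixed_omega is not None else np.exp(params[2])
    q = rate_matrix(kappa, omega, freqs)
    p = transition_probabilities(q, t, freqs)
    with np.errstate(divide="ignore"):
        logterm = np.log(np.clip(freqs[:, None] * p, 1e-300, None))
    return -float((counts * logterm).sum())


def _flux_fractions(kappa: float, omega: float, freqs: np.ndarray) -> float:
    """Proportion of the substitution rate that is synonymous."""
    s = codon_structure()
    q = rate_matrix(kappa, omega, freqs)
    off = q.copy()
    np.fill_diagonal(off, 0.0)
    flux = freqs[:, None] * off
    total = flux.sum()
    return float(flux[s["synonymous"]].sum() / total) if total > 0 else 0.0


def _site_proportions(kappa: float, freqs: np.ndarray) -> float:
    """Fraction of mutational opportunity that is synonymous, i.e. the
    synonymous flux under the same model with omega = 1."""
    return _flux_fractions(kappa, 1.0, freqs)


def fit_pairwise_omega(aln: CodonAlignment, freqs: np.ndarray | None = None,
                       fit_fixed: bool = True) -> OmegaFit:
    """ML fit of (t, kappa, omega) for a pairwise codon alignment, plus
    fixed-omega fits at 0.5 and 1 and their chi-square(1) LRT p-values.

    Pairs without any substitution are reported with Ka = Ks = 0 and no
    LRT (the test is undefined; they form their own summary category).
    """
    if len(aln.seqs) != 2:
        raise ValueError("pairwise fit requires exactly 2 sequences")
    counts = _pair_count_matrix(aln)
    n_codons = int(counts.sum())
    if freqs is None:
        freqs = np.full(N_CODONS, 1.0 / N_CODONS)
    ident = float(np.trace(counts))
    if n_codons == 0:
        raise ValueError("no ungapped codon columns")
    if ident == counts.sum():
        ll = -_pairwise_nll(np.log([_T_BOUNDS[0], 2.0]), counts, freqs, 1.0)
        return OmegaFit(0.0, 0.0, float("nan"), float("nan"), 0.0,
                        ll, ll, ll, float("nan"), float("nan"),
                        n_codons, zero_substitutions=True)

    ng = ng86_counts(aln)
    t0 = max((ng["ks"] * 3 * _site_proportions(2.0, freqs)
              + ng["ka"] * 3 * (1 - _site_proportions(2.0, freqs)))
             if not ng["saturated"] else 0.3, 1e-3)
    w0 = ng["omega"] if np.isfinite(ng.get("omega", np.nan)) and ng["omega"] > 0 else 0.5

    def _fit(fixed_omega, starts):
        best = None
        for x0 in starts:
            res = optimize.minimize(
                _pairwise_nll, np.log(x0), args=(counts, freqs, fixed_omega),
                method="L-BFGS-B",
                bounds=[(math.log(a), math.log(b)) for a, b in
                        ([_T_BOUNDS, _KAPPA_BOUNDS] +
                         ([] if fixed_omega is not None else [_OMEGA_BOUNDS]))],
                options={"ftol": 1e-12, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
        return best

    w0c = min(max(w0, _OMEGA_BOUNDS[0] * 2), _OMEGA_BOUNDS[1] / 2)
    free = _fit(None, [[t0, 2.0, w0c], [0.2, 2.0, 0.5]])
    t, kappa, omega = np.exp(free.x)
    fixed_half = _fit(0.5, [[t, kappa]]) if fit_fixed else None
    fixed_one = _fit(1.0, [[t, kappa]]) if fit_fixed else None

    logl_free = -free.fun
    ll_half = -fixed_half.fun if fixed_half else float("nan")
    ll_one = -fixed_one.fun if fixed_one else float("nan")
    p_half = float(stats.chi2.sf(max(0.0, 2 * (logl_free - ll_half)), 1)) if fit_fixed else float("nan")
    p_one = float(stats.chi2.sf(max(0.0, 2 * (logl_free - ll_one)), 1)) if fit_fixed else float("nan")

    s_frac = _site_proportions(kappa, freqs)
    rho_s = _flux_fractions(kappa, omega, freqs)
    s_sites, n_sites = 3 * s_frac, 3 * (1 - s_frac)
    ks = t * rho_s / s_sites if s_sites > 0 else float("nan")
    ka = t * (1 - rho_s) / n_sites if n_sites > 0 else float("nan")
    return OmegaFit(float(ka), float(ks), float(omega), float(kappa), float(t),
                    float(logl_free), float(ll_half), float(ll_one),
                    p_half, p_one, n_codons,
                    converged=bool(free.success))


# ---------------------------------------------------------------------------
# trees and the pruning likelihood


@dataclass
class TreeNode:
    name: str = ""
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.1
    foreground: bool = False

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def branches(self) -> list["TreeNode"]:
        out = []
        for c in self.children:
            out.append(c)
            out.extend(c.branches())
        return out


def parse_newick(text: str) -> TreeNode:
    """Minimal newick parser; '#1' after a name/length marks the
    foreground branch (PAML convention)."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                else:
                    break
            if text[pos] != ")":
                raise ValueError(f"unbalanced parentheses at {pos}")
            pos += 1
        # label / foreground tag / branch length
        label = ""
        while pos < len(text) and text[pos] not in ",()":
            label += text[pos]
            pos += 1
        if ":" in label:
            label, _, blen = label.partition(":")
            if blen.endswith("#1"):
                node.foreground = True
                blen = blen[:-2]
            if blen:
                node.length = float(blen)
        if label.endswith("#1"):
            node.foreground = True
            label = label[:-2]
        node.name = label
        return node

    root = parse_node()
    return root


def _pruning_loglik(root: TreeNode, aln: CodonAlignment,
                    p_for_branch, freqs: np.ndarray) -> float:
    """Felsenstein pruning over the alignment's ungapped codon columns.

    ``p_for_branch(node)`` returns the 61x61 transition matrix of the
    branch above ``node``.
    """
    cols = aln.ungapped_codon_columns()
    patterns: dict[tuple[str, ...], int] = {}
    for col in cols:
        patterns[col] = patterns.get(col, 0) + 1
    ids = {name: i for i, name in enumerate(aln.ids)}
    pats = list(patterns)
    counts = np.array([patterns[p] for p in pats], dtype=float)
    npat = len(pats)

    def partial(node: TreeNode) -> np.ndarray:
        if not node.children:
            L = np.zeros((N_CODONS, npat))
            row = ids[node.name]
            for k, pat in enumerate(pats):
                L[CODON_INDEX[pat[row]], k] = 1.0
            return L
        L = np.ones((N_CODONS, npat))
        for child in node.children:
            L *= p_for_branch(child) @ partial(child)
        return L

    site_lik = freqs @ partial(root)
    return float((counts * np.log(np.clip(site_lik, 1e-300, None))).sum())


def pruning_loglik(root: TreeNode, aln: CodonAlignment, kappa: float,
                   omega: float, freqs: np.ndarray | None = None) -> float:
    """One-ratio pruning log-likelihood (used for cross-checks)."""
    if freqs is None:
        freqs = np.full(N_CODONS, 1.0 / N_CODONS)
    q = rate_matrix(kappa, omega, freqs)
    cache: dict[float, np.ndarray] = {}

    def p_for(node: TreeNode) -> np.ndarray:
        if node.length not in cache:
            cache[node.length] = transition_probabilities(q, node.length, freqs)
        return cache[node.length]

    return _pruning_loglik(root, aln, p_for, freqs)


def fit_branch_omega(aln: CodonAlignment, tree: TreeNode | str,
                     freqs: np.ndarray | None = None) -> BranchOmegaFit:
    """Two-ratio branch model: foreground omega on the tagged branch,
    background omega elsewhere; LRT against foreground omega = 1."""
    root = parse_newick(tree) if isinstance(tree, str) else tree
    leaves = {lf.name for lf in root.leaves()}
    if len(leaves) < 3:
        raise ValueError("branch model needs >= 3 taxa")
    if not leaves <= set(aln.ids):
        raise ValueError(f"tree leaves {leaves - set(aln.ids)} missing from alignment")
    branches = root.branches()
    fg = [b for b in branches if b.foreground]
    if len(fg) != 1:
        raise ValueError("exactly one foreground branch required")
    if freqs is None:
        freqs = np.full(N_CODONS, 1.0 / N_CODONS)
    nb = len(branches)

    def nll(params, fixed_fg):
        blens = np.exp(params[:nb])
        kappa = np.exp(params[nb])
        w_bg = np.exp(params[nb + 1])
        w_fg = fixed_fg if fixed_fg is not None else np.exp(params[nb + 2])
        q_bg = rate_matrix(kappa, w_bg, freqs)
        q_fg = rate_matrix(kappa, w_fg, freqs)
        pmats = {}
        for i, b in enumerate(branches):
            q = q_fg if b.foreground else q_bg
            pmats[id(b)] = transition_probabilities(q, blens[i], freqs)
        return -_pruning_loglik(root, aln, lambda node: pmats[id(node)], freqs)

    def fit(fixed_fg):
        x0 = np.log(np.concatenate([np.full(nb, 0.1), [2.0, 0.5],
                                    [] if fixed_fg is not None else [0.5]]))
        bounds = ([(math.log(*_T_BOUNDS[:1]), math.log(_T_BOUNDS[1]))] * nb
                  + [(math.log(_KAPPA_BOUNDS[0]), math.log(_KAPPA_BOUNDS[1]))]
                  + [(math.log(_OMEGA_BOUNDS[0]), math.log(_OMEGA_BOUNDS[1]))]
                  * (1 if fixed_fg is not None else 2))
        return optimize.minimize(nll, x0, args=(fixed_fg,), method="L-BFGS-B",
                                 bounds=bounds, options={"ftol": 1e-12})

    free = fit(None)
    fixed = fit(1.0)
    kappa = float(np.exp(free.x[nb]))
    w_bg = float(np.exp(free.x[nb + 1]))
    w_fg = float(np.exp(free.x[nb + 2]))
    ll_free, ll_fixed = -free.fun, -fixed.fun
    p = float(stats.chi2.sf(max(0.0, 2 * (ll_free - ll_fixed)), 1))
    return BranchOmegaFit(w_fg, w_bg, kappa, ll_free, ll_fixed, p,
                          converged=bool(free.success and fixed.success))


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(distances: np.ndarray, ids: list[str],
            bootstrap_matrices: list[np.ndarray] | None = None):
    """Neighbor-joining tree (Bio.Phylo) with optional bootstrap support.

    Supports are the fraction of bootstrap distance matrices whose NJ
    tree contains the same bipartition, written to clade.confidence.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.shape[0] != distances.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(distances, distances.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")

    def build(mat):
        dm = DistanceMatrix(list(ids),
                            [[float(mat[i, j]) for j in range(i + 1)] for i in range(len(ids))])
        return DistanceTreeConstructor().nj(dm)

    tree = build(distances)

    def bipartitions(t):
        allset = frozenset(ids)
        out = set()
        for clade in t.get_nonterminals():
            names = frozenset(lf.name for lf in clade.get_terminals())
            if 1 < len(names) < len(ids):
                out.add(min(names, allset - names, key=sorted))
        return out

    if bootstrap_matrices:
        counts: dict[frozenset, int] = {}
        for mat in bootstrap_matrices:
            for bp in bipartitions(build(mat)):
                counts[bp] = counts.get(bp, 0) + 1
        n = len(bootstrap_matrices)
        allset = frozenset(ids)
        for clade in tree.get_nonterminals():
            names = frozenset(lf.name for lf in clade.get_terminals())
            if 1 < len(names) < len(ids):
                key = min(names, allset - names, key=sorted)
                clade.confidence = 100.0 * counts.get(key, 0) / n
    return tree


def _p_distance_matrix(columns: list[tuple[str, ...]], n_seq: int) -> np.ndarray:
    d = np.zeros((n_seq, n_seq))
    for i in range(n_seq):
        for j in range(i + 1, n_seq):
            tot = diff = 0
            for col in columns:
                a, b = col[i], col[j]
                for x, y in zip(a, b):
                    tot += 1
                    diff += x != y
            d[i, j] = d[j, i] = diff / tot if tot else 0.0
    return d


def polarize_by_tree(cds_1: str, cds_2: str, outgroup_cds: dict[str, str],
                     bootstrap: int = 1000, seed: int = 0) -> tuple[bool, float] | None:
    """Decide the parental copy from an NJ gene tree with outgroups.

    All sequences are star-aligned onto copy 1 via global protein
    alignments; nucleotide p-distances feed NJ.  The copy with the
    smaller patristic distance to its nearest outgroup ortholog is the
    parent.  Returns ``(parent_is_copy_1, bootstrap_support)``, or None
    when no outgroup sequence is available or the distances tie.
    """
    if not outgroup_cds or not cds_1 or not cds_2:
        return None
    names = ["copy1", "copy2"] + list(outgroup_cds)
    seqs = [cds_1, cds_2] + [outgroup_cds[k] for k in outgroup_cds]

    # star alignment onto copy 1's codon coordinates
    def _clean(cds):
        c = codons_of(cds.upper())
        if c and c[-1] in STOP_CODONS:
            c = c[:-1]
        return c

    ref = _clean(seqs[0])
    ref_prot = translate("".join(ref))
    columns: list[list[str]] = [[c] for c in ref]
    for s in seqs[1:]:
        cod = _clean(s)
        pa, pb = align_protein_pair(ref_prot, translate("".join(cod)))
        proj, ri, si = ["-"] * len(ref), 0, 0
        for ca, cb in zip(pa, pb):
            if ca != "-" and cb != "-":
                proj[ri] = cod[si]
            if ca != "-":
                ri += 1
            if cb != "-":
                si += 1
        for k in range(len(ref)):
            columns[k].append(proj[k])
    cols = [tuple(c) for c in columns if "-" not in c]
    if not cols:
        return None

    def parent_call(sample_cols) -> bool | None:
        d = _p_distance_matrix(sample_cols, len(names))
        if len(names) == 3:
            d1, d2 = d[0, 2], d[1, 2]
        else:
            tree = nj_tree(d, names)
            d1 = min(tree.distance("copy1", o) for o in names[2:])
            d2 = min(tree.distance("copy2", o) for o in names[2:])
        if d1 == d2:
            return None
        return d1 < d2

    point = parent_call(cols)
    if point is None:
        return None
    rng = np.random.default_rng(seed)
    agree = total = 0
    for _ in range(bootstrap):
        idx = rng.integers(0, len(cols), size=len(cols))
        call = parent_call([cols[i] for i in idx])
        if call is not None:
            total += 1
            agree += call == point
    support = agree / total if total else 0.0
    return point, support


# ---------------------------------------------------------------------------
# Table-style summary


def summarize_omega_categories(fits: list[OmegaFit], alpha: float = 0.05) -> dict:
    """Counts and percentages of pairs by Ka/Ks category.

    Primary mutually exclusive categories: no substitutions, omega > 1,
    omega <= 1; plus (over the same total) omega significantly < 1 and
    significantly < 0.5 by the chi-square LRTs.  Zero-substitution pairs
    carry no LRT.  Percentages are rounded to 2 decimals.
    """
    total = len(fits)
    zero = sum(f.zero_substitutions for f in fits)
    gt1 = sum((not f.zero_substitutions) and f.omega > 1 for f in fits)
    lt1 = total - zero - gt1
    sig_lt1 = sum((not f.zero_substitutions) and f.omega < 1
                  and np.isfinite(f.lrt_p_vs_one) and f.lrt_p_vs_one < alpha
                  for f in fits)
    sig_lt_half = sum((not f.zero_substitutions) and f.omega < 0.5
                      and np.isfinite(f.lrt_p_vs_half) and f.lrt_p_vs_half < alpha
                      for f in fits)

    def pct(k):
        return round(100.0 * k / total, 2) if total else float("nan")

    return {
        "total": total,
        "zero_substitution": zero, "zero_substitution_pct": pct(zero),
        "omega_gt_1": gt1, "omega_gt_1_pct": pct(gt1),
        "omega_lt_1": lt1, "omega_lt_1_pct": pct(lt1),
        "omega_sig_lt_1": sig_lt1, "omega_sig_lt_1_pct": pct(sig_lt1),
        "omega_sig_lt_0.5": sig_lt_half, "omega_sig_lt_0.5_pct": pct(sig_lt_half),
    }
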