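"""Tissue enrichment, specificity, and expression-divergence calls.

EST-based enrichment uses a one-sided Fisher 2x2 per gene x tissue
(gene's ESTs in the tissue vs everywhere else, against the pool),
BH-corrected across all tests; tiling-array specificity uses per-gene
Z-scores across tissues (Z > 2.5); RNA-seq expressed calls threshold
FPKM.  Divergence categories compare the enriched-tissue sets of a
daughter gene (NDG) and its parent; cis-regulatory element sets are
compared as strict subset relations.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import EnrichmentCall, HomologyHit

logger = logging.getLogger(__name__)


def assign_ests(hits_by_est: dict[str, list[HomologyHit]],
                min_identity: float = 95.0, max_evalue: float = 1e-20,
                min_score: float = 100.0, min_margin: float = 5.0) -> dict[str, str]:
    """EST -> gene assignment by best hit with margin.

    An EST is assigned to its best-scoring gene only when the best hit
    passes all three thresholds AND its score exceeds the second-best
    gene's by at least ``min_margin``; otherwise it stays unassigned.
    """
    out: dict[str, str] = {}
    for est, hits in hits_by_est.items():
        if not hits:
            continue
        ranked = sorted(hits, key=lambda h: -h.score)
        best = ranked[0]
        if (best.identity < min_identity or best.evalue > max_evalue
                or best.score < min_score):
            continue
        runner = next((h for h in ranked[1:] if h.subject_id != best.subject_id), None)
        if runner is not None and best.score - runner.score < min_margin:
            continue
        out[est] = best.subject_id
    return out


def est_enrichment(gene_tissue_counts: dict[str, dict[str, float]],
                   totals_per_tissue: dict[str, float] | None = None,
                   grand_total: float | None = None) -> dict[tuple[str, str], dict]:
    """One-sided Fisher enrichment per gene x tissue with BH correction.

    The 2x2 table is: [gene's ESTs in the tissue, gene's other ESTs;
    all ESTs in the tissue, all other ESTs].  Returns per (gene, tissue)
    a dict with ``p`` and ``q``.
    """
    if totals_per_tissue is None:
        totals_per_tissue = defaultdict(float)
        for counts in gene_tissue_counts.values():
            for t, v in counts.items():
                totals_per_tissue[t] += v
    if grand_total is None:
        grand_total = sum(totals_per_tissue.values())
    keys, pvals = [], []
    for gene, counts in gene_tissue_counts.items():
        gene_total = sum(counts.values())
        if gene_total > grand_total:
            raise ValueError(f"{gene}: gene total exceeds grand total")
        for tissue in totals_per_tissue:
            a = counts.get(tissue, 0.0)
            tissue_total = totals_per_tissue[tissue]
            if a > tissue_total or a > gene_total:
                raise ValueError(f"inconsistent margins for {gene}/{tissue}")
            table = [[int(round(a)), int(round(gene_total - a))],
                     [int(round(tissue_total)), int(round(grand_total - tissue_total))]]
            _, p = stats.fisher_exact(table, alternative="greater")
            keys.append((gene, tissue))
            pvals.append(float(p))
    qvals = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    return {k: {"p": p, "q": float(q)} for k, p, q in zip(keys, pvals, qvals)}


def enrichment_calls(gene_tissue_counts: dict[str, dict[str, float]],
                     alpha: float = 0.05, platform: str = "EST") -> dict[str, EnrichmentCall]:
    """Per-gene enriched-tissue sets at FDR q < alpha."""
    res = est_enrichment(gene_tissue_counts)
    calls: dict[str, EnrichmentCall] = {}
    for gene in gene_tissue_counts:
        calls[gene] = EnrichmentCall(gene, platform)
    for (gene, tissue), r in res.items():
        calls[gene].fdr_q[tissue] = r["q"]
        if r["q"] < alpha:
            calls[gene].enriched_tissues[tissue] = r["p"]
    return calls


def tiling_specificity(intensities: dict[str, dict[str, float]],
                       z_threshold: float = 2.5) -> dict[str, list[str]]:
    """Tissue-specific calls from per-gene Z-scores across tissues.

    Z is computed per gene across its tissues ((value - row mean) / row
    SD); tissues with Z > ``z_threshold`` are specific.  Genes with zero
    row SD get no call (logged).
    """
    out: dict[str, list[str]] = {}
    for gene, row in intensities.items():
        if len(row) < 3:
            raise ValueError(f"{gene}: need >= 3 tissues")
        vals = np.array(list(row.values()), dtype=float)
        sd = vals.std(ddof=1)
        if sd == 0:
            logger.info("flat profile for %s; no specificity call", gene)
            out[gene] = []
            continue
        z = (vals - vals.mean()) / sd
        out[gene] = [t for t, zi in zip(row, z) if zi > z_threshold]
    return out


def expressed_flags(fpkm: dict[str, float], threshold: float = 1.0) -> dict[str, bool]:
    """Expressed-in-tissue booleans: FPKM >= threshold (inclusive)."""
    return {tissue: v >= threshold for tissue, v in fpkm.items()}


def divergence_call(ndg: EnrichmentCall, parent: EnrichmentCall,
                    cross_platform: bool = False) -> str:
    """Expression-divergence category from the two enriched-tissue sets:
    same (both empty or identical), ndg_gained_specificity,
    ndg_lost_specificity, or switched_tissue."""
    if ndg.platform != parent.platform and not cross_platform:
        raise ValueError(
            f"platform mismatch ({ndg.platform} vs {parent.platform}); "
            "set cross_platform=True to compare anyway")
    s_ndg = set(ndg.enriched_tissues)
    s_parent = set(parent.enriched_tissues)
    if s_ndg == s_parent:
        return "same"
    if not s_parent and s_ndg:
        return "ndg_gained_specificity"
    if not s_ndg and s_parent:
        return "ndg_lost_specificity"
    return "switched_tissue"


def compare_cis_elements(set_ndg: set[str] | list[str],
                         set_parent: set[str] | list[str]) -> str | None:
    """Compare cis-regulatory element sets of daughter and parent.

    same: equal non-empty sets; parent_extra: NDG strict subset of
    parent; ndg_extra: parent strict subset of NDG; different: anything
    else (disjoint or crossing).  Both empty -> None (no annotation).
    """
    s_ndg, s_parent = set(set_ndg), set(set_parent)
    if not s_ndg and not s_parent:
        return None
    if s_ndg == s_parent:
        return "same"
    if s_ndg < s_parent:
        return "parent_extra"
    if s_parent < s_ndg:
        return "ndg_extra"
    return "different"
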