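"""Bisulfite methylation calling and NDG-vs-parent divergence tests.

Per-cytosine calls are one-sided binomial tests of the methylated read
count against the non-conversion error rate estimated from a
no-methylation control contig (the chloroplast analogue), BH-corrected
across all covered cytosines.  Pair-level tests compare gene-body
methylation-status conservation against the background conservation of
all duplicate pairs, and promoter/terminator (200 bp) methylation levels
against the genome-wide background level.
"""

from __future__ import annotations

import logging

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CytosineRecord, GeneModel, MethylationComparison

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def estimate_error_rate(control_records: list[CytosineRecord]) -> float:
    """Bisulfite non-conversion error rate from a no-methylation control:
    total methylated reads over total reads."""
    total = sum(r.total_reads for r in control_records)
    meth = sum(r.methylated_reads for r in control_records)
    if total == 0:
        raise ValueError("control contig has zero coverage")
    covered = sum(r.total_reads > 0 for r in control_records)
    if covered < 1000:
        logger.warning("only %d covered control cytosines; error-rate "
                       "estimate will be noisy", covered)
    return meth / total


def context_of(genome: dict[str, str], contig: str, position: int, strand: str) -> str:
    """CG / CHG / CHH context of a cytosine, strand-aware (H = A, C, T).

    On the minus strand the context is read on the reverse complement.
    """
    seq = genome[contig]
    if strand == "+":
        if seq[position] != "C":
            raise ValueError(f"base at {contig}:{position}(+) is not C")
        nxt1 = seq[position + 1] if position + 1 < len(seq) else "N"
        nxt2 = seq[position + 2] if position + 2 < len(seq) else "N"
    elif strand == "-":
        if seq[position] != "G":
            raise ValueError(f"base at {contig}:{position}(-) is not C on the minus strand")
        nxt1 = _COMP[seq[position - 1]] if position - 1 >= 0 else "N"
        nxt2 = _COMP[seq[position - 2]] if position - 2 >= 0 else "N"
    else:
        raise ValueError(f"bad strand {strand!r}")
    if nxt1 == "G":
        return "CG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def call_cytosine(record: CytosineRecord, error_rate: float) -> tuple[str, float]:
    """One-sided binomial p for one cytosine: P(X >= k | n, error_rate).

    Returns (provisional call at p < 0.05, p); genome-wide calls should
    go through :func:`call_all_cytosines` for FDR correction.
    """
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    if record.total_reads < 1:
        return "uncovered", float("nan")
    p = float(stats.binom.sf(record.methylated_reads - 1, record.total_reads, error_rate))
    return ("methylated" if p < 0.05 else "unmethylated"), p


def call_all_cytosines(records: list[CytosineRecord], error_rate: float,
                       alpha: float = 0.05) -> list[CytosineRecord]:
    """Binomial test per covered cytosine, methylated iff BH q < alpha.

    Uncovered rows (zero reads) are passed through untested, never an
    error.  Records are annotated in place and returned.
    """
    covered = [r for r in records if r.total_reads >= 1]
    for r in records:
        if r.total_reads < 1:
            r.call, r.p, r.q = "uncovered", float("nan"), float("nan")
    if not covered:
        return records
    pvals = [call_cytosine(r, error_rate)[1] for r in covered]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    for r, p, q in zip(covered, pvals, qvals):
        r.p, r.q = float(p), float(q)
        r.call = "methylated" if q < alpha else "unmethylated"
    return records


def gene_body_conservation(pair_id: str,
                           aligned_positions: list[tuple[int, int]],
                           calls_1: dict[int, str], calls_2: dict[int, str],
                           background_conservation: float,
                           direction: str = "less") -> MethylationComparison | None:
    """Methylation-status conservation of a pair over aligned cytosines.

    ``aligned_positions`` maps copy-1 positions to copy-2 positions (from
    the pair's nucleotide alignment); a position is covered when both
    copies have a methylated/unmethylated call there.  Conservation
    counts positions with equal calls (conserved methylation AND
    conserved un-methylation).  The binomial test compares the conserved
    fraction to the background conservation of all duplicate pairs;
    the default lower tail asks for significantly LOW conservation.
    Returns None when no cytosine is covered in both copies.
    """
    if not 0 < background_conservation < 1:
        raise ValueError("background conservation must be in (0,1)")
    covered = conserved = 0
    for p1, p2 in aligned_positions:
        c1, c2 = calls_1.get(p1), calls_2.get(p2)
        if c1 in ("methylated", "unmethylated") and c2 in ("methylated", "unmethylated"):
            covered += 1
            conserved += c1 == c2
    if covered == 0:
        return None
    test = stats.binomtest(conserved, covered, background_conservation,
                           alternative=direction)
    return MethylationComparison(pair_id, covered, conserved,
                                 conserved / covered, float(test.pvalue),
                                 region="gene_body")


def regulatory_region_level(gene: GeneModel, calls: dict[tuple[str, int], str],
                            region: str, background_level: float,
                            contig_length: int | None = None,
                            window: int = 200) -> MethylationComparison | None:
    """Methylation level of the 200 bp promoter (upstream of the TSS) or
    terminator (downstream of the TTS) window, upper-tail binomial test
    against the genome-wide background level.

    Windows are strand-aware and truncated at contig edges.  The level
    is methylated called cytosines over called cytosines in the window.
    Returns None when the window has no called cytosine.
    """
    if region not in ("promoter", "terminator"):
        raise ValueError("region must be 'promoter' or 'terminator'")
    if not 0 < background_level < 1:
        raise ValueError("background level must be in (0,1)")
    upstream = (region == "promoter") == (gene.strand == "+")
    if upstream:
        start, end = gene.start - window, gene.start
    else:
        start, end = gene.end, gene.end + window
    if start < 0:
        logger.info("%s %s window truncated at contig start", gene.gene_id, region)
        start = 0
    if contig_length is not None and end > contig_length:
        logger.info("%s %s window truncated at contig end", gene.gene_id, region)
        end = contig_length
    covered = meth = 0
    for (contig, pos), call in calls.items():
        if contig == gene.contig and start <= pos < end and call in ("methylated", "unmethylated"):
            covered += 1
            meth += call == "methylated"
    if covered == 0:
        return None
    test = stats.binomtest(meth, covered, background_level, alternative="greater")
    return MethylationComparison(f"{gene.gene_id}:{region}", covered, meth,
                                 meth / covered, float(test.pvalue), region=region)


def bh_correct(comparisons: list[MethylationComparison], alpha: float = 0.05) -> list[MethylationComparison]:
    """BH q-values across a family of pair/region comparisons."""
    if not comparisons:
        return comparisons
    qvals = multipletests([c.p for c in comparisons], method="fdr_bh")[1]
    for c, q in zip(comparisons, qvals):
        c.q = float(q)
    return comparisons
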