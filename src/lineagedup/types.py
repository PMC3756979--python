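"""Shared domain containers for the lineage-duplicate pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._codon import translate


@dataclass
class GeneModel:
    """An annotated protein-coding gene.

    Coordinates are 0-based half-open internally; GFF3 on disk is
    1-based inclusive (the io layer converts).
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    cds_sequence: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        ivals = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
        self.cds_intervals = ivals
        if self.cds_sequence and len(self.cds_sequence) % 3:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def protein(self) -> str:
        p = translate(self.cds_sequence)
        return p[:-1] if p.endswith("*") else p

    @property
    def length(self) -> int:
        return self.end - self.start

    def cds_offset(self, contig_pos: int) -> int | None:
        """Offset of a contig position within the spliced CDS (5'->3' on
        the coding strand), or None if the position is non-coding."""
        spliced = 0
        if self.strand == "+":
            for s, e in self.cds_intervals:
                if s <= contig_pos < e:
                    return spliced + (contig_pos - s)
                spliced += e - s
            return None
        for s, e in reversed(self.cds_intervals):
            if s <= contig_pos < e:
                return spliced + (e - 1 - contig_pos)
            spliced += e - s
        return None


@dataclass
class SimConfig:
    """Knobs of the synthetic-data generators.

    Defaults mirror the study conditions the pipeline is meant for:
    an 80-haplotype population sample, a 2.21% bisulfite non-conversion
    error rate, and recent low-divergence duplicates.
    """

    seed: int = 0
    n_haplotypes: int = 80
    theta: float = 5.0
    locus_length: int = 1000
    omega_true: float = 0.2
    kappa_true: float = 2.0
    branch_length_true: float = 0.15
    error_rate_true: float = 0.0221
    enrichment_factor: float = 10.0
    spectrum_skew: float = 0.0

    def __post_init__(self) -> None:
        for name in ("error_rate_true",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_haplotypes < 2:
            raise ValueError("n_haplotypes must be >= 2")


@dataclass
class PlantedPair:
    parent_id: str
    ndg_id: str
    duplication_class: str  # tandem | segmental | dispersed


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic-genome simulation, for recovery tests."""

    pairs: list[PlantedPair] = field(default_factory=list)
    chimera_donors: dict[str, list[str]] = field(default_factory=dict)
    methylated_positions: dict[str, set[int]] = field(default_factory=dict)
    enriched_tissue: dict[str, str] = field(default_factory=dict)
    selection_regime: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [(p.parent_id, p.ndg_id) for p in self.pairs]
        if len(ids) != len(set(ids)):
            raise ValueError("planted pairs must be unique")


@dataclass
class HomologyHit:
    """One pairwise homology hit (tabular BLAST-like record)."""

    query_id: str
    subject_id: str
    identity: float  # percent
    evalue: float
    score: float
    query_interval: tuple[int, int] = (0, 0)
    subject_interval: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity must be in [0,100], got {self.identity}")


@dataclass
class SyntenyBlock:
    """A maximal collinear chain of reciprocal-best gene anchors."""

    species_a: str
    species_b: str
    anchors: list[tuple[str, str]]
    a_interval: tuple[str, int, int] = ("", 0, 0)  # contig, start, end
    b_interval: tuple[str, int, int] = ("", 0, 0)
    orientation: str = "+"

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class ParalogPair:
    gene_1: str
    gene_2: str
    identity: float = float("nan")
    coverage: float = float("nan")
    duplication_class: str = ""  # tandem | segmental | dispersed
    parent_id: str = ""
    ndg_id: str = ""
    polarization_method: str = "undetermined"  # synteny_fraction | gene_tree | undetermined
    chimera: bool = False
    chimera_donors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.parent_id and self.ndg_id:
            if {self.parent_id, self.ndg_id} != {self.gene_1, self.gene_2}:
                raise ValueError("polarized ids must match the pair's genes")


@dataclass
class OmegaFit:
    """Pairwise codon-model ML fit plus fixed-omega LRTs."""

    ka: float
    ks: float
    omega: float
    kappa: float
    t: float
    logl_free: float
    logl_fixed_half: float = float("nan")
    logl_fixed_one: float = float("nan")
    lrt_p_vs_half: float = float("nan")
    lrt_p_vs_one: float = float("nan")
    n_codons: int = 0
    zero_substitutions: bool = False
    converged: bool = True


@dataclass
class BranchOmegaFit:
    """Two-ratio branch-model fit with foreground-omega=1 LRT."""

    omega_foreground: float
    omega_background: float
    kappa: float
    logl_free: float
    logl_fg_fixed_one: float
    lrt_p: float
    converged: bool = True


@dataclass
class HaplotypeMatrix:
    """Biallelic SNP states (0/1) for n samples at ordered positions."""

    sample_ids: list[str]
    positions: np.ndarray  # 0-based on the locus
    genotypes: np.ndarray  # shape (n_samples, n_sites), values 0/1
    locus_contig: str = "locus"
    locus_start: int = 0
    locus_length: int = 0
    gene: GeneModel | None = None
    ref_alleles: list[str] | None = None  # nucleotide of state 0 per site
    alt_alleles: list[str] | None = None  # nucleotide of state 1 per site

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x sites)")
        if len(self.sample_ids) < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.genotypes.shape != (len(self.sample_ids), len(self.positions)):
            raise ValueError("genotype shape mismatch")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass
class SiteClassCounts:
    """Fractional synonymous/nonsynonymous site totals and per-SNP classes."""

    l_total: float
    l_syn: float
    l_nonsyn: float
    snp_classes: dict[int, str] = field(default_factory=dict)  # position -> class


@dataclass
class NeutralityResult:
    gene_id: str
    gene_class: str = ""  # ndg | parent | null-locus
    pi: float = float("nan")
    theta_w: float = float("nan")
    tajima_d: float = float("nan")
    fuli_d: float = float("nan")
    fuli_f: float = float("nan")
    empirical_p: dict[str, float] = field(default_factory=dict)
    fdr_q: dict[str, float] = field(default_factory=dict)
    selection_flag: bool = False


@dataclass
class MKTable:
    fixed_nonsyn: int
    fixed_syn: int
    poly_nonsyn: int
    poly_syn: int
    fisher_p: float = float("nan")
    fdr_q: float = float("nan")

    def __post_init__(self) -> None:
        for v in (self.fixed_nonsyn, self.fixed_syn, self.poly_nonsyn, self.poly_syn):
            if v < 0:
                raise ValueError("MK counts must be non-negative")


@dataclass
class EmpiricalNull:
    statistic: str
    values: np.ndarray
    min_spacing: int = 25_000
    source_count: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("null values must be finite")


@dataclass
class ExpressionProfile:
    gene_id: str
    platform: str  # EST | MPSS | smallRNA | tiling | RNAseq
    values: dict[str, float] = field(default_factory=dict)  # tissue -> value

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("tissue map must be non-empty")
        if any(v < 0 for v in self.values.values()):
            raise ValueError("expression values must be >= 0")


@dataclass
class EnrichmentCall:
    gene_id: str
    platform: str = ""
    enriched_tissues: dict[str, float] = field(default_factory=dict)  # tissue -> p
    fdr_q: dict[str, float] = field(default_factory=dict)
    specific_tissues: list[str] = field(default_factory=list)


@dataclass
class CytosineRecord:
    contig: str
    position: int  # 0-based
    strand: str
    context: str  # CG | CHG | CHH
    methylated_reads: int
    total_reads: int
    call: str = "uncovered"  # methylated | unmethylated | uncovered
    p: float = float("nan")
    q: float = float("nan")

    def __post_init__(self) -> None:
        if self.methylated_reads > self.total_reads:
            raise ValueError("methylated reads exceed total reads")


@dataclass
class MethylationComparison:
    pair_id: str
    covered: int
    conserved: int
    fraction: float
    p: float = float("nan")
    q: float = float("nan")
    region: str = "gene_body"  # gene_body | promoter | terminator

    def __post_init__(self) -> None:
        if self.conserved > self.covered:
            raise ValueError("conserved cytosines exceed covered cytosines")
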