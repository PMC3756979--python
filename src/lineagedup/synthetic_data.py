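"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is seeded and deterministic: the same configuration
produces byte-identical output.  The generators emulate the study design
the pipeline targets — a four-genome synteny comparison with recent
lineage-specific duplicates in the focal species, an 80-haplotype
population sample, EST tissue pools, bisulfite cytosine reports with a
no-methylation control contig, and cis-element annotations — without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._codon import (
    CODON_INDEX,
    SENSE_CODONS,
    STOP_CODONS,
    codons_of,
    rate_matrix,
    transition_probabilities,
)
from .types import (
    CytosineRecord,
    ExpressionProfile,
    GeneModel,
    HaplotypeMatrix,
    ParalogPair,
    PlantedPair,
    PlantedTruth,
    SimConfig,
)

# ---------------------------------------------------------------------------
# codon-sequence evolution


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random stop-free CDS of ``n_codons`` codons (ATG start)."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    codons = [SENSE_CODONS[i] for i in idx]
    codons[0] = "ATG"
    return "".join(codons)


def evolve_codon_pair(ancestor_cds: str, t: float, omega: float, kappa: float,
                      seed: int | np.random.Generator) -> str:
    """Evolve a descendant CDS under the GY94 codon model.

    Each codon evolves independently by the continuous-time Markov chain
    over the 61 sense codons; the descendant is drawn directly from the
    exact transition matrix P(t) = exp(Qt), so no stop codon can ever be
    introduced and omega=0 forbids amino-acid change outright.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons = codons_of(ancestor_cds)
    trailing_stop = ""
    if codons and codons[-1] in STOP_CODONS:
        trailing_stop = codons[-1]
        codons = codons[:-1]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c} at codon {i}")
        if c not in CODON_INDEX:
            raise ValueError(f"unrecognized codon {c!r} at codon {i}")
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if t == 0:
        return ancestor_cds
    q = rate_matrix(kappa, omega)
    p = transition_probabilities(q, t)
    cum = np.cumsum(p, axis=1)
    u = rng.random(len(codons))
    out = []
    for c, ui in zip(codons, u):
        j = int(np.searchsorted(cum[CODON_INDEX[c]], ui))
        out.append(SENSE_CODONS[min(j, len(SENSE_CODONS) - 1)])
    return "".join(out) + trailing_stop


# ---------------------------------------------------------------------------
# genome simulation


@dataclass
class GenomeSet:
    """Per-species genomes and gene models from one simulation."""

    genomes: dict[str, dict[str, str]]  # species -> contig -> sequence
    genes: dict[str, list[GeneModel]]  # species -> gene models in genomic order
    focal_species: str = "focal"


_INTERGENIC = 200  # bp between consecutive genes


def _assemble_contig(rng: np.random.Generator, contig: str, species: str,
                     cds_list: list[tuple[str, str]]) -> tuple[str, list[GeneModel]]:
    """Lay genes along a contig with random intergenic spacers."""
    nts = np.array(list("ACGT"))
    parts: list[str] = []
    genes: list[GeneModel] = []
    pos = 0
    for gene_id, cds in cds_list:
        spacer = "".join(rng.choice(nts, size=_INTERGENIC))
        parts.append(spacer)
        pos += _INTERGENIC
        start = pos
        parts.append(cds)
        pos += len(cds)
        genes.append(
            GeneModel(gene_id, contig, start, pos, "+",
                      cds_intervals=[(start, pos)], cds_sequence=cds)
        )
    parts.append("".join(rng.choice(nts, size=_INTERGENIC)))
    return "".join(parts), genes


def simulate_genomes(
    config: SimConfig,
    n_genes: int = 100,
    n_species: int = 4,
    n_tandem: int = 3,
    n_segmental_blocks: int = 1,
    n_dispersed: int = 3,
    n_chimera: int = 1,
    duplicate_branch_length: float = 0.05,
    divergence_noise: float | None = None,
    order_noise: int = 2,
    min_codons: int = 110,
    max_codons: int = 200,
) -> tuple[GenomeSet, PlantedTruth]:
    """Simulate a focal genome plus outgroups sharing a synteny backbone.

    The focal species carries planted lineage-specific duplicates of all
    three mechanisms.  Tandem daughters sit immediately next to their
    parent; segmental blocks copy a two-gene window to a distant slot;
    dispersed daughters are single genes copied to isolated distant
    slots.  One chimeric gene fuses the 5' half of one backbone gene with
    the 3' half of another.  Daughter copies accrue
    ``duplicate_branch_length`` of extra codon-model divergence, so they
    are recent relative to the inter-species divergence
    (``divergence_noise``, default the config's branch length).

    Returns the genome set and the planted ground truth.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if n_genes < 20:
        raise ValueError("need at least 20 backbone genes")
    if n_segmental_blocks > 0 and n_genes < 30:
        raise ValueError(
            "too few genes to place a segmental block (a duplicated 2-gene "
            "window plus >= 13 genes of separation from other planted "
            "duplicates); increase n_genes or set n_segmental_blocks=0")
    rng = np.random.default_rng(config.seed)
    t_sp = config.branch_length_true if divergence_noise is None else divergence_noise
    kappa, omega = config.kappa_true, config.omega_true

    lengths = rng.integers(min_codons, max_codons + 1, size=n_genes)
    ancestors = [random_cds(int(L), rng) for L in lengths]
    backbone_ids = [f"g{i:04d}" for i in range(n_genes)]

    species_names = ["focal"] + [f"outgroup{i}" for i in range(1, n_species)]
    # per-species backbone sequences, evolved independently from the ancestor
    seqs: dict[str, list[str]] = {}
    for sp in species_names:
        if t_sp == 0:
            seqs[sp] = list(ancestors)
        else:
            seqs[sp] = [evolve_codon_pair(a, t_sp, omega, kappa, rng) for a in ancestors]

    truth = PlantedTruth()
    focal = list(zip(backbone_ids, seqs["focal"]))  # (gene_id, cds), mutated below

    # Tandem parents and the non-tandem insertion slots must be mutually
    # distant in gene order, or a dispersed daughter could pick up a
    # spurious segmental companion.  Backbone separation >= 13 suffices:
    # insertions only ever increase index distances, and the segmental
    # companion rule reaches 11 final-order genes.
    n_constrained = n_tandem + n_segmental_blocks + n_dispersed
    lo, hi = 3, n_genes - 3
    gap = (hi - lo) / max(n_constrained, 1)
    if gap < 13:
        raise ValueError(
            "too few genes to separate the planted duplicates: each tandem "
            "parent and each segmental/dispersed insertion slot needs >= 13 "
            "genes of separation; increase n_genes or plant fewer duplicates")
    jitter = int(gap - 13)
    constrained = [lo + int(round(k * gap)) + int(rng.integers(0, jitter + 1))
                   for k in range(n_constrained)]
    candidates = [c for c in range(lo, hi) if all(abs(c - s) > 1 for s in constrained)]
    rng.shuffle(candidates)
    rng.shuffle(constrained)
    citer = iter(constrained)
    used: set[int] = set(constrained)
    used.update(c + 1 for c in constrained)
    used.update(c - 1 for c in constrained)

    def pick_free(block: int = 1) -> int:
        for c in candidates:
            if all(c + o not in used for o in range(-1, block + 1)):
                used.update(range(c - 1, c + block + 1))
                return c
        raise ValueError("could not place duplicate source genes; increase n_genes")

    def duplicate(cds: str) -> str:
        if duplicate_branch_length == 0:
            return cds
        return evolve_codon_pair(cds, duplicate_branch_length, omega, kappa, rng)

    insertions: list[tuple[int, str, str]] = []  # (backbone slot, gene_id, cds)

    # tandem: daughter inserted immediately after its parent
    for k in range(n_tandem):
        src = next(citer)
        ndg_id = f"ndg_t{k}"
        insertions.append((src + 1, ndg_id, duplicate(seqs["focal"][src])))
        truth.pairs.append(PlantedPair(backbone_ids[src], ndg_id, "tandem"))

    # segmental: a 2-gene window copied to a distant slot, order preserved
    # (list.insert at a shared slot reverses, so plant the window backwards)
    for k in range(n_segmental_blocks):
        dest = next(citer)
        src = pick_free(block=2)
        for off in (1, 0):
            ndg_id = f"ndg_s{k}_{off}"
            insertions.append((dest, ndg_id, duplicate(seqs["focal"][src + off])))
            truth.pairs.append(PlantedPair(backbone_ids[src + off], ndg_id, "segmental"))

    # dispersed: a single gene copied to an isolated distant slot
    for k in range(n_dispersed):
        dest = next(citer)
        src = pick_free()
        ndg_id = f"ndg_d{k}"
        insertions.append((dest, ndg_id, duplicate(seqs["focal"][src])))
        truth.pairs.append(PlantedPair(backbone_ids[src], ndg_id, "dispersed"))

    # chimera: in-frame fusion of the 5' half of one donor, 3' half of another
    for k in range(n_chimera):
        d1, d2, dest = pick_free(), pick_free(), pick_free()
        c1 = codons_of(seqs["focal"][d1])
        c2 = codons_of(seqs["focal"][d2])
        fused = "".join(c1[: len(c1) // 2] + c2[len(c2) // 2 :])
        gid = f"chimera{k}"
        insertions.append((dest, gid, fused))
        truth.chimera_donors[gid] = [backbone_ids[d1], backbone_ids[d2]]

    # apply insertions from the right so earlier slot indices stay valid
    for slot, gid, cds in sorted(insertions, key=lambda x: -x[0]):
        focal.insert(slot, (gid, cds))

    genomes: dict[str, dict[str, str]] = {}
    genes: dict[str, list[GeneModel]] = {}
    for sp in species_names:
        # outgroup gene ids are namespaced so cross-species ids never collide
        order = focal if sp == "focal" else \
            [(f"{sp}.{gid}", s) for gid, s in zip(backbone_ids, seqs[sp])]
        if sp != "focal" and order_noise > 0 and t_sp > 0:
            order = list(order)
            for _ in range(order_noise):
                i = int(rng.integers(0, len(order) - 1))
                order[i], order[i + 1] = order[i + 1], order[i]
        contig_seq, gene_models = _assemble_contig(rng, "chr1", sp, order)
        genomes[sp] = {"chr1": contig_seq}
        genes[sp] = gene_models

    return GenomeSet(genomes, genes, "focal"), truth


# ---------------------------------------------------------------------------
# coalescent haplotypes (Hudson's algorithm, infinite sites)


@dataclass
class _CoalTree:
    parent: np.ndarray  # parent node per node (-1 at root)
    blen: np.ndarray  # branch length to parent
    n_leaves: int

    def leaves_below(self, node: int) -> list[int]:
        children: dict[int, list[int]] = {}
        for i, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(i)
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                out.append(v)
            else:
                stack.extend(children.get(v, []))
        return out


def _simulate_coalescent_tree(n: int, rng: np.random.Generator) -> _CoalTree:
    """Standard neutral coalescent: exponential waiting times, random
    pair merges; time measured in units of 2N generations."""
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=int)
    time = np.zeros(total)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    blen = np.zeros(total)
    for v in range(total):
        if parent[v] >= 0:
            blen[v] = time[parent[v]] - time[v]
    return _CoalTree(parent, blen, n)


def simulate_haplotypes(config: SimConfig, gene: GeneModel | None = None,
                        rng: np.random.Generator | None = None,
                        reference_seq: str | None = None) -> HaplotypeMatrix:
    """One neutral-coalescent locus with infinite-sites mutations.

    theta is per locus (2Nμ per site times locus length folded in).  With
    ``spectrum_skew < 0``, that fraction of mutations is reassigned to
    external branches, mimicking the excess of rare variants left by a
    recent sweep; the genealogy itself stays neutral (a documented
    caricature, sufficient to give the neutrality tests signal).
    """
    if config.theta < 0:
        raise ValueError("theta must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_haplotypes
    L = config.locus_length
    tree = _simulate_coalescent_tree(n, rng)
    total_len = tree.blen.sum()
    # theta is per locus on the Watterson scale (E[S] = a1 * theta):
    # mutations fall on branches at rate theta/2 per unit branch length.
    n_mut = rng.poisson(config.theta / 2.0 * total_len)
    geno_cols: list[np.ndarray] = []
    skew = min(0.0, config.spectrum_skew)
    if n_mut > 0:
        branch_probs = tree.blen / total_len
        nodes = rng.choice(len(tree.blen), size=n_mut, p=branch_probs)
        if skew < 0:
            ext_len = tree.blen[: tree.n_leaves]
            ext_probs = ext_len / ext_len.sum()
            reassign = rng.random(n_mut) < -skew
            nodes[reassign] = rng.choice(tree.n_leaves, size=int(reassign.sum()),
                                         p=ext_probs)
        for node in nodes:
            col = np.zeros(n, dtype=np.int8)
            col[tree.leaves_below(int(node))] = 1
            if 0 < col.sum() < n:
                geno_cols.append(col)
    if geno_cols:
        pos = np.sort(rng.choice(L, size=len(geno_cols), replace=False)) \
            if len(geno_cols) <= L else np.arange(len(geno_cols))
        geno = np.stack(geno_cols, axis=1)
    else:
        pos = np.zeros(0, dtype=int)
        geno = np.zeros((n, 0), dtype=np.int8)
    contig = gene.contig if gene else "locus"
    start = gene.start if gene else 0
    nts = "ACGT"
    ref = []
    alt = []
    for p in pos:
        r = reference_seq[int(p)] if reference_seq else nts[int(rng.integers(4))]
        choices = [b for b in nts if b != r]
        ref.append(r)
        alt.append(choices[int(rng.integers(3))])
    return HaplotypeMatrix([f"acc{i:03d}" for i in range(n)], pos, geno,
                           locus_contig=contig, locus_start=start,
                           locus_length=L, gene=gene,
                           ref_alleles=ref, alt_alleles=alt)


# ---------------------------------------------------------------------------
# expression counts


def simulate_est_counts(n_genes: int, tissues: list[str],
                        enriched: dict[str, str] | None,
                        config: SimConfig,
                        n_est_per_gene: int = 60) -> list[ExpressionProfile]:
    """Multinomial EST tissue allocation, with planted enriched genes.

    An enriched gene's target-tissue probability is multiplied by the
    config's enrichment factor and renormalized.
    """
    if not tissues:
        raise ValueError("tissues must be non-empty")
    if config.enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    enriched = enriched or {}
    rng = np.random.default_rng(config.seed)
    base = np.full(len(tissues), 1.0 / len(tissues))
    tissue_idx = {t: i for i, t in enumerate(tissues)}
    out = []
    for g in range(n_genes):
        gid = f"g{g:04d}"
        probs = base.copy()
        if gid in enriched:
            probs[tissue_idx[enriched[gid]]] *= config.enrichment_factor
            probs /= probs.sum()
        counts = rng.multinomial(n_est_per_gene, probs)
        out.append(ExpressionProfile(gid, "EST",
                                     dict(zip(tissues, map(float, counts)))))
    return out


# ---------------------------------------------------------------------------
# bisulfite counts


def _iter_cytosines(seq: str, contig: str):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i, b in enumerate(seq):
        if b == "C":
            yield contig, i, "+"
        elif b == "G":
            yield contig, i, "-"


def simulate_bisulfite(genome: dict[str, str], true_methylated: dict[str, set[int]],
                       depth: float, error_rate_true: float, seed: int,
                       methylated_rate: float = 0.8,
                       control_contig: str = "chloroplast",
                       control_length: int = 10_000) -> list[CytosineRecord]:
    """Per-cytosine read counts: Binomial(depth_i, m_i).

    m_i is ``methylated_rate`` at truly methylated positions and the
    bisulfite non-conversion error rate elsewhere.  A control contig with
    no true methylation (the chloroplast analogue) is appended unless the
    genome already contains one, so the error rate is estimable from the
    output alone.
    """
    if not 0 <= error_rate_true < 0.5:
        raise ValueError("error_rate_true must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    genome = dict(genome)
    if control_contig not in genome:
        nts = np.array(list("ACGT"))
        genome[control_contig] = "".join(rng.choice(nts, size=control_length))
    records = []
    for contig, seq in genome.items():
        meth_set = set() if contig == control_contig else true_methylated.get(contig, set())
        for ctg, pos, strand in _iter_cytosines(seq, contig):
            n = int(rng.poisson(depth))
            m_rate = methylated_rate if pos in meth_set else error_rate_true
            k = int(rng.binomial(n, m_rate)) if n > 0 else 0
            from .methylation import context_of  # local import avoids a cycle

            ctx = context_of(genome, ctg, pos, strand)
            records.append(CytosineRecord(ctg, pos, strand, ctx, k, n))
    return records


# ---------------------------------------------------------------------------
# cis elements

CIS_ELEMENT_UNIVERSE = [f"motif{i:02d}" for i in range(30)]


def simulate_cis_elements(pairs: list[ParalogPair], divergence_mode: str | dict[str, str],
                          seed: int) -> dict[str, list[str]]:
    """Element sets per gene, drawn so the requested divergence mode is
    recoverable by set comparison.

    ``divergence_mode`` is one of same | parent_extra | ndg_extra |
    different, or a per-pair-id map ("gene1|gene2") of modes.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for p in pairs:
        mode = divergence_mode if isinstance(divergence_mode, str) else \
            divergence_mode[f"{p.gene_1}|{p.gene_2}"]
        parent = p.parent_id or p.gene_1
        ndg = p.ndg_id or p.gene_2
        universe = list(CIS_ELEMENT_UNIVERSE)
        rng.shuffle(universe)
        shared = universe[: int(rng.integers(2, 5))]
        extra1, extra2 = universe[5:7], universe[7:9]
        if mode == "same":
            out[parent], out[ndg] = list(shared), list(shared)
        elif mode == "parent_extra":
            out[parent], out[ndg] = shared + extra1, list(shared)
        elif mode == "ndg_extra":
            out[parent], out[ndg] = list(shared), shared + extra1
        elif mode == "different":
            out[parent], out[ndg] = shared + extra1, shared + extra2
        else:
            raise ValueError(f"unknown divergence mode {mode!r}")
    return out
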