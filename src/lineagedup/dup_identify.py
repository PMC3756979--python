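"""Identification of lineage-specific new duplicate genes (NDGs).

The pipeline follows the classic comparative design: build reciprocal
best-hit (RBH) orthologs and collinear gene-anchor synteny blocks between
the focal genome and each outgroup; call a focal gene lineage-specific
when it sits outside all syntenic regions AND has no reciprocal ortholog
in any outgroup; pair each such gene with its best paralog (>=50%
identity, >=70% coverage at the protein level); classify the duplication
mechanism (tandem / segmental / dispersed); detect chimeric fusions; and
polarize parent vs daughter by synteny fraction, falling back to a
bootstrapped neighbor-joining gene tree with outgroup orthologs.

Synteny here is gene-anchor collinear chaining rather than nucleotide
chain/nets: the criteria are stated at gene level, so anchor chains give
the same per-gene calls without external aligners.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .types import GeneModel, HomologyHit, ParalogPair, SyntenyBlock

logger = logging.getLogger(__name__)

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")

# Karlin-Altschul parameters for BLOSUM62 with affine gaps (11/1),
# used to attach BLAST-like e-values to internal alignment scores.
_KA_LAMBDA = 0.267
_KA_K = 0.041


def _aligner(mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    a.mode = mode
    if mode == "global":
        # do not penalize terminal gaps so short-vs-long stays sensible
        a.target_end_gap_score = 0.0
        a.query_end_gap_score = 0.0
    return a


def align_proteins(seq_a: str, seq_b: str, mode: str = "local"):
    """Affine-gap protein alignment with identity/coverage summaries.

    Returns ``(identity_pct, coverage_pct, (a_interval, b_interval),
    score)``.  Identity is identical columns over columns where both
    sequences have a residue; coverage is the aligned residue span over
    the longer sequence length.

    The reported intervals and summaries come from the maximal
    homologous segment of the alignment (best-scoring run of columns
    under match +1 / mismatch -1): affine local alignments occasionally
    chain through low-identity non-homologous stretches with marginally
    positive score, which would otherwise inflate coverage on e.g.
    chimeric genes.  The raw DP score is reported unchanged.
    """
    for name, s in (("a", seq_a), ("b", seq_b)):
        if not s:
            raise ValueError(f"sequence {name} is empty")
        bad = set(s.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(f"non-amino-acid characters in sequence {name}: {bad}")
    if mode not in ("local", "global"):
        raise ValueError("mode must be 'local' or 'global'")
    aln = _aligner(mode).align(seq_a.upper(), seq_b.upper())[0]
    blocks_a, blocks_b = aln.aligned
    columns: list[tuple[int, int, bool]] = []
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        for i in range(ae - as_):
            columns.append((as_ + i, bs + i,
                            seq_a[as_ + i].upper() == seq_b[bs + i].upper()))
    if not columns:
        return 0.0, 0.0, ((0, 0), (0, 0)), 0.0
    # Kadane over +-1 column scores -> maximal homologous run
    best_sum = cur_sum = -1.0
    best = (0, 0)
    start = 0
    for i, (_, _, m) in enumerate(columns):
        s = 1.0 if m else -1.0
        if cur_sum <= 0:
            cur_sum, start = s, i
        else:
            cur_sum += s
        if cur_sum > best_sum:
            best_sum, best = cur_sum, (start, i + 1)
    seg = columns[best[0] : best[1]]
    matches = sum(m for _, _, m in seg)
    identity = 100.0 * matches / len(seg)
    a_iv = (seg[0][0], seg[-1][0] + 1)
    b_iv = (seg[0][1], seg[-1][1] + 1)
    span = max(a_iv[1] - a_iv[0], b_iv[1] - b_iv[0])
    coverage = 100.0 * span / max(len(seq_a), len(seq_b))
    return identity, min(coverage, 100.0), (a_iv, b_iv), float(aln.score)


def _evalue(score: float, m: int, n: int) -> float:
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def _kmer_set(seq: str, k: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all_hits(proteins_a: dict[str, str], proteins_b: dict[str, str],
                    max_evalue: float = 10.0, kmer_prefilter: int = 5) -> list[HomologyHit]:
    """Internal desk-scale homology search: k-mer seeded pairs are
    aligned locally and reported with BLAST-like e-values."""
    kmers_b = {gid: _kmer_set(s, kmer_prefilter) for gid, s in proteins_b.items()}
    hits: list[HomologyHit] = []
    for qid, qseq in proteins_a.items():
        qk = _kmer_set(qseq, kmer_prefilter)
        for sid, sseq in proteins_b.items():
            if qid == sid or not (qk & kmers_b[sid]):
                continue
            identity, coverage, (qiv, siv), score = align_proteins(qseq, sseq, "local")
            ev = _evalue(score, len(qseq), len(sseq))
            if ev <= max_evalue:
                hits.append(HomologyHit(qid, sid, identity, ev, score, qiv, siv))
    return hits


def call_orthologs(hits_ab: list[HomologyHit], hits_ba: list[HomologyHit],
                   max_evalue: float = 0.001) -> list[tuple[str, str]]:
    """Reciprocal best hits with both e-values below the cutoff.

    Best is by score, then e-value, then subject id; exact ties on
    (score, e-value) produce no call (logged).
    """

    def best_map(hits: list[HomologyHit]) -> dict[str, HomologyHit | None]:
        by_query: dict[str, list[HomologyHit]] = defaultdict(list)
        for h in hits:
            by_query[h.query_id].append(h)
        out: dict[str, HomologyHit | None] = {}
        for q, hs in by_query.items():
            hs = sorted(hs, key=lambda h: (-h.score, h.evalue, h.subject_id))
            if len(hs) > 1 and (hs[0].score, hs[0].evalue) == (hs[1].score, hs[1].evalue):
                logger.info("tied best hits for %s; no call", q)
                out[q] = None
            else:
                out[q] = hs[0]
        return out

    best_ab, best_ba = best_map(hits_ab), best_map(hits_ba)
    pairs = []
    for a, h in best_ab.items():
        if h is None or h.evalue >= max_evalue:
            continue
        back = best_ba.get(h.subject_id)
        if back is not None and back.subject_id == a and back.evalue < max_evalue:
            pairs.append((a, h.subject_id))
    return sorted(pairs)


def build_synteny(genes_a: list[GeneModel], genes_b: list[GeneModel],
                  hits: list[HomologyHit], min_anchors: int = 3,
                  max_gap: int = 5, species_a: str = "a",
                  species_b: str = "b") -> list[SyntenyBlock]:
    """Collinear chains of RBH gene anchors.

    ``hits`` contains both search directions; RBH anchors are chained per
    contig pair by longest-increasing-subsequence dynamic programming
    with at most ``max_gap`` skipped genes between consecutive anchors
    (both orientations tried).  Chains are extracted greedily by size;
    each gene joins at most one block.
    """
    ids_a = {g.gene_id for g in genes_a}
    ids_b = {g.gene_id for g in genes_b}
    for h in hits:
        if h.query_id not in ids_a | ids_b or h.subject_id not in ids_a | ids_b:
            raise ValueError(f"hit references unknown gene: {h.query_id}/{h.subject_id}")
    hits_ab = [h for h in hits if h.query_id in ids_a and h.subject_id in ids_b]
    hits_ba = [h for h in hits if h.query_id in ids_b and h.subject_id in ids_a]
    anchors = call_orthologs(hits_ab, hits_ba, max_evalue=0.001)

    idx_a = {g.gene_id: i for i, g in enumerate(genes_a)}
    idx_b = {g.gene_id: i for i, g in enumerate(genes_b)}
    gene_a = {g.gene_id: g for g in genes_a}
    gene_b = {g.gene_id: g for g in genes_b}

    by_contig: dict[tuple[str, str], list[tuple[int, int, str, str]]] = defaultdict(list)
    for a, b in anchors:
        by_contig[(gene_a[a].contig, gene_b[b].contig)].append((idx_a[a], idx_b[b], a, b))

    blocks: list[SyntenyBlock] = []
    for (ca, cb), anc in by_contig.items():
        anc = sorted(anc)
        available = list(anc)
        while True:
            chain = _best_chain(available, max_gap)
            if len(chain) < max(min_anchors, 1):
                break
            pairs = [(a, b) for _, _, a, b in chain]
            ga = [gene_a[a] for a, _ in pairs]
            gb = [gene_b[b] for _, b in pairs]
            orient = "+" if len(chain) < 2 or chain[-1][1] >= chain[0][1] else "-"
            blocks.append(SyntenyBlock(
                species_a, species_b, pairs,
                (ca, min(g.start for g in ga), max(g.end for g in ga)),
                (cb, min(g.start for g in gb), max(g.end for g in gb)),
                orient,
            ))
            used = set(chain)
            available = [x for x in available if x not in used]
            if len(available) < min_anchors:
                break
    return blocks


def _best_chain(anchors: list[tuple[int, int, str, str]], max_gap: int):
    """Longest collinear chain (either orientation) under the gap limit."""

    def lis(items, sign):
        n = len(items)
        best_len = [1] * n
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                da = items[i][0] - items[j][0]
                db = sign * (items[i][1] - items[j][1])
                if 0 < da <= max_gap + 1 and 0 < db <= max_gap + 1:
                    if best_len[j] + 1 > best_len[i]:
                        best_len[i] = best_len[j] + 1
                        prev[i] = j
        if not items:
            return []
        end = max(range(n), key=lambda i: best_len[i])
        chain = []
        while end >= 0:
            chain.append(items[end])
            end = prev[end]
        return chain[::-1]

    fwd = lis(anchors, +1)
    rev = lis(anchors, -1)
    return fwd if len(fwd) >= len(rev) else rev


def synteny_fraction(gene: GeneModel, blocks: list[SyntenyBlock],
                     genes_a: list[GeneModel]) -> float:
    """Fraction of the gene's length covered by syntenic aligned regions.

    The aligned footprint of a block is the union of its a-side anchor
    gene bodies — the gene-anchor analogue of the aligned segments of a
    nucleotide chain.  A gene inserted between anchors overlaps nothing.
    """
    gene_a = {g.gene_id: g for g in genes_a}
    intervals = []
    for blk in blocks:
        for a, _ in blk.anchors:
            g = gene_a.get(a)
            if g is not None and g.contig == gene.contig:
                intervals.append((g.start, g.end))
    if not intervals:
        return 0.0
    intervals.sort()
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    cov = sum(max(0, min(gene.end, e) - max(gene.start, s)) for s, e in merged)
    return cov / gene.length


def find_lineage_specific(
    genes_focal: list[GeneModel],
    blocks_by_outgroup: dict[str, list[SyntenyBlock]],
    orthologs_by_outgroup: dict[str, list[tuple[str, str]]],
    max_synteny_fraction: float = 0.3,
) -> list[str]:
    """Focal genes outside syntenic regions of ALL outgroups and without
    a reciprocal ortholog in ANY outgroup (both criteria required)."""
    if set(blocks_by_outgroup) != set(orthologs_by_outgroup):
        raise ValueError("synteny and ortholog comparisons must cover the same outgroups")
    with_ortholog = set()
    for pairs in orthologs_by_outgroup.values():
        with_ortholog.update(a for a, _ in pairs)
    out = []
    for g in genes_focal:
        if g.gene_id in with_ortholog:
            continue
        frac = max(
            (synteny_fraction(g, blocks, genes_focal) for blocks in blocks_by_outgroup.values()),
            default=0.0,
        )
        if frac < max_synteny_fraction:
            out.append(g.gene_id)
    return out


def pair_paralogs(lineage_specific: list[str], proteins: dict[str, str],
                  min_identity: float = 50.0, min_coverage: float = 70.0,
                  kmer_prefilter: int = 5) -> list[ParalogPair]:
    """Pair each lineage-specific gene with its best-scoring paralog
    meeting the identity and coverage thresholds."""
    kmers = {gid: _kmer_set(s, kmer_prefilter) for gid, s in proteins.items()}
    pairs = []
    for gid in lineage_specific:
        if gid not in proteins:
            raise ValueError(f"no protein for {gid}")
        best = None
        qk = kmers[gid]
        for sid, sseq in proteins.items():
            if sid == gid or not (qk & kmers[sid]):
                continue
            identity, coverage, _, score = align_proteins(proteins[gid], sseq, "local")
            if identity >= min_identity and coverage >= min_coverage:
                if best is None or score > best[0] or (score == best[0] and sid < best[1]):
                    best = (score, sid, identity, coverage)
        if best is not None:
            _, sid, identity, coverage = best
            pairs.append(ParalogPair(gid, sid, identity, coverage))
    return pairs


def classify_duplication(pair: ParalogPair, genes_focal: list[GeneModel],
                         all_pairs: list[ParalogPair],
                         max_companion_distance: int = 10) -> str:
    """tandem iff the copies are adjacent on the same contig; segmental
    iff a companion paralog pair lies within ``max_companion_distance``
    intervening genes on both segments with consistent order; otherwise
    dispersed."""
    idx = {g.gene_id: i for i, g in enumerate(genes_focal)}
    contig = {g.gene_id: g.contig for g in genes_focal}
    for gid in (pair.gene_1, pair.gene_2):
        if gid not in idx:
            raise ValueError(f"{gid} not in focal gene order")
    i1, i2 = idx[pair.gene_1], idx[pair.gene_2]
    if contig[pair.gene_1] == contig[pair.gene_2] and abs(i1 - i2) == 1:
        return "tandem"
    for other in all_pairs:
        if {other.gene_1, other.gene_2} == {pair.gene_1, pair.gene_2}:
            continue
        if other.gene_1 not in idx or other.gene_2 not in idx:
            continue
        for h1, h2 in ((other.gene_1, other.gene_2), (other.gene_2, other.gene_1)):
            j1, j2 = idx[h1], idx[h2]
            if contig[h1] != contig[pair.gene_1] or contig[h2] != contig[pair.gene_2]:
                continue
            d1, d2 = j1 - i1, j2 - i2
            # <= max intervening genes, endpoints excluded; same relative
            # order on both segments makes the segments mutually syntenic
            if (0 < abs(d1) <= max_companion_distance + 1
                    and 0 < abs(d2) <= max_companion_distance + 1
                    and np.sign(d1) == np.sign(d2)):
                return "segmental"
    return "dispersed"


def polarize(pair: ParalogPair, blocks_by_outgroup: dict[str, list[SyntenyBlock]],
             genes_focal: list[GeneModel],
             outgroup_cds: dict[str, str] | None = None,
             focal_cds: dict[str, str] | None = None,
             max_fraction: float = 0.3, bootstrap: int = 1000,
             support_threshold: float = 0.5, seed: int = 0) -> ParalogPair:
    """Assign parent and daughter (NDG) roles within a pair.

    The copy with < ``max_fraction`` of its length in syntenic regions is
    the NDG (the other the parent).  If both or neither qualify, a
    neighbor-joining gene tree of the two copies plus outgroup orthologs
    decides: the copy closer to the orthologs is the parent, accepted
    when >= ``support_threshold`` of bootstrap column resamples agree.
    Otherwise the pair stays undetermined.
    """
    gene_map = {g.gene_id: g for g in genes_focal}
    fracs = {}
    for gid in (pair.gene_1, pair.gene_2):
        fracs[gid] = max(
            (synteny_fraction(gene_map[gid], blocks, genes_focal)
             for blocks in blocks_by_outgroup.values()),
            default=0.0,
        )
    low = [g for g, f in fracs.items() if f < max_fraction]
    if len(low) == 1:
        ndg = low[0]
        parent = pair.gene_2 if ndg == pair.gene_1 else pair.gene_1
        return _with_polarization(pair, parent, ndg, "synteny_fraction")
    # tie: gene tree with outgroup orthologs
    if not outgroup_cds or not focal_cds:
        return _with_polarization(pair, "", "", "undetermined")
    from .molevol import polarize_by_tree  # deferred import; molevol owns NJ

    call = polarize_by_tree(
        focal_cds.get(pair.gene_1, ""), focal_cds.get(pair.gene_2, ""),
        outgroup_cds, bootstrap=bootstrap, seed=seed,
    )
    if call is None or call[1] < support_threshold:
        return _with_polarization(pair, "", "", "undetermined")
    parent_is_1, _support = call
    parent = pair.gene_1 if parent_is_1 else pair.gene_2
    ndg = pair.gene_2 if parent_is_1 else pair.gene_1
    return _with_polarization(pair, parent, ndg, "gene_tree")


def _with_polarization(pair: ParalogPair, parent: str, ndg: str, method: str) -> ParalogPair:
    return ParalogPair(pair.gene_1, pair.gene_2, pair.identity, pair.coverage,
                       pair.duplication_class, parent, ndg, method,
                       pair.chimera, list(pair.chimera_donors))


def detect_chimera(gene_id: str, hits: list[HomologyHit],
                   te_annotation: list[tuple[str, int, int]] | None = None,
                   max_reciprocal_overlap: float = 0.2,
                   max_evalue: float = 1e-3) -> dict:
    """Chimera call: >= 2 donor genes hit near-disjoint query regions.

    Donor query intervals must overlap each other by < the reciprocal
    threshold (fraction of either interval).  ``te_annotation`` lists
    transposable-element intervals as ``(donor_id, start, end)``; a donor
    whose hit interval overlaps one makes the call a TE fusion.
    Returns ``{"chimera": bool, "donors": [...], "te_fusion": bool}``.
    """
    best_per_donor: dict[str, HomologyHit] = {}
    for h in hits:
        if h.query_id != gene_id or h.subject_id == gene_id or h.evalue >= max_evalue:
            continue
        cur = best_per_donor.get(h.subject_id)
        if cur is None or h.score > cur.score:
            best_per_donor[h.subject_id] = h
    donors: list[HomologyHit] = []
    for h in sorted(best_per_donor.values(), key=lambda x: -x.score):
        ok = True
        for d in donors:
            s = max(h.query_interval[0], d.query_interval[0])
            e = min(h.query_interval[1], d.query_interval[1])
            ov = max(0, e - s)
            len_h = h.query_interval[1] - h.query_interval[0]
            len_d = d.query_interval[1] - d.query_interval[0]
            if len_h and len_d and (ov / len_h >= max_reciprocal_overlap
                                    or ov / len_d >= max_reciprocal_overlap):
                ok = False
                break
        if ok:
            donors.append(h)
    is_chimera = len(donors) >= 2
    te_fusion = False
    if is_chimera and te_annotation:
        for d in donors:
            for te_id, s, e in te_annotation:
                if d.subject_id == te_id and \
                        max(d.subject_interval[0], s) < min(d.subject_interval[1], e):
                    te_fusion = True
    return {
        "chimera": is_chimera,
        "donors": [d.subject_id for d in donors] if is_chimera else [],
        "te_fusion": te_fusion,
    }


def presence_fixation(calls: dict[str, str]) -> str:
    """``segregating`` if any accession lacks a genomic hit ('absent'),
    else ``fixed``.  'present' and 'unannotated-hit' both count as a hit."""
    if not calls:
        raise ValueError("need at least one accession call")
    for acc, status in calls.items():
        if status not in ("present", "absent", "unannotated-hit"):
            raise ValueError(f"unknown presence status {status!r} for {acc}")
    return "segregating" if any(s == "absent" for s in calls.values()) else "fixed"


def identify_ndg_pairs(genome_set, min_identity: float = 50.0,
                       min_coverage: float = 70.0, max_gap: int = 5,
                       min_anchors: int = 3, seed: int = 0) -> list[ParalogPair]:
    """End-to-end identification on a simulated (or loaded) genome set:
    returns classified, polarized paralog pairs of the focal species."""
    focal = genome_set.focal_species
    genes_focal = genome_set.genes[focal]
    proteins = {sp: {g.gene_id: g.protein for g in gl}
                for sp, gl in genome_set.genes.items()}
    outgroups = [sp for sp in genome_set.genes if sp != focal]

    blocks_by_og: dict[str, list] = {}
    orthos_by_og: dict[str, list] = {}
    best_hit_by_og: dict[str, dict[str, str]] = {}
    for og in outgroups:
        hits_ab = all_vs_all_hits(proteins[focal], proteins[og])
        hits_ba = all_vs_all_hits(proteins[og], proteins[focal])
        blocks_by_og[og] = build_synteny(genes_focal, genome_set.genes[og],
                                         hits_ab + hits_ba, min_anchors=min_anchors,
                                         max_gap=max_gap, species_a=focal, species_b=og)
        orthos_by_og[og] = call_orthologs(hits_ab, hits_ba)
        # best (not necessarily reciprocal) hit per focal gene: two recent
        # paralogs often tie for reciprocity yet share one clear outgroup
        # ortholog, which the gene-tree polarization can still use
        best: dict[str, HomologyHit] = {}
        for h in hits_ab:
            if h.evalue < 0.001 and (h.query_id not in best
                                     or h.score > best[h.query_id].score):
                best[h.query_id] = h
        best_hit_by_og[og] = {q: h.subject_id for q, h in best.items()}

    ls_genes = find_lineage_specific(genes_focal, blocks_by_og, orthos_by_og)
    pairs = pair_paralogs(ls_genes, proteins[focal], min_identity, min_coverage)

    # flag chimeric lineage-specific genes; their "pairs" (if any) are kept
    # flagged but never serve as segmental companions
    self_hits = all_vs_all_hits(proteins[focal], proteins[focal])
    chimera_of: dict[str, dict] = {}
    for gid in ls_genes:
        report = detect_chimera(gid, self_hits)
        if report["chimera"]:
            chimera_of[gid] = report
    for p in pairs:
        if p.gene_1 in chimera_of:
            p.chimera = True
            p.chimera_donors = chimera_of[p.gene_1]["donors"]
    companion_pairs = [p for p in pairs if not p.chimera]

    focal_cds = {g.gene_id: g.cds_sequence for g in genes_focal}
    ortholog_cds_of: dict[str, dict[str, str]] = {}
    for og in outgroups:
        og_cds = {g.gene_id: g.cds_sequence for g in genome_set.genes[og]}
        for a, b in best_hit_by_og[og].items():
            ortholog_cds_of.setdefault(a, {})[f"{og}:{b}"] = og_cds[b]

    out = []
    for p in pairs:
        cls = classify_duplication(p, genes_focal, companion_pairs)
        q = ParalogPair(p.gene_1, p.gene_2, p.identity, p.coverage, cls,
                        chimera=p.chimera, chimera_donors=list(p.chimera_donors))
        partner_orths = {**ortholog_cds_of.get(q.gene_1, {}),
                         **ortholog_cds_of.get(q.gene_2, {})}
        q = polarize(q, blocks_by_og, genes_focal,
                     outgroup_cds=partner_orths, focal_cds=focal_cds, seed=seed)
        out.append(q)
    return out


def find_chimeras(genome_set, max_evalue: float = 1e-3) -> dict[str, dict]:
    """Chimera reports for every lineage-specific focal gene (driver used
    alongside :func:`identify_ndg_pairs`)."""
    focal = genome_set.focal_species
    proteins = {g.gene_id: g.protein for g in genome_set.genes[focal]}
    self_hits = all_vs_all_hits(proteins, proteins)
    out = {}
    for gid in proteins:
        report = detect_chimera(gid, self_hits, max_evalue=max_evalue)
        if report["chimera"]:
            out[gid] = report
    return out
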