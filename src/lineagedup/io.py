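"""Reading and writing the pipeline's on-disk formats.

FASTA via Biopython; GFF3 1-based inclusive on disk (0-based half-open
in memory); haplotypes as phased-GT VCF 4.2; everything tabular as TSV
through pandas.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import CytosineRecord, GeneModel, HaplotypeMatrix, HomologyHit, ParalogPair

HIT_COLUMNS = [
    "query_id", "subject_id", "identity", "alignment_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "score",
]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(path: str | os.PathLike, genes: Iterable[GeneModel], source: str = "lineagedup") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.contig}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(g.cds_intervals):
                fh.write(
                    f"{g.contig}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{(s - g.cds_intervals[0][0]) % 3 if g.strand == '+' else '.'}\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


def _parse_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | os.PathLike, cds_sequences: dict[str, str] | None = None) -> list[GeneModel]:
    """Parse gene and CDS features into GeneModel records.

    ``cds_sequences`` (e.g. from a CDS FASTA keyed by gene id) attaches
    spliced CDS sequences; otherwise cds_sequence stays empty.
    """
    genes: dict[str, GeneModel] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = f[:9]
            a = _parse_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID", f"{contig}:{start}-{end}")
                genes[gid] = GeneModel(gid, contig, int(start) - 1, int(end), strand)
                order.append(gid)
            elif ftype == "CDS":
                parent = a.get("Parent", a.get("ID", ""))
                cds.setdefault(parent, []).append((int(start) - 1, int(end)))
    out = []
    for gid in order:
        g = genes[gid]
        g.cds_intervals = sorted(cds.get(gid, []))
        if cds_sequences and gid in cds_sequences:
            g.cds_sequence = cds_sequences[gid]
        out.append(g)
    return out


def write_vcf(path: str | os.PathLike, hap: HaplotypeMatrix,
              ref_alt: tuple[str, str] = ("A", "T")) -> None:
    """Write a biallelic haplotype matrix as a phased VCF 4.2.

    Haploid samples are written as single phased alleles.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={hap.locus_contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(hap.sample_ids) + "\n")
        for j, pos in enumerate(hap.positions):
            gts = "\t".join(str(int(g)) for g in hap.genotypes[:, j])
            fh.write(
                f"{hap.locus_contig}\t{hap.locus_start + int(pos) + 1}\t.\t{ref_alt[0]}\t{ref_alt[1]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | os.PathLike) -> HaplotypeMatrix:
    """Read a haploid-GT VCF back into a HaplotypeMatrix.

    Sites with missing calls are dropped (logged via a warning), matching
    the pipeline's no-missing-data policy.
    """
    samples: list[str] = []
    contig = "locus"
    positions: list[int] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            f = line.rstrip("\n").split("\t")
            contig = f[0]
            calls = [c.split(":")[0] for c in f[9:]]
            flat = [a for c in calls for a in c.replace("|", "/").split("/")]
            if any(a == "." for a in flat):
                continue
            positions.append(int(f[1]) - 1)
            rows.append([int(a) for a in flat])
    geno = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(samples), 0), np.int8)
    length = (positions[-1] + 1) if positions else 0
    return HaplotypeMatrix(samples, np.array(positions, dtype=int), geno,
                           locus_contig=contig, locus_length=length)


def write_hits(path: str | os.PathLike, hits: Iterable[HomologyHit]) -> None:
    rows = []
    for h in hits:
        qs, qe = h.query_interval
        ss, se = h.subject_interval
        rows.append([h.query_id, h.subject_id, h.identity, qe - qs, 0, 0,
                     qs + 1, qe, ss + 1, se, h.evalue, h.score])
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False, header=False)


def read_hits(path: str | os.PathLike) -> list[HomologyHit]:
    """Read a 12-column tabular hit file (BLAST outfmt-6 layout)."""
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)
    return [
        HomologyHit(r.query_id, r.subject_id, float(r.identity), float(r.evalue),
                    float(r.score), (int(r.q_start) - 1, int(r.q_end)),
                    (int(r.s_start) - 1, int(r.s_end)))
        for r in df.itertuples()
    ]


def write_pairs(path: str | os.PathLike, pairs: Iterable[ParalogPair]) -> None:
    rows = [
        {
            "gene_1": p.gene_1, "gene_2": p.gene_2, "identity": p.identity,
            "coverage": p.coverage, "class": p.duplication_class,
            "parent_id": p.parent_id, "ndg_id": p.ndg_id,
            "polarization_method": p.polarization_method,
            "chimera": p.chimera, "chimera_donors": ",".join(p.chimera_donors),
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | os.PathLike) -> list[ParalogPair]:
    df = pd.read_csv(path, sep="\t").fillna({"parent_id": "", "ndg_id": "",
                                             "class": "", "chimera_donors": ""})
    return [
        ParalogPair(r.gene_1, r.gene_2, float(r.identity), float(r.coverage),
                    str(r._5), str(r.parent_id), str(r.ndg_id),
                    str(r.polarization_method), bool(r.chimera),
                    [d for d in str(r.chimera_donors).split(",") if d])
        for r in df.itertuples()
    ]


def write_cytosine_report(path: str | os.PathLike, records: Iterable[CytosineRecord]) -> None:
    rows = [
        [r.contig, r.position + 1, r.strand, r.context, r.methylated_reads,
         r.total_reads - r.methylated_reads]
        for r in records
    ]
    pd.DataFrame(rows, columns=["contig", "pos", "strand", "context",
                                "meth_reads", "unmeth_reads"]).to_csv(
        path, sep="\t", index=False, header=False)


def read_cytosine_report(path: str | os.PathLike) -> list[CytosineRecord]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig", "pos", "strand", "context", "meth", "unmeth"])
    return [
        CytosineRecord(str(r.contig), int(r.pos) - 1, str(r.strand), str(r.context),
                       int(r.meth), int(r.meth) + int(r.unmeth))
        for r in df.itertuples()
    ]
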