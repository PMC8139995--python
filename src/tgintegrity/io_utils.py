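"""Readers and writers for the standard formats the pipeline consumes and
emits: FASTA, GFF3, FASTQ, SAM, VCF v4.2, BED, and the contig->chromosome
map TSV.  All emitted files follow the 1-based conventions of their formats;
in-memory coordinates are 0-based half-open except ``SmallVariant.pos``.
"""
from __future__ import annotations

import os
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import gffutils
import pysam
from pyfaidx import Fasta

from .synthgenome import GeneModel, ReadSimulation, ToyGenome, Transcript
from .variant_consensus import SmallVariant

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "load_gff3",
    "write_chrom_map",
    "read_chrom_map",
    "write_vcf",
    "read_vcf",
    "write_bed",
    "read_bed",
    "write_fastq_pair",
    "write_truth_sam",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(contigs: Iterable[Tuple[str, str]], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> Dict[str, str]:
    fa = Fasta(path, as_raw=True, sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_RNA_TYPE = {"protein_coding": "mRNA", "lincRNA": "lnc_RNA", "other": "transcript"}


def write_gff3(genome: ToyGenome, path: str) -> None:
    lines = ["##gff-version 3"]
    for cid, seq in genome.contigs:
        lines.append(f"##sequence-region {cid} 1 {len(seq)}")
    for g in genome.genes:
        gs, ge = g.span
        lines.append(
            "\t".join(
                [
                    g.contig_id,
                    "toygen",
                    "gene",
                    str(gs + 1),
                    str(ge),
                    ".",
                    g.strand,
                    ".",
                    f"ID={g.gene_id};biotype={g.biotype};canonical={g.canonical_id}",
                ]
            )
        )
        for t in g.transcripts:
            ts, te = t.span
            rna = _RNA_TYPE.get(g.biotype, "transcript")
            lines.append(
                "\t".join(
                    [
                        g.contig_id,
                        "toygen",
                        rna,
                        str(ts + 1),
                        str(te),
                        ".",
                        g.strand,
                        ".",
                        f"ID={t.transcript_id};Parent={g.gene_id}",
                    ]
                )
            )
            for s, e in t.exons:
                lines.append(
                    "\t".join(
                        [
                            g.contig_id,
                            "toygen",
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            g.strand,
                            ".",
                            f"Parent={t.transcript_id}",
                        ]
                    )
                )
            # CDS phase in transcript order
            cds_tx = t.cds if g.strand == "+" else list(reversed(t.cds))
            cum = 0
            phases = {}
            for s, e in cds_tx:
                phases[(s, e)] = (3 - cum % 3) % 3
                cum += e - s
            for s, e in t.cds:
                lines.append(
                    "\t".join(
                        [
                            g.contig_id,
                            "toygen",
                            "CDS",
                            str(s + 1),
                            str(e),
                            ".",
                            g.strand,
                            str(phases[(s, e)]),
                            f"Parent={t.transcript_id}",
                        ]
                    )
                )
            for kind, ivs in (("five_prime_UTR", t.utr5), ("three_prime_UTR", t.utr3)):
                for s, e in ivs:
                    lines.append(
                        "\t".join(
                            [
                                g.contig_id,
                                "toygen",
                                kind,
                                str(s + 1),
                                str(e),
                                ".",
                                g.strand,
                                ".",
                                f"Parent={t.transcript_id}",
                            ]
                        )
                    )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_gff3(path: str) -> List[GeneModel]:
    """Rebuild gene models from a GFF3 annotation (gffutils-backed)."""
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: List[GeneModel] = []
    for g in db.features_of_type("gene"):
        transcripts: List[Transcript] = []
        for t in db.children(g, level=1):
            exons, cds, u5, u3 = [], [], [], []
            for f in db.children(t, level=1):
                iv = (f.start - 1, f.end)
                if f.featuretype == "exon":
                    exons.append(iv)
                elif f.featuretype == "CDS":
                    cds.append(iv)
                elif f.featuretype == "five_prime_UTR":
                    u5.append(iv)
                elif f.featuretype == "three_prime_UTR":
                    u3.append(iv)
            transcripts.append(
                Transcript(t.id, sorted(exons), sorted(cds), sorted(u5), sorted(u3))
            )
        canonical = g.attributes.get("canonical", [None])[0]
        if canonical is None:
            best = max(t.cds_len for t in transcripts)
            canonical = sorted(
                [t.transcript_id for t in transcripts if t.cds_len == best]
            )[0]
        genes.append(
            GeneModel(
                gene_id=g.id,
                contig_id=g.seqid,
                strand=g.strand,
                biotype=g.attributes.get("biotype", ["protein_coding"])[0],
                transcripts=transcripts,
                canonical_id=canonical,
            )
        )
    genes.sort(key=lambda x: (x.contig_id, x.span[0]))
    return genes


# ---------------------------------------------------------------------------
# chrom map TSV
# ---------------------------------------------------------------------------


def write_chrom_map(chrom_map: Mapping[str, Tuple[str, int]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tchromosome\toffset\n")
        for cid in sorted(chrom_map):
            chrom, off = chrom_map[cid]
            fh.write(f"{cid}\t{chrom}\t{off}\n")


def read_chrom_map(path: str) -> Dict[str, Tuple[str, int]]:
    out: Dict[str, Tuple[str, int]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            cid, chrom, off = line.rstrip("\n").split("\t")
            out[cid] = (chrom, int(off))
    return out


# ---------------------------------------------------------------------------
# VCF v4.2 (pysam-backed)
# ---------------------------------------------------------------------------


def _vcf_header(contigs: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for cid, ln in contigs.items():
        header.contigs.add(cid, length=ln)
    header.add_meta(
        "INFO",
        items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"), ("Description", "Total read depth")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "SAF"), ("Number", "1"), ("Type", "Integer"), ("Description", "Alt support, forward strand")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "SAR"), ("Number", "1"), ("Type", "Integer"), ("Description", "Alt support, reverse strand")],
    )
    return header


def write_vcf(
    variants: Sequence[SmallVariant], contigs: Mapping[str, int], path: str
) -> None:
    header = _vcf_header(contigs)
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in sorted(variants, key=lambda x: x.key):
            rec = out.new_record(
                contig=v.contig, start=v.pos - 1, alleles=(v.ref, v.alt), id=v.id
            )
            if v.qual is not None:
                rec.qual = v.qual
            if v.depth is not None:
                rec.info["DP"] = v.depth
            if v.alt_fwd is not None:
                rec.info["SAF"] = v.alt_fwd
            if v.alt_rev is not None:
                rec.info["SAR"] = v.alt_rev
            out.write(rec)


def read_vcf(
    path: str,
    depth_tag: str = "DP",
    fwd_tag: str = "SAF",
    rev_tag: str = "SAR",
) -> List[SmallVariant]:
    out: List[SmallVariant] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                out.append(
                    SmallVariant(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        qual=rec.qual,
                        depth=rec.info.get(depth_tag),
                        alt_fwd=rec.info.get(fwd_tag),
                        alt_rev=rec.info.get(rev_tag),
                        id=rec.id,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(intervals: Mapping[str, Sequence[Tuple[int, int]]], path: str) -> None:
    with open(path, "w") as fh:
        for cid in sorted(intervals):
            for s, e in intervals[cid]:
                fh.write(f"{cid}\t{s}\t{e}\n")


def read_bed(path: str) -> Dict[str, List[Tuple[int, int]]]:
    out: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cid, s, e = line.split()[:3]
            out.setdefault(cid, []).append((int(s), int(e)))
    for cid in out:
        out[cid].sort()
    return out


# ---------------------------------------------------------------------------
# FASTQ + truth SAM
# ---------------------------------------------------------------------------


def write_fastq_pair(sim: ReadSimulation, path1: str, path2: str, qual_char: str = "I") -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r1, r2 in sim.pairs:
            f1.write(f"@{r1.name}/1\n{r1.seq_sequenced}\n+\n{qual_char * len(r1.seq_sequenced)}\n")
            f2.write(f"@{r2.name}/2\n{r2.seq_sequenced}\n+\n{qual_char * len(r2.seq_sequenced)}\n")


def write_truth_sam(sim: ReadSimulation, path: str) -> None:
    """Coordinate-sorted SAM of the truth alignments against the combined
    reference, with mate fields and template length set."""
    names = [cid for cid, _ in sim.reference]
    lengths = {cid: len(s) for cid, s in sim.reference}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": cid, "LN": lengths[cid]} for cid in names],
    }
    tid = {cid: i for i, cid in enumerate(names)}
    records = []
    for r1, r2 in sim.pairs:
        for me, other in ((r1, r2), (r2, r1)):
            a = pysam.AlignedSegment()
            a.query_name = me.name
            a.query_sequence = me.seq_forward
            a.query_qualities = pysam.qualitystring_to_array("I" * len(me.seq_forward))
            flag = 0x1 | (0x40 if me.mate == 1 else 0x80)
            if me.reverse:
                flag |= 0x10
            if other.reverse:
                flag |= 0x20
            same = me.ref_name == other.ref_name
            fully = all(op == 0 for op, _ in me.cigar) and all(
                op == 0 for op, _ in other.cigar
            )
            if same and fully:
                flag |= 0x2
            a.flag = flag
            a.reference_id = tid[me.ref_name]
            a.reference_start = me.ref_pos0
            a.mapping_quality = 60
            a.cigar = me.cigar
            a.next_reference_id = tid[other.ref_name]
            a.next_reference_start = other.ref_pos0
            if same and fully:
                left = min(me.ref_pos0, other.ref_pos0)
                right = max(
                    me.ref_pos0 + len(me.seq_forward),
                    other.ref_pos0 + len(other.seq_forward),
                )
                a.template_length = (right - left) if me.ref_pos0 == left else -(right - left)
            else:
                a.template_length = 0
            records.append(a)
    records.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name, a.flag))
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for a in records:
            out.write(a)
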