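"""Seeded generator of annotated toy genomes, transgenic derivatives,
planted small variants, paired-end reads with truth alignments, and two
emulated caller outputs.

The generator emulates the study design of a transgenic-line resequencing
experiment: a multi-contig annotated reference, a binary-vector construct
whose T-DNA integrates at a chosen site (with a junction deletion, one or
two copies, optionally with the vector backbone), a spectrum of planted
small variants, 100-bp paired-end reads at ~35x coverage, and two imperfect
caller outputs that differ in variant representation (MNP-joining vs
primitive-decomposed).

Everything is deterministic for a fixed (config, seed).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .variant_consensus import SmallVariant

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "Transcript",
    "GeneModel",
    "ToyGenome",
    "TDNAConstruct",
    "InsertionSpec",
    "TruthSet",
    "TransgenicGenome",
    "VariantSpectrum",
    "CallerLaws",
    "build_reference",
    "default_construct",
    "build_transgenic_genome",
    "table_line_specs",
    "plant_variants",
    "simulate_reads",
    "emulate_callers",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    """Intervals are genomic, 0-based half-open, sorted."""

    transcript_id: str
    exons: List[Tuple[int, int]]
    cds: List[Tuple[int, int]] = field(default_factory=list)
    utr5: List[Tuple[int, int]] = field(default_factory=list)
    utr3: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span(self) -> Tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class GeneModel:
    gene_id: str
    contig_id: str
    strand: str  # '+' or '-'
    biotype: str  # protein_coding | lincRNA | other
    transcripts: List[Transcript]
    canonical_id: str

    @property
    def canonical(self) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == self.canonical_id:
                return t
        raise ValueError(f"canonical transcript {self.canonical_id} not found")

    @property
    def span(self) -> Tuple[int, int]:
        s = min(t.span[0] for t in self.transcripts)
        e = max(t.span[1] for t in self.transcripts)
        return (s, e)

    @property
    def tss(self) -> int:
        """0-based position of the transcription start (strand-aware)."""
        s, e = self.span
        return s if self.strand == "+" else e - 1


@dataclass
class ToyGenome:
    contigs: List[Tuple[str, str]]
    genes: List[GeneModel]
    chrom_map: Optional[Dict[str, Tuple[str, int]]] = None
    antisense_pair: Optional[Tuple[str, str]] = None

    def seq(self, contig_id: str) -> str:
        for cid, s in self.contigs:
            if cid == contig_id:
                return s
        raise KeyError(contig_id)

    @property
    def seqs(self) -> Dict[str, str]:
        return dict(self.contigs)

    @property
    def lengths(self) -> Dict[str, int]:
        return {cid: len(s) for cid, s in self.contigs}

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def genes_on(self, contig_id: str) -> List[GeneModel]:
        return [g for g in self.genes if g.contig_id == contig_id]


@dataclass
class TDNAConstruct:
    """Binary vector with a T-DNA interval (0-based half-open on the vector).

    The vector is circular; it is linearized so that the T-DNA starts at the
    origin, which means a T-DNA/backbone/T-DNA integration carries the
    complete vector sequence as a contiguous substring.
    """

    vector_seq: str
    tdna_interval: Tuple[int, int]
    payload: Tuple[str, ...] = ("35S-thaumatin-II", "nos-nptII")
    vector_id: str = "vector"

    def __post_init__(self) -> None:
        t0, t1 = self.tdna_interval
        if not (0 <= t0 < t1 <= len(self.vector_seq)):
            raise ConfigError("tdna_interval outside vector sequence")
        if t1 - t0 < 1000:
            raise ConfigError("T-DNA must be at least 1 kb")

    @property
    def tdna_seq(self) -> str:
        t0, t1 = self.tdna_interval
        return self.vector_seq[t0:t1]

    @property
    def backbone_seq(self) -> str:
        """Backbone in circular order following the T-DNA right border."""
        t0, t1 = self.tdna_interval
        return self.vector_seq[t1:] + self.vector_seq[:t0]


@dataclass
class InsertionSpec:
    """Planted integration site.

    ``left_junction`` is the 1-based last retained reference base before the
    insert; the right junction (first retained base) is
    left_junction + deletion_len + 1.
    """

    contig_id: str
    left_junction: int
    deletion_len: int = 0
    copies: int = 1
    structure: str = "TDNA_ONLY"  # TDNA_ONLY | TDNA_BACKBONE_TDNA

    def __post_init__(self) -> None:
        if self.deletion_len < 0:
            raise ConfigError("deletion_len must be >= 0")
        if self.copies not in (1, 2):
            raise ConfigError("copies must be 1 or 2")
        if self.structure == "TDNA_BACKBONE_TDNA" and self.copies != 2:
            raise ConfigError("TDNA_BACKBONE_TDNA requires copies = 2")
        if self.structure not in ("TDNA_ONLY", "TDNA_BACKBONE_TDNA"):
            raise ConfigError(f"unknown structure {self.structure!r}")

    @property
    def right_junction(self) -> int:
        return self.left_junction + self.deletion_len + 1


@dataclass
class TruthSet:
    insertions: List[InsertionSpec] = field(default_factory=list)
    variants: List[SmallVariant] = field(default_factory=list)
    read_origins: Dict[str, Tuple[str, int, int, str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "insertions": [
                    {
                        "contig_id": i.contig_id,
                        "left_junction": i.left_junction,
                        "deletion_len": i.deletion_len,
                        "copies": i.copies,
                        "structure": i.structure,
                    }
                    for i in self.insertions
                ],
                "variants": [
                    {"contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt}
                    for v in self.variants
                ],
                "n_reads": len(self.read_origins),
            },
            indent=1,
        )


# segment: (mut_start, mut_end, target_contig, target_start), colinear forward
Segment = Tuple[int, int, str, int]


@dataclass
class TransgenicGenome:
    """A mutated genome plus the coordinate map onto the combined reference
    (original contigs + vector contig)."""

    contigs: List[Tuple[str, str]]
    segments: Dict[str, List[Segment]]
    base: ToyGenome
    construct: TDNAConstruct
    truth: TruthSet

    @property
    def combined_reference(self) -> List[Tuple[str, str]]:
        return list(self.base.contigs) + [
            (self.construct.vector_id, self.construct.vector_seq)
        ]

    def seq(self, contig_id: str) -> str:
        for cid, s in self.contigs:
            if cid == contig_id:
                return s
        raise KeyError(contig_id)

    def project(self, contig: str, s: int, e: int) -> List[Tuple[str, int, int]]:
        """Project a mutated-genome interval onto reference pieces
        (ref_contig, ref_start, length)."""
        out = []
        for ms, me, tc, ts in self.segments[contig]:
            os_, oe = max(s, ms), min(e, me)
            if oe > os_:
                out.append((tc, ts + (os_ - ms), oe - os_))
        return out


# ---------------------------------------------------------------------------
# Reference genome generation
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Toy-reference settings.

    ``gene_density`` is the approximate number of genes per 10 kb;
    ``gc`` the genome-wide GC fraction (cucumber-like default).
    """

    n_contigs: int = 2
    contig_len: Union[int, Sequence[int]] = 80_000
    gene_density: float = 0.8
    gc: float = 0.35
    lincrna_frac: float = 0.2
    alt_transcript_frac: float = 0.3
    antisense_pair: bool = True
    make_chrom_map: bool = True

    def contig_lengths(self) -> List[int]:
        if isinstance(self.contig_len, int):
            return [self.contig_len] * self.n_contigs
        lens = list(self.contig_len)
        if len(lens) != self.n_contigs:
            raise ConfigError("contig_len list does not match n_contigs")
        return lens


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _exonic_to_genomic(
    exons: List[Tuple[int, int]], a: int, b: int
) -> List[Tuple[int, int]]:
    """Map the exonic-coordinate interval [a, b) onto genomic sub-intervals."""
    out = []
    off = 0
    for s, e in exons:
        ln = e - s
        lo, hi = max(a, off), min(b, off + ln)
        if hi > lo:
            out.append((s + (lo - off), s + (hi - off)))
        off += ln
    return out


def _mirror(ivs: List[Tuple[int, int]], start: int, span: int) -> List[Tuple[int, int]]:
    return sorted((start + span - e, start + span - s) for s, e in ivs)


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    contig_id: str,
    start: int,
    strand: str,
    biotype: str,
    alt_transcript_frac: float,
) -> GeneModel:
    """Build one gene; intervals are first laid out in transcript-local
    forward coordinates, then mirrored for minus-strand genes."""
    n_exons = int(rng.integers(1, 4))
    exon_lens = rng.integers(350, 701, n_exons)
    intron_lens = rng.integers(150, 501, max(0, n_exons - 1))
    local_exons: List[Tuple[int, int]] = []
    cur = 0
    for i, ln in enumerate(exon_lens):
        local_exons.append((cur, cur + int(ln)))
        cur += int(ln)
        if i < len(intron_lens):
            cur += int(intron_lens[i])
    span = local_exons[-1][1]
    exonic = int(exon_lens.sum())

    transcripts: List[Transcript] = []
    if biotype == "protein_coding":
        utr5 = int(rng.integers(30, 121))
        utr3 = int(rng.integers(30, 121))
        cds_len = exonic - utr5 - utr3
        if cds_len < 90:
            utr5 = utr3 = 30
            cds_len = exonic - 60
        cds_len -= cds_len % 3
        utr3 = exonic - utr5 - cds_len
        layouts = [(f"{gene_id}.t1", utr5, cds_len)]
        if rng.random() < alt_transcript_frac and cds_len >= 108:
            trunc = 3 * int(rng.integers(5, 16))
            if cds_len - trunc >= 60:
                layouts.append((f"{gene_id}.t2", utr5, cds_len - trunc))
        for tid, u5, cl in layouts:
            cds_ivs = _exonic_to_genomic(local_exons, u5, u5 + cl)
            u5_ivs = _exonic_to_genomic(local_exons, 0, u5)
            u3_ivs = _exonic_to_genomic(local_exons, u5 + cl, exonic)
            transcripts.append(
                Transcript(tid, list(local_exons), cds_ivs, u5_ivs, u3_ivs)
            )
    else:
        transcripts.append(Transcript(f"{gene_id}.t1", list(local_exons)))

    if strand == "-":
        for t in transcripts:
            t.exons = _mirror(t.exons, 0, span)
            t.cds = _mirror(t.cds, 0, span)
            t.utr5 = _mirror(t.utr5, 0, span)
            t.utr3 = _mirror(t.utr3, 0, span)
    # shift to genomic position
    for t in transcripts:
        t.exons = [(start + s, start + e) for s, e in t.exons]
        t.cds = [(start + s, start + e) for s, e in t.cds]
        t.utr5 = [(start + s, start + e) for s, e in t.utr5]
        t.utr3 = [(start + s, start + e) for s, e in t.utr3]

    # canonical = longest CDS, ties broken lexicographically by id
    best_len = max(t.cds_len for t in transcripts)
    canonical = sorted(
        [t for t in transcripts if t.cds_len == best_len],
        key=lambda t: t.transcript_id,
    )[0]
    return GeneModel(gene_id, contig_id, strand, biotype, transcripts, canonical.transcript_id)


def _force_cds_sequence(
    rng: np.random.Generator, arr: np.ndarray, gene: GeneModel
) -> None:
    """Overwrite the canonical CDS so it translates cleanly ATG..stop."""
    t = gene.canonical
    if not t.cds:
        return
    cds_len = t.cds_len
    n_mid = cds_len // 3 - 2
    mid = "".join(rng.choice(_NONSTOP_CODONS) for _ in range(n_mid))
    cds_seq = "ATG" + mid + str(rng.choice(list(_STOPS)))
    if gene.strand == "+":
        off = 0
        for s, e in t.cds:
            arr[s:e] = list(cds_seq[off : off + (e - s)])
            off += e - s
    else:
        off = 0
        for s, e in reversed(t.cds):  # transcript order = reversed genomic
            piece = cds_seq[off : off + (e - s)]
            arr[s:e] = list(revcomp(piece))
            off += e - s


def _make_antisense_pair(
    rng: np.random.Generator, contig_id: str, p0: int, next_id: int
) -> Tuple[GeneModel, GeneModel]:
    """An overlapping antisense gene pair: a plus-strand gene with TSS at p0
    and a minus-strand gene whose CDS ends 219 bases upstream of that TSS
    (so a 361-base deletion ending at the TSS removes exactly its first
    142 coding bases)."""
    gp_id, gm_id = f"G{next_id:04d}", f"G{next_id + 1:04d}"
    plus = GeneModel(
        gp_id,
        contig_id,
        "+",
        "protein_coding",
        [
            Transcript(
                f"{gp_id}.t1",
                exons=[(p0, p0 + 1260)],
                cds=[(p0 + 60, p0 + 1059)],
                utr5=[(p0, p0 + 60)],
                utr3=[(p0 + 1059, p0 + 1260)],
            )
        ],
        f"{gp_id}.t1",
    )
    s = p0 - 1500
    minus = GeneModel(
        gm_id,
        contig_id,
        "-",
        "protein_coding",
        [
            Transcript(
                f"{gm_id}.t1",
                exons=[(s, p0 + 120)],
                cds=[(p0 - 1119, p0 - 219)],
                utr5=[(p0 - 219, p0 + 120)],
                utr3=[(s, p0 - 1119)],
            )
        ],
        f"{gm_id}.t1",
    )
    return plus, minus


def build_reference(config: GeneratorConfig, seed: int) -> ToyGenome:
    """Deterministic annotated toy reference for a fixed (config, seed)."""
    rng = np.random.default_rng(seed)
    lengths = config.contig_lengths()
    for ln in lengths:
        if ln < 10_000:
            raise ConfigError("contig lengths must be >= 10 kb")
    contigs: List[Tuple[str, np.ndarray]] = []
    for i, ln in enumerate(lengths):
        contigs.append((f"ctg{i + 1:04d}", _random_seq(rng, ln, config.gc)))

    genes: List[GeneModel] = []
    counter = 1
    pair_ids: Optional[Tuple[str, str]] = None
    reserved: Dict[str, Tuple[int, int]] = {}
    if config.antisense_pair and config.gene_density > 0:
        cid = contigs[0][0]
        p0 = lengths[0] // 2
        reserved[cid] = (p0 - 1700, p0 + 1500)

    if config.gene_density > 0:
        pitch = 10_000 / config.gene_density
        for (cid, arr), ln in zip(contigs, lengths):
            cursor = 1500
            while True:
                start = cursor + int(rng.uniform(0.2, 1.2) * pitch)
                strand = "+" if rng.random() < 0.5 else "-"
                biotype = (
                    "lincRNA" if rng.random() < config.lincrna_frac else "protein_coding"
                )
                gene = _make_gene(
                    rng,
                    f"G{counter:04d}",
                    cid,
                    start,
                    strand,
                    biotype,
                    config.alt_transcript_frac,
                )
                gspan = gene.span
                if gspan[1] + 1000 > ln:
                    break
                if cid in reserved:
                    rs, re_ = reserved[cid]
                    if gspan[0] < re_ and gspan[1] > rs:
                        cursor = re_ + 200
                        continue
                genes.append(gene)
                counter += 1
                cursor = gspan[1] + 200

        if config.antisense_pair:
            cid = contigs[0][0]
            p0 = lengths[0] // 2
            plus, minus = _make_antisense_pair(rng, cid, p0, counter)
            counter += 2
            genes.extend([plus, minus])
            pair_ids = (plus.gene_id, minus.gene_id)

    for gene in genes:
        arr = dict((c, a) for c, a in contigs)[gene.contig_id]
        _force_cds_sequence(rng, arr, gene)

    chrom_map = None
    if config.make_chrom_map:
        chrom_map = {}
        offsets = {"chr1": 0, "chr2": 0}
        for i, (cid, arr) in enumerate(contigs):
            chrom = f"chr{(i % 2) + 1}"
            chrom_map[cid] = (chrom, offsets[chrom])
            offsets[chrom] += len(arr) + 1000
    genes.sort(key=lambda g: (g.contig_id, g.span[0]))
    return ToyGenome(
        contigs=[(cid, "".join(arr)) for cid, arr in contigs],
        genes=genes,
        chrom_map=chrom_map,
        antisense_pair=pair_ids,
    )


def default_construct(seed: int = 528, vector_len: int = 6000, tdna_len: int = 3500) -> TDNAConstruct:
    """Parameterized stand-in for a binary transformation vector; the T-DNA
    occupies the start of the linearized circular sequence."""
    rng = np.random.default_rng(seed)
    vec = "".join(rng.choice(_BASES, size=vector_len))
    return TDNAConstruct(vector_seq=vec, tdna_interval=(0, tdna_len))


# ---------------------------------------------------------------------------
# Transgenic genome construction
# ---------------------------------------------------------------------------


def _insert_pieces(construct: TDNAConstruct, spec: InsertionSpec) -> List[Tuple[int, int]]:
    """Insert composition as (vector_start, vector_end) pieces."""
    t0, t1 = construct.tdna_interval
    L = len(construct.vector_seq)
    if spec.structure == "TDNA_ONLY":
        return [(t0, t1)] * spec.copies
    # T-DNA + backbone (circular order) + T-DNA: two T-DNA copies and one
    # backbone copy; contains the full vector when t0 == 0.
    pieces = [(t0, t1), (t1, L)]
    if t0 > 0:
        pieces.append((0, t0))
    pieces.append((t0, t1))
    return pieces


def _merge_colinear(pieces: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in pieces:
        if out and out[-1][1] == s:
            out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def build_transgenic_genome(
    ref: ToyGenome,
    construct: TDNAConstruct,
    specs: Union[InsertionSpec, Sequence[InsertionSpec]],
    protected: Optional[Mapping[str, Sequence[Tuple[int, int]]]] = None,
) -> Tuple[TransgenicGenome, TruthSet]:
    """Apply one or more T-DNA integrations to the reference.

    Mutated contig = ref[1..left_junction] + insert + ref[right_junction..];
    a coordinate segment map onto the combined reference (genome + vector)
    is kept for read simulation and truth alignments.
    """
    if isinstance(specs, InsertionSpec):
        specs = [specs]
    by_contig: Dict[str, List[InsertionSpec]] = {}
    for sp in specs:
        lens = ref.lengths
        if sp.contig_id not in lens:
            raise ConfigError(f"unknown contig {sp.contig_id}")
        if not (0 < sp.left_junction and sp.right_junction <= lens[sp.contig_id]):
            raise ConfigError(
                f"junctions {sp.left_junction}/{sp.right_junction} outside contig"
            )
        if protected:
            for s, e in protected.get(sp.contig_id, ()):  # 0-based half-open
                if sp.left_junction > s and sp.left_junction - 1 < e:
                    raise ConfigError(
                        f"junction {sp.left_junction} inside protected interval ({s},{e})"
                    )
        by_contig.setdefault(sp.contig_id, []).append(sp)

    contigs: List[Tuple[str, str]] = []
    segments: Dict[str, List[Segment]] = {}
    for cid, seq in ref.contigs:
        csp = sorted(by_contig.get(cid, []), key=lambda s: s.left_junction)
        for a, b in zip(csp, csp[1:]):
            if b.left_junction <= a.right_junction:
                raise ConfigError("overlapping insertion specs on one contig")
        parts: List[str] = []
        segs: List[Segment] = []
        cursor_ref = 0
        cursor_mut = 0
        for sp in csp:
            left0 = sp.left_junction  # 0-based end of retained prefix
            right0 = sp.left_junction + sp.deletion_len
            if left0 > cursor_ref:
                parts.append(seq[cursor_ref:left0])
                segs.append((cursor_mut, cursor_mut + left0 - cursor_ref, cid, cursor_ref))
                cursor_mut += left0 - cursor_ref
            for vs, ve in _merge_colinear(_insert_pieces(construct, sp)):
                parts.append(construct.vector_seq[vs:ve])
                segs.append((cursor_mut, cursor_mut + ve - vs, construct.vector_id, vs))
                cursor_mut += ve - vs
            cursor_ref = right0
        parts.append(seq[cursor_ref:])
        if len(seq) > cursor_ref:
            segs.append((cursor_mut, cursor_mut + len(seq) - cursor_ref, cid, cursor_ref))
            cursor_mut += len(seq) - cursor_ref
        contigs.append((cid, "".join(parts)))
        segments[cid] = segs

    truth = TruthSet(insertions=list(specs))
    tg = TransgenicGenome(
        contigs=contigs, segments=segments, base=ref, construct=construct, truth=truth
    )
    return tg, truth


def _find_intergenic_site(
    genome: ToyGenome, need: int, clearance: int = 1700, skip_contigs: Sequence[str] = ()
) -> Tuple[str, int]:
    """Largest intergenic gap able to host a deletion of ``need`` bases with
    ``clearance`` distance from any gene span; returns (contig, left_junction)."""
    best: Tuple[int, str, int] = (0, "", 0)
    for cid, seq in genome.contigs:
        if cid in skip_contigs:
            continue
        spans = sorted(g.span for g in genome.genes_on(cid))
        prev = 1000
        gaps = []
        for (s, e) in spans:
            gaps.append((prev, s))
            prev = e
        gaps.append((prev, len(seq) - 1000))
        for gs, ge in gaps:
            width = ge - gs - 2 * clearance
            if width > best[0]:
                mid = (gs + ge) // 2
                best = (width, cid, mid)
    width, cid, mid = best
    if width < need + 10:
        raise ConfigError("no intergenic gap large enough for the requested site")
    return cid, mid - need // 2  # left_junction (1-based last retained = mid-ish)


def table_line_specs(
    genome: ToyGenome,
) -> Dict[str, InsertionSpec]:
    """The three study-line-like integration fixtures.

    line212: 1304-nt junction deletion, one T-DNA copy, intergenic site.
    line224: 361-nt deletion ending at the TSS of the antisense pair's
             plus-strand gene (promoter hit + antisense gene disruption).
    line225: 95-nt deletion, two T-DNA copies with vector backbone,
             intergenic site.
    """
    specs: Dict[str, InsertionSpec] = {}
    c212, lj212 = _find_intergenic_site(genome, 1304)
    specs["line212"] = InsertionSpec(c212, lj212, 1304, 1, "TDNA_ONLY")
    if genome.antisense_pair:
        plus = next(g for g in genome.genes if g.gene_id == genome.antisense_pair[0])
        p0 = plus.span[0]  # 0-based TSS of the plus gene
        # right junction (first retained base, 1-based) = TSS base = p0+1
        specs["line224"] = InsertionSpec(plus.contig_id, p0 - 361, 361, 1, "TDNA_ONLY")
    # prefer a different contig for line225 when available
    skip = (c212,) if len(genome.contigs) > 1 else ()
    try:
        c225, lj225 = _find_intergenic_site(genome, 95, skip_contigs=skip)
    except ConfigError:
        c225, lj225 = _find_intergenic_site(genome, 95)
    specs["line225"] = InsertionSpec(c225, lj225, 95, 2, "TDNA_BACKBONE_TDNA")
    return specs


# ---------------------------------------------------------------------------
# Planted small variants
# ---------------------------------------------------------------------------


@dataclass
class VariantSpectrum:
    """Planted variant-type spectrum; defaults reflect the observed type
    proportions in the study's consensus callsets (62% deletions, 27% SNPs,
    7% insertions, 2% MNPs, 2% complex), transition-rich SNPs (Ts/Tv ~ 1.7)
    and 1-bp-dominant indels."""

    fractions: Dict[str, float] = field(
        default_factory=lambda: {
            "DEL": 0.62,
            "SNP": 0.27,
            "INS": 0.07,
            "MNP": 0.02,
            "COMPLEX": 0.02,
        }
    )
    ts_weight: float = 0.63
    del_1bp_frac: float = 0.975
    ins_1bp_frac: float = 0.885
    max_indel_len: int = 6
    hotspot: Optional[Tuple[str, float]] = None

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"type fractions sum to {total}, not 1")


def plant_variants(
    genome: ToyGenome,
    spectrum: VariantSpectrum,
    n: int,
    seed: int,
    exclude: Optional[Mapping[str, Sequence[Tuple[int, int]]]] = None,
) -> List[SmallVariant]:
    """Plant ``n`` non-overlapping truth variants following the spectrum.

    Positions are uniform per contig (length-weighted), except that a
    configured hotspot contig receives its share of all variants.  Raises
    when the variants cannot be placed without overlap.
    """
    if n < 0:
        raise ConfigError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if n == 0:
        return []
    used: Dict[str, np.ndarray] = {}
    for cid, seq in genome.contigs:
        mask = np.zeros(len(seq), dtype=bool)
        mask[:3] = True
        mask[-3:] = True
        for s, e in (exclude or {}).get(cid, ()):  # 0-based half-open
            mask[max(0, s - 2) : min(len(seq), e + 2)] = True
        used[cid] = mask
    types = list(spectrum.fractions)
    probs = np.array([spectrum.fractions[t] for t in types])
    type_draw = rng.choice(types, size=n, p=probs)

    hot_cid, hot_share = spectrum.hotspot or (None, 0.0)
    other = [(cid, len(s)) for cid, s in genome.contigs if cid != hot_cid]
    other_w = np.array([ln for _, ln in other], dtype=float)
    other_w = other_w / other_w.sum() if len(other) else other_w

    out: List[SmallVariant] = []
    seqs = genome.seqs
    for i in range(n):
        vtype = type_draw[i]
        # the contig is decided once per variant so the hotspot share stays
        # binomial even when dense contigs reject more placements
        if hot_cid is not None and rng.random() < hot_share:
            cid = hot_cid
        elif len(other):
            cid = other[int(rng.choice(len(other), p=other_w))][0]
        else:
            cid = hot_cid
        seq = seqs[cid]
        mask = used[cid]
        placed = False
        for _attempt in range(300):
            pos = int(rng.integers(3, len(seq) - 10))  # 1-based anchor
            p0 = pos - 1
            ref, alt = _draw_alleles(rng, seq, p0, vtype, spectrum)
            if ref is None:
                continue
            foot0, foot1 = p0 - 1, p0 + len(ref) + 1
            if mask[foot0:foot1].any():
                continue
            mask[foot0:foot1] = True
            out.append(SmallVariant(cid, pos, ref, alt, id=f"truth{i}"))
            placed = True
            break
        if not placed:
            raise ConfigError(f"could not place variant {i} without overlap")
    out.sort(key=lambda v: v.key)
    return out


def _draw_alleles(
    rng: np.random.Generator,
    seq: str,
    p0: int,
    vtype: str,
    sp: VariantSpectrum,
) -> Tuple[Optional[str], Optional[str]]:
    def snp_alt(base: str) -> str:
        if rng.random() < sp.ts_weight:
            return _TRANSITION[base]
        return _TRANSVERSIONS[base][int(rng.integers(0, 2))]

    anchor = seq[p0]
    if anchor == "N":
        return None, None
    if vtype == "SNP":
        return anchor, snp_alt(anchor)
    if vtype == "MNP":
        ln = 2 if rng.random() < 0.8 else 3
        ref = seq[p0 : p0 + ln]
        alt = "".join(snp_alt(b) for b in ref)
        return ref, alt
    if vtype == "DEL":
        ln = 1 if rng.random() < sp.del_1bp_frac else int(
            rng.integers(2, sp.max_indel_len + 1)
        )
        ref = seq[p0 : p0 + ln + 1]
        return ref, anchor
    if vtype == "INS":
        ln = 1 if rng.random() < sp.ins_1bp_frac else int(
            rng.integers(2, sp.max_indel_len + 1)
        )
        ins = "".join(rng.choice(_BASES, size=ln))
        return anchor, anchor + ins
    if vtype == "COMPLEX":
        rlen = int(rng.integers(2, 4))
        alen = int(rng.choice([l for l in (1, 2, 3, 4) if l != rlen]))
        ref = seq[p0 : p0 + rlen]
        for _ in range(20):
            alt = "".join(rng.choice(_BASES, size=alen))
            if alt[0] != ref[0] and alt[-1] != ref[-1]:
                return ref, alt
        return None, None
    raise ConfigError(f"unknown variant type {vtype}")


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimRead:
    name: str
    mate: int  # 1 or 2
    seq_sequenced: str  # as sequenced (R2 is reverse-complemented)
    ref_name: str
    ref_pos0: int  # leftmost aligned reference position
    cigar: List[Tuple[int, int]]  # pysam op codes (0=M, 4=S)
    reverse: bool
    seq_forward: str  # reference-forward orientation (for SAM)


@dataclass
class ReadSimulation:
    pairs: List[Tuple[SimRead, SimRead]]
    read_origins: Dict[str, Tuple[str, int, int, str]]
    reference: List[Tuple[str, str]]  # combined reference (genome + vector)


def _align_interval(
    segs: List[Segment], s: int, e: int
) -> Tuple[str, int, List[Tuple[int, int]]]:
    """Truth alignment of mutated-coordinate interval [s, e): map to the
    segment with the largest overlap; the remainder is soft-clipped."""
    best = None
    for ms, me, tc, ts in segs:
        ov = min(e, me) - max(s, ms)
        if ov > 0 and (best is None or ov > best[0]):
            best = (ov, ms, me, tc, ts)
    assert best is not None
    ov, ms, me, tc, ts = best
    os_, oe = max(s, ms), min(e, me)
    cigar: List[Tuple[int, int]] = []
    if os_ > s:
        cigar.append((4, os_ - s))
    cigar.append((0, oe - os_))
    if e > oe:
        cigar.append((4, e - oe))
    return tc, ts + (os_ - ms), cigar


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    arr = list(seq)
    for i in rng.choice(len(seq), size=k, replace=False):
        cur = arr[i]
        choices = [b for b in "ACGT" if b != cur]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def simulate_reads(
    tg: TransgenicGenome,
    coverage: float = 35.0,
    read_len: int = 100,
    insert_mean: int = 350,
    insert_sd: int = 35,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSimulation:
    """Paired-end reads from the transgenic genome with truth alignments
    against the combined reference (genome contigs + vector contig).

    Reads fully inside retained genomic sequence align with simple matches;
    reads overlapping an integration junction are soft-clipped at the
    junction; reads fully inside the insert align to the vector contig.
    """
    if coverage <= 0:
        raise ConfigError("coverage must be > 0")
    if read_len > insert_mean:
        raise ConfigError("read_len must be <= insert_mean")
    for cid, seq in tg.contigs:
        if len(seq) < insert_mean + 4 * insert_sd:
            raise ConfigError(f"contig {cid} shorter than insert_mean + 4*sd")
    rng = np.random.default_rng(seed)
    pairs: List[Tuple[SimRead, SimRead]] = []
    origins: Dict[str, Tuple[str, int, int, str]] = {}
    idx = 0
    for cid, seq in tg.contigs:
        segs = tg.segments[cid]
        clen = len(seq)
        n_pairs = int(round(clen * coverage / (2 * read_len)))
        frags = np.clip(
            np.rint(rng.normal(insert_mean, insert_sd, n_pairs)).astype(int),
            read_len,
            clen,
        )
        starts = rng.integers(0, clen - frags + 1)
        for frag, start in zip(frags, starts):
            name = f"sim{idx:07d}"
            idx += 1
            s1, e1 = int(start), int(start) + read_len
            s2, e2 = int(start) + int(frag) - read_len, int(start) + int(frag)
            fwd1 = _apply_errors(rng, seq[s1:e1], error_rate)
            fwd2 = _apply_errors(rng, seq[s2:e2], error_rate)
            rn1, rp1, cg1 = _align_interval(segs, s1, e1)
            rn2, rp2, cg2 = _align_interval(segs, s2, e2)
            r1 = SimRead(name, 1, fwd1, rn1, rp1, cg1, False, fwd1)
            r2 = SimRead(name, 2, revcomp(fwd2), rn2, rp2, cg2, True, fwd2)
            pairs.append((r1, r2))
            origins[f"{name}/1"] = (cid, s1, e1, "+")
            origins[f"{name}/2"] = (cid, s2, e2, "-")
    return ReadSimulation(
        pairs=pairs, read_origins=origins, reference=tg.combined_reference
    )


# ---------------------------------------------------------------------------
# Emulated callers
# ---------------------------------------------------------------------------


@dataclass
class CallerLaws:
    """Quality/depth/strand annotation laws for the emulated callers.

    Depth is Poisson around ``depth_mean``; alt support equals depth
    (homozygous line) split binomially between strands; quality is a clipped
    normal Phred score."""

    qual_mean: float = 60.0
    qual_sd: float = 12.0
    qual_min: float = 1.0
    depth_mean: float = 20.0


def _join_adjacent_snps(variants: List[SmallVariant]) -> List[SmallVariant]:
    out: List[SmallVariant] = []
    run: List[SmallVariant] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1:
            out.append(run[0])
        else:
            first = run[0]
            out.append(
                replace(
                    first,
                    ref="".join(v.ref for v in run),
                    alt="".join(v.alt for v in run),
                )
            )
        run.clear()

    for v in sorted(variants, key=lambda x: x.key):
        if (
            run
            and v.vtype == "SNP"
            and run[-1].vtype == "SNP"
            and v.contig == run[-1].contig
            and v.pos == run[-1].pos + 1
        ):
            run.append(v)
        elif v.vtype == "SNP":
            flush()
            run.append(v)
        else:
            flush()
            out.append(v)
    flush()
    return out


def _decompose_mnps(variants: List[SmallVariant]) -> List[SmallVariant]:
    out: List[SmallVariant] = []
    for v in variants:
        if v.vtype == "MNP":
            for k, (rb, ab) in enumerate(zip(v.ref, v.alt)):
                if rb != ab:
                    out.append(replace(v, pos=v.pos + k, ref=rb, alt=ab))
        else:
            out.append(v)
    return out


def emulate_callers(
    truth_variants: Sequence[SmallVariant],
    genome: ToyGenome,
    style: str,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    laws: Optional[CallerLaws] = None,
    seed: int = 0,
) -> List[SmallVariant]:
    """Emulate one caller's output from the truth set.

    ``style='JOINED'`` merges adjacent truth SNPs into MNP records (a
    haplotype-based caller's representation); ``style='PRIMITIVE'`` emits
    per-base records.  False positives are uniform SNPs outside truth loci;
    false negatives drop truth records independently.
    """
    if style not in ("JOINED", "PRIMITIVE"):
        raise ValueError(f"unknown caller style {style!r}")
    if not (0 <= fp_rate <= 1 and 0 <= fn_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    laws = laws or CallerLaws()
    rng = np.random.default_rng(seed)
    keep = [v for v in truth_variants if rng.random() >= fn_rate]
    if style == "JOINED":
        calls = _join_adjacent_snps(keep)
    else:
        calls = _decompose_mnps(keep)

    # false positives, uniform outside truth footprints
    n_truth = len(truth_variants)
    n_fp = int(rng.binomial(n_truth, fp_rate)) if n_truth else 0
    if n_fp:
        forbidden: Dict[str, set] = {}
        for v in truth_variants:
            forbidden.setdefault(v.contig, set()).update(
                range(v.pos - 2, v.end + 3)
            )
        cl = [(cid, len(s)) for cid, s in genome.contigs]
        w = np.array([ln for _, ln in cl], dtype=float)
        w /= w.sum()
        seqs = genome.seqs
        made = 0
        while made < n_fp:
            cid = cl[int(rng.choice(len(cl), p=w))][0]
            pos = int(rng.integers(3, len(seqs[cid]) - 3))
            if pos in forbidden.get(cid, ()):  # avoid truth loci
                continue
            base = seqs[cid][pos - 1]
            if base == "N":
                continue
            alts = [b for b in "ACGT" if b != base]
            calls.append(
                SmallVariant(cid, pos, base, alts[int(rng.integers(0, 3))], id=f"fp{made}")
            )
            forbidden.setdefault(cid, set()).add(pos)
            made += 1

    out: List[SmallVariant] = []
    for i, v in enumerate(sorted(calls, key=lambda x: x.key)):
        depth = int(rng.poisson(laws.depth_mean))
        alt_fwd = int(rng.binomial(depth, 0.5))
        qual = float(max(laws.qual_min, rng.normal(laws.qual_mean, laws.qual_sd)))
        out.append(
            replace(
                v,
                qual=round(qual, 2),
                depth=depth,
                alt_fwd=alt_fwd,
                alt_rev=depth - alt_fwd,
                id=f"em{i}",
            )
        )
    return out
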