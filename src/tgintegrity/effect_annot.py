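"""Region assignment and coding-effect prediction on canonical transcripts.

Each consensus variant is assigned to a genomic region class (CDS exon,
UTRs, non-coding exon, intron, 1500-bp upstream/downstream flanks,
intergenic) and, when coding, to an effect term by codon-level translation
of the canonical transcript; effect terms map to fixed impact tiers
(HIGH / MODERATE / LOW / MODIFIER).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq

from .synthgenome import GeneModel, Transcript, revcomp
from .variant_consensus import SmallVariant

__all__ = [
    "AnnotatedVariant",
    "REGION_PRECEDENCE",
    "EFFECT_IMPACT",
    "assign_region",
    "select_canonical",
    "predict_effect",
    "annotate",
    "ns_s_tally",
]

REGION_PRECEDENCE = (
    "EXON_CDS",
    "UTR5",
    "UTR3",
    "NC_EXON",
    "INTRON",
    "UPSTREAM",
    "DOWNSTREAM",
    "INTERGENIC",
)

_REGION_RANK = {r: i for i, r in enumerate(REGION_PRECEDENCE)}

EFFECT_IMPACT: Dict[str, str] = {
    "frameshift_variant": "HIGH",
    "start_lost": "HIGH",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "missense_variant": "MODERATE",
    "inframe_indel": "MODERATE",
    "synonymous_variant": "LOW",
    "utr_variant": "MODIFIER",
    "intron_variant": "MODIFIER",
    "upstream_variant": "MODIFIER",
    "downstream_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
}

_NONCODING_EFFECT = {
    "UTR5": "utr_variant",
    "UTR3": "utr_variant",
    "NC_EXON": "utr_variant",
    "INTRON": "intron_variant",
    "UPSTREAM": "upstream_variant",
    "DOWNSTREAM": "downstream_variant",
    "INTERGENIC": "intergenic_variant",
}

NS_EFFECTS = ("missense_variant", "stop_gained", "stop_lost", "start_lost")


@dataclass
class AnnotatedVariant:
    variant: SmallVariant
    region: str
    gene_id: Optional[str]
    effect: str
    impact: str
    contexts: List[Tuple[str, str]] = field(default_factory=list)  # (gene_id, region)
    warning: Optional[str] = None


def select_canonical(gene: GeneModel) -> str:
    """Canonical transcript = longest CDS, ties broken lexicographically."""
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    best = max(t.cds_len for t in gene.transcripts)
    return sorted(
        t.transcript_id for t in gene.transcripts if t.cds_len == best
    )[0]


def _position_region(p0: int, gene: GeneModel, flank: int) -> Optional[str]:
    """Region of a 0-based position relative to one gene, or None."""
    t = gene.canonical
    gs, ge = t.span
    if gs <= p0 < ge:
        in_exon = any(s <= p0 < e for s, e in t.exons)
        if not in_exon:
            return "INTRON"
        if any(s <= p0 < e for s, e in t.cds):
            return "EXON_CDS"
        if any(s <= p0 < e for s, e in t.utr5):
            return "UTR5"
        if any(s <= p0 < e for s, e in t.utr3):
            return "UTR3"
        return "NC_EXON"
    if gene.strand == "+":
        if gs - flank <= p0 < gs:
            return "UPSTREAM"
        if ge <= p0 < ge + flank:
            return "DOWNSTREAM"
    else:
        if ge <= p0 < ge + flank:
            return "UPSTREAM"
        if gs - flank <= p0 < gs:
            return "DOWNSTREAM"
    return None


def variant_anchor_pos0(v: SmallVariant) -> int:
    """0-based representative position: first changed base (indels skip the
    anchor base)."""
    if v.vtype in ("INS", "DEL"):
        return v.pos  # base after the anchor
    return v.pos - 1


def assign_region(
    variant: SmallVariant,
    genes: Sequence[GeneModel],
    flank: int = 1500,
) -> Tuple[str, List[Tuple[str, str]]]:
    """(summary region, all (gene_id, region) contexts).

    The summary class is chosen by the fixed precedence over all genes a
    position qualifies for; a variant outside every gene and flank is
    INTERGENIC with no gene context.
    """
    p0 = variant_anchor_pos0(variant)
    contexts: List[Tuple[str, str]] = []
    for g in genes:
        if g.contig_id != variant.contig:
            continue
        r = _position_region(p0, g, flank)
        if r is not None:
            contexts.append((g.gene_id, r))
    if not contexts:
        return "INTERGENIC", []
    contexts.sort(key=lambda c: (_REGION_RANK[c[1]], c[0]))
    return contexts[0][1], contexts


def _cds_map(t: Transcript, strand: str) -> List[int]:
    """Genomic 0-based positions of CDS bases, in transcript order."""
    pos: List[int] = []
    for s, e in t.cds:
        pos.extend(range(s, e))
    if strand == "-":
        pos.reverse()
    return pos


def predict_effect(
    variant: SmallVariant,
    gene: GeneModel,
    refs: Mapping[str, str],
    region: Optional[str] = None,
    flank: int = 1500,
) -> Tuple[str, str, Optional[str]]:
    """(effect, impact, warning) of a variant on the canonical transcript.

    CDS indels: frameshift when the net length change is not divisible by 3,
    otherwise inframe.  CDS substitutions are translated codon-wise: a
    destroyed start codon -> start_lost; a new internal stop -> stop_gained;
    a destroyed terminal stop -> stop_lost; an amino-acid change ->
    missense; otherwise synonymous.  Non-coding regions map to their
    region's term.  A canonical CDS that does not translate cleanly flags a
    warning and the effect is computed on the raw frame.
    """
    if region is None:
        region, _ = assign_region(variant, [gene], flank)
    if region != "EXON_CDS":
        eff = _NONCODING_EFFECT[region]
        return eff, EFFECT_IMPACT[eff], None

    t = gene.canonical
    seq = refs[gene.contig_id]
    cds_pos = _cds_map(t, gene.strand)
    cds_index = {p: i for i, p in enumerate(cds_pos)}
    cds_seq = "".join(seq[p] for p in cds_pos)
    if gene.strand == "-":
        cds_seq = "".join(
            revcomp(seq[p]) for p in cds_pos
        )
    warning = None
    prot = str(Seq(cds_seq[: 3 * (len(cds_seq) // 3)]).translate())
    if not (
        len(cds_seq) % 3 == 0
        and prot.startswith("M")
        and prot.endswith("*")
        and "*" not in prot[:-1]
    ):
        warning = "reference CDS does not translate cleanly"

    if variant.vtype in ("INS", "DEL", "COMPLEX"):
        net = len(variant.alt) - len(variant.ref)
        if net % 3 != 0:
            return "frameshift_variant", "HIGH", warning
        return "inframe_indel", "MODERATE", warning

    # substitution: collect in-CDS changed bases (MNPs may leak outside)
    changed: List[Tuple[int, str]] = []  # (cds index, alt base, genome strand)
    spill = False
    for k, (rb, ab) in enumerate(zip(variant.ref, variant.alt)):
        if rb == ab:
            continue
        p0 = variant.pos - 1 + k
        if p0 in cds_index:
            changed.append((cds_index[p0], ab))
        else:
            spill = True
    if not changed:
        eff = "synonymous_variant"  # degenerate: no CDS base actually changes
        return eff, EFFECT_IMPACT[eff], warning

    n_codons = len(cds_seq) // 3
    codons = {}
    for ci, ab in changed:
        base = ab if gene.strand == "+" else revcomp(ab)
        idx = ci // 3
        if idx >= n_codons:
            continue
        codon = codons.get(idx, cds_seq[3 * idx : 3 * idx + 3])
        off = ci % 3
        codons[idx] = codon[:off] + base + codon[off + 1 :]

    effect = None
    if 0 in codons and codons[0] != "ATG":
        effect = "start_lost"
    if effect is None:
        for idx in sorted(codons):
            mutated = codons[idx]
            original = cds_seq[3 * idx : 3 * idx + 3]
            mut_aa = str(Seq(mutated).translate())
            orig_aa = str(Seq(original).translate())
            terminal = idx == n_codons - 1 and orig_aa == "*"
            if mut_aa == "*" and orig_aa != "*":
                effect = "stop_gained"
                break
            if terminal and mut_aa != "*":
                effect = "stop_lost"
                break
            if mut_aa != orig_aa and effect is None:
                effect = "missense_variant"
        if effect is None:
            effect = "synonymous_variant"

    # an MNP spilling over the CDS boundary would add only MODIFIER-tier
    # terms for its non-CDS bases, so the coding call is already the most
    # severe of the split parts
    return effect, EFFECT_IMPACT[effect], warning


def annotate(
    variants: Sequence[SmallVariant],
    genes: Sequence[GeneModel],
    refs: Mapping[str, str],
    flank: int = 1500,
) -> List[AnnotatedVariant]:
    """Annotate a callset: one summary region + effect + impact per variant."""
    by_contig: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    out: List[AnnotatedVariant] = []
    for v in variants:
        region, contexts = assign_region(v, by_contig.get(v.contig, ()), flank)
        gene_id = contexts[0][0] if contexts else None
        if region == "EXON_CDS":
            gene = next(g for g in by_contig[v.contig] if g.gene_id == gene_id)
            effect, impact, warning = predict_effect(v, gene, refs, region=region)
        else:
            effect = _NONCODING_EFFECT[region]
            impact = EFFECT_IMPACT[effect]
            warning = None
        out.append(
            AnnotatedVariant(
                variant=v,
                region=region,
                gene_id=gene_id,
                effect=effect,
                impact=impact,
                contexts=contexts,
                warning=warning,
            )
        )
    return out


def ns_s_tally(annotated: Sequence[AnnotatedVariant]) -> Tuple[int, int, Optional[float]]:
    """(non-synonymous count, synonymous count, NS/S ratio or None).

    Only coding substitutions (SNP/MNP) are counted; NS = missense +
    stop_gained + stop_lost + start_lost, S = synonymous.
    """
    ns = s = 0
    for a in annotated:
        if a.variant.vtype not in ("SNP", "MNP"):
            continue
        if a.effect in NS_EFFECTS:
            ns += 1
        elif a.effect == "synonymous_variant":
            s += 1
    ratio = (ns / s) if s else None
    return ns, s, ratio
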