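"""Per-line summary statistics of consensus callsets and annotations:
variation rate, type spectrum, Ts/Tv and substitution spectrum, indel
length laws, region densities, impact tiers, the high-impact effect table,
10-kb binned densities, hotspot contigs, and verification precision.

Rounding conventions are fixed per statistic so printed numbers are
reproducible: rates to 3 significant figures, table-style percentages to
2 decimals, prose-style percentages to the nearest integer.
"""
from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .effect_annot import NS_EFFECTS, REGION_PRECEDENCE, AnnotatedVariant
from .synthgenome import GeneModel, ToyGenome
from .variant_consensus import SmallVariant, VTYPES

__all__ = [
    "SummaryReport",
    "round_sig",
    "variation_rate",
    "ts_tv",
    "substitution_spectrum",
    "indel_spectrum",
    "compute_region_lengths",
    "region_density",
    "binned_distribution",
    "hotspot_contigs",
    "hi_effect_table",
    "verification_precision",
    "summarize_line",
]

_PURINES = {"A", "G"}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

HI_EFFECT_ORDER = ("frameshift_variant", "start_lost", "stop_gained", "stop_lost")


def round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def variation_rate(n_variants: int, genome_len: int) -> Tuple[float, float]:
    """(raw rate, rate rounded to 3 significant figures), variants per base."""
    if genome_len <= 0:
        raise ValueError("genome_len must be > 0")
    raw = n_variants / genome_len
    return raw, round_sig(raw, 3)


def _snp_changes(callset: Sequence[SmallVariant]) -> List[Tuple[str, str]]:
    """Per-base substitutions; MNPs contribute their decomposed SNPs."""
    out = []
    for v in callset:
        if v.vtype == "SNP":
            out.append((v.ref, v.alt))
        elif v.vtype == "MNP":
            for rb, ab in zip(v.ref, v.alt):
                if rb != ab:
                    out.append((rb, ab))
    return out


def ts_tv(callset: Sequence[SmallVariant]) -> Tuple[int, int, Optional[float]]:
    """(transitions, transversions, Ts/Tv ratio or None when Tv = 0)."""
    ts = tv = 0
    for rb, ab in _snp_changes(callset):
        if (rb, ab) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    return ts, tv, (ts / tv if tv else None)


def substitution_spectrum(
    callset: Sequence[SmallVariant],
) -> Tuple[Dict[str, int], Dict[str, int]]:
    """(12-class ordered spectrum, 6-class strand-collapsed spectrum).

    Collapsed classes are unordered base pairs, as in prose summaries
    (transitions C/T and G/A; transversions C/G, A/T, C/A, G/T).
    """
    full: Dict[str, int] = Counter()
    collapsed: Dict[str, int] = Counter()
    for rb, ab in _snp_changes(callset):
        full[f"{rb}>{ab}"] += 1
        collapsed["/".join(sorted((rb, ab)))] += 1
    return dict(sorted(full.items())), dict(sorted(collapsed.items()))


def indel_spectrum(
    callset: Sequence[SmallVariant],
) -> Tuple[Dict[int, int], Dict[int, int], Optional[float]]:
    """(deletion length histogram, insertion length histogram, del/ins
    ratio or None when there are no insertions)."""
    dels: Dict[int, int] = Counter()
    ins: Dict[int, int] = Counter()
    for v in callset:
        ln = abs(len(v.ref) - len(v.alt))
        if v.vtype == "DEL":
            dels[ln] += 1
        elif v.vtype == "INS":
            ins[ln] += 1
    n_del, n_ins = sum(dels.values()), sum(ins.values())
    return (
        dict(sorted(dels.items())),
        dict(sorted(ins.items())),
        (n_del / n_ins if n_ins else None),
    )


def compute_region_lengths(
    genome: ToyGenome, genes: Sequence[GeneModel], flank: int = 1500
) -> Dict[str, int]:
    """Bases of each region class, assigning every genome position to
    exactly one class under the region precedence (overlaps collapsed)."""
    import numpy as np

    lengths = {r: 0 for r in REGION_PRECEDENCE}
    rank = {r: i for i, r in enumerate(REGION_PRECEDENCE)}
    for cid, seq in genome.contigs:
        n = len(seq)
        best = np.full(n, len(REGION_PRECEDENCE) - 1, dtype=np.int8)  # INTERGENIC

        def paint(ivs, region):
            r = rank[region]
            for s, e in ivs:
                s, e = max(0, s), min(n, e)
                if e > s:
                    np.minimum(best[s:e], r, out=best[s:e])

        for g in genes:
            if g.contig_id != cid:
                continue
            t = g.canonical
            gs, ge = t.span
            paint([(gs, ge)], "INTRON")
            if t.cds:
                paint(t.cds, "EXON_CDS")
                paint(t.utr5, "UTR5")
                paint(t.utr3, "UTR3")
            else:
                paint(t.exons, "NC_EXON")
            if g.strand == "+":
                paint([(gs - flank, gs)], "UPSTREAM")
                paint([(ge, ge + flank)], "DOWNSTREAM")
            else:
                paint([(ge, ge + flank)], "UPSTREAM")
                paint([(gs - flank, gs)], "DOWNSTREAM")
        vals, counts = np.unique(best, return_counts=True)
        for r, c in zip(vals, counts):
            lengths[REGION_PRECEDENCE[int(r)]] += int(c)
    return lengths


def region_density(
    annotated: Sequence[AnnotatedVariant], region_lengths: Mapping[str, int]
) -> Dict[str, float]:
    """Variants per Mb of each region class."""
    counts = Counter(a.region for a in annotated)
    out: Dict[str, float] = {}
    for region, ln in region_lengths.items():
        out[region] = (counts.get(region, 0) / (ln / 1e6)) if ln > 0 else 0.0
    return out


def binned_distribution(
    callset: Sequence[SmallVariant],
    chrom_map: Optional[Mapping[str, Tuple[str, int]]] = None,
    bin_size: int = 10_000,
) -> Dict[Tuple[str, int], int]:
    """Variant counts in half-open bins of ``bin_size`` starting at base 1.

    Bin index is 1-based: position ``bin_size`` falls in bin 1, position
    ``bin_size + 1`` in bin 2.  With a chrom_map, contig positions are
    projected onto chromosomes first.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    out: Dict[Tuple[str, int], int] = Counter()
    for v in callset:
        chrom, pos = v.contig, v.pos
        if chrom_map is not None and v.contig in chrom_map:
            chrom, off = chrom_map[v.contig]
            pos = v.pos + off
        out[(chrom, (pos - 1) // bin_size + 1)] += 1
    return dict(out)


def hotspot_contigs(
    callset: Sequence[SmallVariant], threshold: float = 0.2
) -> List[Tuple[str, float]]:
    """Contigs carrying at least ``threshold`` of all variants, sorted by
    share descending."""
    if not callset:
        raise ValueError("hotspot detection needs at least one variant")
    counts = Counter(v.contig for v in callset)
    total = sum(counts.values())
    shares = [(cid, c / total) for cid, c in counts.items()]
    shares.sort(key=lambda x: (-x[1], x[0]))
    return [(cid, share) for cid, share in shares if share >= threshold]


def hi_effect_table(
    annotated: Sequence[AnnotatedVariant],
) -> Dict[str, Dict[str, float]]:
    """Counts and percentages (2 decimals) per HIGH-impact effect term."""
    hi = [a for a in annotated if a.impact == "HIGH"]
    total = len(hi)
    counts = Counter(a.effect for a in hi)
    out: Dict[str, Dict[str, float]] = {}
    for eff in HI_EFFECT_ORDER:
        c = counts.get(eff, 0)
        out[eff] = {
            "count": c,
            "pct": round(100 * c / total, 2) if total else 0.0,
        }
    return out


def verification_precision(n_confirmed: int, n_tested: int) -> int:
    """Wet-lab verification precision as a whole percent."""
    if not (0 <= n_confirmed <= n_tested) or n_tested <= 0:
        raise ValueError("need 0 <= n_confirmed <= n_tested, n_tested > 0")
    return round(100 * n_confirmed / n_tested)


# ---------------------------------------------------------------------------
# Full per-line report
# ---------------------------------------------------------------------------


@dataclass
class SummaryReport:
    line: str
    n_variants: int
    genome_len: int
    variation_rate: float
    variation_rate_3sf: float
    type_counts: Dict[str, int]
    type_fractions: Dict[str, float]
    ts_count: int
    tv_count: int
    ts_tv_ratio: Optional[float]
    substitution_full: Dict[str, int]
    substitution_collapsed: Dict[str, int]
    del_lengths: Dict[int, int]
    ins_lengths: Dict[int, int]
    del_ins_ratio: Optional[float]
    region_counts: Dict[str, int]
    region_densities: Dict[str, float]
    impact_counts: Dict[str, int]
    impact_fractions: Dict[str, float]
    hi_table: Dict[str, Dict[str, float]]
    ns: int
    s: int
    ns_s_ratio: Optional[float]
    binned: Dict[str, int]  # "chrom:bin" -> count
    hotspots: List[Tuple[str, float]]

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["del_lengths"] = {str(k): v for k, v in self.del_lengths.items()}
        d["ins_lengths"] = {str(k): v for k, v in self.ins_lengths.items()}
        return json.dumps(d, indent=1)


def summarize_line(
    line: str,
    callset: Sequence[SmallVariant],
    annotated: Sequence[AnnotatedVariant],
    genome: ToyGenome,
    flank: int = 1500,
    bin_size: int = 10_000,
    hotspot_threshold: float = 0.2,
    region_lengths: Optional[Mapping[str, int]] = None,
) -> SummaryReport:
    n = len(callset)
    raw, r3 = variation_rate(n, genome.total_length)
    type_counts = Counter(v.vtype for v in callset)
    ts, tv, ratio = ts_tv(callset)
    full, collapsed = substitution_spectrum(callset)
    dels, ins, di = indel_spectrum(callset)
    if region_lengths is None:
        region_lengths = compute_region_lengths(genome, genome.genes, flank)
    densities = region_density(annotated, region_lengths)
    region_counts = Counter(a.region for a in annotated)
    impact_counts = Counter(a.impact for a in annotated)
    n_ann = len(annotated)
    from .effect_annot import ns_s_tally

    ns, s, nsr = ns_s_tally(annotated)
    binned = binned_distribution(callset, genome.chrom_map, bin_size)
    return SummaryReport(
        line=line,
        n_variants=n,
        genome_len=genome.total_length,
        variation_rate=raw,
        variation_rate_3sf=r3,
        type_counts={t: type_counts.get(t, 0) for t in VTYPES},
        type_fractions={
            t: (type_counts.get(t, 0) / n if n else 0.0) for t in VTYPES
        },
        ts_count=ts,
        tv_count=tv,
        ts_tv_ratio=ratio,
        substitution_full=full,
        substitution_collapsed=collapsed,
        del_lengths=dels,
        ins_lengths=ins,
        del_ins_ratio=di,
        region_counts={r: region_counts.get(r, 0) for r in REGION_PRECEDENCE},
        region_densities=densities,
        impact_counts={
            k: impact_counts.get(k, 0) for k in ("HIGH", "MODERATE", "LOW", "MODIFIER")
        },
        impact_fractions={
            k: (impact_counts.get(k, 0) / n_ann if n_ann else 0.0)
            for k in ("HIGH", "MODERATE", "LOW", "MODIFIER")
        },
        hi_table=hi_effect_table(annotated),
        ns=ns,
        s=s,
        ns_s_ratio=nsr,
        binned={f"{c}:{b}": v for (c, b), v in sorted(binned.items())},
        hotspots=hotspot_contigs(callset, hotspot_threshold) if callset else [],
    )
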