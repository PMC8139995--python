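"""Transgene integration-site detection from paired-end alignments.

Reads mapped to the vector contig whose mates map to a genomic contig
(discordant pairs), plus genomic reads soft-clipped exactly at a junction
whose clipped tail matches a T-DNA border (split reads), are clustered into
left/right junction evidence.  Paired clusters become insertion events with
junction coordinates, junction-deletion length, read-depth-based copy
number, insert structure (with or without vector backbone), and a
gene-model-based site classification.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .synthgenome import GeneModel, TDNAConstruct

logger = logging.getLogger(__name__)

__all__ = [
    "ChimericEvidence",
    "InsertionEvent",
    "harvest_evidence",
    "call_insertions",
    "infer_structure",
    "classify_site",
    "scan",
    "events_to_tsv",
    "events_to_json",
    "events_to_bed",
]


@dataclass
class ChimericEvidence:
    """One read's worth of junction evidence.

    ``side`` is 'L' for anchors upstream of the insert (junction at the
    anchor's right end) and 'R' for anchors downstream (junction at the
    anchor's left end).  ``pos`` is the 1-based candidate junction base;
    split-read evidence is exact.
    """

    read_id: str
    contig: str
    pos: int
    strand: str
    side: str  # 'L' | 'R'
    kind: str  # DISCORDANT_PAIR | SPLIT_READ
    vector_pos: Optional[int] = None


@dataclass
class InsertionEvent:
    contig_id: str
    left_junction: Optional[int]
    right_junction: Optional[int]
    copies: Optional[int] = None
    structure: str = "UNRESOLVED"
    site_class: Optional[str] = None
    affected_genes: List[Dict[str, object]] = field(default_factory=list)
    support: Tuple[int, int] = (0, 0)
    approximate: bool = False
    ci: int = 0

    @property
    def deletion_len(self) -> Optional[int]:
        if self.left_junction is None or self.right_junction is None:
            return None
        return self.right_junction - self.left_junction - 1


# ---------------------------------------------------------------------------
# Evidence harvesting
# ---------------------------------------------------------------------------


def _border_windows(construct: TDNAConstruct, width: int = 40) -> Tuple[str, str]:
    tdna = construct.tdna_seq
    return tdna[:width], tdna[-width:]


def harvest_evidence(
    alignments: Union[str, pysam.AlignmentFile],
    vector_id: str,
    construct: Optional[TDNAConstruct] = None,
    min_clip: int = 12,
) -> List[ChimericEvidence]:
    """Collect discordant-pair and split-read evidence from a SAM/BAM.

    A pair with one mate on the vector and one on a genomic contig yields one
    DISCORDANT_PAIR record anchored on the genomic mate.  A genomic read
    soft-clipped by >= min_clip bases whose clipped tail exactly matches a
    T-DNA border window yields one SPLIT_READ record at the clip boundary
    (requires ``construct``).
    """
    if isinstance(alignments, str):
        af = pysam.AlignmentFile(alignments, "r")
        close = True
    else:
        af, close = alignments, False
    left_w = right_w = None
    if construct is not None:
        left_w, right_w = _border_windows(construct)
    out: List[ChimericEvidence] = []
    skipped = 0
    try:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name == vector_id:
                continue
            if read.is_paired and (
                read.mate_is_unmapped or read.next_reference_id < 0
            ):
                skipped += 1
                continue
            # discordant pair: genomic anchor with mate on the vector
            if read.is_paired and read.next_reference_name == vector_id:
                if read.is_reverse:
                    out.append(
                        ChimericEvidence(
                            read.query_name,
                            read.reference_name,
                            read.reference_start + 1,
                            "-",
                            "R",
                            "DISCORDANT_PAIR",
                            read.next_reference_start + 1,
                        )
                    )
                else:
                    out.append(
                        ChimericEvidence(
                            read.query_name,
                            read.reference_name,
                            read.reference_end,
                            "+",
                            "L",
                            "DISCORDANT_PAIR",
                            read.next_reference_start + 1,
                        )
                    )
            # split read: soft clip matching a T-DNA border
            if left_w is None or read.cigartuples is None:
                continue
            cig = read.cigartuples
            seq = read.query_sequence or ""
            if cig[-1][0] == 4 and cig[-1][1] >= min_clip:
                clip = seq[len(seq) - cig[-1][1] :]
                m = min(len(clip), len(left_w))
                if clip[:m] == left_w[:m]:
                    out.append(
                        ChimericEvidence(
                            read.query_name,
                            read.reference_name,
                            read.reference_end,
                            "-" if read.is_reverse else "+",
                            "L",
                            "SPLIT_READ",
                        )
                    )
            if cig[0][0] == 4 and cig[0][1] >= min_clip:
                clip = seq[: cig[0][1]]
                m = min(len(clip), len(right_w))
                if clip[-m:] == right_w[-m:]:
                    out.append(
                        ChimericEvidence(
                            read.query_name,
                            read.reference_name,
                            read.reference_start + 1,
                            "-" if read.is_reverse else "+",
                            "R",
                            "SPLIT_READ",
                        )
                    )
    finally:
        if close:
            af.close()
    if skipped:
        logger.info("skipped %d records with missing mate information", skipped)
    out.sort(key=lambda ev: (ev.contig, ev.pos))
    return out


# ---------------------------------------------------------------------------
# Junction calling
# ---------------------------------------------------------------------------


@dataclass
class _Cluster:
    contig: str
    side: str
    evidence: List[ChimericEvidence]

    @property
    def support(self) -> int:
        return len(self.evidence)

    @property
    def splits(self) -> List[ChimericEvidence]:
        return [e for e in self.evidence if e.kind == "SPLIT_READ"]

    def junction(self) -> Tuple[int, bool]:
        """(1-based junction estimate, exact?)."""
        sp = self.splits
        if sp:
            vals, counts = np.unique([e.pos for e in sp], return_counts=True)
            return int(vals[np.argmax(counts)]), True
        # innermost anchor end: rightmost for L, leftmost for R
        if self.side == "L":
            return max(e.pos for e in self.evidence), False
        return min(e.pos for e in self.evidence), False


def _cluster(
    evidence: Sequence[ChimericEvidence], side: str, cluster_gap: int
) -> List[_Cluster]:
    out: List[_Cluster] = []
    cur: List[ChimericEvidence] = []
    for ev in evidence:
        if ev.side != side:
            continue
        if cur and (ev.contig != cur[-1].contig or ev.pos - cur[-1].pos > cluster_gap):
            out.append(_Cluster(cur[0].contig, side, cur))
            cur = []
        cur.append(ev)
    if cur:
        out.append(_Cluster(cur[0].contig, side, cur))
    return out


def call_insertions(
    evidence: Sequence[ChimericEvidence],
    cluster_gap: int = 1000,
    min_support: int = 3,
    insert_size: int = 350,
) -> List[InsertionEvent]:
    """Group evidence into junction clusters and pair them into events.

    Evidence must be sorted by genomic position (``harvest_evidence``
    returns it sorted).  Junctions come from split reads when present,
    otherwise from the innermost anchor end, flagged approximate with a
    +/- insert-size confidence interval.
    """
    evidence = sorted(evidence, key=lambda e: (e.contig, e.pos))
    lefts = [c for c in _cluster(evidence, "L", cluster_gap) if c.support >= min_support]
    rights = [c for c in _cluster(evidence, "R", cluster_gap) if c.support >= min_support]
    events: List[InsertionEvent] = []
    used_r: set = set()
    for lc in lefts:
        lj, l_exact = lc.junction()
        best = None
        for ri, rc in enumerate(rights):
            if ri in used_r or rc.contig != lc.contig:
                continue
            rj, _ = rc.junction()
            if rj < lj - insert_size:
                continue
            d = rj - lj
            if best is None or d < best[0]:
                best = (d, ri)
        if best is None:
            events.append(
                InsertionEvent(
                    contig_id=lc.contig,
                    left_junction=lj,
                    right_junction=None,
                    structure="UNRESOLVED",
                    support=(lc.support, 0),
                    approximate=not l_exact,
                    ci=0 if l_exact else insert_size,
                )
            )
            continue
        ri = best[1]
        used_r.add(ri)
        rc = rights[ri]
        rj, r_exact = rc.junction()
        exact = l_exact and r_exact
        lj_adj, rj_adj = lj, rj
        if rj_adj < lj_adj + 1:  # approximate anchors may slightly cross
            rj_adj = lj_adj + 1  # clamp to a zero-length site deletion
        events.append(
            InsertionEvent(
                contig_id=lc.contig,
                left_junction=lj_adj,
                right_junction=rj_adj,
                structure="UNRESOLVED",
                support=(lc.support, rc.support),
                approximate=not exact,
                ci=0 if exact else insert_size,
            )
        )
    for ri, rc in enumerate(rights):
        if ri in used_r:
            continue
        rj, r_exact = rc.junction()
        events.append(
            InsertionEvent(
                contig_id=rc.contig,
                left_junction=None,
                right_junction=rj,
                structure="UNRESOLVED",
                support=(0, rc.support),
                approximate=not r_exact,
                ci=0 if r_exact else insert_size,
            )
        )
    events.sort(key=lambda e: (e.contig_id, e.left_junction or e.right_junction or 0))
    return events


# ---------------------------------------------------------------------------
# Copy number / structure inference
# ---------------------------------------------------------------------------


def _depth_arrays(
    alignments: Union[str, pysam.AlignmentFile],
    contigs: Sequence[str],
) -> Dict[str, np.ndarray]:
    """Streaming per-base depth (aligned blocks only) for selected contigs."""
    if isinstance(alignments, str):
        af = pysam.AlignmentFile(alignments, "r")
        close = True
    else:
        af, close = alignments, False
    want = set(contigs)
    lengths = {name: ln for name, ln in zip(af.references, af.lengths)}
    depth = {c: np.zeros(lengths[c] + 1, dtype=np.int32) for c in want}
    try:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            rn = read.reference_name
            if rn not in want:
                continue
            d = depth[rn]
            pos = read.reference_start
            for op, ln in read.cigartuples or ():
                if op in (0, 7, 8):  # M/=/X consume both
                    d[pos] += 1
                    d[pos + ln] -= 1
                    pos += ln
                elif op in (2, 3):  # D/N consume reference
                    pos += ln
    finally:
        if close:
            af.close()
    return {c: np.cumsum(depth[c][:-1]) for c in want}


def infer_structure(
    alignments: Union[str, pysam.AlignmentFile],
    event: InsertionEvent,
    construct: TDNAConstruct,
    depth_bin: int = 100,
    backbone_min_depth: int = 3,
    backbone_min_frac: float = 0.5,
) -> InsertionEvent:
    """Set copy number and insert structure from read depth.

    copies = round(median depth over the T-DNA interval / median genomic
    depth), floored at 1; structure is TDNA_BACKBONE_TDNA iff copies == 2
    and at least ``backbone_min_frac`` of backbone positions have depth >=
    ``backbone_min_depth``.
    """
    vec_id = construct.vector_id
    depth = _depth_arrays(alignments, [vec_id, event.contig_id])
    gen = depth[event.contig_id]
    med_gen = float(np.median(gen))
    if med_gen <= 0:
        event.copies = None
        event.structure = "UNRESOLVED"
        return event
    t0, t1 = construct.tdna_interval
    vec = depth[vec_id]
    med_tdna = float(np.median(vec[t0:t1]))
    event.copies = max(1, int(np.floor(med_tdna / med_gen + 0.5)))
    backbone = np.concatenate([vec[:t0], vec[t1:]])
    if event.copies == 2 and backbone.size and (
        float(np.mean(backbone >= backbone_min_depth)) >= backbone_min_frac
    ):
        event.structure = "TDNA_BACKBONE_TDNA"
    else:
        event.structure = "TDNA_ONLY"
    return event


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def classify_site(
    event: InsertionEvent,
    genes: Sequence[GeneModel],
    promoter_len: int = 1500,
) -> InsertionEvent:
    """Classify the integration site against gene models.

    GENIC_DISRUPTING when the junction deletion or the insertion point falls
    inside a transcript span; else PROMOTER when within ``promoter_len``
    upstream of a TSS (strand-aware); else INTERGENIC.  All qualifying genes
    are listed with the number of deleted CDS bases; the summary class obeys
    the precedence GENIC_DISRUPTING > PROMOTER > INTERGENIC.
    """
    if event.left_junction is None and event.right_junction is None:
        raise ValueError("event has no junctions")
    lj = event.left_junction or event.right_junction
    rj = event.right_junction or event.left_junction
    d0, d1 = lj, rj - 1  # 0-based half-open deleted interval
    k = d0  # insertion point: between 0-based offsets d0-1 and d0
    affected: List[Dict[str, object]] = []
    for g in genes:
        if g.contig_id != event.contig_id:
            continue
        gs, ge = g.span
        disrupting = _overlap(d0, d1, gs, ge) > 0 or (gs < k < ge)
        if disrupting:
            cds_del = sum(
                _overlap(d0, d1, s, e) for s, e in g.canonical.cds
            )
            affected.append(
                {"gene_id": g.gene_id, "relation": "GENIC_DISRUPTING", "deleted_cds": cds_del}
            )
            continue
        if g.strand == "+":
            p0, p1 = gs - promoter_len, gs
            in_prom = _overlap(d0, d1, p0, p1) > 0 or (p0 < k <= p1)
        else:
            p0, p1 = ge, ge + promoter_len
            in_prom = _overlap(d0, d1, p0, p1) > 0 or (p0 <= k < p1)
        if in_prom:
            affected.append(
                {"gene_id": g.gene_id, "relation": "PROMOTER", "deleted_cds": 0}
            )
    event.affected_genes = affected
    if any(a["relation"] == "GENIC_DISRUPTING" for a in affected):
        event.site_class = "GENIC_DISRUPTING"
    elif any(a["relation"] == "PROMOTER" for a in affected):
        event.site_class = "PROMOTER"
    else:
        event.site_class = "INTERGENIC"
    return event


# ---------------------------------------------------------------------------
# Orchestration + exports
# ---------------------------------------------------------------------------


def scan(
    sam_path: str,
    vector_id: str,
    construct: TDNAConstruct,
    genes: Sequence[GeneModel],
    cluster_gap: int = 1000,
    min_support: int = 3,
    min_clip: int = 12,
    promoter_len: int = 1500,
) -> List[InsertionEvent]:
    """Full insertion scan: harvest -> call -> structure -> site class."""
    ev = harvest_evidence(sam_path, vector_id, construct, min_clip=min_clip)
    events = call_insertions(ev, cluster_gap=cluster_gap, min_support=min_support)
    out = []
    for e in events:
        if e.left_junction is not None and e.right_junction is not None:
            e = infer_structure(sam_path, e, construct)
        e = classify_site(e, genes, promoter_len=promoter_len)
        out.append(e)
    return out


def _event_dict(e: InsertionEvent) -> Dict[str, object]:
    return {
        "contig_id": e.contig_id,
        "left_junction": e.left_junction,
        "right_junction": e.right_junction,
        "deletion_len": e.deletion_len,
        "copies": e.copies,
        "structure": e.structure,
        "site_class": e.site_class,
        "affected_genes": e.affected_genes,
        "support_left": e.support[0],
        "support_right": e.support[1],
        "approximate": e.approximate,
        "ci": e.ci,
    }


def events_to_json(events: Sequence[InsertionEvent]) -> str:
    return json.dumps([_event_dict(e) for e in events], indent=1)


def events_to_tsv(events: Sequence[InsertionEvent]) -> str:
    cols = [
        "contig_id",
        "left_junction",
        "right_junction",
        "deletion_len",
        "copies",
        "structure",
        "site_class",
        "support_left",
        "support_right",
        "approximate",
        "affected_genes",
    ]
    lines = ["\t".join(cols)]
    for e in events:
        d = _event_dict(e)
        d["affected_genes"] = ";".join(
            f"{a['gene_id']}:{a['relation']}:{a['deleted_cds']}" for a in e.affected_genes
        )
        lines.append("\t".join(str(d[c]) for c in cols))
    return "\n".join(lines) + "\n"


def events_to_bed(events: Sequence[InsertionEvent]) -> str:
    """Junction intervals, BED (0-based half-open)."""
    lines = []
    for i, e in enumerate(events):
        lj = e.left_junction or e.right_junction
        rj = e.right_junction or e.left_junction
        lines.append(f"{e.contig_id}\t{lj - 1}\t{rj}\tinsertion_{i + 1}\t{e.support[0] + e.support[1]}\t.")
    return "\n".join(lines) + ("\n" if lines else "")
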