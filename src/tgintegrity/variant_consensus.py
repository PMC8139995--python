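"""Dual-caller small-variant consensus.

Normalizes two independent callsets to a common primitive representation,
applies the fixed filter cascade (low-complexity mask, Phred quality,
depth window, per-strand alt support) and keeps only the calls common to
both callers.  Includes a from-scratch DUST-style low-complexity masker.

Internally all interval arithmetic is 0-based half-open; ``SmallVariant.pos``
is 1-based as in VCF, with indels anchored on the preceding base.
"""
from __future__ import annotations

import itertools
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "SmallVariant",
    "FilterConfig",
    "classify_type",
    "dust_mask",
    "normalize",
    "apply_filters",
    "intersect_callsets",
    "compare_lines",
]

_IUPAC = set("ACGTN")

VTYPES = ("SNP", "MNP", "INS", "DEL", "COMPLEX")


def classify_type(ref: str, alt: str) -> str:
    """Derive the variant type from the two alleles.

    SNP 1/1; MNP n/n (n>1); INS when ref is a proper prefix of alt;
    DEL when alt is a proper prefix of ref; COMPLEX otherwise.
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt:
        raise ValueError("empty allele")
    if set(ref) - _IUPAC or set(alt) - _IUPAC:
        raise ValueError(f"non-IUPAC characters in alleles {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt alleles identical: {ref!r}")
    if len(ref) == len(alt):
        return "SNP" if len(ref) == 1 else "MNP"
    if len(alt) > len(ref) and alt.startswith(ref):
        return "INS"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "DEL"
    return "COMPLEX"


@dataclass
class SmallVariant:
    """One small variant, VCF-style (1-based, anchored indels)."""

    contig: str
    pos: int
    ref: str
    alt: str
    qual: Optional[float] = None
    depth: Optional[int] = None
    alt_fwd: Optional[int] = None
    alt_rev: Optional[int] = None
    id: Optional[str] = None

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        self.vtype = classify_type(self.ref, self.alt)

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference footprint."""
        return self.pos + len(self.ref) - 1

    def __hash__(self) -> int:  # pragma: no cover - convenience
        return hash(self.key)


# ---------------------------------------------------------------------------
# DUST-style low-complexity masking
# ---------------------------------------------------------------------------

_TRIPLET_CODE = {b: i for i, b in enumerate("ACGT")}


def _triplet_index(seq: str, i: int) -> int:
    """Code of triplet starting at i, or -1 if it contains a non-ACGT base."""
    try:
        return (
            _TRIPLET_CODE[seq[i]] * 16
            + _TRIPLET_CODE[seq[i + 1]] * 4
            + _TRIPLET_CODE[seq[i + 2]]
        )
    except KeyError:
        return -1


def dust_window_score(window: str) -> float:
    """Triplet-pair score of one window: S = sum c_t(c_t-1)/2 over the 64
    triplet types, normalized by the number of triplet slots (len-2).

    Triplets containing N (or any non-ACGT base) are not counted.
    """
    L = len(window)
    if L < 3:
        return 0.0
    counts: Dict[int, int] = {}
    for i in range(L - 2):
        t = _triplet_index(window, i)
        if t >= 0:
            counts[t] = counts.get(t, 0) + 1
    s = sum(c * (c - 1) // 2 for c in counts.values())
    return s / (L - 2)


def dust_mask(
    seq: str, window: int = 64, threshold: float = 20.0
) -> List[Tuple[int, int]]:
    """Low-complexity intervals of ``seq`` (0-based half-open, merged).

    Slides a window of up to ``window`` bases over the sequence; a window
    whose normalized triplet score exceeds ``threshold`` marks its full
    extent as low complexity.  Overlapping marked windows are merged.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    seq = seq.upper()
    n = len(seq)
    if n < 3:
        return []
    # rolling triplet counts over window [i, i+window)
    counts = [0] * 64
    score = 0  # raw pair score of current window
    raw: List[Tuple[int, int]] = []

    def add(i: int) -> None:
        nonlocal score
        t = _triplet_index(seq, i)
        if t >= 0:
            score += counts[t]
            counts[t] += 1

    def drop(i: int) -> None:
        nonlocal score
        t = _triplet_index(seq, i)
        if t >= 0:
            counts[t] -= 1
            score -= counts[t]

    # initial window at i=0
    first_end = min(window, n)
    for j in range(first_end - 2):
        add(j)
    i = 0
    while True:
        wlen = min(window, n - i)
        if wlen < 3:
            break
        if score / (wlen - 2) > threshold:
            raw.append((i, i + wlen))
        # advance
        if i + window < n:
            add(i + window - 2)
        drop(i)
        i += 1
    # merge overlapping / adjacent intervals
    merged: List[Tuple[int, int]] = []
    for s, e in raw:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# Normalization (left-alignment, parsimony, MNP decomposition)
# ---------------------------------------------------------------------------


def _ref_base(refs: Mapping[str, str], contig: str, pos0: int) -> str:
    return refs[contig][pos0].upper()


def _check_ref(refs: Mapping[str, str], v: SmallVariant) -> None:
    have = str(refs[v.contig][v.pos - 1 : v.pos - 1 + len(v.ref)]).upper()
    if have != v.ref:
        raise ValueError(
            f"record {v.id or v.key}: REF {v.ref!r} does not match reference "
            f"{have!r} at {v.contig}:{v.pos}"
        )


def _left_align(
    refs: Mapping[str, str], contig: str, pos: int, ref: str, alt: str
) -> Tuple[int, str, str]:
    """vt-style left alignment + parsimony trim of one allele pair."""
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos <= 1:
                    raise ValueError(
                        f"cannot left-align variant at start of contig {contig}"
                    )
                b = _ref_base(refs, contig, pos - 2)
                ref, alt = b + ref, b + alt
                pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize(
    callset: Iterable[SmallVariant], refs: Mapping[str, str]
) -> List[SmallVariant]:
    """Reduce a callset to sorted, duplicate-free primitives.

    Indels are left-aligned and parsimony-trimmed; MNPs are decomposed into
    per-base SNPs tagged with their source record id; COMPLEX records are
    kept atomic (trimmed only).  Raises if a REF allele disagrees with the
    reference sequence.
    """
    out: Dict[Tuple[str, int, str, str], SmallVariant] = {}
    for v in callset:
        _check_ref(refs, v)
        src = v.id if v.id is not None else f"{v.contig}:{v.pos}:{v.ref}>{v.alt}"
        pos, ref, alt = _left_align(refs, v.contig, v.pos, v.ref, v.alt)
        if len(ref) == len(alt):
            # SNP or MNP remainder: emit per-base SNPs at differing positions
            for k, (rb, ab) in enumerate(zip(ref, alt)):
                if rb != ab:
                    p = replace(v, pos=pos + k, ref=rb, alt=ab, id=src)
                    out.setdefault(p.key, p)
        else:
            p = replace(v, pos=pos, ref=ref, alt=alt, id=src)
            out.setdefault(p.key, p)
    return sorted(out.values(), key=lambda x: x.key)


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

FILTER_ORDER = ("mask", "malformed", "qual", "min_depth", "max_depth", "strand")


@dataclass
class FilterConfig:
    """The fixed filter cascade applied to each callset before intersection.

    ``min_depth``/``max_depth`` are exclusive bounds (a record survives when
    min_depth < depth < max_depth); ``min_alt_per_strand`` encodes the
    double-strand support rule.  ``mask`` maps contig -> sorted low-complexity
    intervals (0-based half-open).
    """

    min_qual: float = 30.0
    min_depth: int = 10
    max_depth: int = 29
    min_alt_per_strand: int = 1
    mask: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_depth >= self.max_depth:
            raise ValueError("min_depth must be < max_depth")
        if self.min_qual < 0:
            raise ValueError("min_qual must be >= 0")


def _in_mask(cfg: FilterConfig, v: SmallVariant) -> bool:
    ivs = cfg.mask.get(v.contig, ())
    p0, p1 = v.pos - 1, v.end  # 0-based half-open footprint
    for s, e in ivs:
        if s < p1 and e > p0:
            return True
        if s >= p1:
            break
    return False


def apply_filters(
    callset: Iterable[SmallVariant], config: FilterConfig
) -> Tuple[List[SmallVariant], Dict[str, int]]:
    """Apply the cascade in fixed order; tally each removal on the first
    failing filter so the tallies are reproducible."""
    kept: List[SmallVariant] = []
    tallies: Dict[str, int] = OrderedDict((k, 0) for k in FILTER_ORDER)
    for v in callset:
        if _in_mask(config, v):
            tallies["mask"] += 1
        elif v.qual is None or v.depth is None or v.alt_fwd is None or v.alt_rev is None:
            tallies["malformed"] += 1
        elif v.qual < config.min_qual:
            tallies["qual"] += 1
        elif v.depth <= config.min_depth:
            tallies["min_depth"] += 1
        elif v.depth >= config.max_depth:
            tallies["max_depth"] += 1
        elif v.alt_fwd < config.min_alt_per_strand or v.alt_rev < config.min_alt_per_strand:
            tallies["strand"] += 1
        else:
            kept.append(v)
    return kept, dict(tallies)


# ---------------------------------------------------------------------------
# Intersection and three-way comparison
# ---------------------------------------------------------------------------


def intersect_callsets(
    a: Sequence[SmallVariant],
    b: Sequence[SmallVariant],
    refs: Mapping[str, str],
    mode: str = "primitive",
) -> List[SmallVariant]:
    """Calls of ``a`` supported by ``b``, reported in a's representation.

    In the default primitive mode an ``a`` record is retained iff every
    primitive derived from it occurs among b's primitives; COMPLEX records
    are atomic and therefore match only exactly.  ``mode='exact'`` matches
    raw records instead.
    """
    if mode == "exact":
        bkeys = {v.key for v in b}
        return [v for v in a if v.key in bkeys]
    if mode != "primitive":
        raise ValueError(f"unknown intersection mode {mode!r}")
    b_prims = {p.key for p in normalize(b, refs)}
    out: List[SmallVariant] = []
    for i, v in enumerate(a):
        tagged = replace(v, id=f"__a{i}")
        prims = normalize([tagged], refs)
        if prims and all(p.key in b_prims for p in prims):
            out.append(v)
    return out


def compare_lines(
    callsets: Mapping[str, Sequence[SmallVariant]],
    refs: Optional[Mapping[str, str]] = None,
) -> Dict[str, object]:
    """Three-way Venn partition of per-line callsets on primitive identity.

    Returns the 7 disjoint cells (keys joined with '&'), per-line totals,
    per-line specific counts, and the shared count with per-line integer
    percentages.
    """
    names = list(callsets)
    if len(names) != 3:
        raise ValueError("compare_lines expects exactly 3 callsets")
    keysets = {}
    for name, cs in callsets.items():
        if refs is not None:
            keysets[name] = {p.key for p in normalize(cs, refs)}
        else:
            keysets[name] = {v.key for v in cs}
    cells: Dict[str, int] = {}
    universe = set().union(*keysets.values())
    for r in range(1, 4):
        for combo in itertools.combinations(names, r):
            inside = set(universe)
            for n in combo:
                inside &= keysets[n]
            for n in names:
                if n not in combo:
                    inside -= keysets[n]
            cells["&".join(combo)] = len(inside)
    shared = cells["&".join(names)]
    totals = {n: len(keysets[n]) for n in names}
    return {
        "cells": cells,
        "totals": totals,
        "specific": {n: cells[n] for n in names},
        "shared": shared,
        "shared_pct": {
            n: (round(100 * shared / totals[n]) if totals[n] else 0) for n in names
        },
    }
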