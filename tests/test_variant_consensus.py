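"""Classification, DUST masking, normalization, the filter cascade, and
callset intersection, each checked against an independent oracle or
brute-force computation."""
import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgintegrity.synthgenome import VariantSpectrum, plant_variants
from tgintegrity.variant_consensus import (
    FilterConfig,
    SmallVariant,
    apply_filters,
    classify_type,
    compare_lines,
    dust_mask,
    intersect_callsets,
    normalize,
)


class TestClassifyType:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "G", "SNP"),
            ("AT", "GC", "MNP"),
            ("ATG", "A", "DEL"),
            ("A", "AT", "INS"),
            ("AT", "GCC", "COMPLEX"),
        ],
    )
    def test_examples(self, ref, alt, expected):
        assert classify_type(ref, alt) == expected

    def test_exhaustive_short_allele_pairs(self):
        """All allele pairs of length <= 3 classify per the invariant table."""
        alleles = [
            "".join(c) for n in (1, 2, 3) for c in itertools.product("ACGT", repeat=n)
        ]
        for ref in alleles:
            for alt in alleles:
                if ref == alt:
                    with pytest.raises(ValueError):
                        classify_type(ref, alt)
                    continue
                got = classify_type(ref, alt)
                if len(ref) == len(alt):
                    want = "SNP" if len(ref) == 1 else "MNP"
                elif len(alt) > len(ref) and alt.startswith(ref):
                    want = "INS"
                elif len(ref) > len(alt) and ref.startswith(alt):
                    want = "DEL"
                else:
                    want = "COMPLEX"
                assert got == want, (ref, alt)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=4),
        st.text(alphabet="ACGT", min_size=1, max_size=4),
    )
    def test_type_is_total_and_consistent(self, ref, alt):
        """Every distinct allele pair gets exactly one type consistent with
        the allele-length table."""
        if ref == alt:
            with pytest.raises(ValueError):
                classify_type(ref, alt)
            return
        got = classify_type(ref, alt)
        assert got in {"SNP", "MNP", "INS", "DEL", "COMPLEX"}
        if got in ("SNP", "MNP"):
            assert len(ref) == len(alt)
        elif got == "INS":
            assert alt.startswith(ref)
        elif got == "DEL":
            assert ref.startswith(alt)

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            classify_type("A", "X")
        with pytest.raises(ValueError):
            classify_type("", "A")


def _brute_dust(seq, window=64, threshold=20.0):
    """Independent brute-force triplet scorer: per-window Counter score."""
    seq = seq.upper()
    raw = []
    for i in range(len(seq)):
        w = seq[i : i + window]
        if len(w) < 3:
            break
        counts = Counter(
            w[j : j + 3] for j in range(len(w) - 2) if "N" not in w[j : j + 3]
        )
        s = sum(c * (c - 1) // 2 for c in counts.values())
        if s / (len(w) - 2) > threshold:
            raw.append((i, i + len(w)))
    merged = []
    for s_, e in raw:
        if merged and s_ <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s_, e))
    return merged


class TestDustMask:
    def test_homopolymer_fully_masked(self):
        assert dust_mask("A" * 100) == [(0, 100)]

    def test_four_periodic_repeat_unmasked_at_default(self):
        assert dust_mask("ACGT" * 25) == []

    def test_too_short(self):
        assert dust_mask("AC") == []

    def test_n_breaks_triplets(self):
        # interleaved Ns leave no scoring triplet at all
        assert dust_mask("AANAANAANAAN" * 20) == []

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=120))
    def test_oracle_equivalence_property(self, s):
        assert dust_mask(s) == _brute_dust(s)

    def test_oracle_equivalence_random_strings(self):
        """Matches the brute-force scorer on 200 random 100-base strings
        (low-complexity inserts planted in half of them)."""
        rng = np.random.default_rng(17)
        for k in range(200):
            s = "".join(rng.choice(list("ACGT"), 100))
            if k % 2:
                i = int(rng.integers(0, 40))
                ln = int(rng.integers(20, 60))
                s = (s[:i] + "A" * ln + s[i:])[:100]
            assert dust_mask(s) == _brute_dust(s), s


@pytest.fixture(scope="module")
def toy_refs():
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), 5_000))
    # embed a homopolymer run for left-alignment cases
    seq = seq[:1000] + "C" + "A" * 8 + seq[1009:]
    return {"c1": seq}


class TestNormalize:
    def test_mnp_decomposition(self, toy_refs):
        seq = toy_refs["c1"]
        v = SmallVariant("c1", 100, seq[99:101], _other(seq[99]) + _other(seq[100]))
        prims = normalize([v], toy_refs)
        assert [(p.pos, p.ref, p.alt) for p in prims] == [
            (100, seq[99], _other(seq[99])),
            (101, seq[100], _other(seq[100])),
        ]
        assert all(p.id == prims[0].id for p in prims)  # tagged with source

    def test_deletion_left_aligned_in_repeat(self, toy_refs):
        """Equivalent placements of a 1-base deletion inside the A-run all
        normalize to the same left-most record (brute-force equivalence)."""
        seq = toy_refs["c1"]
        assert seq[1000:1009] == "C" + "A" * 8
        got = set()
        for pos in range(1001, 1008):  # anchor anywhere inside the run
            v = SmallVariant("c1", pos, seq[pos - 1 : pos + 1], seq[pos - 1])
            (p,) = normalize([v], toy_refs)
            got.add((p.pos, p.ref, p.alt))
        assert got == {(1001, "CA", "C")}

    def test_idempotent_and_primitive_preserving(self, toy_refs):
        rng = np.random.default_rng(3)
        seq = toy_refs["c1"]
        calls = []
        for i in range(60):
            pos = int(rng.integers(10, 4_900))
            kind = rng.choice(["SNP", "DEL", "INS"])
            if kind == "SNP":
                calls.append(SmallVariant("c1", pos, seq[pos - 1], _other(seq[pos - 1])))
            elif kind == "DEL":
                calls.append(SmallVariant("c1", pos, seq[pos - 1 : pos + 2], seq[pos - 1]))
            else:
                calls.append(SmallVariant("c1", pos, seq[pos - 1], seq[pos - 1] + "T"))
        once = normalize(calls, toy_refs)
        twice = normalize(once, toy_refs)
        assert [p.key for p in once] == [p.key for p in twice]
        assert [p.key for p in once] == sorted(set(p.key for p in once))

    def test_reference_mismatch_named(self, toy_refs):
        bad_ref = "G" if toy_refs["c1"][49] != "G" else "C"
        v = SmallVariant("c1", 50, bad_ref, "T", id="rec7")
        with pytest.raises(ValueError, match="rec7"):
            normalize([v], toy_refs)


def _other(base):
    return {"A": "G", "G": "A", "C": "T", "T": "C"}[base]


def _rec(pos=100, qual=50.0, depth=20, fwd=10, rev=10, contig="c1", ref="A", alt="G"):
    return SmallVariant(contig, pos, ref, alt, qual, depth, fwd, rev)


class TestApplyFilters:
    def test_boundary_rules(self, toy_refs):
        cfg = FilterConfig()
        seq = toy_refs["c1"]

        def one(**kw):
            pos = kw.pop("pos", 100)
            v = _rec(pos=pos, ref=seq[pos - 1], alt=_other(seq[pos - 1]), **kw)
            kept, tallies = apply_filters([v], cfg)
            return kept, tallies

        kept, t = one(qual=29.9)
        assert not kept and t["qual"] == 1
        kept, _ = one(qual=30.0)
        assert kept
        kept, t = one(depth=10)
        assert not kept and t["min_depth"] == 1
        kept, _ = one(depth=11)
        assert kept
        kept, t = one(depth=29)
        assert not kept and t["max_depth"] == 1
        kept, _ = one(depth=28)
        assert kept
        kept, t = one(fwd=7, rev=0)
        assert not kept and t["strand"] == 1
        kept, t = one(depth=None)
        assert not kept and t["malformed"] == 1

    def test_mask_is_first_filter(self):
        cfg = FilterConfig(mask={"c1": [(90, 110)]})
        kept, t = apply_filters([_rec(pos=100, qual=1.0)], cfg)
        assert not kept and t["mask"] == 1 and t["qual"] == 0

    def test_monotonicity_over_random_callsets(self):
        """Tightening any threshold never increases the surviving count."""
        rng = np.random.default_rng(23)
        for _ in range(100):
            calls = [
                _rec(
                    pos=int(rng.integers(1, 10_000)),
                    qual=float(rng.uniform(0, 80)),
                    depth=int(rng.integers(0, 45)),
                    fwd=int(rng.integers(0, 4)),
                    rev=int(rng.integers(0, 4)),
                )
                for _ in range(40)
            ]
            base = len(apply_filters(calls, FilterConfig())[0])
            tighter = [
                FilterConfig(min_qual=40),
                FilterConfig(min_depth=15),
                FilterConfig(max_depth=25),
                FilterConfig(min_alt_per_strand=2),
            ]
            for cfg in tighter:
                assert len(apply_filters(calls, cfg)[0]) <= base

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            FilterConfig(min_depth=30, max_depth=29)


class TestIntersectCallsets:
    def test_identity(self, toy_refs):
        seq = toy_refs["c1"]
        a = [SmallVariant("c1", p, seq[p - 1], _other(seq[p - 1])) for p in (50, 80)]
        assert [v.key for v in intersect_callsets(a, a, toy_refs)] == [v.key for v in a]

    def test_mnp_matches_its_component_snps(self, toy_refs):
        seq = toy_refs["c1"]
        mnp = SmallVariant("c1", 200, seq[199:201], _other(seq[199]) + _other(seq[200]))
        snps = [
            SmallVariant("c1", 200, seq[199], _other(seq[199])),
            SmallVariant("c1", 201, seq[200], _other(seq[200])),
        ]
        out = intersect_callsets([mnp], snps, toy_refs)
        assert [v.key for v in out] == [mnp.key]  # A's representation kept

    def test_partial_primitive_support_drops_record(self, toy_refs):
        seq = toy_refs["c1"]
        mnp = SmallVariant("c1", 200, seq[199:201], _other(seq[199]) + _other(seq[200]))
        one_snp = [SmallVariant("c1", 200, seq[199], _other(seq[199]))]
        assert intersect_callsets([mnp], one_snp, toy_refs) == []

    def test_disjoint(self, toy_refs):
        seq = toy_refs["c1"]
        a = [SmallVariant("c1", 50, seq[49], _other(seq[49]))]
        b = [SmallVariant("c1", 60, seq[59], _other(seq[59]))]
        assert intersect_callsets(a, b, toy_refs) == []

    def test_consensus_primitives_bounded(self, genome, refs):
        truth = plant_variants(genome, VariantSpectrum(), 400, seed=8)
        a = truth[:300]
        b = truth[100:]
        out = intersect_callsets(a, b, refs)
        out_prims = {p.key for p in normalize(out, refs)}
        a_prims = {p.key for p in normalize(a, refs)}
        b_prims = {p.key for p in normalize(b, refs)}
        assert out_prims <= (a_prims & b_prims)
        # no COMPLEX in the overlap slice => equality
        if not any(v.vtype == "COMPLEX" for v in truth[100:300]):
            assert out_prims == (a_prims & b_prims)


class TestCompareLines:
    def _mk(self, positions):
        return [SmallVariant("c1", p, "A", "G") for p in positions]

    def test_identical_callsets(self):
        cs = {n: self._mk(range(10, 30)) for n in ("l1", "l2", "l3")}
        res = compare_lines(cs)
        assert res["shared"] == 20
        assert res["cells"]["l1"] == res["cells"]["l1&l2"] == 0

    def test_pairwise_disjoint(self):
        cs = {
            "l1": self._mk(range(0, 10)),
            "l2": self._mk(range(100, 115)),
            "l3": self._mk(range(200, 220)),
        }
        res = compare_lines(cs)
        assert res["specific"] == {"l1": 10, "l2": 15, "l3": 20}
        assert res["shared"] == 0

    def test_random_partition_matches_brute_force(self):
        rng = np.random.default_rng(5)
        sets = {
            n: set(map(int, rng.choice(300, size=120, replace=False)))
            for n in ("l1", "l2", "l3")
        }
        res = compare_lines({n: self._mk(s) for n, s in sets.items()})
        s1, s2, s3 = sets["l1"], sets["l2"], sets["l3"]
        assert res["cells"]["l1&l2&l3"] == len(s1 & s2 & s3)
        assert res["cells"]["l1&l2"] == len((s1 & s2) - s3)
        assert res["cells"]["l1"] == len(s1 - s2 - s3)
        total = sum(
            v for k, v in res["cells"].items() if "l1" in k.split("&")
        )
        assert total == len(s1)  # cells of one line sum to its total


class TestEndToEndRecovery:
    def test_perfect_emulated_consensus_equals_truth(self, genome, refs):
        from tgintegrity.synthgenome import emulate_callers

        truth = plant_variants(genome, VariantSpectrum(), 2_000, seed=3)
        a = emulate_callers(truth, genome, "JOINED", seed=5)
        b = emulate_callers(truth, genome, "PRIMITIVE", seed=6)
        consensus = intersect_callsets(a, b, refs)
        assert {p.key for p in normalize(consensus, refs)} == {
            p.key for p in normalize(truth, refs)
        }
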