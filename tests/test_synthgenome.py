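"""Generator invariants: determinism, annotation validity, insertion
conservation, spectrum recovery, read-simulation truth alignments, and
emulated-caller behavior."""
import math
from collections import Counter

import numpy as np
import pysam
import pytest
from Bio.Seq import Seq

from tgintegrity import io_utils
from tgintegrity.synthgenome import (
    CallerLaws,
    ConfigError,
    GeneratorConfig,
    InsertionSpec,
    VariantSpectrum,
    build_reference,
    build_transgenic_genome,
    default_construct,
    emulate_callers,
    plant_variants,
    revcomp,
    simulate_reads,
)
from tgintegrity.variant_consensus import normalize


def _se(p, n):
    return math.sqrt(p * (1 - p) / n)


class TestBuildReference:
    def test_deterministic_outputs(self, tmp_path):
        cfg = GeneratorConfig(n_contigs=2, contig_len=50_000)
        paths = []
        for run in ("a", "b"):
            g = build_reference(cfg, seed=7)
            fa = tmp_path / f"{run}.fasta"
            gff = tmp_path / f"{run}.gff3"
            io_utils.write_fasta(g.contigs, str(fa))
            io_utils.write_gff3(g, str(gff))
            paths.append((fa.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]

    def test_zero_gene_density(self):
        g = build_reference(GeneratorConfig(gene_density=0.0), seed=1)
        assert g.genes == []

    def test_contig_too_short_rejected(self):
        with pytest.raises(ConfigError):
            build_reference(GeneratorConfig(contig_len=5_000), seed=1)

    def test_annotation_valid_and_cds_translates(self, tmp_path, genome):
        """Exhaustive scan of the emitted GFF3: every canonical CDS length is
        divisible by 3 and translates ATG..stop without internal stops."""
        fa = tmp_path / "g.fasta"
        gff = tmp_path / "g.gff3"
        io_utils.write_fasta(genome.contigs, str(fa))
        io_utils.write_gff3(genome, str(gff))
        seqs = io_utils.read_fasta(str(fa))
        genes = io_utils.load_gff3(str(gff))
        assert len(genes) == len(genome.genes)
        n_coding = 0
        for g in genes:
            for t in g.transcripts:
                assert t.exons == sorted(t.exons)
                for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
                    assert e1 <= s2  # non-overlapping
                for s, e in t.utr5 + t.utr3:
                    assert any(es <= s and e <= ee for es, ee in t.exons)
            t = g.canonical
            if not t.cds:
                continue
            n_coding += 1
            assert t.cds_len % 3 == 0
            cds = "".join(seqs[g.contig_id][s:e] for s, e in t.cds)
            if g.strand == "-":
                cds = revcomp(cds)
            prot = str(Seq(cds).translate())
            assert prot.startswith("M") and prot.endswith("*")
            assert "*" not in prot[:-1]
        assert n_coding > 0

    def test_overlapping_antisense_pair_exists(self, genome):
        gp, gm = genome.antisense_pair
        plus = next(g for g in genome.genes if g.gene_id == gp)
        minus = next(g for g in genome.genes if g.gene_id == gm)
        assert plus.strand == "+" and minus.strand == "-"
        ps, pe = plus.span
        ms, me = minus.span
        assert ps < me and ms < pe  # spans overlap


class TestTransgenicGenome:
    def test_length_conservation(self, genome, construct):
        ref_len = len(genome.seq("ctg0001"))
        tdna_len = len(construct.tdna_seq)
        for deletion in (0, 95, 361, 1304):
            spec = InsertionSpec("ctg0001", 20_000, deletion, 1, "TDNA_ONLY")
            tg, _ = build_transgenic_genome(genome, construct, spec)
            assert len(tg.seq("ctg0001")) == ref_len + tdna_len - deletion

    def test_junction_sequence_composition(self, genome, construct):
        spec = InsertionSpec("ctg0001", 20_000, 50, 1, "TDNA_ONLY")
        ref = genome.seq("ctg0001")
        tg, _ = build_transgenic_genome(genome, construct, spec)
        mut = tg.seq("ctg0001")
        assert mut[:20_000] == ref[:20_000]
        assert mut[20_000 : 20_000 + len(construct.tdna_seq)] == construct.tdna_seq
        assert mut[20_000 + len(construct.tdna_seq) :] == ref[20_050:]

    def test_backbone_structure_contains_full_vector(self, genome, construct):
        spec = InsertionSpec("ctg0001", 20_000, 0, 2, "TDNA_BACKBONE_TDNA")
        tg, _ = build_transgenic_genome(genome, construct, spec)
        mut = tg.seq("ctg0001")
        assert construct.vector_seq in mut
        # two T-DNA copies, one backbone copy
        assert mut.count(construct.tdna_seq[:50]) >= 2

    def test_protected_interval_rejected(self, genome, construct):
        spec = InsertionSpec("ctg0001", 20_000, 10, 1)
        with pytest.raises(ConfigError):
            build_transgenic_genome(
                genome, construct, spec, protected={"ctg0001": [(19_900, 20_100)]}
            )

    def test_backbone_requires_two_copies(self):
        with pytest.raises(ConfigError):
            InsertionSpec("ctg0001", 100, 0, 1, "TDNA_BACKBONE_TDNA")


class TestPlantVariants:
    def test_empty(self, genome):
        assert plant_variants(genome, VariantSpectrum(), 0, seed=1) == []

    def test_reproducible_sorted_nonoverlapping(self, genome):
        a = plant_variants(genome, VariantSpectrum(), 500, seed=3)
        b = plant_variants(genome, VariantSpectrum(), 500, seed=3)
        assert [v.key for v in a] == [v.key for v in b]
        assert [v.key for v in a] == sorted(v.key for v in a)
        for u, v in zip(a, a[1:]):
            if u.contig == v.contig:
                assert v.pos > u.end  # non-overlapping footprints

    def test_spectrum_recovery(self, genome):
        n = 10_000
        sp = VariantSpectrum()
        vs = plant_variants(genome, sp, n, seed=3)
        counts = Counter(v.vtype for v in vs)
        assert abs(counts["DEL"] / n - 0.62) <= 3 * _se(0.62, n)
        assert abs(counts["SNP"] / n - 0.27) <= 3 * _se(0.27, n)

    def test_ts_weight_recovery(self, genome):
        sp = VariantSpectrum(ts_weight=0.63)
        vs = plant_variants(genome, sp, 5_000, seed=4)
        from tgintegrity.varstats import ts_tv

        ts, tv, ratio = ts_tv(vs)
        n = ts + tv
        assert abs(ts / n - 0.63) <= 3 * _se(0.63, n)
        assert 1.4 < ratio < 2.1  # configured weight corresponds to ~1.7

    def test_alleles_match_reference(self, genome, refs):
        for v in plant_variants(genome, VariantSpectrum(), 300, seed=9):
            assert refs[v.contig][v.pos - 1 : v.end] == v.ref

    def test_overfull_placement_rejected(self):
        tiny = build_reference(
            GeneratorConfig(n_contigs=1, contig_len=10_000, gene_density=0.0,
                            antisense_pair=False),
            seed=1,
        )
        with pytest.raises(ConfigError):
            plant_variants(tiny, VariantSpectrum(), 50_000, seed=1)


class TestSimulateReads:
    def test_mean_depth_near_target(self, genome, construct):
        spec = InsertionSpec("ctg0001", 20_000, 100, 1)
        tg, _ = build_transgenic_genome(genome, construct, spec)
        sim = simulate_reads(tg, coverage=35, read_len=100, seed=2)
        total = sum(len(s) for _, s in tg.contigs)
        depth = sum(len(r.seq_sequenced) for p in sim.pairs for r in p) / total
        assert abs(depth - 35) / 35 < 0.10

    def test_error_free_reads_match_source(self, genome, construct):
        spec = InsertionSpec("ctg0001", 20_000, 100, 1)
        tg, _ = build_transgenic_genome(genome, construct, spec)
        sim = simulate_reads(tg, coverage=2, error_rate=0.0, seed=2)
        seqs = dict(tg.contigs)
        for r1, r2 in sim.pairs[:500]:
            c, s, e, strand = sim.read_origins[f"{r1.name}/1"]
            assert r1.seq_sequenced == seqs[c][s:e]
            c, s, e, strand = sim.read_origins[f"{r2.name}/2"]
            assert r2.seq_sequenced == revcomp(seqs[c][s:e])

    def test_junction_reads_softclipped_at_junction(self, genome, construct):
        """Reads straddling the left junction are soft-clipped exactly at
        the truth junction coordinate (recomputed from read_origins)."""
        spec = InsertionSpec("ctg0001", 20_000, 100, 1)
        tg, _ = build_transgenic_genome(genome, construct, spec)
        sim = simulate_reads(tg, coverage=35, seed=2)
        left0 = spec.left_junction  # 0-based end of retained prefix
        n_checked = 0
        for r1, r2 in sim.pairs:
            for r in (r1, r2):
                c, s, e, _ = sim.read_origins[f"{r.name}/{r.mate}"]
                # straddles the left junction with its larger part genomic
                if c == "ctg0001" and s < left0 - 55 and left0 + 12 < e:
                    clips = [ln for op, ln in r.cigar if op == 4]
                    assert len(clips) == 1
                    assert r.ref_name == "ctg0001"
                    # reference-consumed end equals the junction
                    m = sum(ln for op, ln in r.cigar if op == 0)
                    assert r.ref_pos0 + m == left0
                    n_checked += 1
        assert n_checked >= 5

    def test_truth_sam_structurally_valid(self, line_sams):
        path = line_sams["line212"]["sam"]
        with pysam.AlignmentFile(path) as af:
            assert af.header["HD"]["SO"] == "coordinate"
            last = {}
            n = 0
            for read in af:
                n += 1
                assert read.is_paired
                assert read.query_length == sum(
                    ln for op, ln in read.cigartuples if op in (0, 1, 4)
                )
                key = read.reference_id
                assert read.reference_start >= last.get(key, 0)
                last[key] = read.reference_start
            assert n % 2 == 0 and n > 0

    def test_short_genome_rejected(self, construct):
        tiny = build_reference(
            GeneratorConfig(n_contigs=1, contig_len=10_000, gene_density=0.0,
                            antisense_pair=False),
            seed=1,
        )
        spec = InsertionSpec("ctg0001", 5_000, 0, 1)
        tg, _ = build_transgenic_genome(tiny, construct, spec)
        with pytest.raises(ConfigError):
            simulate_reads(tg, insert_mean=13_000, insert_sd=500, seed=1)


class TestEmulateCallers:
    def test_perfect_callers_match_truth(self, genome, refs):
        truth = plant_variants(genome, VariantSpectrum(), 1_000, seed=3)
        t_prims = {p.key for p in normalize(truth, refs)}
        for style in ("JOINED", "PRIMITIVE"):
            calls = emulate_callers(truth, genome, style, seed=5)
            assert {p.key for p in normalize(calls, refs)} == t_prims

    def test_total_dropout(self, genome):
        truth = plant_variants(genome, VariantSpectrum(), 100, seed=3)
        assert emulate_callers(truth, genome, "JOINED", fn_rate=1.0, seed=1) == []

    def test_fp_fn_binomial(self, genome, refs):
        truth = plant_variants(genome, VariantSpectrum(), 1_000, seed=3)
        calls = emulate_callers(
            truth, genome, "PRIMITIVE", fp_rate=0.1, fn_rate=0.1, seed=5
        )
        t_prims = {p.key for p in normalize(truth, refs)}
        c_prims = {p.key for p in normalize(calls, refs)}
        # count recovered truth *records* via primitive containment
        tp = sum(
            1
            for v in truth
            if all(p.key in c_prims for p in normalize([v], refs))
        )
        assert abs(tp - 900) <= 3 * math.sqrt(1_000 * 0.1 * 0.9)

    def test_records_carry_annotations(self, genome):
        truth = plant_variants(genome, VariantSpectrum(), 50, seed=3)
        for v in emulate_callers(truth, genome, "JOINED", seed=1):
            assert v.qual is not None and v.depth is not None
            assert v.alt_fwd + v.alt_rev == v.depth
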