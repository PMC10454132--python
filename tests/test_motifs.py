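import pytest

from knoxnet.motifs import (
    GenomicRegion,
    compile_motif,
    default_motifs,
    extract_introns,
    extract_promoter,
    scan_gene,
    scan_region,
)

REVCOMP = str.maketrans("ACGT", "TGCA")


def rc(s):
    return s.translate(REVCOMP)[::-1]


def region(seq, strand="+", kind="promoter", ordinal=0):
    return GenomicRegion("chr1", 0, len(seq), strand, kind, ordinal, seq)


def naive_scan(seq, motif, strands="both"):
    """Independent oracle: expand the degenerate word, substring-search."""
    words = set(motif.expand())
    hits = []
    L = len(motif.pattern)
    for off in range(len(seq) - L + 1):
        sub = seq[off : off + L]
        if sub in words:
            hits.append((off, "+", motif.name))
        if strands == "both" and rc(sub) in words:
            hits.append((off, "-", motif.name))
    return sorted(hits)


class TestCompileMotif:
    @pytest.mark.parametrize(
        "pattern, size",
        [("KGACM", 4), ("TGAYTGA", 2), ("TGATKKGA", 4), ("N", 4), ("ACGT", 1)],
    )
    def test_expansion_sizes(self, pattern, size):
        assert compile_motif("m", pattern).expansion_size == size

    def test_illegal_symbol_named(self):
        with pytest.raises(ValueError, match="'X'"):
            compile_motif("bad", "TGAXT")

    def test_expansion_set_matches_size(self):
        m = compile_motif("m", "TGATKKGA")
        words = m.expand()
        assert len(words) == len(set(words)) == 4
        assert all(len(w) == 8 for w in words)


class TestScanRegion:
    def test_tgaytga_forward_only(self):
        m = compile_motif("bs2", "TGAYTGA")
        hits = scan_region(region("TGACTGA"), [m], strands="both")
        assert [(h.offset, h.strand_within_region) for h in hits] == [(0, "+")]
        assert hits[0].matched == "TGACTGA"

    def test_kgacm_single_forward_hit(self):
        m = compile_motif("bs1", "KGACM")
        hits = scan_region(region("GGACA"), [m], strands="both")
        assert [(h.offset, h.strand_within_region) for h in hits] == [(0, "+")]

    def test_reverse_strand_hit(self):
        m = compile_motif("bs1", "KGACM")
        seq = rc("TGACC")  # GGTCA
        hits = scan_region(region(seq), [m], strands="both")
        assert [(h.offset, h.strand_within_region) for h in hits] == [(0, "-")]
        assert rc(hits[0].matched) in m.expand()

    def test_n_in_sequence_never_matches(self):
        m = compile_motif("bs1", "KGACM")
        assert scan_region(region("GGANA"), [m]) == []

    def test_overlapping_hits_all_reported(self):
        m = compile_motif("aa", "AA")
        hits = scan_region(region("AAAA"), [m], strands="forward")
        assert [h.offset for h in hits] == [0, 1, 2]

    def test_matches_naive_expansion_oracle_on_random_sequences(self):
        import numpy as np

        rng = np.random.default_rng(50)
        motifs = default_motifs()
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            reg = region(seq)
            for m in motifs:
                ours = sorted(
                    (h.offset, h.strand_within_region, h.motif)
                    for h in scan_region(reg, [m], strands="both")
                )
                assert ours == naive_scan(seq, m)

    def test_revcomp_invariance_of_hit_multiset(self):
        import numpy as np

        rng = np.random.default_rng(51)
        motifs = default_motifs()
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            fwd = scan_region(region(seq), motifs, strands="both")
            rev = scan_region(region(rc(seq)), motifs, strands="both")
            fwd_set = sorted((h.motif, min(h.matched, rc(h.matched))) for h in fwd)
            rev_set = sorted((h.motif, min(h.matched, rc(h.matched))) for h in rev)
            assert fwd_set == rev_set


def write_gene(tmp_path, contig, gff_rows):
    fasta = tmp_path / "g.fa"
    fasta.write_text(">chr1\n" + contig + "\n")
    gff = tmp_path / "g.gff3"
    gff.write_text("##gff-version 3\n" + "\n".join(gff_rows) + "\n")
    return fasta, gff


class TestExtractPromoter:
    def test_plus_strand_coordinates(self, tmp_path):
        contig = "A" * 10000
        fasta, gff = write_gene(
            tmp_path,
            contig,
            ["chr1\t.\tgene\t5000\t6000\t.\t+\t.\tID=g1"],
        )
        reg = extract_promoter(fasta, gff, "g1", length=3000)
        assert (reg.start, reg.end) == (1999, 4999)
        assert len(reg.sequence) == 3000

    def test_minus_strand_reverse_complemented(self, tmp_path):
        contig = "A" * 5000 + "C" * 3000 + "A" * 2000
        fasta, gff = write_gene(
            tmp_path,
            contig,
            ["chr1\t.\tgene\t4001\t5000\t.\t-\t.\tID=g1"],
        )
        reg = extract_promoter(fasta, gff, "g1", length=3000)
        assert (reg.start, reg.end) == (5000, 8000)
        assert reg.sequence == "G" * 3000  # revcomp of C-run

    def test_clipped_at_contig_edge(self, tmp_path):
        contig = "A" * 500
        fasta, gff = write_gene(
            tmp_path, contig, ["chr1\t.\tgene\t100\t200\t.\t+\t.\tID=g1"]
        )
        reg = extract_promoter(fasta, gff, "g1", length=3000)
        assert len(reg.sequence) == 99

    def test_unknown_gene_is_error(self, tmp_path):
        fasta, gff = write_gene(
            tmp_path, "A" * 100, ["chr1\t.\tgene\t50\t80\t.\t+\t.\tID=g1"]
        )
        with pytest.raises(KeyError, match="nope"):
            extract_promoter(fasta, gff, "nope")


class TestExtractIntrons:
    def test_single_intron_coordinates(self, tmp_path):
        contig = "ACGT" * 100
        rows = [
            "chr1\t.\tgene\t1\t250\t.\t+\t.\tID=g1",
            "chr1\t.\tmRNA\t1\t250\t.\t+\t.\tID=g1.1;Parent=g1",
            "chr1\t.\texon\t1\t100\t.\t+\t.\tID=e1;Parent=g1.1",
            "chr1\t.\texon\t151\t250\t.\t+\t.\tID=e2;Parent=g1.1",
        ]
        fasta, gff = write_gene(tmp_path, contig, rows)
        introns = extract_introns(fasta, gff, "g1")
        assert len(introns) == 1
        assert (introns[0].start, introns[0].end) == (100, 150)
        assert introns[0].ordinal == 1
        assert introns[0].sequence == contig[100:150]

    def test_minus_strand_ordinals_follow_transcript(self, tmp_path):
        contig = "A" * 60 + "C" * 20 + "A" * 40 + "G" * 30 + "A" * 50
        rows = [
            "chr1\t.\tgene\t1\t200\t.\t-\t.\tID=g1",
            "chr1\t.\tmRNA\t1\t200\t.\t-\t.\tID=g1.1;Parent=g1",
            "chr1\t.\texon\t1\t60\t.\t-\t.\tID=e3;Parent=g1.1",
            "chr1\t.\texon\t81\t120\t.\t-\t.\tID=e2;Parent=g1.1",
            "chr1\t.\texon\t151\t200\t.\t-\t.\tID=e1;Parent=g1.1",
        ]
        fasta, gff = write_gene(tmp_path, contig, rows)
        introns = extract_introns(fasta, gff, "g1")
        assert [i.ordinal for i in introns] == [1, 2]
        # intron 1 is the one nearest the transcript 5' end = highest
        # forward coordinates on a minus-strand gene
        assert introns[0].start == 120 and introns[0].end == 150
        assert introns[0].sequence == rc("G" * 30)

    def test_single_exon_gene_has_no_introns(self, tmp_path):
        rows = [
            "chr1\t.\tgene\t1\t100\t.\t+\t.\tID=g1",
            "chr1\t.\tmRNA\t1\t100\t.\t+\t.\tID=g1.1;Parent=g1",
            "chr1\t.\texon\t1\t100\t.\t+\t.\tID=e1;Parent=g1.1",
        ]
        fasta, gff = write_gene(tmp_path, "A" * 120, rows)
        assert extract_introns(fasta, gff, "g1") == []

    def test_gene_without_transcript_is_error(self, tmp_path):
        fasta, gff = write_gene(
            tmp_path, "A" * 100, ["chr1\t.\tgene\t1\t50\t.\t+\t.\tID=g1"]
        )
        with pytest.raises(KeyError):
            extract_introns(fasta, gff, "g1")


class TestScanGene:
    def test_planted_counts_by_region(self, tmp_path):
        from knoxnet.simulate import (
            PlantSpec,
            SequenceSimConfig,
            simulate_sequences,
            write_sequences,
        )

        cfg = SequenceSimConfig(
            planted=(
                PlantSpec("KNOX/BLH_bs1", "promoter"),
                PlantSpec("KNOX/BLH_bs1", "promoter"),
                PlantSpec("KNOX/BLH_bs2", "intron", 1),
            ),
            seed=3,
        )
        genome, gff_text, truth = simulate_sequences(cfg)
        write_sequences(genome, gff_text, tmp_path / "g.fa", tmp_path / "g.gff3")
        summary = scan_gene(
            tmp_path / "g.fa", tmp_path / "g.gff3", cfg.gene_id,
            default_motifs(),
        )
        assert summary.promoter_count == 2
        assert summary.intron_count == 1
        assert summary.total == 3
        assert summary.count_by_motif() == {
            "KNOX/BLH_bs1": 2, "KNOX/BLH_bs2": 1,
        }

    def test_partition_consistency(self, tmp_path):
        from knoxnet.simulate import (
            PlantSpec,
            SequenceSimConfig,
            simulate_sequences,
            write_sequences,
        )

        cfg = SequenceSimConfig(
            planted=tuple(
                PlantSpec(m, k, o)
                for m, k, o in [
                    ("KNOX/BLH_bs1", "promoter", 0),
                    ("KNOX/BLH_bs2", "promoter", 0),
                    ("KNOX/BLH_bs3", "intron", 1),
                    ("KNOX/BLH_bs1", "intron", 2),
                    ("KNOX/BLH_bs2", "intron", 3),
                ]
            ),
            seed=4,
        )
        genome, gff_text, truth = simulate_sequences(cfg)
        write_sequences(genome, gff_text, tmp_path / "g.fa", tmp_path / "g.gff3")
        s = scan_gene(
            tmp_path / "g.fa", tmp_path / "g.gff3", cfg.gene_id,
            default_motifs(),
        )
        assert s.total == sum(s.count_by_motif().values())
        assert s.total == sum(s.count_by_region().values())
        assert s.total == s.promoter_count + s.intron_count

    def test_bed_output_valid_intervals(self, tmp_path):
        from knoxnet.simulate import (
            PlantSpec,
            SequenceSimConfig,
            simulate_sequences,
            write_sequences,
        )

        cfg = SequenceSimConfig(
            strand="-",
            planted=(
                PlantSpec("KNOX/BLH_bs3", "promoter"),
                PlantSpec("KNOX/BLH_bs2", "intron", 3, strand="-"),
            ),
            seed=5,
        )
        genome, gff_text, _ = simulate_sequences(cfg)
        write_sequences(genome, gff_text, tmp_path / "g.fa", tmp_path / "g.gff3")
        s = scan_gene(
            tmp_path / "g.fa", tmp_path / "g.gff3", cfg.gene_id,
            default_motifs(),
        )
        s.write_bed(tmp_path / "hits.bed")
        contig = genome[cfg.contig_id]
        for line in (tmp_path / "hits.bed").read_text().splitlines():
            chrom, start, end, name, score, strand = line.split("\t")
            start, end = int(start), int(end)
            assert 0 <= start < end <= len(contig)
            word = contig[start:end]
            motif = next(m for m in default_motifs() if m.name == name)
            assert word in motif.expand() or rc(word) in motif.expand()
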