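"""Interval containers, BED-dialect I/O, and the interval-arithmetic engine."""

import numpy as np
import pytest

from coopreg.genome import (
    GeneModel,
    Genome,
    GenomicInterval,
    SignalTrack,
    intersect_many,
    nearest_tss,
    overlap_bp,
    read_gene_table,
    read_gtf_genes,
    read_intervals,
    write_gene_table,
    write_intervals,
)

from conftest import random_genes, random_intervals


# ---------------------------------------------------------------------------
# containers


def test_interval_rejects_inverted_and_negative_coordinates():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 200, 100)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 5, 5)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 10)


def test_genome_validation_and_interval_bounds(small_genome):
    with pytest.raises(ValueError):
        Genome({"chr1": 0})
    iv = GenomicInterval("chr1", 0, 200_000)
    with pytest.raises(ValueError):
        iv.validate_against(small_genome)
    GenomicInterval("chr1", 0, 100_000).validate_against(small_genome)


@pytest.mark.parametrize(
    "strand,tx_start,tx_end,expected_tss",
    [("+", 100, 500, 100), ("-", 100, 500, 499)],
)
def test_tss_is_strand_dependent_five_prime_end(strand, tx_start, tx_end, expected_tss):
    g = GeneModel("g1", "chr1", strand, tx_start, tx_end)
    assert g.tss == expected_tss


# ---------------------------------------------------------------------------
# I/O


def test_bed6_line_maps_fields_directly(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t200\tpk1\t50\t+\n")
    (iv,) = read_intervals(p, "bed6")
    assert iv == GenomicInterval("chr1", 100, 200, strand="+", name="pk1", score=50.0)


def test_empty_file_reads_as_empty_list(tmp_path):
    p = tmp_path / "empty.bed"
    p.write_text("")
    assert read_intervals(p, "bed3") == []


def test_malformed_line_error_names_line_number(tmp_path):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t200\t100\n")
    with pytest.raises(ValueError, match="line 1"):
        read_intervals(p, "bed3")


def test_unsupported_format_rejected(tmp_path):
    with pytest.raises(ValueError, match="unsupported"):
        write_intervals([], tmp_path / "x", "gff")


@pytest.mark.parametrize("fmt", ["bed3", "bed6", "narrowPeak", "segments"])
def test_round_trip_identity_on_random_records(fmt, tmp_path, rng):
    records = []
    for i in range(50):
        start = int(rng.integers(0, 10_000))
        end = start + int(rng.integers(1, 1000))
        if fmt == "bed3":
            records.append(GenomicInterval("chr1", start, end))
        elif fmt == "segments":
            records.append(GenomicInterval("chr1", start, end, name=f"E{rng.integers(1, 12)}"))
        elif fmt == "bed6":
            records.append(
                GenomicInterval(
                    "chr1", start, end, strand="+-."[rng.integers(3)],
                    name=f"pk{i}", score=float(rng.integers(0, 1000)),
                )
            )
        else:
            records.append(
                GenomicInterval(
                    "chr1", start, end, strand="+-."[rng.integers(3)],
                    name=f"pk{i}", score=float(rng.integers(0, 1000)),
                    signal=float(np.round(rng.uniform(0, 50), 4)),
                    pvalue=float(np.round(rng.uniform(0, 300), 4)),
                    qvalue=float(np.round(rng.uniform(0, 300), 4)),
                    summit=int(rng.integers(-1, end - start)),
                )
            )
    path = tmp_path / f"t.{fmt}"
    write_intervals(records, path, fmt)
    assert read_intervals(path, fmt) == records


def test_narrowpeak_preserves_undetermined_summit(tmp_path):
    iv = GenomicInterval("chr1", 0, 100, name="p", score=1.0, signal=2.0,
                         pvalue=-1.0, qvalue=-1.0, summit=-1)
    path = tmp_path / "p.narrowPeak"
    write_intervals([iv], path, "narrowPeak")
    assert read_intervals(path, "narrowPeak")[0].summit == -1


def test_bed6_none_score_survives_round_trip(tmp_path):
    iv = GenomicInterval("chr1", 0, 10, name="x")
    path = tmp_path / "s.bed"
    write_intervals([iv], path, "bed6")
    assert read_intervals(path, "bed6")[0].score is None


def test_gene_table_round_trip_and_duplicate_detection(tmp_path, rng):
    genes = random_genes(rng, 20)
    path = tmp_path / "genes.tsv"
    write_gene_table(genes, path)
    assert read_gene_table(path) == genes
    with open(path, "a") as fh:
        fh.write("g0000\tchr1\t+\t10\t20\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_gene_table(path)


def test_gtf_one_based_closed_converted_at_boundary(tmp_path):
    p = tmp_path / "g.gtf"
    p.write_text(
        'chr1\tsrc\tgene\t101\t500\t.\t+\t.\tgene_id "gA";\n'
        'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "gA";\n'
        'chr1\tsrc\tgene\t701\t900\t.\t-\t.\tgene_id "gB";\n'
    )
    genes = read_gtf_genes(p)
    assert genes == [
        GeneModel("gA", "chr1", "+", 100, 500),
        GeneModel("gB", "chr1", "-", 700, 900),
    ]
    assert genes[1].tss == 899


def test_bedgraph_round_trip_preserves_binned_values(tmp_path, small_genome):
    rng = np.random.default_rng(3)
    track = SignalTrack.zeros(small_genome, bin_size=200)
    for chrom in track.data:
        track.data[chrom][:] = rng.integers(0, 20, size=len(track.data[chrom]))
    path = tmp_path / "sig.bedgraph"
    track.to_bedgraph(path, small_genome)
    back = SignalTrack.from_bedgraph(path, small_genome, bin_size=200)
    for chrom in track.data:
        np.testing.assert_allclose(back.data[chrom], track.data[chrom])


# ---------------------------------------------------------------------------
# arithmetic


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (("chr1", 0, 10), ("chr1", 5, 20), 5),
        (("chr1", 0, 10), ("chr2", 0, 10), 0),
        (("chr1", 0, 10), ("chr1", 10, 20), 0),  # half-open adjacency
    ],
)
def test_overlap_bp_examples(a, b, expected):
    assert overlap_bp(GenomicInterval(*a), GenomicInterval(*b)) == expected


def test_overlap_bp_symmetric_and_never_negative(rng):
    ivs = random_intervals(rng, 60)
    for a, b in zip(ivs[::2], ivs[1::2]):
        assert overlap_bp(a, b) == overlap_bp(b, a) >= 0


def test_intersect_many_trivial_cases():
    q = [GenomicInterval("chr1", 0, 100)]
    s = [GenomicInterval("chr1", i * 30, i * 30 + 20) for i in range(3)]
    assert [len(h) for h in intersect_many(q, s)] == [3]
    far = [GenomicInterval("chr2", 0, 10)]
    assert intersect_many(q, far) == [[]]


def test_intersect_many_equals_bruteforce_on_random_instances(rng):
    for _ in range(100):
        q = random_intervals(rng, 25, named=True)
        s = random_intervals(rng, 25, named=True)
        fast = intersect_many(q, s)
        for qi, hits in zip(q, fast):
            brute = sorted(
                (x for x in s if overlap_bp(qi, x) > 0),
                key=lambda iv: (iv.start, iv.end, iv.name or ""),
            )
            assert hits == brute


def test_nearest_tss_inside_peak_distance_zero():
    genes = [
        GeneModel("geneA", "chr1", "+", 1100, 2000),
        GeneModel("geneB", "chr1", "+", 5000, 6000),
    ]
    assert nearest_tss(GenomicInterval("chr1", 1000, 1200), genes) == ("geneA", 0)


def test_nearest_tss_signed_distance_from_midpoint():
    genes = [
        GeneModel("gL", "chr1", "+", 900, 1000),
        GeneModel("gR", "chr1", "+", 1400, 1500),
    ]
    # peak midpoint 1100: gL at 900 (|d|=200) beats gR at 1400 (|d|=300)
    assert nearest_tss(GenomicInterval("chr1", 1050, 1150), genes) == ("gL", -200)


def test_nearest_tss_tie_broken_lexicographically():
    genes = [
        GeneModel("gB", "chr1", "+", 1200, 1300),
        GeneModel("gA", "chr1", "+", 800, 1000),  # tss 800, |d|=200 vs gB 1200, |d|=200
    ]
    assert nearest_tss(GenomicInterval("chr1", 950, 1050), genes)[0] == "gA"


def test_nearest_tss_no_gene_on_chromosome_is_unassigned():
    genes = [GeneModel("g1", "chr2", "+", 0, 100)]
    assert nearest_tss(GenomicInterval("chr1", 0, 10), genes) == (None, None)


def test_nearest_tss_matches_exhaustive_search(rng):
    genes = random_genes(rng, 100)
    peaks = random_intervals(rng, 500, max_pos=100_000)
    for p in peaks:
        mid = p.midpoint
        best = None
        for g in genes:
            if g.chrom != p.chrom:
                continue
            d = 0 if p.start <= g.tss < p.end else g.tss - mid
            key = (abs(d), g.gene_id)
            if best is None or key < best[0]:
                best = (key, g.gene_id, d)
        expected = (best[1], best[2]) if best else (None, None)
        assert nearest_tss(p, genes) == expected


def test_nearest_tss_summit_anchor_uses_point_source():
    genes = [
        GeneModel("gL", "chr1", "+", 100, 200),
        GeneModel("gR", "chr1", "+", 1900, 2000),
    ]
    peak = GenomicInterval("chr1", 800, 1300, summit=50)  # summit at 850, midpoint 1050
    assert nearest_tss(peak, genes, anchor="summit")[0] == "gL"
    assert nearest_tss(peak, genes, anchor="midpoint")[0] == "gR"
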