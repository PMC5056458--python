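"""VCF round-trips, site filtering and allele-count extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feralscan.simulate import write_fixture
from feralscan.variant_io import (MISSING, GenomeLayout, SiteTable,
                                  allele_counts, filter_sites, read_bed,
                                  read_gff3, read_variants, write_vcf)


def test_layout_validation():
    with pytest.raises(ValueError):
        GenomeLayout(("chr1", "chr1"), (100, 100))
    with pytest.raises(ValueError):
        GenomeLayout(("chr1",), (0,))
    layout = GenomeLayout(("chr1", "chr2"), (100, 200))
    assert "chr2" in layout and layout.length_of("chr2") == 200


def test_layout_tsv_round_trip(tmp_path):
    layout = GenomeLayout(("chr1", "chr2"), (5_000_000, 4_000_000))
    layout.to_tsv(tmp_path / "len.tsv")
    back = GenomeLayout.from_tsv(tmp_path / "len.tsv")
    assert back == layout


# ---------------------------------------------------------------------------
# VCF round trip with the synthetic fixture
# ---------------------------------------------------------------------------


def test_vcf_round_trip_preserves_table(tmp_path, demo_sim):
    params, _, table = demo_sim[0], demo_sim[1], demo_sim[3]
    paths = write_fixture(params, table, tmp_path)
    layout = params.layout()
    back = read_variants(paths["vcf"], layout,
                         individuals=table.individual_ids,
                         pools=list(table.pools))
    assert back.n_sites == table.n_sites
    pd.testing.assert_frame_equal(back.sites, table.sites)
    np.testing.assert_array_equal(back.genotypes, table.genotypes)
    np.testing.assert_array_equal(back.haplotypes, table.haplotypes)
    for name in table.pools:
        np.testing.assert_array_equal(back.pools[name], table.pools[name])


def _mini_vcf(tmp_path, body):
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=100000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
    )
    path = tmp_path / "mini.vcf"
    path.write_text(header + body)
    return path


def test_multiallelic_records_are_skipped_and_counted(tmp_path):
    body = (
        "chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0|1\t1|1\n"
        "chr1\t200\t.\tA\tC,G\t.\tPASS\t.\tGT\t0|1\t0|2\n"
        "chr1\t300\t.\tA\tC\t.\tPASS\t.\tGT\t0|0\t0|1\n"
    )
    layout = GenomeLayout(("chr1",), (100_000,))
    table = read_variants(_mini_vcf(tmp_path, body), layout)
    assert table.n_sites == 2
    assert table.meta["skipped_multiallelic"] == 1


def test_position_beyond_chromosome_length_raises(tmp_path):
    body = "chr1\t200000\t.\tA\tC\t.\tPASS\t.\tGT\t0|1\t1|1\n"
    layout = GenomeLayout(("chr1",), (100_000,))
    with pytest.raises(ValueError, match="beyond"):
        read_variants(_mini_vcf(tmp_path, body), layout)


def test_empty_vcf_gives_empty_table(tmp_path):
    layout = GenomeLayout(("chr1",), (100_000,))
    table = read_variants(_mini_vcf(tmp_path, ""), layout)
    assert table.n_sites == 0


def test_missing_genotypes_read_as_missing(tmp_path):
    body = "chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t./.\t0|1\n"
    layout = GenomeLayout(("chr1",), (100_000,))
    table = read_variants(_mini_vcf(tmp_path, body), layout)
    assert table.genotypes[0, 0] == MISSING
    assert table.genotypes[0, 1] == 1


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def _pool_only_table(counts):
    counts = np.asarray(counts)
    sites = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(1, len(counts) + 1) * 100,
        "ref": "A", "alt": "C"})
    return SiteTable(sites=sites, pools={"p1": counts.astype(np.int64)})


def _geno_table(genotypes):
    g = np.asarray(genotypes, dtype=np.int8)
    sites = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(1, g.shape[0] + 1) * 100,
        "ref": "A", "alt": "C"})
    ids = tuple(f"i{k}" for k in range(g.shape[1]))
    return SiteTable(sites=sites, individual_ids=ids, genotypes=g)


def test_single_supporting_read_removed():
    table = _pool_only_table([[10, 1], [10, 2], [12, 0]])
    out = filter_sites(table)
    # 1-read and 0-read alt support fail; only the 2-read site survives
    assert out.n_sites == 1
    assert out.sites["pos"].tolist() == [200]


def test_incomplete_genotypes_removed():
    g = np.ones((2, 10), dtype=np.int8)
    g[0, :3] = MISSING  # 7/10 called = 70% < 80%
    out = filter_sites(_geno_table(g))
    assert out.n_sites == 1
    assert out.sites["pos"].tolist() == [200]


def test_all_passing_sites_unchanged(demo_table):
    _, table = demo_table
    again = filter_sites(table)
    assert again.n_sites == table.n_sites
    np.testing.assert_array_equal(again.genotypes, table.genotypes)


@settings(derandomize=True, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_filter_sites_idempotent(seed):
    rng = np.random.default_rng(seed)
    g = rng.integers(-1, 3, size=(30, 10)).astype(np.int8)
    table = _geno_table(g)
    table.pools["p1"] = rng.integers(0, 4, size=(30, 2)).astype(np.int64)
    once = filter_sites(table)
    twice = filter_sites(once)
    assert once.n_sites == twice.n_sites
    np.testing.assert_array_equal(once.genotypes, twice.genotypes)
    np.testing.assert_array_equal(once.pools["p1"], twice.pools["p1"])


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------


def test_allele_counts_homozygous_ref():
    major, minor = allele_counts(_geno_table(np.zeros((1, 10))))
    assert (major[0], minor[0]) == (20, 0)


def test_allele_counts_all_heterozygous():
    major, minor = allele_counts(_geno_table(np.ones((1, 5))))
    assert (major[0], minor[0]) == (5, 5)


def test_allele_counts_match_per_individual_tally(rng):
    g = rng.integers(-1, 3, size=(50, 12)).astype(np.int8)
    major, minor = allele_counts(_geno_table(g))
    for i in range(50):
        alt = sum(int(x) for x in g[i] if x != MISSING)
        ref = sum(2 - int(x) for x in g[i] if x != MISSING)
        assert major[i] == max(ref, alt)
        assert minor[i] == min(ref, alt)
        # conservation: major + minor = 2 x called individuals
        called = sum(1 for x in g[i] if x != MISSING)
        assert major[i] + minor[i] == 2 * called


def test_allele_counts_window_restriction(demo_table):
    _, table = demo_table
    major, minor = allele_counts(table, window=("chr1", 0, 100_000))
    idx = table.window_index("chr1", 0, 100_000)
    assert len(major) == len(idx) > 0


def test_unknown_channel_raises(demo_table):
    _, table = demo_table
    with pytest.raises(KeyError):
        allele_counts(table, channel="pool:nope")


# ---------------------------------------------------------------------------
# interval files
# ---------------------------------------------------------------------------


def test_bed_and_gff_readers(tmp_path):
    bed = tmp_path / "r.bed"
    bed.write_text("chr1\t0\t500\tgeneA\nchr2\t100\t900\tgeneB\n")
    df = read_bed(bed)
    assert df["name"].tolist() == ["geneA", "geneB"]
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t101\t500\t.\t+\t.\tID=g1;Name=GENE1\n"
        "chr1\tsrc\texon\t101\t200\t.\t+\t.\tID=g1.e1\n")
    gdf = read_gff3(gff)
    assert gdf.iloc[0]["name"] == "GENE1"
    assert gdf.iloc[0]["start"] == 100 and gdf.iloc[0]["end"] == 500
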