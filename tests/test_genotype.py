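"""Genotype IO, Hardy-Weinberg testing and gene-window extraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mixge import (
    GeneLocus,
    GenotypeMatrix,
    SnpRecord,
    extract_gene_snps,
    filter_hwe,
    hwe_exact_pvalue,
    read_gene_loci,
    read_genotypes,
)
from mixge.simulate import SimulationConfig, simulate_genotypes, write_dosage_table, write_vcf

from hwe_oracle import hwe_exact_pvalue_oracle


def _matrix(dosages, positions=None, chrom="1"):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = [
        SnpRecord(f"s{j}", chrom, (positions[j] if positions else 100 + j), "A", "G")
        for j in range(m)
    ]
    return GenotypeMatrix([f"i{i}" for i in range(n)], snps, dosages)


# ---------------------------------------------------------------------------
# readers


def test_vcf_gt_and_dosage_fields(tmp_path):
    """GT-only records convert allele counts; DS wins when present."""
    path = tmp_path / "three.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="d">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
        "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\n"
        "1\t200\trs2\tA\tG\t.\tPASS\t.\tGT:DS\t0/0:0.12\t0/1:1.43\n"
        "1\t300\trs3\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\n"  # multi-allelic: skipped
    )
    gm = read_genotypes(str(path))
    # hand-transcribed expectation from the fixture above
    assert gm.snp_ids == ["rs1", "rs2"]
    np.testing.assert_allclose(gm.dosages, [[1.0, 0.12], [2.0, 1.43]], atol=1e-6)
    assert gm.snps[0].call_source == "hard_call"
    assert gm.snps[1].call_source == "dosage"


def test_vcf_region_query_empty(tmp_path):
    gm = simulate_genotypes(SimulationConfig(n_subjects=5, n_snps=4, seed=1))
    path = tmp_path / "g.vcf"
    write_vcf(gm, str(path))
    empty = read_genotypes(str(path), region=("1", 1, 99))
    assert empty.n_snps == 0 and empty.n_subjects == 5


def test_dosage_table_roundtrip(tmp_path):
    gm = simulate_genotypes(
        SimulationConfig(n_subjects=12, n_snps=6, seed=2, dosage_jitter_sd=0.05)
    )
    path = tmp_path / "d.csv"
    write_dosage_table(gm, str(path))
    back = read_genotypes(str(path))
    np.testing.assert_allclose(back.dosages, gm.dosages, atol=1e-12)
    assert back.subject_ids == gm.subject_ids


def test_vcf_roundtrip_with_missing(tmp_path):
    gm = _matrix([[0, 1], [np.nan, 2], [1, 0]])
    path = tmp_path / "m.vcf"
    write_vcf(gm, str(path))
    back = read_genotypes(str(path))
    assert np.isnan(back.dosages[1, 0])
    np.testing.assert_allclose(back.dosages[0], [0, 1])


def test_unreadable_file_errors():
    with pytest.raises(Exception):
        read_genotypes("/nonexistent/file.vcf")


def test_bed_loci_converted_to_1_based(tmp_path):
    path = tmp_path / "genes.bed"
    path.write_text("chr1\t999\t2000\tTGFBR1\n")
    (locus,) = read_gene_loci(str(path))
    assert (locus.start, locus.end) == (1000, 2000)
    csv = tmp_path / "genes.csv"
    csv.write_text("chr1,1000,2000,TGFBR1\n")
    (locus2,) = read_gene_loci(str(csv))
    assert (locus2.start, locus2.end) == (1000, 2000)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def test_hwe_monomorphic_is_one():
    assert hwe_exact_pvalue(25, 0, 0) == 1.0
    assert hwe_exact_pvalue(0, 0, 7) == 1.0


@pytest.mark.parametrize(
    "counts",
    [(25, 50, 25), (5, 1, 5), (3, 10, 2), (0, 5, 95), (40, 20, 40), (1, 1, 1)],
)
def test_hwe_matches_enumeration_oracle(counts):
    assert hwe_exact_pvalue(*counts) == pytest.approx(
        hwe_exact_pvalue_oracle(*counts), abs=1e-12
    )


def test_hwe_het_deficit_is_small():
    assert hwe_exact_pvalue(5, 1, 5) < 0.02


def test_hwe_rejects_all_zero():
    with pytest.raises(ValueError):
        hwe_exact_pvalue(0, 0, 0)


@given(
    st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
)
def test_hwe_allele_label_symmetry(a, h, b):
    if a + h + b == 0:
        return
    assert hwe_exact_pvalue(a, h, b) == pytest.approx(
        hwe_exact_pvalue(b, h, a), abs=1e-12
    )
    p = hwe_exact_pvalue(a, h, b)
    assert 0 < p <= 1


# ---------------------------------------------------------------------------
# gene windows


def test_extract_flank_boundaries():
    gm = _matrix(np.zeros((3, 4)), positions=[999, 1000, 3000, 3001])
    locus = GeneLocus("g", "1", 1000, 2000, flank_bp=1000)
    out = extract_gene_snps(gm, locus)
    assert out.snp_ids == ["s0", "s1", "s2"]  # 3001 excluded, 999 included


def test_extract_preserves_order_and_counts():
    rng = np.random.default_rng(0)
    positions = [100, 500, 1500, 2500, 3500, 5000, 7000, 9000, 9500, 12000]
    gm = _matrix(rng.integers(0, 3, size=(5, 10)), positions=positions)
    locus = GeneLocus("g", "1", 1400, 9000, flank_bp=100)
    out = extract_gene_snps(gm, locus)
    # hand count: positions within [1300, 9100] -> 1500, 2500, 3500, 5000, 7000, 9000
    assert out.snp_ids == ["s2", "s3", "s4", "s5", "s6", "s7"]


def test_extract_idempotent():
    gm = _matrix(np.zeros((3, 5)), positions=[10, 600, 1200, 1900, 4000])
    locus = GeneLocus("g", "1", 500, 2000, flank_bp=200)
    once = extract_gene_snps(gm, locus)
    twice = extract_gene_snps(once, locus)
    assert twice.snp_ids == once.snp_ids


def test_extract_chrom_mismatch_returns_empty():
    gm = _matrix(np.zeros((2, 3)), chrom="2")
    out = extract_gene_snps(gm, GeneLocus("g", "1", 1, 1000))
    assert out.n_snps == 0


# ---------------------------------------------------------------------------
# HWE filter


def test_filter_keeps_hwe_proportions():
    rng = np.random.default_rng(1)
    gm = simulate_genotypes(SimulationConfig(n_subjects=200, n_snps=40, seed=3))
    kept, report = filter_hwe(gm)
    assert kept.n_snps == 40
    assert report["kept"].all()


def test_filter_removes_extreme_het_deficit():
    rng = np.random.default_rng(2)
    cfg = SimulationConfig(n_subjects=100, n_snps=100, seed=4)
    gm = simulate_genotypes(cfg)
    bad = np.concatenate([np.zeros(50), np.full(50, 2.0)])
    rng.shuffle(bad)
    dosages = np.column_stack([gm.dosages, bad])
    snps = gm.snps + [SnpRecord("bad", "1", 99_999, "A", "G")]
    gm2 = GenotypeMatrix(gm.subject_ids, snps, dosages)
    kept, report = filter_hwe(gm2, alpha=0.05, correction="bonferroni")
    assert "bad" not in kept.snp_ids
    # its Bonferroni-corrected p stays far below alpha even across 101 tests
    assert report.loc[report.snp_id == "bad", "hwe_p_adj"].item() < 0.05


def test_filter_removes_monomorphic():
    gm = _matrix(np.column_stack([np.zeros(20), np.random.default_rng(5).integers(0, 3, 20)]))
    kept, report = filter_hwe(gm)
    assert "s0" not in kept.snp_ids
    assert report.loc[report.snp_id == "s0", "monomorphic"].item()


def test_filter_hwe_calibration_under_hwe():
    """SNPs simulated in HWE are essentially never removed (Bonferroni 0.05).

    Bonferroni bounds the family-wise false-removal rate by alpha, so
    the per-SNP removal fraction is far below alpha/m and most replicate
    matrices lose nothing at all.
    """
    removed = []
    for rep in range(200):
        gm = simulate_genotypes(SimulationConfig(n_subjects=80, n_snps=20, seed=1000 + rep))
        kept, _ = filter_hwe(gm)
        removed.append(gm.n_snps - kept.n_snps)
    removed = np.array(removed)
    assert removed.sum() / (200 * 20) < 0.005  # per-SNP removal fraction
    assert np.mean(removed > 0) <= 0.05  # family-wise, guaranteed by Bonferroni


def test_missingness_policy():
    rng = np.random.default_rng(6)
    d = rng.integers(0, 3, size=(50, 2)).astype(float)
    d[:20, 1] = np.nan  # 40% missing -> dropped
    d[0, 0] = np.nan  # 2% missing -> mean-imputed
    gm = _matrix(d)
    imputed, keep = gm.imputed_dosages()
    assert list(keep) == [True, False]
    assert imputed[0, 0] == pytest.approx(np.nanmean(d[:, 0]))
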