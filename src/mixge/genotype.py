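"""Genotype input, Hardy-Weinberg filtering and per-gene SNP extraction.

Genotypes are represented as alt-allele dosages in [0, 2] (possibly
fractional after imputation) in a subjects x SNPs matrix, together with
per-SNP metadata.  Gene windows are 1-based inclusive with a flanking
margin (default 1 kb) on either side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "SnpRecord",
    "GenotypeMatrix",
    "GeneLocus",
    "read_genotypes",
    "read_gene_loci",
    "hwe_exact_pvalue",
    "hwe_het_log_probs",
    "extract_gene_snps",
    "filter_hwe",
]


@dataclass(frozen=True)
class SnpRecord:
    """Metadata for one biallelic SNP."""

    snp_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    maf: float = float("nan")
    call_source: str = "hard_call"  # or "dosage"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: pos must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.snp_id}: ref and alt alleles identical")


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs dosage matrix with SNP metadata.

    ``dosages[i, j]`` is the expected alt-allele count for subject i at
    SNP j, in [0, 2]; missing entries are NaN.  Column order matches
    ``snps``.
    """

    subject_ids: list[str]
    snps: list[SnpRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape if self.dosages.ndim == 2 else (len(self.subject_ids), 0)
        if self.dosages.ndim != 2:
            self.dosages = self.dosages.reshape(n, m)
        if n != len(self.subject_ids) or m != len(self.snps):
            raise ValueError("dosage matrix shape does not match subject/SNP lists")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicated subject ids")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != m:
            raise ValueError("duplicated SNP ids")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def select_snps(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            subject_ids=list(self.subject_ids),
            snps=[self.snps[j] for j in idx],
            dosages=self.dosages[:, idx],
        )

    def select_subjects(self, ids: list[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [lookup[s] for s in ids]
        return GenotypeMatrix(
            subject_ids=list(ids),
            snps=list(self.snps),
            dosages=self.dosages[rows, :],
        )

    def imputed_dosages(self, max_missing: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
        """Mean-impute missing dosages per SNP.

        Returns (imputed matrix, boolean keep-mask of SNPs with missingness
        <= max_missing).  The per-SNP mean equals 2 x allele frequency.
        """
        d = self.dosages.copy()
        miss = np.isnan(d)
        keep = miss.mean(axis=0) <= max_missing
        col_mean = np.nanmean(np.where(miss, np.nan, d), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(miss)
        d[idx] = col_mean[idx[1]]
        return d, keep


@dataclass(frozen=True)
class GeneLocus:
    """A gene's genomic interval (1-based inclusive) plus flanking margin."""

    gene_name: str
    chrom: str
    start: int
    end: int
    flank_bp: int = 1000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_name}: start > end")
        if self.flank_bp < 0:
            raise ValueError(f"{self.gene_name}: negative flank")


# ---------------------------------------------------------------------------
# readers


def _read_vcf(path: str, region: tuple[str, int, int] | None) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    subjects = list(vcf.samples)
    if not subjects:
        raise ValueError(f"{path}: VCF has no samples")
    snps: list[SnpRecord] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if region is not None:
            chrom, start, end = region
            if var.CHROM != chrom or not (start <= var.POS <= end):
                continue
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic record %s:%d", var.CHROM, var.POS)
            continue
        ds = None
        try:
            raw = var.format("DS")
        except KeyError:
            raw = None
        if raw is not None:
            ds = np.asarray(raw, dtype=float).reshape(-1)
            ds = np.where((ds < 0) | (ds > 2), np.nan, ds)
            source = "dosage"
        if ds is None:
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = np.asarray(var.gt_types, dtype=float)
            ds = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
            source = "hard_call"
        af = float(np.nanmean(ds) / 2.0) if np.isfinite(ds).any() else float("nan")
        maf = min(af, 1.0 - af) if math.isfinite(af) else float("nan")
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snps.append(
            SnpRecord(vid, var.CHROM, var.POS, var.REF, var.ALT[0], maf, source)
        )
        cols.append(ds)
    dosages = np.column_stack(cols) if cols else np.empty((len(subjects), 0))
    return GenotypeMatrix(subjects, snps, dosages)


def _read_dosage_table(
    path: str, snp_meta: pd.DataFrame | None, region: tuple[str, int, int] | None
) -> GenotypeMatrix:
    df = pd.read_csv(path)
    if df.shape[1] < 1 or df.columns[0] != "subject_id":
        raise ValueError(f"{path}: dosage table must start with a subject_id column")
    subjects = df["subject_id"].astype(str).tolist()
    if not subjects:
        raise ValueError(f"{path}: no subjects")
    snp_ids = list(df.columns[1:])
    meta: dict[str, tuple[str, int, str, str]] = {}
    if snp_meta is not None:
        for row in snp_meta.itertuples(index=False):
            meta[str(row.snp_id)] = (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
    snps = []
    for j, sid in enumerate(snp_ids):
        chrom, pos, ref, alt = meta.get(sid, ("0", j + 1, "A", "B"))
        snps.append(SnpRecord(sid, chrom, pos, ref, alt, call_source="dosage"))
    dosages = df[snp_ids].to_numpy(dtype=float)
    af = np.nanmean(dosages, axis=0) / 2.0
    snps = [
        replace(s, maf=float(min(a, 1 - a)) if math.isfinite(a) else float("nan"))
        for s, a in zip(snps, af)
    ]
    gm = GenotypeMatrix(subjects, snps, dosages)
    if region is not None:
        chrom, start, end = region
        keep = [
            j for j, s in enumerate(gm.snps) if s.chrom == chrom and start <= s.pos <= end
        ]
        gm = gm.select_snps(keep)
    return gm


def read_genotypes(
    path: str,
    region: tuple[str, int, int] | None = None,
    snp_meta: str | pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Read genotype dosages from a VCF or a plain dosage table.

    VCF records use the DS (dosage) FORMAT field when present, else GT
    hard calls converted to alt-allele counts; multi-allelic records are
    skipped with a warning.  Plain tables are CSV with a ``subject_id``
    first column and one column per SNP, values in [0, 2] or empty/NA;
    SNP positions are taken from an optional metadata table
    (snp_id, chrom, pos, ref, alt) and otherwise synthesized as
    chrom "0", pos = column index.

    ``region`` is (chrom, start, end), 1-based inclusive; a region with
    no records yields a matrix with zero SNPs.
    """
    p = str(path)
    if isinstance(snp_meta, str):
        snp_meta = pd.read_csv(snp_meta)
    if p.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _read_vcf(p, region)
    return _read_dosage_table(p, snp_meta, region)


def read_gene_loci(path: str, flank_bp: int = 1000, bed: bool | None = None) -> list[GeneLocus]:
    """Read gene loci from a 4-column table (chrom, start, end, name).

    Files ending in ``.bed`` (or with ``bed=True``) are treated as 0-based
    half-open and converted to 1-based inclusive; otherwise coordinates
    are taken as 1-based inclusive already.
    """
    if bed is None:
        bed = str(path).endswith(".bed")
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     names=["chrom", "start", "end", "name"], comment="#")
    loci = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if bed:
            start, end = start + 1, end
        loci.append(GeneLocus(str(row.name), str(row.chrom), start, end, flank_bp))
    return loci


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_het_log_probs(n_total: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional probabilities of heterozygote counts.

    Given ``n_total`` diploid genotypes and ``n_a`` copies of the A allele
    (out of 2*n_total), the heterozygote count under Hardy-Weinberg
    proportions follows the exact conditional distribution

        P(n_Aa | n_a) = n! / (n_AA! n_Aa! n_aa!) * 2^n_Aa / C(2n, n_a)-form,

    supported on het counts with the parity of ``n_a`` from
    max(0, n_a - n_total)... min(n_a, 2*n_total - n_a).  Returns
    (het_counts, log probabilities), computed in log space.
    """
    n_b = 2 * n_total - n_a
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    n_aa_ = (n_a - hets) // 2
    n_bb_ = (n_b - hets) // 2
    logp = (
        gammaln(n_total + 1)
        - gammaln(n_aa_ + 1)
        - gammaln(hets + 1)
        - gammaln(n_bb_ + 1)
        + hets * math.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n_total + 1)
    )
    # normalize for numerical safety; the formula is already a distribution
    logp -= _logsumexp(logp)
    return hets, logp


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    return float(m + np.log(np.sum(np.exp(x - m))))


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts compatible with the observed
    allele counts, the conditional probabilities that do not exceed the
    probability of the observed heterozygote count.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_AA + n_Aa
    hets, logp = hwe_het_log_probs(n, n_a)
    obs = np.searchsorted(hets, n_Aa)
    if obs >= len(hets) or hets[obs] != n_Aa:
        raise ValueError("observed het count incompatible with allele counts")
    # tolerance on the log scale guards ties against round-off
    mask = logp <= logp[obs] + 1e-10
    p = float(np.exp(_logsumexp(logp[mask])))
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# extraction and filtering


def extract_gene_snps(matrix: GenotypeMatrix, locus: GeneLocus) -> GenotypeMatrix:
    """Column subset of SNPs inside the locus window extended by the flank.

    Keeps SNPs with start - flank <= pos <= end + flank on the locus
    chromosome, in the original column order.  A chromosome mismatch for
    every SNP yields an empty matrix with a warning.
    """
    lo = max(1, locus.start - locus.flank_bp)
    hi = locus.end + locus.flank_bp
    on_chrom = [j for j, s in enumerate(matrix.snps) if s.chrom == locus.chrom]
    if matrix.n_snps and not on_chrom:
        logger.warning(
            "no SNPs on chromosome %s for gene %s", locus.chrom, locus.gene_name
        )
    keep = [j for j in on_chrom if lo <= matrix.snps[j].pos <= hi]
    return matrix.select_snps(keep)


def _hard_call_counts(dosages: np.ndarray) -> np.ndarray:
    """Genotype counts (n0, n1, n2) per SNP after rounding dosages.

    Ties (x.5) round half up; missing entries are ignored.
    """
    d = np.floor(dosages + 0.5)
    counts = np.empty((dosages.shape[1], 3), dtype=int)
    for g in (0, 1, 2):
        counts[:, g] = np.nansum(d == g, axis=0)
    return counts


def filter_hwe(
    matrix: GenotypeMatrix,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    max_missing: float = 0.10,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the Hardy-Weinberg filter across the SNPs of a matrix.

    Dosages are rounded to hard calls for counting; SNPs whose
    multiplicity-corrected exact-test p-value falls below ``alpha`` are
    removed, as are monomorphic SNPs and SNPs with more than
    ``max_missing`` missingness.  Correction is Bonferroni (default) or
    Benjamini-Hochberg, applied across the SNPs of this matrix.

    Returns the filtered matrix and a per-SNP report with columns
    snp_id, hwe_p, hwe_p_adj, monomorphic, high_missing, kept.
    """
    if correction not in ("bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    m = matrix.n_snps
    if m == 0:
        return matrix, pd.DataFrame(
            columns=["snp_id", "hwe_p", "hwe_p_adj", "monomorphic", "high_missing", "kept"]
        )
    miss_frac = np.isnan(matrix.dosages).mean(axis=0)
    counts = _hard_call_counts(matrix.dosages)
    pvals = np.ones(m)
    mono = np.zeros(m, dtype=bool)
    for j in range(m):
        n0, n1, n2 = counts[j]
        total = n0 + n1 + n2
        if total == 0:
            mono[j] = True
            continue
        if n1 == 0 and (n0 == 0 or n2 == 0):
            mono[j] = True
        pvals[j] = hwe_exact_pvalue(n0, n1, n2)
    if correction == "bonferroni":
        p_adj = np.minimum(pvals * m, 1.0)
    else:
        p_adj = _bh_adjust(pvals)
    high_miss = miss_frac > max_missing
    kept = (p_adj >= alpha) & ~mono & ~high_miss
    report = pd.DataFrame(
        {
            "snp_id": matrix.snp_ids,
            "hwe_p": pvals,
            "hwe_p_adj": p_adj,
            "monomorphic": mono,
            "high_missing": high_miss,
            "kept": kept,
        }
    )
    return matrix.select_snps(np.where(kept)[0]), report


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
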