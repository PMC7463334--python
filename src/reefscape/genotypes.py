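"""Genotype matrices: VCF I/O, quality filters, LD pruning, population
structure covariates, and Weir & Cockerham (1984) F_ST.

Genotypes are biallelic SNPs coded as alternate-allele dosage 0/1/2 with -1
for missing.  Multi-locus F_ST is the ratio-of-sums of the WC84 variance
components (sum of a over loci divided by sum of a+b+c), the convention of
hierfstat and most population-genetic software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with site assignments.

    ``codes``: int8 array (n_individuals, n_snps), values in {0, 1, 2, -1}.
    ``individuals``: DataFrame with columns id, site, lon, lat.
    ``snps``: DataFrame with columns scaffold, pos (1-based), ref, alt.
    """

    codes: np.ndarray
    individuals: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x snps)")
        if self.codes.shape != (len(self.individuals), len(self.snps)):
            raise ValueError("codes shape does not match individual/snp tables")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or -1 (missing)")
        if (self.individuals["site"].astype(str) == "").any():
            raise ValueError("site labels must be non-empty")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def sites(self) -> np.ndarray:
        return self.individuals["site"].to_numpy()

    def snp_ids(self) -> np.ndarray:
        return (
            self.snps["scaffold"].astype(str) + ":" + self.snps["pos"].astype(str)
        ).to_numpy()

    def dosage(self) -> np.ndarray:
        """Float dosage with NaN for missing."""
        d = self.codes.astype(float)
        d[self.codes == MISSING] = np.nan
        return d

    def subset(self, ind_idx=None, snp_idx=None) -> "GenotypeMatrix":
        ind_idx = np.arange(self.n_individuals) if ind_idx is None else np.asarray(ind_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            codes=self.codes[np.ix_(ind_idx, snp_idx)],
            individuals=self.individuals.iloc[ind_idx].reset_index(drop=True),
            snps=self.snps.iloc[snp_idx].reset_index(drop=True),
        )

    # ---------------------------------------------------------------- I/O
    def to_vcf(self, path: str) -> None:
        """Write a minimal VCF 4.2 with GT-only genotype fields."""
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.individuals["id"].astype(str))
                + "\n"
            )
            for j in range(self.n_snps):
                rec = self.snps.iloc[j]
                gts = "\t".join(gt_strings[int(g)] for g in self.codes[:, j])
                fh.write(
                    f"{rec['scaffold']}\t{rec['pos']}\t.\t{rec.get('ref', 'A')}\t"
                    f"{rec.get('alt', 'T')}\t.\tPASS\t.\tGT\t{gts}\n"
                )

    @classmethod
    def from_vcf(cls, path: str, sites: pd.DataFrame) -> "GenotypeMatrix":
        """Read biallelic SNPs from a VCF; non-biallelic records are skipped.

        ``sites``: DataFrame with columns id, site, lon, lat covering every
        sample in the VCF.
        """
        from cyvcf2 import VCF

        vcf = VCF(path)
        samples = list(vcf.samples)
        site_map = sites.set_index("id")
        missing_ids = [s for s in samples if s not in site_map.index]
        if missing_ids:
            raise ValueError(f"samples without site assignment: {missing_ids[:5]}")
        rows, meta, n_skipped = [], [], 0
        for rec in vcf:
            if len(rec.ALT) != 1 or not rec.is_snp:
                n_skipped += 1
                continue
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = rec.gt_types
            codes = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
            rows.append(codes.astype(np.int8))
            meta.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        if n_skipped:
            logger.info("skipped %d non-biallelic/non-SNP records", n_skipped)
        codes = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), np.int8)
        individuals = site_map.loc[samples].reset_index()
        snps = pd.DataFrame(meta, columns=["scaffold", "pos", "ref", "alt"])
        return cls(codes=codes, individuals=individuals, snps=snps)


# -------------------------------------------------------------- filtering
def filter_snps(
    matrix: GenotypeMatrix,
    maf: float = 0.05,
    major_geno: float = 0.95,
    miss: float = 0.1,
) -> GenotypeMatrix:
    """Quality-filter a genotype matrix.

    Drops individuals with missing rate >= ``miss``, then SNPs with missing
    rate >= ``miss``, minor allele frequency <= ``maf``, or most frequent
    genotype class at frequency >= ``major_geno``.  Returns the filtered
    matrix; per-step counts are logged.
    """
    miss_ind = (matrix.codes == MISSING).mean(axis=1)
    keep_ind = np.flatnonzero(miss_ind < miss)
    m = matrix.subset(ind_idx=keep_ind)
    logger.info("individual filter: %d -> %d", matrix.n_individuals, m.n_individuals)

    d = m.dosage()
    with np.errstate(invalid="ignore"):
        miss_snp = np.isnan(d).mean(axis=0)
        n_called = (~np.isnan(d)).sum(axis=0)
        p_alt = np.nansum(d, axis=0) / np.maximum(2 * n_called, 1)
        maf_v = np.minimum(p_alt, 1 - p_alt)
        geno_counts = np.stack([(m.codes == g).sum(axis=0) for g in (0, 1, 2)])
        major = geno_counts.max(axis=0) / np.maximum(n_called, 1)
    keep = (miss_snp < miss) & (maf_v > maf) & (major < major_geno) & (n_called > 0)
    logger.info(
        "snp filter: %d -> %d (miss %d, maf %d, major-genotype %d)",
        m.n_snps,
        int(keep.sum()),
        int((miss_snp >= miss).sum()),
        int((maf_v <= maf).sum()),
        int((major >= major_geno).sum()),
    )
    out = m.subset(snp_idx=np.flatnonzero(keep))
    if out.n_snps == 0 or out.n_individuals == 0:
        raise ValueError("filtering removed all SNPs or all individuals")
    return out


def ld_prune(matrix: GenotypeMatrix, r2: float = 0.3, window_snps: int = 50) -> GenotypeMatrix:
    """Greedy LD pruning on squared Pearson correlation of dosages.

    SNPs are visited in (scaffold, position) order; a SNP is dropped when its
    pairwise-complete r^2 with any *kept* SNP among the previous
    ``window_snps`` kept SNPs on the same scaffold exceeds the threshold
    (first-kept-wins).
    """
    order = np.lexsort((matrix.snps["pos"].to_numpy(), matrix.snps["scaffold"].to_numpy()))
    m = matrix.subset(snp_idx=order)
    d = m.dosage()
    scaffolds = m.snps["scaffold"].to_numpy()
    kept: list[int] = []
    kept_scaffold: list[str] = []
    for j in range(m.n_snps):
        drop = False
        window = [
            k for k, s in zip(kept[-window_snps:], kept_scaffold[-window_snps:])
            if s == scaffolds[j]
        ]
        for k in window:
            if _pairwise_r2(d[:, k], d[:, j]) > r2:
                drop = True
                break
        if not drop:
            kept.append(j)
            kept_scaffold.append(scaffolds[j])
    return m.subset(snp_idx=np.array(kept, dtype=int))


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


# ----------------------------------------------- population structure axis
def structure_covariate(
    matrix: GenotypeMatrix, method: str = "pca", k: int = 1, csv_path: str | None = None
) -> np.ndarray:
    """Per-individual population-structure covariate(s), shape (n, k).

    Default is the leading principal axes of the centered dosage matrix
    (missing imputed to the locus mean), standing in for the first
    discriminant function a DAPC would supply; ``method='csv'`` loads an
    externally computed covariate instead (passed through unchanged).
    """
    if method == "csv":
        if csv_path is None:
            raise ValueError("csv method requires csv_path")
        df = pd.read_csv(csv_path)
        cov = df.set_index(df.columns[0]).loc[matrix.individuals["id"]].to_numpy(float)
        return cov[:, :k]
    if method != "pca":
        raise ValueError(f"unknown method {method!r}")
    if k >= matrix.n_individuals:
        raise ValueError("k must be smaller than the number of individuals")
    d = matrix.dosage()
    mu = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), mu, d) - mu
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    if np.any(s[:k] < 1e-10):
        logger.warning("zero-variance structure axis among the leading %d", k)
    return u[:, :k] * s[:k]


# --------------------------------------------------------------- WC84 FST
def wc_fst_components(
    codes: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir & Cockerham (1984) variance components (a, b, c).

    ``codes``: (n, L) dosage codes with -1 missing; ``groups``: length-n
    population labels.  Components are computed from the alternate allele
    (the estimator is invariant to the choice).  Loci with fewer than two
    populations called, or monomorphic loci, contribute (0, 0, 0).
    """
    labels = np.unique(groups)
    r_max = len(labels)
    n_il = np.zeros((r_max, codes.shape[1]))  # individuals called
    p_il = np.zeros((r_max, codes.shape[1]))  # alt allele freq
    h_il = np.zeros((r_max, codes.shape[1]))  # het proportion
    for i, g in enumerate(labels):
        sub = codes[groups == g]
        called = sub != MISSING
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(sub == MISSING, 0, sub).sum(axis=0) / np.maximum(2 * n, 1)
            h = (sub == 1).sum(axis=0) / np.maximum(n, 1)
        n_il[i], p_il[i], h_il[i] = n, p, h

    present = n_il > 0
    r = present.sum(axis=0).astype(float)
    valid = r >= 2
    n_sum = n_il.sum(axis=0)
    nbar = n_sum / np.maximum(r, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_sum - (n_il**2).sum(axis=0) / np.maximum(n_sum, 1)) / np.maximum(r - 1, 1)
        pbar = (n_il * p_il).sum(axis=0) / np.maximum(n_sum, 1)
        s2 = (n_il * (p_il - pbar) ** 2 * present).sum(axis=0) / np.maximum(
            (r - 1) * nbar, 1e-300
        )
        hbar = (n_il * h_il).sum(axis=0) / np.maximum(n_sum, 1)
        a = (nbar / np.maximum(nc, 1e-300)) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / np.maximum(nbar - 1, 1e-300)
        )
        b = (nbar / np.maximum(nbar - 1, 1e-300)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    a = np.where(valid, a, 0.0)
    b = np.where(valid, b, 0.0)
    c = np.where(valid, c, 0.0)
    return a, b, c


def multilocus_fst(codes: np.ndarray, groups: np.ndarray) -> float:
    """Multi-locus WC84 theta: sum(a) / sum(a + b + c) across loci."""
    a, b, c = wc_fst_components(codes, groups)
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError("no variable loci callable in the grouping")
    return float(a.sum() / denom)


def pairwise_fst(
    matrix: GenotypeMatrix, min_n: int = 10, clamp_negative: bool = False
) -> pd.DataFrame:
    """Pairwise multi-locus WC84 F_ST between sites with more than ``min_n``
    genotyped individuals (strict inequality, configurable via ``min_n``).

    Returns a table with lexicographically ordered pairs and per-site sample
    sizes; negative estimates are preserved unless ``clamp_negative``.
    """
    counts = matrix.individuals["site"].value_counts()
    eligible = sorted(counts.index[counts > min_n])
    if len(eligible) < 2:
        raise ValueError(
            f"need at least 2 sites with more than {min_n} samples; found {len(eligible)}"
        )
    sites = matrix.sites
    rows = []
    for i, s1 in enumerate(eligible):
        for s2 in eligible[i + 1:]:
            sel = np.flatnonzero((sites == s1) | (sites == s2))
            theta = multilocus_fst(matrix.codes[sel], sites[sel])
            if clamp_negative:
                theta = max(theta, 0.0)
            rows.append((s1, s2, theta, int(counts[s1]), int(counts[s2])))
    return pd.DataFrame(rows, columns=["site1", "site2", "fst", "n1", "n2"])


def fst_scan(
    matrix: GenotypeMatrix, groups: np.ndarray | None = None, window_kb: float = 100.0
) -> pd.DataFrame:
    """Per-SNP WC84 F_ST plus a sliding-window mean along each scaffold.

    Flags candidate low-recombination islands as runs of elevated
    windowed F_ST.  ``groups`` defaults to the matrix site labels.
    """
    if groups is None:
        groups = matrix.sites
    if len(np.unique(groups)) < 2:
        raise ValueError("fst_scan needs at least two populations")
    a, b, c = wc_fst_components(matrix.codes, np.asarray(groups))
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snp = np.where(a + b + c != 0, a / (a + b + c), np.nan)
    out = matrix.snps[["scaffold", "pos"]].copy()
    out["fst"] = per_snp
    win = np.full(len(out), np.nan)
    half = window_kb * 1000 / 2
    for scaf, idx in out.groupby("scaffold").groups.items():
        idx = np.asarray(idx)
        pos = out.loc[idx, "pos"].to_numpy(float)
        f = out.loc[idx, "fst"].to_numpy()
        for j, p0 in enumerate(pos):
            sel = np.abs(pos - p0) <= half
            vals = f[sel]
            win[idx[j]] = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
    out["fst_window"] = win
    return out
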