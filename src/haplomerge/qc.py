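"""Pre-phasing quality-control battery.

Site filters: per-wave and merged missingness, case/control differential
missingness (2x2 Pearson chi-square, BH-FDR), Hardy-Weinberg in controls
(1-df chi-square, BH-FDR), the order-statistic minimum-p batch-artifact scan
across genotyping waves, and minor-allele-frequency censoring.

Sample filters: overall missingness, abnormal (ancestry-adjusted)
heterozygosity, Mahalanobis homogeneous-subset selection on principal
components, and a genotype-correlation duplicate/relatedness screen.

Comparators are strict (">" to exclude on missingness, "<" to censor on MAF)
and exposed where ambiguity matters.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import MISSING, CohortDataset

__all__ = [
    "QCThresholds", "FilterResult", "QCReport",
    "snp_missingness_filter", "differential_missingness_test", "hwe_test",
    "minp_null_cdf", "minp_theoretical_quantiles", "batch_artifact_scan",
    "maf_censor", "pca", "heterozygosity", "runs_of_homozygosity",
    "ancestry_adjusted_heterozygosity", "homogeneous_subset",
    "kinship_matrix", "duplicate_and_relatedness_filter",
    "sample_missingness_filter", "bh_adjust",
]


@dataclass
class QCThresholds:
    """Exclusion thresholds for the full battery (defaults used throughout)."""

    snp_missing_max: float = 0.05
    diffmiss_fdr: float = 0.2
    hwe_fdr: float = 0.2
    batch_fdr: float = 0.1
    maf_min: float = 0.001
    het_sd: float = 4.0
    mahalanobis_p: float = 5.73e-7
    sample_missing_max: float = 0.05
    kinship_max: float = 0.0825
    duplicate_kinship: float = 0.45

    def __post_init__(self) -> None:
        for name in ("snp_missing_max", "diffmiss_fdr", "hwe_fdr", "batch_fdr",
                     "maf_min", "mahalanobis_p", "sample_missing_max",
                     "kinship_max", "duplicate_kinship"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of range: {v}")
        if self.het_sd <= 0:
            raise ValueError("het_sd must be positive")


@dataclass
class FilterResult:
    """Outcome of one filter: what was tested, what was excluded, and why."""

    name: str
    kind: str                      # "site" or "sample"
    n_tested: int
    excluded: np.ndarray           # site indices (panel) or sample ids
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


@dataclass
class QCReport:
    """Ordered log of applied filters."""

    results: list = field(default_factory=list)

    def add(self, result: FilterResult) -> None:
        self.results.append(result)

    def excluded_sites(self) -> np.ndarray:
        out = [r.excluded for r in self.results if r.kind == "site"]
        return np.unique(np.concatenate(out)) if out else np.array([], dtype=np.int64)

    def excluded_samples(self) -> np.ndarray:
        out = [np.asarray(r.excluded) for r in self.results if r.kind == "sample"]
        return np.unique(np.concatenate(out)) if out else np.array([], dtype=object)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"filter": r.name, "kind": r.kind, "n_tested": r.n_tested,
                 "n_excluded": r.n_excluded} for r in self.results]
        return pd.DataFrame(rows)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _missing_fraction(geno: np.ndarray) -> np.ndarray:
    return (geno == MISSING).mean(axis=0) if geno.shape[0] else np.zeros(geno.shape[1])


def snp_missingness_filter(cohort: CohortDataset, threshold: float = 0.05) -> FilterResult:
    """Exclude sites missing in > threshold of samples in any single wave or overall."""
    waves = cohort.samples["wave"].to_numpy()
    geno = cohort.genotypes
    per_wave = []
    for wv in np.unique(waves):
        rows = waves == wv
        if not rows.any():
            raise ValueError(f"empty wave {wv}")
        per_wave.append(_missing_fraction(geno[rows]))
    wave_max = np.max(per_wave, axis=0)
    merged = _missing_fraction(geno)
    bad = (wave_max > threshold) | (merged > threshold)
    table = pd.DataFrame({
        "site": cohort.site_indices,
        "max_wave_missing": wave_max,
        "merged_missing": merged,
        "excluded": bad,
    })
    return FilterResult("snp_missingness", "site", cohort.n_sites,
                        cohort.site_indices[bad], table)


def _chi2_2x2(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vectorized Pearson chi-square for 2x2 tables [[a,b],[c,d]], no continuity."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    return chi2


def differential_missingness_test(cohort: CohortDataset,
                                  fdr_threshold: float = 0.2,
                                  case_flags: np.ndarray | None = None,
                                  method: str = "chi2") -> FilterResult:
    """Per-site 2x2 (missing/observed x case/control) test with BH-FDR.

    ``method="chi2"`` (default) is the Pearson chi-square without continuity
    correction; ``method="fisher"`` uses Fisher's exact test (slower, exact
    at small counts).
    """
    if case_flags is None:
        case_flags = cohort.samples["case"].to_numpy(dtype=bool)
    if case_flags.all() or not case_flags.any():
        raise ValueError("need both cases and controls")
    geno = cohort.genotypes
    miss = geno == MISSING
    m_case = miss[case_flags].sum(axis=0)
    o_case = case_flags.sum() - m_case
    m_ctrl = miss[~case_flags].sum(axis=0)
    o_ctrl = (~case_flags).sum() - m_ctrl
    chi2 = _chi2_2x2(m_case, o_case, m_ctrl, o_ctrl)
    if method == "fisher":
        p = np.array([stats.fisher_exact([[a, b], [c, d]]).pvalue
                      for a, b, c, d in zip(m_case, o_case, m_ctrl, o_ctrl)])
    elif method == "chi2":
        p = stats.chi2.sf(chi2, df=1)
        p[chi2 == 0] = 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    p_adj = bh_adjust(p)
    bad = p_adj <= fdr_threshold
    table = pd.DataFrame({"site": cohort.site_indices, "chi2": chi2,
                          "p": p, "p_adj": p_adj, "excluded": bad})
    return FilterResult("differential_missingness", "site", cohort.n_sites,
                        cohort.site_indices[bad], table)


def hwe_chi2(n_rr: np.ndarray, n_ra: np.ndarray, n_aa: np.ndarray) -> np.ndarray:
    """1-df Hardy-Weinberg chi-square from genotype counts (vectorized)."""
    n_rr, n_ra, n_aa = (np.asarray(x, dtype=float) for x in (n_rr, n_ra, n_aa))
    n = n_rr + n_ra + n_aa
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (n_ra + 2 * n_aa) / (2 * n)
    q = 1.0 - p
    e_rr, e_ra, e_aa = n * q * q, 2 * n * p * q, n * p * p
    chi2 = np.zeros_like(n)
    poly = (p > 0) & (p < 1) & (n > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2[poly] = ((n_rr - e_rr) ** 2 / e_rr + (n_ra - e_ra) ** 2 / e_ra
                      + (n_aa - e_aa) ** 2 / e_aa)[poly]
    return chi2


def hwe_test(cohort: CohortDataset, control_flags: np.ndarray | None = None,
             fdr_threshold: float = 0.2) -> FilterResult:
    """HWE chi-square in controls; monomorphic sites get p = 1, never excluded."""
    if control_flags is None:
        control_flags = ~cohort.samples["case"].to_numpy(dtype=bool)
    if not control_flags.any():
        raise ValueError("need at least one control sample")
    geno = cohort.genotypes[control_flags]
    n_rr = (geno == 0).sum(axis=0)
    n_ra = (geno == 1).sum(axis=0)
    n_aa = (geno == 2).sum(axis=0)
    chi2 = hwe_chi2(n_rr, n_ra, n_aa)
    p = stats.chi2.sf(chi2, df=1)
    mono = (n_ra + n_aa == 0) | (n_ra + n_rr == 0)
    p[mono] = 1.0
    p[chi2 == 0] = 1.0
    p_adj = bh_adjust(p)
    bad = p_adj <= fdr_threshold
    table = pd.DataFrame({"site": cohort.site_indices, "chi2": chi2,
                          "p": p, "p_adj": p_adj, "excluded": bad})
    return FilterResult("hwe", "site", cohort.n_sites, cohort.site_indices[bad], table)


def minp_null_cdf(y, n_batches: int):
    """CDF of the minimum of ``n_batches`` independent Uniform(0,1) p-values."""
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y must lie in [0, 1]")
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    out = 1.0 - (1.0 - y) ** n_batches
    return float(out) if out.ndim == 0 else out


def minp_theoretical_quantiles(n: int, n_batches: int) -> np.ndarray:
    """Expected order-statistic quantiles of minimum p-values: 1-(1-i/n)^(1/m)."""
    i = np.arange(1, n + 1, dtype=float)
    return 1.0 - (1.0 - i / n) ** (1.0 / n_batches)


def batch_artifact_scan(cohort: CohortDataset, fdr_threshold: float = 0.1) -> FilterResult:
    """Minimum-p scan for wave-specific allele-frequency shifts.

    For each wave, a one-vs-rest 2x2 allele-count chi-square is computed per
    site; the per-site statistic is the minimum p over waves. Because the
    minimum of m uniforms is not uniform, the FDR adjustment divides the
    expected count under the order-statistic null, n_snps * (1-(1-p)^m), by
    the observed count of minima at or below p.
    """
    waves = cohort.samples["wave"].to_numpy()
    uniq = np.unique(waves)
    if uniq.size < 2:
        raise ValueError("need at least two waves")
    geno = cohort.genotypes
    obs = geno != MISSING
    alt_all = np.where(obs, geno, 0).sum(axis=0).astype(float)
    tot_all = 2.0 * obs.sum(axis=0)
    minp = np.ones(cohort.n_sites)
    for wv in uniq:
        rows = waves == wv
        alt_w = np.where(obs[rows], geno[rows], 0).sum(axis=0).astype(float)
        tot_w = 2.0 * obs[rows].sum(axis=0)
        alt_r, tot_r = alt_all - alt_w, tot_all - tot_w
        chi2 = _chi2_2x2(alt_w, tot_w - alt_w, alt_r, tot_r - alt_r)
        p = stats.chi2.sf(chi2, df=1)
        p[chi2 == 0] = 1.0
        minp = np.minimum(minp, p)
    n_snps, m = cohort.n_sites, uniq.size
    order = np.argsort(minp, kind="stable")
    # observed count of minima <= each site's p; ties all see the full count
    _, inv, cnt = np.unique(minp[order], return_inverse=True, return_counts=True)
    observed_count = np.empty(n_snps)
    observed_count[order] = np.cumsum(cnt)[inv].astype(float)
    expected = n_snps * minp_null_cdf(minp, m)
    p_fdr = np.where(minp > 0, expected / observed_count, 0.0)
    bad = p_fdr <= fdr_threshold
    table = pd.DataFrame({
        "site": cohort.site_indices, "min_p": minp, "p_fdr": p_fdr,
        "excluded": bad,
    })
    table.attrs["theoretical_quantiles"] = minp_theoretical_quantiles(n_snps, m)
    return FilterResult("batch_artifacts", "site", n_snps, cohort.site_indices[bad], table)


def maf_censor(cohort: CohortDataset, maf_min: float = 0.001) -> FilterResult:
    """Censor sites with observed MAF strictly below ``maf_min``."""
    geno = cohort.genotypes
    obs = geno != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(obs, geno, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))
    freq = np.nan_to_num(freq, nan=0.0)
    maf = np.minimum(freq, 1.0 - freq)
    bad = maf < maf_min
    table = pd.DataFrame({"site": cohort.site_indices, "maf": maf, "excluded": bad})
    return FilterResult("maf_censor", "site", cohort.n_sites,
                        cohort.site_indices[bad], table)


def pca(genotypes: np.ndarray, n_components: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the frequency-standardized genotype matrix.

    Missing genotypes are mean-imputed before the decomposition. Returns
    (scores, loadings); component signs are fixed so the largest-magnitude
    loading of each component is positive.
    """
    G = np.asarray(genotypes, dtype=float)
    miss = G == MISSING
    if miss.any():
        G = G.copy()
        n_obs = (~miss).sum(axis=0)
        col_mean = np.where(n_obs > 0,
                            np.nansum(np.where(miss, np.nan, G), axis=0) / np.maximum(n_obs, 1),
                            0.0)
        G[miss] = np.take(col_mean, np.nonzero(miss)[1])
    p = G.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    keep = sd > 0
    Z = (G[:, keep] - 2.0 * p[keep]) / sd[keep]
    U, D, Vt = np.linalg.svd(Z, full_matrices=False)
    k = min(n_components, D.size)
    scores = U[:, :k] * D[:k]
    loadings = Vt[:k]
    for j in range(k):
        i = np.argmax(np.abs(loadings[j]))
        if loadings[j, i] < 0:
            loadings[j] = -loadings[j]
            scores[:, j] = -scores[:, j]
    return scores, loadings


def heterozygosity(cohort: CohortDataset) -> np.ndarray:
    """Per-sample heterozygous fraction among non-missing calls."""
    geno = cohort.genotypes
    obs = (geno != MISSING).sum(axis=1)
    het = (geno == 1).sum(axis=1)
    return np.where(obs > 0, het / np.maximum(obs, 1), 0.0)


def runs_of_homozygosity(cohort: CohortDataset, min_run: int = 25) -> np.ndarray:
    """Per-sample total length (in sites) of homozygous runs >= ``min_run``.

    Missing calls break a run. This is a desk-scale stand-in for
    physical-length ROH callers.
    """
    geno = cohort.genotypes
    hom = (geno == 0) | (geno == 2)
    out = np.zeros(geno.shape[0])
    for i in range(geno.shape[0]):
        row = hom[i]
        # run-length encode
        edges = np.flatnonzero(np.diff(np.concatenate([[0], row.view(np.int8), [0]])))
        starts, ends = edges[::2], edges[1::2]
        lengths = ends - starts
        out[i] = lengths[lengths >= min_run].sum()
    return out


def _het_design(pcs: np.ndarray) -> np.ndarray:
    """Intercept + PC1..4 + squares + all pairwise products."""
    pc = np.asarray(pcs, dtype=float)[:, :4]
    cols = [np.ones(pc.shape[0])]
    cols += [pc[:, j] for j in range(4)]
    cols += [pc[:, j] ** 2 for j in range(4)]
    for a in range(4):
        for b in range(a + 1, 4):
            cols.append(pc[:, a] * pc[:, b])
    return np.column_stack(cols)


def _residuals(y: np.ndarray, X: np.ndarray, what: str) -> np.ndarray:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"degenerate design matrix in {what} (rank {rank} < {X.shape[1]})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def ancestry_adjusted_heterozygosity(
    cohort: CohortDataset,
    pcs: np.ndarray,
    roh: np.ndarray | None = None,
    sd_threshold: float = 4.0,
    conjunctive: bool = True,
    min_run: int = 25,
) -> FilterResult:
    """Flag heterozygosity outliers that ancestry and ROH cannot explain.

    Observed heterozygosity is regressed on PC1-4, their squares and pairwise
    products; the residual is the ancestry-adjusted heterozygosity. Both the
    observed and adjusted values are additionally regressed on runs of
    homozygosity. A sample is flagged when the observed het, adjusted het and
    both ROH-regression residuals all sit more than ``sd_threshold`` standard
    deviations from their means (``conjunctive=False`` flags on any one).
    """
    het = heterozygosity(cohort)
    if roh is None:
        roh = runs_of_homozygosity(cohort, min_run=min_run)
    X = _het_design(pcs)
    adj = _residuals(het, X, "ancestry adjustment (PC terms)")
    if np.std(roh) == 0:  # no qualifying runs: ROH explains nothing
        res_obs = het - het.mean()
        res_adj = adj - adj.mean()
    else:
        Xr = np.column_stack([np.ones(len(het)), roh])
        res_obs = _residuals(het, Xr, "ROH regression of observed het")
        res_adj = _residuals(adj, Xr, "ROH regression of adjusted het")

    def zscore(v):
        sd = v.std()
        return np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd

    zs = np.column_stack([zscore(het), zscore(adj), zscore(res_obs), zscore(res_adj)])
    outl = np.abs(zs) > sd_threshold
    flagged = outl.all(axis=1) if conjunctive else outl.any(axis=1)
    table = pd.DataFrame({
        "id": cohort.sample_ids, "het": het, "het_adj": adj,
        "res_obs": res_obs, "res_adj": res_adj, "flagged": flagged,
    })
    return FilterResult("abnormal_heterozygosity", "sample", cohort.n_samples,
                        cohort.sample_ids[flagged], table)


def homogeneous_subset(pc_scores: np.ndarray, anchor_rows: np.ndarray,
                       p_cutoff: float = 5.73e-7, n_components: int = 10) -> np.ndarray:
    """Inlier rows by Mahalanobis distance to the anchor-set PC centroid.

    A sample is kept iff the upper-tail chi-square(k) probability of its
    squared Mahalanobis distance (k = number of PCs) is >= ``p_cutoff``.
    """
    pcs = np.asarray(pc_scores, dtype=float)[:, :n_components]
    k = pcs.shape[1]
    anchors = pcs[np.asarray(anchor_rows)]
    if anchors.shape[0] < k + 1:
        raise ValueError(f"need at least {k + 1} anchor samples for a {k}-dim covariance")
    mu = anchors.mean(axis=0)
    cov = np.cov(anchors, rowvar=False)
    if np.linalg.matrix_rank(cov) < k:
        raise np.linalg.LinAlgError("singular anchor covariance")
    prec = np.linalg.inv(cov)
    d = pcs - mu
    d2 = np.einsum("ij,jk,ik->i", d, prec, d)
    return np.flatnonzero(stats.chi2.sf(d2, df=k) >= p_cutoff)


def kinship_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Kinship proxy: standardized-genotype covariance / 2 (identical pair ~ 0.5)."""
    G = np.asarray(genotypes, dtype=float)
    miss = G == MISSING
    G = np.where(miss, np.nan, G)
    p = np.nanmean(G, axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    keep = sd > 0
    Z = (G[:, keep] - 2.0 * p[keep]) / sd[keep]
    Z = np.nan_to_num(Z, nan=0.0)
    return (Z @ Z.T) / (2.0 * keep.sum())


def cross_kinship(genotypes_a: np.ndarray, genotypes_b: np.ndarray) -> np.ndarray:
    """Kinship proxy between two sample sets on a shared, aligned site set."""
    blocks = []
    for G in (genotypes_a, genotypes_b):
        G = np.asarray(G, dtype=float)
        G = np.where(G == MISSING, np.nan, G)
        blocks.append(G)
    pooled = np.vstack(blocks)
    p = np.nanmean(pooled, axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    keep = sd > 0
    za, zb = (np.nan_to_num((G[:, keep] - 2.0 * p[keep]) / sd[keep], nan=0.0)
              for G in blocks)
    return (za @ zb.T) / (2.0 * keep.sum())


def duplicate_and_relatedness_filter(
    cohort: CohortDataset,
    kinship_max: float = 0.0825,
    duplicate_kinship: float = 0.45,
    kinship: np.ndarray | None = None,
) -> tuple[FilterResult, np.ndarray]:
    """Resolve duplicates and list a relatedness-pruned sample set.

    Duplicate pairs (kinship proxy > ``duplicate_kinship``) are resolved by
    keeping the lower-missingness sample, preferring the case when the flags
    differ. The second return value is the id set additionally pruned at
    ``kinship_max`` (one member of each related pair dropped) for GWAS/PGS.
    A precomputed ``kinship`` matrix (e.g. blockwise over richer per-cohort
    site sets) overrides the default shared-site estimate.
    """
    K = kinship_matrix(cohort.genotypes) if kinship is None else np.asarray(kinship)
    miss = (cohort.genotypes == MISSING).mean(axis=1)
    case = cohort.samples["case"].to_numpy(dtype=bool)
    ids = cohort.sample_ids
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    kin = K[iu, ju]

    dup_drop: set[int] = set()
    for a, b in zip(iu[kin > duplicate_kinship], ju[kin > duplicate_kinship]):
        if case[a] != case[b]:
            dup_drop.add(b if case[a] else a)   # keep the case
        elif miss[a] <= miss[b]:
            dup_drop.add(b)
        else:
            dup_drop.add(a)

    rel_drop = set(dup_drop)
    rel_pairs = (kin >= kinship_max)
    for a, b in zip(iu[rel_pairs], ju[rel_pairs]):
        if a in rel_drop or b in rel_drop:
            continue
        rel_drop.add(b if miss[a] <= miss[b] else a)

    table = pd.DataFrame({"i": ids[iu], "j": ids[ju], "kinship": kin})
    result = FilterResult("duplicates", "sample", n,
                          ids[sorted(dup_drop)], table[kin > duplicate_kinship])
    unrelated_ids = ids[[i for i in range(n) if i not in rel_drop]]
    return result, unrelated_ids


def sample_missingness_filter(cohort: CohortDataset, threshold: float = 0.05) -> FilterResult:
    """Exclude samples with overall missing fraction strictly above threshold."""
    frac = (cohort.genotypes == MISSING).mean(axis=1)
    bad = frac > threshold
    table = pd.DataFrame({"id": cohort.sample_ids, "missing": frac, "excluded": bad})
    return FilterResult("sample_missingness", "sample", cohort.n_samples,
                        cohort.sample_ids[bad], table)
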