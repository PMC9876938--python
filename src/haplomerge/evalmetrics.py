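"""Protocol scoring: trio switch error, imputation r2, batch-effect lambda.

Switch error rate (SER) compares a computational phase against the phase
resolvable from parent-offspring transmission; r2 is the squared Pearson
correlation between imputed dosages and held-out true genotypes, stratified
by reference-panel MAF; lambda_GC measures inflation of an array-membership
association scan (median chi-square over the chi-square(1) median).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import DosageMatrix, PhasedHaplotypes, TrioSet

__all__ = [
    "MafBins", "CHI2_MEDIAN", "trio_resolve_phase", "switch_error_rate",
    "ser_for_trios", "imputation_r2_by_maf", "array_membership_scan",
    "trend_chi2", "lambda_gc", "ser_by_block",
]

CHI2_MEDIAN = 0.4549  # median of chi-square(1), to 4 decimals


@dataclass
class MafBins:
    """Ordered MAF bin edges; bins are (lo, hi]."""

    edges: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5]))

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.edges[-1] != 0.5:
            raise ValueError("final edge must be 0.5")

    def assign(self, maf: np.ndarray) -> np.ndarray:
        """Bin index per site, -1 for maf outside (edges[0], 0.5]."""
        maf = np.asarray(maf, dtype=float)
        idx = np.searchsorted(self.edges, maf, side="left") - 1
        idx[maf <= self.edges[0]] = -1
        idx[maf > self.edges[-1]] = -1
        return idx

    def labels(self) -> list[str]:
        return [f"({lo:g},{hi:g}]" for lo, hi in zip(self.edges[:-1], self.edges[1:])]


@dataclass
class TrioTruthPhase:
    """Trio-resolved truth phase: per offspring, the resolvable het sites
    (as panel site ids, in order) and the transmitted paternal allele."""

    trio_ids: list[str]
    sites: list[np.ndarray]
    paternal_allele: list[np.ndarray]
    n_inconsistent: int
    n_unresolvable: int


def trio_resolve_phase(trios: TrioSet, design_name: str,
                       eval_sites: np.ndarray | None = None) -> TrioTruthPhase:
    """Resolve offspring phase by Mendelian transmission.

    At an offspring heterozygous site the transmitted paternal allele is
    forced when either parent is homozygous; triple-het sites are
    unresolvable and excluded. Mendelian-inconsistent sites are dropped with
    a count.
    """
    g = trios.genotypes[design_name]
    sites = trios.design_sites[design_name]
    if eval_sites is not None:
        keep = np.isin(sites, eval_sites)
        sites = sites[keep]
        g = {k: v[:, keep] for k, v in g.items()}
    F, M, O = g["father"], g["mother"], g["offspring"]
    out_sites, out_pat = [], []
    n_bad = 0
    n_unres = 0
    for t in range(trios.n_trios):
        f, m, o = F[t], M[t], O[t]
        het = o == 1
        # Mendelian consistency at het sites: each parent must be able to
        # transmit one of the two offspring alleles
        pat = np.full(len(o), -1, dtype=np.int8)
        f_hom0, f_hom2 = f == 0, f == 2
        m_hom0, m_hom2 = m == 0, m == 2
        pat[het & f_hom0] = 0
        pat[het & f_hom2] = 1
        pat[het & (f == 1) & m_hom0] = 1
        pat[het & (f == 1) & m_hom2] = 0
        inconsistent = het & ((f_hom0 & m_hom0) | (f_hom2 & m_hom2))
        n_bad += int(inconsistent.sum())
        pat[inconsistent] = -1
        n_unres += int((het & (f == 1) & (m == 1)).sum())
        resolved = pat >= 0
        out_sites.append(sites[resolved])
        out_pat.append(pat[resolved])
    return TrioTruthPhase(trio_ids=list(trios.trio_ids), sites=out_sites,
                          paternal_allele=out_pat, n_inconsistent=n_bad,
                          n_unresolvable=n_unres)


def switch_error_rate(est_orientations: list[np.ndarray],
                      truth_orientations: list[np.ndarray]) -> float:
    """SER over offspring: switches / possible switches.

    Each element holds, for one offspring, the allele carried by (an
    arbitrary labelling of) haplotype 1 at the resolvable het sites, in site
    order. A switch is an adjacent pair whose relative orientation disagrees
    between estimate and truth; the global haplotype labelling cancels, so a
    whole-sample label swap yields SER 0. Offspring with fewer than two
    resolvable sites contribute nothing.
    """
    switches = 0
    possible = 0
    for est, tru in zip(est_orientations, truth_orientations):
        est = np.asarray(est)
        tru = np.asarray(tru)
        if est.shape != tru.shape:
            raise ValueError("estimate/truth orientation lengths differ")
        k = est.size
        if k < 2:
            continue
        d = est != tru
        switches += int(np.sum(d[1:] != d[:-1]))
        possible += k - 1
    return switches / possible if possible else float("nan")


def ser_for_trios(phased: PhasedHaplotypes, truth: TrioTruthPhase,
                  sample_ids: list[str] | None = None) -> float:
    """SER of phased trio offspring against Mendelian truth phase.

    Sites not present (or no longer heterozygous) in the phased estimate are
    skipped; the comparison runs over the remaining resolvable het sites.
    """
    ids = list(phased.sample_ids)
    est_list, tru_list = [], []
    use_ids = truth.trio_ids if sample_ids is None else sample_ids
    site_pos = {s: i for i, s in enumerate(phased.site_indices.tolist())}
    geno = phased.genotype()
    for tid, sites, pat in zip(use_ids, truth.sites, truth.paternal_allele):
        if tid not in ids:
            continue
        row = ids.index(tid)
        cols, keep = [], []
        for j, s in enumerate(sites.tolist()):
            c = site_pos.get(s)
            if c is not None and geno[row, c] == 1:
                cols.append(c)
                keep.append(j)
        if len(cols) < 2:
            continue
        est_list.append(phased.h1[row, cols])
        tru_list.append(pat[keep])
    return switch_error_rate(est_list, tru_list)


def ser_by_block(phased: PhasedHaplotypes, truth: TrioTruthPhase,
                 cm: np.ndarray, n_blocks: int = 4) -> pd.DataFrame:
    """SER within equal-cM blocks of the chromosome, with SNP density.

    Emulates a per-chromosome breakdown on a single simulated chromosome:
    phasing accuracy tracks the number of markers per centimorgan.
    """
    edges = np.linspace(cm.min(), cm.max() + 1e-9, n_blocks + 1)
    rows = []
    for b in range(n_blocks):
        block_sites = np.flatnonzero((cm >= edges[b]) & (cm < edges[b + 1]))
        tr = TrioTruthPhase(
            trio_ids=truth.trio_ids,
            sites=[s[np.isin(s, block_sites)] for s in truth.sites],
            paternal_allele=[p[np.isin(s, block_sites)]
                             for s, p in zip(truth.sites, truth.paternal_allele)],
            n_inconsistent=0, n_unresolvable=0,
        )
        scaffold = np.isin(phased.site_indices, block_sites).sum()
        width = edges[b + 1] - edges[b]
        rows.append({
            "block": b,
            "ser": ser_for_trios(phased, tr),
            "snp_per_cm": scaffold / width if width > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def imputation_r2_by_maf(dosages: DosageMatrix, truth: np.ndarray,
                         bins: MafBins | None = None,
                         group_labels: np.ndarray | None = None,
                         pooled: bool = True) -> pd.DataFrame:
    """Squared correlation between dosages and truth per reference-MAF bin.

    ``truth`` is the (N, S) matrix of held-out genotypes aligned to
    ``dosages``. Pooled mode concatenates all (sample, site) pairs within a
    bin; per-SNP mode averages per-site r2. Bins (or groups) where the truth
    has zero variance are reported as NaN, never 0.
    """
    bins = bins or MafBins()
    truth = np.asarray(truth)
    if truth.shape != dosages.ds.shape:
        raise ValueError("truth must align with the dosage matrix")
    bin_idx = bins.assign(dosages.ref_maf)
    groups = (np.full(truth.shape[0], "all") if group_labels is None
              else np.asarray(group_labels))
    rows = []
    for grp in pd.unique(groups):
        gmask = groups == grp
        for b, lab in enumerate(bins.labels()):
            cols = np.flatnonzero(bin_idx == b)
            if cols.size == 0:
                continue
            t = truth[np.ix_(gmask, cols)].astype(float)
            d = dosages.ds[np.ix_(gmask, cols)]
            if pooled:
                r2 = _pearson_r2(t.ravel(), d.ravel())
                n_skipped = 0
            else:
                vals = []
                n_skipped = 0
                for j in range(cols.size):
                    v = _pearson_r2(t[:, j], d[:, j])
                    if np.isnan(v):
                        n_skipped += 1
                    else:
                        vals.append(v)
                r2 = float(np.mean(vals)) if vals else float("nan")
            rows.append({"group": grp, "bin": lab, "r2": r2,
                         "n_sites": cols.size, "n_skipped": n_skipped})
    return pd.DataFrame(rows)


def trend_chi2(x: np.ndarray, case: np.ndarray) -> float:
    """1-df allele-dosage trend chi-square: n * corr(x, case)^2."""
    x = np.asarray(x, dtype=float)
    case = np.asarray(case, dtype=float)
    if x.std() == 0 or case.std() == 0:
        return 0.0
    r = np.corrcoef(x, case)[0, 1]
    return float(len(x) * r * r)


def lambda_gc(chi2_values: np.ndarray) -> float:
    """Genomic inflation factor: median chi-square / 0.4549."""
    chi2_values = np.asarray(chi2_values, dtype=float)
    if chi2_values.size == 0:
        raise ValueError("no test statistics")
    return float(np.median(chi2_values) / CHI2_MEDIAN)


def membership_scan_arm(x_a: np.ndarray, x_b: np.ndarray,
                        dr2_filters: list[np.ndarray],
                        dr2_thresholds=(0.0, 0.5, 0.9),
                        allow_empty: bool = False) -> list[dict]:
    """One arm of the cohort-membership scan over a DR2-threshold sweep.

    ``x_a`` / ``x_b`` hold the per-cohort values (genotypes or dosages) at
    one evaluation site set; ``dr2_filters`` lists the DR2 vectors of the
    imputed side(s) — a site survives a threshold only if every filter
    passes. Returns one row per threshold.
    """
    member = np.concatenate([np.zeros(x_a.shape[0]), np.ones(x_b.shape[0])])
    X = np.vstack([x_a, x_b]).astype(float)
    rows = []
    for thr in dr2_thresholds:
        keep = np.ones(X.shape[1], dtype=bool)
        for f in dr2_filters:
            keep &= np.asarray(f) >= thr
        if not keep.any():
            if not allow_empty:
                raise ValueError(f"no sites survive DR2 >= {thr}")
            rows.append({"dr2_threshold": thr, "lambda_gc": float("nan"), "n_snps": 0})
            continue
        chi2 = np.array([trend_chi2(X[:, j], member) for j in np.flatnonzero(keep)])
        rows.append({"dr2_threshold": thr, "lambda_gc": lambda_gc(chi2),
                     "n_snps": int(keep.sum())})
    return rows


def array_membership_scan(
    truth_a: np.ndarray, truth_b: np.ndarray,
    ds_a: np.ndarray, ds_b: np.ndarray,
    dr2_a: np.ndarray, dr2_b: np.ndarray,
    dr2_thresholds=(0.0, 0.5, 0.9),
    allow_empty: bool = False,
) -> pd.DataFrame:
    """Cohort-membership association scan at held-out sites.

    Three arms per threshold: cohort-A truth vs cohort-B dosages, cohort-A
    dosages vs cohort-B truth, dosages on both sides. The DR2 filter applies
    to each imputed side; a site survives only if every imputed side passes.
    Rows of the inputs are samples (already restricted to unrelated,
    homogeneous controls); columns are the held-out sites.
    """
    arms = {
        "genoA_vs_impB": (truth_a, ds_b, ("b",)),
        "impA_vs_genoB": (ds_a, truth_b, ("a",)),
        "impA_vs_impB": (ds_a, ds_b, ("a", "b")),
    }
    n_a, n_b = truth_a.shape[0], truth_b.shape[0]
    member = np.concatenate([np.zeros(n_a), np.ones(n_b)])
    dr2 = {"a": np.asarray(dr2_a), "b": np.asarray(dr2_b)}
    rows = []
    for arm, (xa, xb, imputed_sides) in arms.items():
        X = np.vstack([xa, xb]).astype(float)
        for thr in dr2_thresholds:
            keep = np.ones(X.shape[1], dtype=bool)
            for side in imputed_sides:
                keep &= dr2[side] >= thr
            if not keep.any():
                if not allow_empty:
                    raise ValueError(f"no sites survive DR2 >= {thr} in arm {arm}")
                rows.append({"arm": arm, "dr2_threshold": thr,
                             "lambda_gc": float("nan"), "n_snps": 0})
                continue
            chi2 = np.array([trend_chi2(X[:, j], member) for j in np.flatnonzero(keep)])
            rows.append({"arm": arm, "dr2_threshold": thr,
                         "lambda_gc": lambda_gc(chi2), "n_snps": int(keep.sum())})
    return pd.DataFrame(rows)
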