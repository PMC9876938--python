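"""Polygenic-score experiment: GWAS, scoring, attenuation, rank concordance.

A discovery GWAS in one cohort (OLS of the simulated trait on each held-out
site's genotype or dosage, with age, sex and 10 PCs as covariates) yields
per-site effects; scores in the other cohort are the effect-weighted dosage
sums. The experiment contrasts error in discovery (GWAS on imputed dosages,
scoring on truth) against error in scoring (GWAS on truth, scoring on
imputed dosages), per integration protocol, against the truth/truth
reference arm.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "gwas_quantitative", "pgs_score", "variance_explained",
    "rank_concordance", "run_pgs_arms",
]


def gwas_quantitative(X: np.ndarray, y: np.ndarray,
                      covariates: np.ndarray | None = None) -> pd.DataFrame:
    """Per-site OLS of phenotype on dosage plus covariates.

    Residualizes both sides on the covariates (with intercept), which gives
    the same per-site effect as the joint OLS fit. Predictors that are
    constant after residualization are flagged, not estimated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    C = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)])
    q, _ = np.linalg.qr(C)
    y_r = y - q @ (q.T @ y)
    X_r = X - q @ (q.T @ X)
    df = n - C.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough samples for the covariate set")
    sxx = np.einsum("ij,ij->j", X_r, X_r)
    sxy = X_r.T @ y_r
    ok = sxx > 1e-12
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    beta[ok] = sxy[ok] / sxx[ok]
    resid_ss = np.einsum("ij,ij->j", y_r[:, None] - X_r * np.where(ok, beta, 0.0),
                         y_r[:, None] - X_r * np.where(ok, beta, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        se[ok] = np.sqrt(resid_ss[ok] / df / sxx[ok])
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return pd.DataFrame({"site": np.arange(m), "beta": beta, "se": se,
                         "stat": tstat, "p": p, "n": n, "estimated": ok})


def pgs_score(betas: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Score_j = sum_i beta_i * X_ij over the held-out site set.

    Sites whose effect was not estimated (NaN beta) contribute nothing.
    """
    b = np.nan_to_num(np.asarray(betas, dtype=float), nan=0.0)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != b.size:
        raise ValueError("effect vector does not align with the score matrix")
    return X @ b


def _r2(y: np.ndarray, design: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise ValueError("constant phenotype")
    return float(1.0 - np.sum(resid ** 2) / tss)


def variance_explained(scores: np.ndarray, y: np.ndarray,
                       covariates: np.ndarray | None = None,
                       mode: str = "nested") -> float:
    """Trait variance explained by the PGS.

    ``nested`` (default): R2(covariates + PGS) - R2(covariates), which is
    nonnegative by construction. ``two_model``: R2(PGS + covariates) -
    R2(PGS alone), the literal two-model contrast (can be read either way
    around; provided for fidelity).
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(scores, dtype=float)
    n = len(y)
    ones = np.ones((n, 1))
    C = ones if covariates is None else np.column_stack([ones, covariates])
    full = np.column_stack([C, s])
    if mode == "nested":
        return _r2(y, full) - _r2(y, C)
    if mode == "two_model":
        return _r2(y, full) - _r2(y, np.column_stack([ones, s]))
    raise ValueError(f"unknown mode {mode!r}")


def rank_concordance(scores_truth: np.ndarray, scores_other: np.ndarray,
                     n_quantiles: int = 100, top_q: int = 5) -> tuple[np.ndarray, float]:
    """Percentile joint-occupancy matrix and top-quantile overlap.

    Samples are ranked into ``n_quantiles`` bins per score vector (stable
    ties by sample order); the matrix counts joint occupancy, and the
    overlap is |top-q% under both| / |top-q% under truth|.
    """
    st = np.asarray(scores_truth, dtype=float)
    so = np.asarray(scores_other, dtype=float)
    if st.shape != so.shape:
        raise ValueError("score vectors must cover the same samples")
    n = st.size

    def percentiles(v):
        order = np.argsort(v, kind="stable")
        rank = np.empty(n, dtype=np.int64)
        rank[order] = np.arange(n)
        return np.minimum((rank * n_quantiles) // n, n_quantiles - 1)

    pt, po = percentiles(st), percentiles(so)
    mat = np.zeros((n_quantiles, n_quantiles), dtype=np.int64)
    np.add.at(mat, (pt, po), 1)
    top = n_quantiles - top_q
    top_t = pt >= top
    top_o = po >= top
    overlap = float((top_t & top_o).sum() / max(top_t.sum(), 1))
    return mat, overlap


def run_pgs_arms(
    truth: dict[str, np.ndarray],
    dosages: dict[str, dict[str, np.ndarray]],
    phenotype: dict[str, np.ndarray],
    covariates: dict[str, np.ndarray],
    mode: str = "nested",
) -> pd.DataFrame:
    """Cross-cohort PGS experiment over protocols and error arms.

    Keyed by cohort ("A", "B"): ``truth`` holds true genotypes at the
    held-out sites, ``dosages[protocol]`` the imputed dosages, ``phenotype``
    and ``covariates`` the trait and covariate matrices (already restricted
    to the unrelated homogeneous subset). For each discovery->scoring
    direction and each protocol, three arms are computed:

    * truth_truth — GWAS and scoring both on true genotypes (reference);
    * imputed_discovery — GWAS on dosages, scoring on truth;
    * imputed_scoring — GWAS on truth, scoring on dosages.

    Returns one row per (direction, protocol, arm) with dR2, top-5% overlap
    and percentile-diagonal concordance against the truth/truth scores.
    """
    rows = []
    for disc, targ in (("A", "B"), ("B", "A")):
        gwas_truth = gwas_quantitative(truth[disc], phenotype[disc], covariates[disc])
        ref_scores = pgs_score(gwas_truth["beta"].to_numpy(), truth[targ])
        ref_dr2 = variance_explained(ref_scores, phenotype[targ], covariates[targ], mode)
        for protocol in dosages:
            ds_disc = dosages[protocol][disc]
            ds_targ = dosages[protocol][targ]
            gwas_imp = gwas_quantitative(ds_disc, phenotype[disc], covariates[disc])
            arms = {
                "truth_truth": ref_scores,
                "imputed_discovery": pgs_score(gwas_imp["beta"].to_numpy(), truth[targ]),
                "imputed_scoring": pgs_score(gwas_truth["beta"].to_numpy(), ds_targ),
            }
            for arm, scores in arms.items():
                dr2 = (ref_dr2 if arm == "truth_truth" else
                       variance_explained(scores, phenotype[targ], covariates[targ], mode))
                mat, overlap = rank_concordance(ref_scores, scores)
                rows.append({
                    "direction": f"{disc}->{targ}", "protocol": protocol, "arm": arm,
                    "delta_r2": dr2, "top5_overlap": overlap,
                    "diag_mass": float(np.trace(mat) / mat.sum()),
                })
    return pd.DataFrame(rows)
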