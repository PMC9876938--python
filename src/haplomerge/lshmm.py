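"""Desk-scale Li–Stephens haplotype-copying engine.

One engine with a conditioning-set-size knob (``n_states``) stands in for the
production phasing/imputation tools; ``small`` and ``large`` settings
preserve the default-vs-high-resolution contrast those tools expose. Phasing
is iterative conditional posterior decoding of a diploid copying HMM;
imputation is per-haplotype forward-backward against a reference panel with
dosages DS = p(RA) + 2*p(AA) and a MaCH-Rsq style per-site quality (DR2).

Conditioning haplotypes are chosen by Hamming closeness to the current
estimate, a PBWT-free stand-in for the "most informative haplotypes"
heuristics of the real tools. All randomness is confined to the phase
initialization, so runs are reproducible given the seed.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ._kernels import diploid_fb_posterior, diploid_phase_sample, haploid_posterior_alt
from .types import MISSING, CohortDataset, DosageMatrix, HaplotypePanel, PhasedHaplotypes

__all__ = [
    "HMMParams", "ReferencePanel", "phase", "impute", "dr2_quality",
    "consensus_haplotypes", "brute_force_posterior", "diploid_genotype_posterior",
    "recombination_probs",
]

ENGINE_SETTINGS = {"small": 40, "large": 80}


@dataclass
class HMMParams:
    """Copying-model parameters.

    n_states : conditioning haplotypes per sample (the accuracy/cost knob)
    ne : effective-population-size scale for the recombination rate
    error_rate : per-allele copying mismatch probability
    n_iterations : phasing sweeps
    """

    n_states: int = 40
    ne: float = 100.0
    error_rate: float = 1e-3
    n_iterations: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if not (0.0 < self.error_rate < 0.5):
            raise ValueError("error_rate must lie in (0, 0.5)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class ReferencePanel:
    """Phased reference haplotypes over an ordered site set."""

    haps: np.ndarray          # (H, S) uint8
    cm: np.ndarray            # (S,)
    site_indices: np.ndarray  # (S,) panel site ids
    maf: np.ndarray | None = None

    @classmethod
    def from_panel(cls, panel: HaplotypePanel, hap_rows: np.ndarray,
                   site_indices: np.ndarray | None = None) -> "ReferencePanel":
        sites = np.arange(panel.n_sites) if site_indices is None else np.asarray(site_indices)
        haps = panel.haplotypes[np.asarray(hap_rows)][:, sites]
        f = haps.mean(axis=0)
        return cls(haps=haps.astype(np.uint8), cm=panel.cm[sites],
                   site_indices=np.asarray(sites, dtype=np.int64),
                   maf=np.minimum(f, 1.0 - f))

    @property
    def n_haps(self) -> int:
        return self.haps.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haps.shape[1]

    def restrict(self, site_indices: np.ndarray) -> "ReferencePanel":
        pos = {s: i for i, s in enumerate(self.site_indices.tolist())}
        missing = [s for s in np.asarray(site_indices).tolist() if s not in pos]
        if missing:
            raise ValueError(f"sites absent from reference: {missing[:10]}")
        cols = np.array([pos[s] for s in np.asarray(site_indices).tolist()], dtype=np.int64)
        return ReferencePanel(self.haps[:, cols], self.cm[cols],
                              self.site_indices[cols],
                              None if self.maf is None else self.maf[cols])


def recombination_probs(cm: np.ndarray, ne: float, n_states: int) -> np.ndarray:
    """Per-interval switch probability 1 - exp(-4*Ne*dM/K)."""
    d_morgan = np.diff(np.asarray(cm, dtype=float)) / 100.0
    rho = 4.0 * ne * d_morgan / n_states
    rec = np.empty(len(cm))
    rec[0] = 0.0
    rec[1:] = 1.0 - np.exp(-rho)
    return np.clip(rec, 0.0, 0.49)


def _hamming_select(targets: np.ndarray, candidates: np.ndarray, k: int,
                    exclude: np.ndarray | None = None) -> np.ndarray:
    """Rows of ``candidates`` closest to each target row (genotype-vs-haplotype).

    ``targets`` holds genotypes (0/1/2, -1 missing); a candidate haplotype is
    penalized where it is incompatible with a homozygous call. Returns an
    (N, k) index array, deterministic (ties broken by candidate index).
    """
    T = np.asarray(targets, dtype=np.float32)
    C = np.asarray(candidates, dtype=np.float32)
    i0 = (T == 0).astype(np.float32)
    i2 = (T == 2).astype(np.float32)
    D = i0 @ C.T + i2 @ (1.0 - C.T)
    if exclude is not None:
        for n in range(D.shape[0]):
            D[n, exclude[n]] = np.inf
    k = min(k, D.shape[1] - (0 if exclude is None else exclude.shape[1]))
    part = np.argpartition(D, k - 1, axis=1)[:, :k]
    # deterministic ordering within the selected set
    rows = np.arange(D.shape[0])[:, None]
    order = np.lexsort((part, D[rows, part]), axis=1)
    return part[rows, order]


def phase(cohort: CohortDataset, reference: ReferencePanel | None,
          params: HMMParams) -> PhasedHaplotypes:
    """Iterative conditional phasing of a cohort.

    Each sweep re-estimates every sample's diplotype by posterior decoding of
    the diploid copying HMM, conditioning on ``n_states`` haplotypes chosen
    by Hamming closeness from the reference panel plus the other samples'
    current estimates (snapshotted at the start of the sweep). Missing
    genotypes are filled from the copying posterior each sweep; observed
    calls are never overwritten.
    """
    geno = cohort.genotypes
    n, S = geno.shape
    if (reference is None or reference.n_haps == 0) and n == 1:
        raise ValueError("nothing to condition on: empty reference and a single sample")
    if reference is not None:
        ref = reference.restrict(cohort.site_indices)
        ref_haps = ref.haps
        cm = ref.cm
    else:
        ref_haps = np.empty((0, S), dtype=np.uint8)
        cm = np.zeros(S)  # caller should supply a reference for genetic positions
    rng = np.random.default_rng(params.seed)

    # random initialization consistent with the genotypes
    h1 = np.zeros((n, S), dtype=np.uint8)
    h2 = np.zeros((n, S), dtype=np.uint8)
    hom2 = geno == 2
    h1[hom2] = 1
    h2[hom2] = 1
    het = geno == 1
    flip = rng.random((n, S)) < 0.5
    h1[het & flip] = 1
    h2[het & ~flip] = 1
    miss = geno == MISSING
    if miss.any():
        obs = ~miss
        freq = np.where(obs, geno, 0).sum(axis=0) / np.maximum(2.0 * obs.sum(axis=0), 1.0)
        fill1 = rng.random((n, S)) < freq
        fill2 = rng.random((n, S)) < freq
        h1[miss] = fill1[miss]
        h2[miss] = fill2[miss]

    rec = recombination_probs(cm, params.ne, params.n_states)
    cert = np.ones((n, S), dtype=np.float64)
    e = params.error_rate

    for sweep in range(params.n_iterations):
        if sweep == 0 and ref_haps.shape[0] >= params.n_states:
            # first sweep: condition on the reference only — other samples'
            # phases are still random initializations and would drown it out
            snapshot = ref_haps.astype(np.uint8)
            own = None
        else:
            snapshot = np.vstack([ref_haps, h1.copy(), h2.copy()]).astype(np.uint8)
            n_ref = ref_haps.shape[0]
            own = np.stack([n_ref + np.arange(n), n_ref + n + np.arange(n)], axis=1)
        sel = _hamming_select(geno, snapshot, params.n_states, exclude=own)
        for i in range(n):
            cond = snapshot[sel[i]]
            pm = e + cond.astype(np.float64) * (1.0 - 2.0 * e)
            hi1, hi2, ci, _post = diploid_phase_sample(geno[i], pm, rec)
            h1[i], h2[i], cert[i] = hi1, hi2, ci

    return PhasedHaplotypes(
        sample_ids=cohort.sample_ids.copy(),
        site_indices=cohort.site_indices.copy(),
        h1=h1, h2=h2,
        certainty=cert.astype(np.float32),
        imputed=miss,
    )


def impute(phased: PhasedHaplotypes, reference: ReferencePanel,
           params: HMMParams, target_sites: np.ndarray | None = None,
           cohort: CohortDataset | None = None) -> DosageMatrix:
    """Reference-based imputation of phased haplotypes.

    Each haplotype is run through the haploid copying HMM against its
    ``n_states`` nearest reference haplotypes; the two alt-allele posteriors
    combine into genotype probabilities, and DS = p(RA) + 2*p(AA). Where
    ``cohort`` is given, observed genotype calls pass through as DS.
    """
    targets = reference.site_indices if target_sites is None else np.asarray(target_sites)
    missing_targets = np.setdiff1d(targets, reference.site_indices)
    if missing_targets.size:
        raise ValueError(f"target sites absent from reference: {missing_targets[:10].tolist()}")
    scaffold_pos = {s: i for i, s in enumerate(reference.site_indices.tolist())}
    try:
        scaffold_cols = np.array([scaffold_pos[s] for s in phased.site_indices.tolist()],
                                 dtype=np.int64)
    except KeyError as err:
        raise ValueError(f"typed site absent from reference: {err}") from None

    n = phased.h1.shape[0]
    S_ref = reference.n_sites
    rec = recombination_probs(reference.cm, params.ne, params.n_states)
    e = params.error_rate
    K = min(params.n_states, reference.n_haps)
    ref_scaffold = reference.haps[:, scaffold_cols]

    p_alt = np.empty((2, n, S_ref))
    for which, H in enumerate((phased.h1, phased.h2)):
        # nearest reference haplotypes by allele mismatch on the scaffold
        Hf = H.astype(np.float32)
        Rf = ref_scaffold.astype(np.float32)
        D = Hf @ (1.0 - Rf.T) + (1.0 - Hf) @ Rf.T
        part = np.argpartition(D, K - 1, axis=1)[:, :K]
        rows = np.arange(n)[:, None]
        order = np.lexsort((part, D[rows, part]), axis=1)
        sel = part[rows, order]
        for i in range(n):
            obs = np.full(S_ref, MISSING, dtype=np.int8)
            obs[scaffold_cols] = H[i]
            pm = e + reference.haps[sel[i]].astype(np.float64) * (1.0 - 2.0 * e)
            p_alt[which, i] = haploid_posterior_alt(obs, pm, rec)

    tcols = np.array([scaffold_pos[s] for s in targets.tolist()], dtype=np.int64)
    pa = p_alt[0][:, tcols]
    pb = p_alt[1][:, tcols]
    ds = pa + pb  # p(RA) + 2 p(AA) for independent haplotype posteriors
    p0 = (1.0 - pa) * (1.0 - pb)
    p2 = pa * pb
    hard = np.argmax(np.stack([p0, 1.0 - p0 - p2, p2]), axis=0).astype(np.int8)

    if cohort is not None:
        cpos = {s: i for i, s in enumerate(cohort.site_indices.tolist())}
        for j, s in enumerate(targets.tolist()):
            if s in cpos:
                g = cohort.genotypes[:, cpos[s]]
                obs_mask = g != MISSING
                ds[obs_mask, j] = g[obs_mask]
                hard[obs_mask, j] = g[obs_mask]

    ds = np.clip(ds, 0.0, 2.0)
    if ds.shape[0] >= 2:
        dr2 = np.array([dr2_quality(ds[:, j]) for j in range(ds.shape[1])])
    else:
        dr2 = np.zeros(ds.shape[1])  # undefined for a single sample
    ref_maf = (reference.maf[tcols] if reference.maf is not None
               else np.minimum(reference.haps[:, tcols].mean(axis=0),
                               1.0 - reference.haps[:, tcols].mean(axis=0)))
    return DosageMatrix(sample_ids=phased.sample_ids.copy(),
                        site_indices=targets.copy(), ds=ds, dr2=dr2,
                        ref_maf=ref_maf, hard_calls=hard)


def dr2_quality(ds: np.ndarray) -> float:
    """MaCH-Rsq style quality: var(DS) / (2 p (1-p)) with p = mean(DS)/2."""
    ds = np.asarray(ds, dtype=float)
    if ds.size < 2:
        raise ValueError("need at least two samples")
    var = ds.var()
    if var < 1e-12:
        return 0.0
    p = ds.mean() / 2.0
    denom = 2.0 * p * (1.0 - p)
    if denom <= 0.0:
        return 0.0
    return float(np.clip(var / denom, 0.0, 1.0))


def consensus_haplotypes(estimates: list[PhasedHaplotypes]) -> PhasedHaplotypes:
    """Majority vote across phasing runs, interval by interval.

    For each sample, het sites are walked in order; each estimate votes
    "switch" or "no switch" for the interval since the previous het, and the
    majority wins. The first het site anchors the (arbitrary) orientation.
    Genotypes must agree across estimates at non-imputed sites; imputed
    fills are themselves majority-voted.
    """
    if len(estimates) < 2:
        raise ValueError("need at least two estimates")
    base = estimates[0]
    for est in estimates[1:]:
        if not np.array_equal(est.site_indices, base.site_indices):
            raise ValueError("estimates must cover identical sites")
        if not np.array_equal(est.sample_ids, base.sample_ids):
            raise ValueError("estimates must cover identical samples")
        hard = ~(est.imputed | base.imputed)
        if not np.array_equal(est.genotype()[hard], base.genotype()[hard]):
            raise ValueError("estimates disagree on observed genotypes")

    n, S = base.h1.shape
    n_est = len(estimates)
    h1 = np.zeros((n, S), dtype=np.uint8)
    h2 = np.zeros((n, S), dtype=np.uint8)
    cert = np.ones((n, S), dtype=np.float32)

    genos = np.stack([e.genotype() for e in estimates])  # (E, n, S)
    # majority genotype (matters only at imputed sites; identical elsewhere)
    counts = np.stack([(genos == g).sum(axis=0) for g in (0, 1, 2)])  # (3, n, S)
    maj_g = counts.argmax(axis=0).astype(np.int8)

    for i in range(n):
        g = maj_g[i]
        hom2 = g == 2
        h1[i, hom2] = 1
        h2[i, hom2] = 1
        hets = np.flatnonzero(g == 1)
        if hets.size == 0:
            continue
        # orientation votes: allele on haplotype 1 at each het site, but only
        # estimates whose genotype matches the majority get a vote
        valid = genos[:, i, :][:, hets] == 1           # (E, n_het)
        o = np.stack([est.h1[i, hets] for est in estimates])  # (E, n_het)
        # anchor: first het follows the first estimate with a valid call there
        anchor = int(o[np.argmax(valid[:, 0]), 0])
        cur = anchor
        h1[i, hets[0]] = cur
        h2[i, hets[0]] = 1 - cur
        for t in range(1, hets.size):
            both = valid[:, t] & valid[:, t - 1]
            switches = (o[:, t] != o[:, t - 1]) & both
            n_votes = both.sum()
            n_switch = switches.sum()
            do_switch = n_switch * 2 > n_votes  # ties -> no switch
            if do_switch:
                cur = 1 - cur
            h1[i, hets[t]] = cur
            h2[i, hets[t]] = 1 - cur
            if n_votes:
                frac = n_switch / n_votes
                cert[i, hets[t]] = max(frac, 1.0 - frac)
    imputed = np.logical_and.reduce([e.imputed for e in estimates])
    return PhasedHaplotypes(sample_ids=base.sample_ids.copy(),
                            site_indices=base.site_indices.copy(),
                            h1=h1, h2=h2, certainty=cert, imputed=imputed)


def diploid_genotype_posterior(geno: np.ndarray, ref_haps: np.ndarray,
                               rec: np.ndarray, error_rate: float) -> np.ndarray:
    """(S,3) posterior of the emitted genotype via forward-backward.

    At observed sites the emitted genotype is the observation (one-hot);
    missing sites carry the copying-posterior imputation distribution.
    """
    pm = error_rate + np.asarray(ref_haps, dtype=np.float64) * (1.0 - 2.0 * error_rate)
    post = diploid_fb_posterior(np.asarray(geno, dtype=np.int8), pm,
                                np.asarray(rec, dtype=np.float64))
    out = post.copy()
    for s, g in enumerate(np.asarray(geno)):
        if g != MISSING:
            out[s] = 0.0
            out[s, g] = 1.0
    return out


def brute_force_posterior(geno: np.ndarray, ref_haps: np.ndarray,
                          rec: np.ndarray, error_rate: float) -> np.ndarray:
    """Exact genotype posteriors by exhaustive enumeration of copying paths.

    Sums over all pairs of copying paths (K^S per haplotype); only feasible
    for tiny instances (<= ~6 sites, <= ~4 reference haplotypes). Test oracle
    for :func:`diploid_genotype_posterior`; never used in the pipeline.
    """
    ref = np.asarray(ref_haps, dtype=np.float64)
    geno = np.asarray(geno)
    K, S = ref.shape
    if K ** S > 5000:
        raise ValueError("instance too large to enumerate")
    e = error_rate
    paths = np.array(list(itertools.product(range(K), repeat=S)), dtype=np.int64)
    same = paths[:, 1:] == paths[:, :-1]
    r = np.asarray(rec, dtype=float)[1:]
    stay = (1.0 - r) + r / K
    move = r / K
    prior = np.prod(np.where(same, stay, move), axis=1) / K
    p_alt = e + ref[paths, np.arange(S)] * (1.0 - 2.0 * e)  # (P, S)

    M = np.outer(prior, prior)
    for s in range(S):
        g = geno[s]
        if g == MISSING:
            continue
        pa = p_alt[:, s][:, None]
        pb = p_alt[:, s][None, :]
        if g == 0:
            M = M * ((1.0 - pa) * (1.0 - pb))
        elif g == 1:
            M = M * (pa * (1.0 - pb) + (1.0 - pa) * pb)
        else:
            M = M * (pa * pb)
    tot = M.sum()
    out = np.empty((S, 3))
    for s in range(S):
        g = geno[s]
        if g != MISSING:
            out[s] = 0.0
            out[s, g] = 1.0
            continue
        a = p_alt[:, s]
        p2 = a @ M @ a / tot
        p0 = (1.0 - a) @ M @ (1.0 - a) / tot
        out[s] = (p0, 1.0 - p0 - p2, p2)
    return out
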