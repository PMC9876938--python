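"""Synthetic biobank generator.

Simulates a phased haplotype panel with linkage disequilibrium and population
structure, genotyping-array manifests with partial overlap, wave-structured
cohorts with missingness and genotyping error, parent–offspring trios with
known transmitted gametes, and a heritable quantitative trait.

The LD generator is a generational copying process, not a coalescent: each
new haplotype is a recombinant mosaic of two haplotypes of the previous
generation (crossover count Poisson in the map length in Morgans) plus
symmetric mutation. Population differentiation follows a Balding–Nichols
per-population allele-frequency draw. Diploid individuals are consecutive
haplotype pairs, so truth phase is known for every simulated sample.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    ArrayDesign,
    CohortDataset,
    HaplotypePanel,
    PhenotypeSet,
    PopulationModel,
    TrioSet,
)

__all__ = [
    "simulate_panel",
    "make_array_designs",
    "genotype_cohort",
    "make_trios",
    "simulate_phenotype",
    "HapPool",
]


def _recombinant(parent_a: np.ndarray, parent_b: np.ndarray, cm: np.ndarray,
                 map_length_cm: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete: mosaic of two haplotypes with Poisson(L/100) crossovers."""
    n_x = rng.poisson(map_length_cm / 100.0)
    start_with_a = bool(rng.integers(2))
    if n_x == 0:
        return (parent_a if start_with_a else parent_b).copy()
    breaks = np.sort(rng.uniform(0.0, map_length_cm, size=n_x))
    # segment index at each site = number of breakpoints passed
    seg = np.searchsorted(breaks, cm, side="right")
    use_a = (seg % 2 == 0) if start_with_a else (seg % 2 == 1)
    return np.where(use_a, parent_a, parent_b).astype(np.uint8)


def simulate_panel(
    model: PopulationModel,
    n_sites: int,
    n_haplotypes: int,
    map_length_cm: float = 100.0,
    mutation_rate: float = 1e-4,
    n_generations: int = 10,
    seed: int = 0,
    founders: np.ndarray | None = None,
    n_founders: int | None = None,
    growth: str = "immediate",
    chrom: str = "1",
) -> HaplotypePanel:
    """Simulate a phased haplotype panel.

    Parameters
    ----------
    model
        Population structure (number of populations, Fst, weights).
    n_sites, n_haplotypes
        Panel dimensions; ``n_haplotypes`` must be even so haplotypes can be
        paired into diploids.
    map_length_cm
        Total genetic map length of the single simulated chromosome.
    mutation_rate
        Per-site, per-generation symmetric allele-flip probability.
    n_generations
        Copying generations; 0 returns the founders unchanged.
    founders
        Optional explicit founder haplotypes; overrides the Balding–Nichols
        draw (used mainly for controlled tests).
    n_founders
        Size of the founder pool (default: ``n_haplotypes``). A founder pool
        smaller than the output pool acts as a population bottleneck: final
        haplotypes are recombinant mosaics of few distinct founders, which is
        what creates linkage disequilibrium in this generational model.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    if n_haplotypes % 2 != 0:
        raise ValueError("n_haplotypes must be even")
    rng = np.random.default_rng(seed)
    fst = model.fst_array()

    bp = np.cumsum(rng.integers(10, 200, size=n_sites)).astype(np.int64)
    gaps = rng.uniform(0.5, 1.5, size=n_sites - 1)
    cm = np.concatenate([[0.0], np.cumsum(gaps)])
    if cm[-1] > 0:
        cm = cm * (map_length_cm / cm[-1])

    w = model.weights()

    def _allocate(total: int, weights: np.ndarray) -> np.ndarray:
        counts = np.floor(weights * total).astype(int)
        counts = np.maximum(counts, 1 if total >= model.n_pops else 0)
        counts[0] += total - counts.sum()
        return np.repeat(np.arange(model.n_pops), counts)

    pop_of_hap = _allocate(n_haplotypes, w)
    # ancestral diversity is split evenly across populations: a small modern
    # population is not less diverse, merely less represented
    w_founder = np.full(model.n_pops, 1.0 / model.n_pops)

    if founders is not None:
        haps = np.asarray(founders, dtype=np.uint8).copy()
        pop_of_founder = _allocate(haps.shape[0], w_founder if n_generations > 0 else w)
        if n_generations == 0:
            pop_of_founder = pop_of_hap
    else:
        n_f = n_haplotypes if n_founders is None else int(n_founders)
        if n_generations == 0 and n_f != n_haplotypes:
            raise ValueError("with 0 generations the founders are the output")
        pop_of_founder = _allocate(n_f, w_founder) if n_f != n_haplotypes else pop_of_hap
        lo, hi = model.ancestral_freq_range
        p_anc = rng.uniform(lo, hi, size=n_sites)
        freqs = np.empty((model.n_pops, n_sites))
        for k in range(model.n_pops):
            f = fst[k]
            if f == 0.0:
                freqs[k] = p_anc
            else:
                a = p_anc * (1.0 - f) / f
                b = (1.0 - p_anc) * (1.0 - f) / f
                freqs[k] = rng.beta(a, b)
        haps = (rng.random((n_f, n_sites)) < freqs[pop_of_founder]).astype(np.uint8)

    # population expands from the founder bottleneck to the full panel size;
    # "immediate" (default) jumps to full size in the first generation, so
    # LD comes from founder-block sharing while recent shared ancestry among
    # final haplotypes stays rare; "geometric" grows the pool gradually
    n_start = haps.shape[0]
    if n_generations > 0:
        if growth == "immediate":
            sizes = [n_haplotypes] * n_generations
        elif growth == "geometric":
            ratio = (n_haplotypes / n_start) ** (1.0 / n_generations)
            sizes = [min(n_haplotypes, max(n_start, int(round(n_start * ratio ** g))))
                     for g in range(1, n_generations + 1)]
            sizes[-1] = n_haplotypes
        else:
            raise ValueError(f"unknown growth schedule {growth!r}")
    else:
        sizes = []
    pop_of_cur = pop_of_founder
    for size in sizes:
        pop_of_new = pop_of_hap if size == n_haplotypes else _allocate(size, w)
        new = np.empty((size, n_sites), dtype=np.uint8)
        for k in range(model.n_pops):
            rows = np.flatnonzero(pop_of_new == k)
            src = np.flatnonzero(pop_of_cur == k)
            if rows.size == 0:
                continue
            if src.size == 0:
                raise ValueError(f"no source haplotypes for population {k}")
            pa = rng.choice(src, size=rows.size)
            pb = rng.choice(src, size=rows.size)
            for i, r in enumerate(rows):
                new[r] = _recombinant(haps[pa[i]], haps[pb[i]], cm, map_length_cm, rng)
        if mutation_rate > 0:
            flips = rng.random(new.shape) < mutation_rate
            new ^= flips.astype(np.uint8)
        haps = new
        pop_of_cur = pop_of_new

    if n_generations == 0 and haps.shape[0] != n_haplotypes:
        raise ValueError("founder pool does not match n_haplotypes")
    return HaplotypePanel(
        chrom=chrom,
        bp=bp,
        cm=cm,
        ref=np.full(n_sites, "A"),
        alt=np.full(n_sites, "G"),
        haplotypes=haps,
        pop_label=np.array([f"pop{k}" for k in pop_of_hap]),
        founder_flag=np.full(n_haplotypes, n_generations == 0),
    )


def make_array_designs(
    panel: HaplotypePanel,
    size_a: int,
    size_b: int,
    overlap_count: int,
    seed: int = 0,
    names: tuple[str, str] = ("arrayA", "arrayB"),
) -> tuple[ArrayDesign, ArrayDesign]:
    """Two array manifests with a specified marker overlap."""
    n = panel.n_sites
    if overlap_count > min(size_a, size_b):
        raise ValueError("overlap cannot exceed either array size")
    if size_a + size_b - overlap_count > n:
        raise ValueError("designs do not fit on the panel")
    rng = np.random.default_rng(seed)
    pool = rng.permutation(n)
    shared = pool[:overlap_count]
    only_a = pool[overlap_count:overlap_count + size_a - overlap_count]
    rest = pool[overlap_count + size_a - overlap_count:]
    only_b = rest[:size_b - overlap_count]
    a = np.sort(np.concatenate([shared, only_a]))
    b = np.sort(np.concatenate([shared, only_b]))
    return ArrayDesign(names[0], a), ArrayDesign(names[1], b)


class HapPool:
    """Hands out unused panel haplotype rows per population, without reuse."""

    def __init__(self, panel: HaplotypePanel, rng: np.random.Generator):
        self._avail = {}
        for pop in np.unique(panel.pop_label):
            rows = np.flatnonzero(panel.pop_label == pop)
            self._avail[str(pop)] = list(rng.permutation(rows))

    def take(self, pop: str, n: int) -> np.ndarray:
        rows = self._avail.get(pop, [])
        if len(rows) < n:
            raise ValueError(f"haplotype pool for {pop} exhausted (need {n}, have {len(rows)})")
        out = np.array([rows.pop() for _ in range(n)], dtype=np.int64)
        return out

    def remaining(self, pop: str) -> int:
        return len(self._avail.get(pop, []))


def _sample_hap_pairs(pop_mix: dict, n_samples: int, pool: HapPool,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Assign each sample a population label and two panel haplotype rows.

    Labels of the form ``admix_i_j`` draw one gamete from ``pop{i}`` and one
    from ``pop{j}`` (one parent from each population).
    """
    labels = list(pop_mix)
    probs = np.array([pop_mix[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    n_per = np.floor(probs * n_samples).astype(int)
    n_per[0] += n_samples - n_per.sum()
    sample_label, pairs = [], []
    for lab, cnt in zip(labels, n_per):
        if cnt == 0:
            continue
        if lab.startswith("admix_"):
            _, i, j = lab.split("_")
            h1 = pool.take(f"pop{i}", cnt)
            h2 = pool.take(f"pop{j}", cnt)
        else:
            rows = pool.take(lab, 2 * cnt)
            h1, h2 = rows[:cnt], rows[cnt:]
        pairs.append(np.stack([h1, h2], axis=1))
        sample_label.extend([lab] * cnt)
    pair_arr = np.concatenate(pairs, axis=0)
    order = rng.permutation(n_samples)
    return np.array(sample_label)[order], pair_arr[order]


def genotype_cohort(
    panel: HaplotypePanel,
    design: ArrayDesign,
    n_samples: int,
    pop_mix: dict | None = None,
    n_waves: int = 6,
    per_wave_missing_rate=0.01,
    error_rate: float = 0.0,
    seed: int = 0,
    name: str = "cohort",
    pool: HapPool | None = None,
    case_rate: float = 0.3,
) -> CohortDataset:
    """Genotype diploid samples on one array design.

    Genotype = sum of the two underlying haplotype alleles; a symmetric
    per-allele flip with probability ``error_rate`` is applied, then
    missingness is injected per genotyping wave (``per_wave_missing_rate`` is
    a scalar or one rate per wave).
    """
    rng = np.random.default_rng(seed)
    rates = np.broadcast_to(np.asarray(per_wave_missing_rate, dtype=float), (n_waves,))
    if np.any((rates < 0) | (rates > 1)) or not (0 <= error_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if pop_mix is None:
        pop_mix = {str(np.unique(panel.pop_label)[0]): 1.0}
    if pool is None:
        pool = HapPool(panel, rng)
    labels, pairs = _sample_hap_pairs(pop_mix, n_samples, pool, rng)

    sites = design.site_indices
    h1 = panel.haplotypes[pairs[:, 0]][:, sites].astype(np.int8)
    h2 = panel.haplotypes[pairs[:, 1]][:, sites].astype(np.int8)
    if error_rate > 0:
        h1 = h1 ^ (rng.random(h1.shape) < error_rate).astype(np.int8)
        h2 = h2 ^ (rng.random(h2.shape) < error_rate).astype(np.int8)
    geno = (h1 + h2).astype(np.int8)

    wave = rng.integers(0, n_waves, size=n_samples)
    for wv in range(n_waves):
        rows = np.flatnonzero(wave == wv)
        if rows.size and rates[wv] > 0:
            miss = rng.random((rows.size, geno.shape[1])) < rates[wv]
            sub = geno[rows]
            sub[miss] = MISSING
            geno[rows] = sub

    samples = pd.DataFrame({
        "id": [f"{name}_s{i:05d}" for i in range(n_samples)],
        "wave": wave,
        "case": rng.random(n_samples) < case_rate,
        "pop_label": labels,
        "age": rng.integers(18, 66, size=n_samples),
        "sex": rng.integers(0, 2, size=n_samples),
    })
    return CohortDataset(genotypes=geno, site_indices=sites.copy(), samples=samples,
                         provenance=f"simulated:{name}", hap_pair=pairs)


def make_trios(
    panel: HaplotypePanel,
    n_trios: int,
    designs: tuple[ArrayDesign, ArrayDesign],
    map_length_cm: float,
    seed: int = 0,
    pool: HapPool | None = None,
    pop: str = "pop0",
) -> TrioSet:
    """Parent–offspring trios genotyped (error-free) on both arrays.

    Offspring haplotypes are recombinant gametes of the parents; the
    transmitted gametes are stored so trio phase can be resolved exactly.
    """
    rng = np.random.default_rng(seed)
    if pool is None:
        pool = HapPool(panel, rng)
    rows = pool.take(pop, 4 * n_trios).reshape(n_trios, 4)
    S = panel.n_sites
    pat = np.empty((n_trios, S), dtype=np.uint8)
    mat = np.empty((n_trios, S), dtype=np.uint8)
    for t in range(n_trios):
        f1, f2, m1, m2 = panel.haplotypes[rows[t]]
        pat[t] = _recombinant(f1, f2, panel.cm, map_length_cm, rng)
        mat[t] = _recombinant(m1, m2, panel.cm, map_length_cm, rng)

    genotypes, design_sites = {}, {}
    for d in designs:
        s = d.site_indices
        father = (panel.haplotypes[rows[:, 0]][:, s] + panel.haplotypes[rows[:, 1]][:, s]).astype(np.int8)
        mother = (panel.haplotypes[rows[:, 2]][:, s] + panel.haplotypes[rows[:, 3]][:, s]).astype(np.int8)
        child = (pat[:, s] + mat[:, s]).astype(np.int8)
        genotypes[d.name] = {"father": father, "mother": mother, "offspring": child}
        design_sites[d.name] = s.copy()

    return TrioSet(
        trio_ids=[f"trio{t:03d}" for t in range(n_trios)],
        genotypes=genotypes,
        design_sites=design_sites,
        offspring_pat=pat,
        offspring_mat=mat,
        parent_hap_rows=rows,
    )


def simulate_phenotype(
    truth_genotypes: np.ndarray,
    sample_ids: np.ndarray,
    causal_sites: np.ndarray,
    h2: float = 0.5,
    seed: int = 0,
) -> PhenotypeSet:
    """Quantitative trait from standardized causal genotypes.

    g = Z @ beta with Z the column-standardized genotype matrix at the causal
    sites and beta ~ N(0, 1); environmental noise is scaled so that
    var(g)/var(y) = h2 in expectation. Monomorphic causal sites contribute
    nothing (beta recorded, effect skipped).
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    X = np.asarray(truth_genotypes, dtype=float)
    n, m = X.shape
    beta = rng.standard_normal(m)
    p = X.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    poly = sd > 0
    Z = np.zeros_like(X)
    Z[:, poly] = (X[:, poly] - 2.0 * p[poly]) / sd[poly]
    g = Z @ beta
    beta_raw = np.where(poly, beta / np.where(poly, sd, 1.0), 0.0)

    var_g = g.var()
    if h2 == 0.0 or var_g == 0.0:
        e = rng.standard_normal(n)
        y = e if h2 == 0.0 else g + 0.0 * e
        if h2 != 0.0:
            y = g  # degenerate: no genetic variance to scale against
    elif h2 == 1.0:
        y = g.copy()
    else:
        sigma_e = np.sqrt(var_g * (1.0 - h2) / h2)
        y = g + rng.standard_normal(n) * sigma_e
    return PhenotypeSet(
        sample_ids=np.asarray(sample_ids),
        g=g,
        y=y,
        causal_sites=np.asarray(causal_sites, dtype=np.int64),
        beta_std=beta,
        beta_raw=beta_raw,
        h2=h2,
    )
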