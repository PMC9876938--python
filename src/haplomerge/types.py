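"""Core containers shared across the pipeline.

Conventions: sites are indexed 0-based against a single simulated chromosome
(`HaplotypePanel.sites`); genotypes count alt alleles (0/1/2) with ``-1`` for
missing; dosages count alt alleles in [0, 2].
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1  # genotype sentinel


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes with physical and genetic positions.

    ``haplotypes`` is an (H, S) uint8 matrix (alt = 1). ``pop_label`` and
    ``founder_flag`` are per-haplotype. Serves both as the imputation
    reference panel and as the ground truth that protocols are scored
    against.
    """

    chrom: str
    bp: np.ndarray          # (S,) int, strictly increasing
    cm: np.ndarray          # (S,) float, non-decreasing
    ref: np.ndarray         # (S,) allele labels
    alt: np.ndarray
    haplotypes: np.ndarray  # (H, S) uint8
    pop_label: np.ndarray   # (H,) str
    founder_flag: np.ndarray  # (H,) bool

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if np.any(np.diff(self.bp) <= 0):
            raise ValueError("bp positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("cm positions must be non-decreasing")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_sites(self) -> int:
        return self.bp.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def allele_freq(self, hap_rows: np.ndarray | None = None) -> np.ndarray:
        """Alt-allele frequency per site over all (or a subset of) haplotypes."""
        H = self.haplotypes if hap_rows is None else self.haplotypes[hap_rows]
        return H.mean(axis=0)

    def maf(self, hap_rows: np.ndarray | None = None) -> np.ndarray:
        f = self.allele_freq(hap_rows)
        return np.minimum(f, 1.0 - f)


@dataclass
class PopulationModel:
    """Balding–Nichols style population structure.

    Per-population allele frequencies are drawn around an ancestral frequency
    with variance governed by ``fst``; admixed individuals carry one gamete
    from each of two populations.
    """

    n_pops: int = 1
    fst: Sequence[float] | float = 0.0
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    admixture_specs: list[tuple[int, int, float]] = field(default_factory=list)
    pop_weights: Sequence[float] | None = None

    def fst_array(self) -> np.ndarray:
        f = np.broadcast_to(np.asarray(self.fst, dtype=float), (self.n_pops,)).copy()
        if np.any((f < 0) | (f >= 1)):
            raise ValueError("fst must lie in [0, 1)")
        return f

    def weights(self) -> np.ndarray:
        if self.pop_weights is None:
            w = np.full(self.n_pops, 1.0 / self.n_pops)
        else:
            w = np.asarray(self.pop_weights, dtype=float)
            w = w / w.sum()
        if len(w) != self.n_pops:
            raise ValueError("pop_weights length must equal n_pops")
        return w

    def __post_init__(self) -> None:
        for a, b, prop in self.admixture_specs:
            if not (0.0 < prop < 1.0):
                raise ValueError("admixture proportions must lie in (0, 1)")
            if not (0 <= a < self.n_pops and 0 <= b < self.n_pops):
                raise ValueError("admixture populations out of range")


@dataclass
class ArrayDesign:
    """A genotyping array manifest: an ordered subset of panel sites."""

    name: str
    site_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.site_indices, dtype=np.int64)
        if idx.size and (np.any(np.diff(idx) <= 0) or idx[0] < 0):
            raise ValueError("site indices must be strictly increasing and non-negative")
        self.site_indices = idx

    @property
    def n_sites(self) -> int:
        return self.site_indices.shape[0]


@dataclass
class CohortDataset:
    """Diploid genotypes for one cohort on one site set, plus metadata.

    ``genotypes`` is (N, S) int8 over {0,1,2,-1}; ``site_indices`` maps the
    S columns to panel sites; ``samples`` has one row per sample with columns
    id, wave, case, pop_label, age, sex. ``hap_pair`` holds the panel rows
    of each sample's two true haplotypes (-1 where the truth lives elsewhere,
    e.g. trio offspring gametes).
    """

    genotypes: np.ndarray
    site_indices: np.ndarray
    samples: pd.DataFrame
    provenance: str = ""
    hap_pair: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.site_indices = np.asarray(self.site_indices, dtype=np.int64)
        if self.genotypes.shape[0] != len(self.samples):
            raise ValueError("genotype rows must match sample metadata")
        if self.genotypes.shape[1] != self.site_indices.shape[0]:
            raise ValueError("genotype columns must match site set")
        if self.samples["id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotypes must be in {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.site_indices.shape[0]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["id"].to_numpy()

    def missing_fraction(self) -> float:
        return float((self.genotypes == MISSING).mean()) if self.genotypes.size else 0.0

    def subset_sites(self, keep: np.ndarray, provenance: str | None = None) -> "CohortDataset":
        """New dataset restricted to the panel sites in ``keep`` (sorted)."""
        keep = np.asarray(sorted(set(np.asarray(keep).tolist())), dtype=np.int64)
        pos = {s: i for i, s in enumerate(self.site_indices.tolist())}
        cols = np.array([pos[s] for s in keep.tolist() if s in pos], dtype=np.int64)
        kept_sites = self.site_indices[cols]
        return CohortDataset(
            genotypes=self.genotypes[:, cols],
            site_indices=kept_sites,
            samples=self.samples.reset_index(drop=True).copy(),
            provenance=provenance or self.provenance,
            hap_pair=None if self.hap_pair is None else self.hap_pair.copy(),
        )

    def subset_samples(self, row_mask: np.ndarray, provenance: str | None = None) -> "CohortDataset":
        row_mask = np.asarray(row_mask)
        return CohortDataset(
            genotypes=self.genotypes[row_mask],
            site_indices=self.site_indices.copy(),
            samples=self.samples.iloc[row_mask].reset_index(drop=True),
            provenance=provenance or self.provenance,
            hap_pair=None if self.hap_pair is None else self.hap_pair[row_mask],
        )


@dataclass
class TrioSet:
    """Parent–offspring trios genotyped on both arrays, with truth gametes."""

    trio_ids: list[str]
    # per design name: dict with 'father', 'mother', 'offspring' (n_trios, S_design) matrices
    genotypes: dict
    design_sites: dict          # design name -> site indices
    offspring_pat: np.ndarray   # (n_trios, S_panel) transmitted paternal gamete
    offspring_mat: np.ndarray   # (n_trios, S_panel) transmitted maternal gamete
    parent_hap_rows: np.ndarray  # (n_trios, 4) panel rows of parental haplotypes

    @property
    def n_trios(self) -> int:
        return len(self.trio_ids)


@dataclass
class PhenotypeSet:
    """Simulated quantitative trait: y = g + e with var(g)/var(y) = h2."""

    sample_ids: np.ndarray
    g: np.ndarray
    y: np.ndarray
    causal_sites: np.ndarray
    beta_std: np.ndarray   # effects on standardized genotypes, N(0,1)
    beta_raw: np.ndarray   # implied per-alt-allele effects
    h2: float


@dataclass
class PhasedHaplotypes:
    """Phased output: two haplotype vectors per sample over one site set."""

    sample_ids: np.ndarray
    site_indices: np.ndarray
    h1: np.ndarray           # (N, S) uint8
    h2: np.ndarray           # (N, S) uint8
    certainty: np.ndarray    # (N, S) float32 phase certainty
    imputed: np.ndarray      # (N, S) bool; True where genotype was missing

    def genotype(self) -> np.ndarray:
        return (self.h1.astype(np.int8) + self.h2.astype(np.int8))


@dataclass
class DosageMatrix:
    """Imputed alt-allele dosages with a per-site quality estimate."""

    sample_ids: np.ndarray
    site_indices: np.ndarray
    ds: np.ndarray           # (N, S) float, in [0, 2]
    dr2: np.ndarray          # (S,) in [0, 1]
    ref_maf: np.ndarray      # (S,) reference-panel MAF
    hard_calls: np.ndarray | None = None  # (N, S) posterior-mode genotypes

    def __post_init__(self) -> None:
        if self.ds.size and (self.ds.min() < -1e-9 or self.ds.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")
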