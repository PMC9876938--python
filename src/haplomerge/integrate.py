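"""The four data-integration protocols and the masked-SNP evaluation design.

Protocols combine two cohorts genotyped on different arrays before phasing:

* separate     — each cohort phased and imputed on its own marker set;
* intersection — cohorts merged at the markers common to both arrays;
* union        — cohorts merged at the markers on either array, with
                 structural missingness where a sample's array lacks a marker;
* two-stage    — separately phased cohorts are imputed to the union marker
                 set, hard-called, merged with zero missingness, re-phased
                 jointly, then split back to their genotyped markers.

A random subset of the shared markers is masked before any protocol is
built, so every protocol is scored on the identical held-out site set.
Dual-genotyped trio offspring enter merged protocols once, with the array
version chosen by seeded randomization (half from each array).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MISSING, CohortDataset, PhasedHaplotypes

__all__ = [
    "MaskSet", "mask_snps", "append_samples", "split_trio_versions",
    "build_separate", "build_intersection", "build_union",
    "stage1_fill", "merge_stage1", "split_back",
]

PROTOCOLS = ("separate", "intersection", "union", "two_stage")


@dataclass
class MaskSet:
    """Held-out shared markers; truth stays outside every phasing input."""

    site_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.site_indices = np.sort(np.asarray(self.site_indices, dtype=np.int64))

    @property
    def n_sites(self) -> int:
        return len(self.site_indices)


def mask_snps(cohorts: list[CohortDataset], k: int, seed: int = 0) -> tuple[MaskSet, list[CohortDataset]]:
    """Randomly hold out ``k`` sites shared by all cohorts.

    Returns the mask and the cohorts with those sites removed from their
    genotyped site sets.
    """
    shared = cohorts[0].site_indices
    for c in cohorts[1:]:
        shared = np.intersect1d(shared, c.site_indices)
    if k > shared.size:
        raise ValueError(f"cannot mask {k} of {shared.size} shared sites")
    rng = np.random.default_rng(seed)
    masked = np.sort(rng.choice(shared, size=k, replace=False))
    mask = MaskSet(site_indices=masked, seed=seed)
    reduced = [c.subset_sites(np.setdiff1d(c.site_indices, masked),
                              provenance=c.provenance + "+masked") for c in cohorts]
    return mask, reduced


def append_samples(cohort: CohortDataset, extra: CohortDataset,
                   provenance: str | None = None) -> CohortDataset:
    """Concatenate samples of two datasets on an identical site set."""
    if not np.array_equal(cohort.site_indices, extra.site_indices):
        raise ValueError("site sets must match to append samples")
    hp = None
    if cohort.hap_pair is not None and extra.hap_pair is not None:
        hp = np.vstack([cohort.hap_pair, extra.hap_pair])
    return CohortDataset(
        genotypes=np.vstack([cohort.genotypes, extra.genotypes]),
        site_indices=cohort.site_indices.copy(),
        samples=pd.concat([cohort.samples, extra.samples], ignore_index=True),
        provenance=provenance or cohort.provenance,
        hap_pair=hp,
    )


def build_separate(cohort_a: CohortDataset, cohort_b: CohortDataset,
                   offspring_a: CohortDataset | None = None,
                   offspring_b: CohortDataset | None = None) -> tuple[CohortDataset, CohortDataset]:
    """Pass-through protocol: each cohort keeps its own marker set.

    Trio offspring (genotyped on both arrays) are appended to both cohorts,
    each on the matching array's markers.
    """
    out_a = cohort_a if offspring_a is None else append_samples(
        cohort_a, offspring_a.subset_sites(cohort_a.site_indices))
    out_b = cohort_b if offspring_b is None else append_samples(
        cohort_b, offspring_b.subset_sites(cohort_b.site_indices))
    out_a = CohortDataset(out_a.genotypes, out_a.site_indices, out_a.samples,
                          provenance="protocol:separate:A", hap_pair=out_a.hap_pair)
    out_b = CohortDataset(out_b.genotypes, out_b.site_indices, out_b.samples,
                          provenance="protocol:separate:B", hap_pair=out_b.hap_pair)
    return out_a, out_b


def split_trio_versions(offspring_a: CohortDataset, offspring_b: CohortDataset,
                        seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Choose which array version of each dual-genotyped offspring enters a merge.

    A random half takes the array-A version, the rest the array-B version
    (seeded, so every merged protocol retains the same choice).
    """
    ids = offspring_a.sample_ids
    if not np.array_equal(ids, offspring_b.sample_ids):
        raise ValueError("offspring datasets must hold the same samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    half = len(ids) // 2
    from_a = np.zeros(len(ids), dtype=bool)
    from_a[order[:half]] = True
    return from_a, ~from_a


def _merge(cohort_a: CohortDataset, cohort_b: CohortDataset, sites: np.ndarray,
           offspring_a: CohortDataset | None, offspring_b: CohortDataset | None,
           seed: int, provenance: str) -> CohortDataset:
    """Merge two cohorts (plus chosen trio-offspring versions) onto ``sites``."""
    parts = []
    for cohort, tag in ((cohort_a, "A"), (cohort_b, "B")):
        own = np.intersect1d(sites, cohort.site_indices)
        sub = cohort.subset_sites(own)
        geno = np.full((sub.n_samples, len(sites)), MISSING, dtype=np.int8)
        cols = np.searchsorted(sites, sub.site_indices)
        geno[:, cols] = sub.genotypes
        parts.append(CohortDataset(geno, sites, sub.samples, provenance, sub.hap_pair))
    merged = append_samples(parts[0], parts[1], provenance)
    if offspring_a is not None and offspring_b is not None:
        from_a, from_b = split_trio_versions(offspring_a, offspring_b, seed)
        for off, pick in ((offspring_a, from_a), (offspring_b, from_b)):
            sub = off.subset_samples(pick)
            own = np.intersect1d(sites, sub.site_indices)
            sub = sub.subset_sites(own)
            geno = np.full((sub.n_samples, len(sites)), MISSING, dtype=np.int8)
            cols = np.searchsorted(sites, sub.site_indices)
            geno[:, cols] = sub.genotypes
            merged = append_samples(
                merged, CohortDataset(geno, sites, sub.samples, provenance, sub.hap_pair),
                provenance)
    return merged


def build_intersection(cohort_a: CohortDataset, cohort_b: CohortDataset,
                       offspring_a: CohortDataset | None = None,
                       offspring_b: CohortDataset | None = None,
                       seed: int = 0) -> CohortDataset:
    """Merge at the markers common to both arrays."""
    sites = np.intersect1d(cohort_a.site_indices, cohort_b.site_indices)
    if sites.size == 0:
        raise ValueError("cohorts share no sites")
    return _merge(cohort_a, cohort_b, sites, offspring_a, offspring_b, seed,
                  "protocol:intersection")


def build_union(cohort_a: CohortDataset, cohort_b: CohortDataset,
                offspring_a: CohortDataset | None = None,
                offspring_b: CohortDataset | None = None,
                seed: int = 0) -> CohortDataset:
    """Merge at the markers on either array; off-array markers are missing."""
    sites = np.union1d(cohort_a.site_indices, cohort_b.site_indices)
    return _merge(cohort_a, cohort_b, sites, offspring_a, offspring_b, seed,
                  "protocol:union")


def stage1_fill(phased: PhasedHaplotypes, cohort: CohortDataset,
                dosage_hard_calls: np.ndarray, union_sites: np.ndarray) -> CohortDataset:
    """Stage 1 of the two-stage protocol for one cohort.

    Extends the cohort to ``union_sites`` using hard-called imputed genotypes
    (posterior-mode) at markers its own array lacks; observed calls are never
    overwritten. The result has zero missingness.
    """
    union_sites = np.asarray(union_sites, dtype=np.int64)
    n = cohort.n_samples
    geno = np.asarray(dosage_hard_calls, dtype=np.int8).copy()
    if geno.shape != (n, len(union_sites)):
        raise ValueError("hard-call matrix must cover samples x union sites")
    cols = np.searchsorted(union_sites, cohort.site_indices)
    own = cohort.genotypes
    obs = own != MISSING
    sub = geno[:, cols]
    sub[obs] = own[obs]
    geno[:, cols] = sub
    if (geno == MISSING).any():
        raise ValueError("stage-1 output must have zero missingness")
    return CohortDataset(geno, union_sites, cohort.samples.copy(),
                         provenance="protocol:two_stage:stage1", hap_pair=cohort.hap_pair)


def merge_stage1(filled_a: CohortDataset, filled_b: CohortDataset,
                 offspring_ids: np.ndarray | None = None,
                 seed: int = 0) -> CohortDataset:
    """Merge the two zero-missingness stage-1 cohorts for joint re-phasing.

    Offspring present in both cohorts are kept once, with the version chosen
    by the same seeded half/half split as the other merged protocols.
    """
    if not np.array_equal(filled_a.site_indices, filled_b.site_indices):
        raise ValueError("stage-1 cohorts must share the union site set")
    if offspring_ids is not None and len(offspring_ids):
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(offspring_ids))
        half = len(offspring_ids) // 2
        take_a = set(np.asarray(offspring_ids)[order[:half]].tolist())
        take_b = set(np.asarray(offspring_ids)[order[half:]].tolist())
        keep_a = np.array([sid not in take_b for sid in filled_a.sample_ids])
        keep_b = np.array([sid not in take_a for sid in filled_b.sample_ids])
        filled_a = filled_a.subset_samples(keep_a)
        filled_b = filled_b.subset_samples(keep_b)
    return append_samples(filled_a, filled_b, "protocol:two_stage:merged")


def split_back(phased: PhasedHaplotypes, sample_ids: np.ndarray,
               site_indices: np.ndarray) -> PhasedHaplotypes:
    """Restore one cohort's genotyped site set after joint re-phasing."""
    rows = pd.Index(phased.sample_ids).get_indexer(sample_ids)
    if (rows < 0).any():
        raise ValueError("samples missing from the merged phased set")
    pos = pd.Index(phased.site_indices).get_indexer(site_indices)
    if (pos < 0).any():
        raise ValueError("sites missing from the merged phased set")
    return PhasedHaplotypes(
        sample_ids=np.asarray(sample_ids).copy(),
        site_indices=np.asarray(site_indices, dtype=np.int64).copy(),
        h1=phased.h1[np.ix_(rows, pos)],
        h2=phased.h2[np.ix_(rows, pos)],
        certainty=phased.certainty[np.ix_(rows, pos)],
        imputed=phased.imputed[np.ix_(rows, pos)],
    )
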