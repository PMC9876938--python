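"""End-to-end experiment driver.

Chains simulate -> qc -> integrate -> phase/impute -> evaluate -> pgs on the
synthetic biobank and emits tidy TSV reports. Every stage draws from its own
named random stream derived from the master seed, so outputs are
bit-reproducible for a given configuration.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evalmetrics, integrate, lshmm, pgsassoc, qc, simcore
from .rand import stage_rng, stage_seed
from .types import (CohortDataset, DosageMatrix, HaplotypePanel, PhenotypeSet,
                    PopulationModel, TrioSet)

__all__ = ["RunConfig", "SimData", "run_all", "simulate_biobank", "run_qc",
           "build_protocols", "phase_impute_protocols", "evaluate_protocols",
           "pgs_experiment", "truth_genotypes"]


@dataclass
class RunConfig:
    """Desk-scale defaults: one chromosome, two cohorts on two arrays.

    Array sizes follow the ~1 : 1.8 size ratio and ~28% overlap of the two
    production arrays this study emulates, scaled to a 2,000-site chromosome.
    """

    seed: int = 0
    # panel: a founder bottleneck recombined over generations in a large
    # pool gives array-like LD with little close relatedness among samples
    n_sites: int = 2000
    n_haplotypes: int = 12000
    n_founders: int = 96
    map_length_cm: float = 200.0
    mutation_rate: float = 3e-4
    n_generations: int = 16
    fst: tuple = (0.0, 0.1)
    pop_weights: tuple = (0.85, 0.15)
    # arrays
    array_a_size: int = 840
    array_b_size: int = 1510
    array_overlap: int = 400
    # cohorts
    n_cohort_a: int = 600
    n_cohort_b: int = 400
    n_waves: int = 6
    wave_missing_rate: float = 0.01
    genotyping_error: float = 1e-3
    pop_mix: dict = field(default_factory=lambda: {"pop0": 0.80, "pop1": 0.12, "admix_0_1": 0.08})
    # reference panel
    ref_size: int = 400
    ref_pop0_frac: float = 0.9
    # trios / mask / phenotype
    n_trios: int = 40
    mask_k: int = 100
    h2: float = 0.5
    # engine
    engine_settings: tuple = ("small",)
    n_states: dict = field(default_factory=lambda: dict(lshmm.ENGINE_SETTINGS))
    ne: float = 100.0
    hmm_error: float = 1e-3
    n_iterations: int = 2
    consensus_runs: int = 1
    # evaluation
    dr2_thresholds: tuple = (0.0, 0.5, 0.9)
    protocols: tuple = integrate.PROTOCOLS
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)

    @classmethod
    def compact(cls, seed: int = 0, **overrides) -> "RunConfig":
        """Half-scale configuration: same marker density, array-size ratios
        and population structure as the default, at half the chromosome and
        cohort sizes. Useful for quick experiments and repeated-seed studies.
        """
        base = dict(
            seed=seed,
            n_sites=1000, n_haplotypes=8000, n_founders=96,
            map_length_cm=100.0, n_generations=16,
            array_a_size=420, array_b_size=755, array_overlap=200,
            n_cohort_a=300, n_cohort_b=200, n_waves=3,
            ref_size=300, n_trios=24, mask_k=60,
            n_states={"small": 24, "large": 48},
            protocols=("separate", "intersection", "union"),
        )
        base.update(overrides)
        return cls(**base)

    def hmm_params(self, setting: str, seed_tag: str = "phase") -> lshmm.HMMParams:
        return lshmm.HMMParams(
            n_states=self.n_states[setting], ne=self.ne, error_rate=self.hmm_error,
            n_iterations=self.n_iterations,
            seed=stage_seed(self.seed, f"{seed_tag}:{setting}"),
        )


@dataclass
class SimData:
    panel: HaplotypePanel
    design_a: simcore.ArrayDesign
    design_b: simcore.ArrayDesign
    cohort_a: CohortDataset
    cohort_b: CohortDataset
    trios: TrioSet
    ref_rows: np.ndarray


def simulate_biobank(cfg: RunConfig) -> SimData:
    """Simulate the panel, arrays, cohorts, trios and reference allocation."""
    model = PopulationModel(n_pops=2, fst=list(cfg.fst), pop_weights=list(cfg.pop_weights),
                            admixture_specs=[(0, 1, 0.08)])
    panel = simcore.simulate_panel(
        model, cfg.n_sites, cfg.n_haplotypes, cfg.map_length_cm,
        cfg.mutation_rate, cfg.n_generations, seed=stage_seed(cfg.seed, "panel"),
        n_founders=cfg.n_founders)
    design_a, design_b = simcore.make_array_designs(
        panel, cfg.array_a_size, cfg.array_b_size, cfg.array_overlap,
        seed=stage_seed(cfg.seed, "designs"))

    pool = simcore.HapPool(panel, stage_rng(cfg.seed, "pool"))
    n_ref0 = int(round(cfg.ref_size * cfg.ref_pop0_frac))
    ref_rows = np.sort(np.concatenate([
        pool.take("pop0", n_ref0), pool.take("pop1", cfg.ref_size - n_ref0)]))

    cohort_a = simcore.genotype_cohort(
        panel, design_a, cfg.n_cohort_a, pop_mix=cfg.pop_mix, n_waves=cfg.n_waves,
        per_wave_missing_rate=cfg.wave_missing_rate, error_rate=cfg.genotyping_error,
        seed=stage_seed(cfg.seed, "cohortA"), name="cohA", pool=pool)
    cohort_b = simcore.genotype_cohort(
        panel, design_b, cfg.n_cohort_b, pop_mix=cfg.pop_mix, n_waves=cfg.n_waves,
        per_wave_missing_rate=cfg.wave_missing_rate, error_rate=cfg.genotyping_error,
        seed=stage_seed(cfg.seed, "cohortB"), name="cohB", pool=pool)
    trios = simcore.make_trios(panel, cfg.n_trios, (design_a, design_b),
                               cfg.map_length_cm, seed=stage_seed(cfg.seed, "trios"),
                               pool=pool)
    return SimData(panel, design_a, design_b, cohort_a, cohort_b, trios, ref_rows)


@dataclass
class QCData:
    cohort_a: CohortDataset
    cohort_b: CohortDataset
    report_a: qc.QCReport
    report_b: qc.QCReport
    pcs: pd.DataFrame          # merged-cohort PC scores (10), indexed by id
    homogeneous_ids: np.ndarray
    unrelated_ids: np.ndarray


def _site_battery(cohort: CohortDataset, thr: qc.QCThresholds) -> qc.QCReport:
    report = qc.QCReport()
    current = cohort
    for result in (
        qc.snp_missingness_filter(current, thr.snp_missing_max),
        qc.differential_missingness_test(current, thr.diffmiss_fdr),
    ):
        report.add(result)
        current = current.subset_sites(np.setdiff1d(current.site_indices, result.excluded))
    controls = (~current.samples["case"].to_numpy(dtype=bool)) & \
        (current.samples["pop_label"].to_numpy() == "pop0")
    report.add(qc.hwe_test(current, controls, thr.hwe_fdr))
    current = current.subset_sites(np.setdiff1d(current.site_indices, report.results[-1].excluded))
    report.add(qc.batch_artifact_scan(current, thr.batch_fdr))
    current = current.subset_sites(np.setdiff1d(current.site_indices, report.results[-1].excluded))
    report.add(qc.maf_censor(current, thr.maf_min))
    return report


def run_qc(sim: SimData, cfg: RunConfig) -> QCData:
    """Site and sample QC for both cohorts, plus the GWAS/PGS sample subsets."""
    thr = cfg.qc_thresholds
    cohorts = {}
    reports = {}
    for key, cohort in (("A", sim.cohort_a), ("B", sim.cohort_b)):
        rep = _site_battery(cohort, thr)
        keep_sites = np.setdiff1d(cohort.site_indices, rep.excluded_sites())
        reduced = cohort.subset_sites(keep_sites, provenance=cohort.provenance + "+siteqc")
        smiss = qc.sample_missingness_filter(reduced, thr.sample_missing_max)
        rep.add(smiss)
        keep = ~np.isin(reduced.sample_ids, smiss.excluded)
        cohorts[key] = reduced.subset_samples(keep)
        reports[key] = rep

    # merged view on shared QC'ed sites for PCA / heterozygosity / kinship
    shared = np.intersect1d(cohorts["A"].site_indices, cohorts["B"].site_indices)
    sub_a = cohorts["A"].subset_sites(shared)
    sub_b = cohorts["B"].subset_sites(shared)
    merged = integrate.append_samples(sub_a, sub_b, "qc:merged")
    scores, _ = qc.pca(merged.genotypes, n_components=10)
    pcs = pd.DataFrame(scores, index=merged.sample_ids,
                       columns=[f"PC{i+1}" for i in range(scores.shape[1])])

    # blockwise kinship: within-cohort pairs use the cohort's full QC'ed site
    # set (less estimator noise); cross-cohort pairs use the shared sites
    n_a, n_b = cohorts["A"].n_samples, cohorts["B"].n_samples
    K = np.empty((n_a + n_b, n_a + n_b))
    K[:n_a, :n_a] = qc.kinship_matrix(cohorts["A"].genotypes)
    K[n_a:, n_a:] = qc.kinship_matrix(cohorts["B"].genotypes)
    K[:n_a, n_a:] = qc.cross_kinship(sub_a.genotypes, sub_b.genotypes)
    K[n_a:, :n_a] = K[:n_a, n_a:].T

    for key in ("A", "B"):
        cohort = cohorts[key]
        rows = pcs.index.get_indexer(cohort.sample_ids)
        het = qc.ancestry_adjusted_heterozygosity(
            cohort, pcs.to_numpy()[rows], sd_threshold=thr.het_sd)
        reports[key].add(het)
        keep = ~np.isin(cohort.sample_ids, het.excluded)
        cohorts[key] = cohort.subset_samples(keep)

    anchor = np.flatnonzero(merged.samples["pop_label"].to_numpy() == "pop0")
    inlier_rows = qc.homogeneous_subset(scores, anchor, thr.mahalanobis_p)
    homogeneous_ids = merged.sample_ids[inlier_rows]
    dup, unrelated_ids = qc.duplicate_and_relatedness_filter(
        merged, thr.kinship_max, thr.duplicate_kinship, kinship=K)
    reports["A"].add(dup)

    return QCData(cohort_a=cohorts["A"], cohort_b=cohorts["B"],
                  report_a=reports["A"], report_b=reports["B"], pcs=pcs,
                  homogeneous_ids=homogeneous_ids, unrelated_ids=unrelated_ids)


def _offspring_dataset(trios: TrioSet, design_name: str, sites: np.ndarray) -> CohortDataset:
    """Trio offspring as a cohort on one array (restricted to ``sites``)."""
    g = trios.genotypes[design_name]["offspring"]
    dsites = trios.design_sites[design_name]
    keep = np.isin(dsites, sites)
    samples = pd.DataFrame({
        "id": trios.trio_ids,
        "wave": 0, "case": False, "pop_label": "pop0",
        "age": 10, "sex": 0,
    })
    return CohortDataset(genotypes=g[:, keep], site_indices=dsites[keep],
                         samples=samples, provenance=f"trio_offspring:{design_name}")


@dataclass
class ProtocolData:
    mask: integrate.MaskSet
    cohort_a: CohortDataset       # masked, QC'ed, no offspring
    cohort_b: CohortDataset
    offspring_a: CohortDataset    # offspring on array A sites (masked removed)
    offspring_b: CohortDataset
    inputs: dict                  # protocol -> phasing input datasets


def build_protocols(sim: SimData, qcd: QCData, cfg: RunConfig) -> ProtocolData:
    mask, (coh_a, coh_b) = integrate.mask_snps(
        [qcd.cohort_a, qcd.cohort_b], cfg.mask_k, seed=stage_seed(cfg.seed, "mask"))
    off_a = _offspring_dataset(sim.trios, sim.design_a.name, coh_a.site_indices)
    off_b = _offspring_dataset(sim.trios, sim.design_b.name, coh_b.site_indices)
    merge_seed = stage_seed(cfg.seed, "trio_choice")
    inputs = {}
    if "separate" in cfg.protocols or "two_stage" in cfg.protocols:
        inputs["separate"] = integrate.build_separate(coh_a, coh_b, off_a, off_b)
    if "intersection" in cfg.protocols:
        inputs["intersection"] = integrate.build_intersection(coh_a, coh_b, off_a, off_b,
                                                              seed=merge_seed)
    if "union" in cfg.protocols:
        inputs["union"] = integrate.build_union(coh_a, coh_b, off_a, off_b, seed=merge_seed)
    return ProtocolData(mask=mask, cohort_a=coh_a, cohort_b=coh_b,
                        offspring_a=off_a, offspring_b=off_b, inputs=inputs)


def _phase_maybe_consensus(dataset: CohortDataset, reference: lshmm.ReferencePanel,
                           cfg: RunConfig, setting: str, tag: str):
    runs = max(1, cfg.consensus_runs)
    if runs == 1:
        return lshmm.phase(dataset, reference, cfg.hmm_params(setting, f"phase:{tag}"))
    estimates = [lshmm.phase(dataset, reference, cfg.hmm_params(setting, f"phase:{tag}:{r}"))
                 for r in range(runs)]
    return lshmm.consensus_haplotypes(estimates)


def phase_impute_protocols(sim: SimData, prot: ProtocolData, cfg: RunConfig,
                           setting: str = "small") -> dict:
    """Phase every protocol input and impute all samples to the reference.

    Returns per protocol: the phased set(s), a DosageMatrix over all panel
    sites per original cohort side ("A"/"B"), and per-side DR2 at masked
    sites (recomputed within each side, as a production pipeline would).
    """
    reference = lshmm.ReferencePanel.from_panel(sim.panel, sim.ref_rows)
    params = cfg.hmm_params(setting, "impute")
    out = {}

    def impute_side(phased, cohort_for_passthrough):
        return lshmm.impute(phased, reference, params, cohort=cohort_for_passthrough)

    def split_rows(ids):
        side = np.full(len(ids), "T")  # trio offspring
        side[np.char.startswith(ids.astype(str), "cohA")] = "A"
        side[np.char.startswith(ids.astype(str), "cohB")] = "B"
        return side

    if "separate" in cfg.protocols:
        in_a, in_b = prot.inputs["separate"]
        ph_a = _phase_maybe_consensus(in_a, reference, cfg, setting, "separate:A")
        ph_b = _phase_maybe_consensus(in_b, reference, cfg, setting, "separate:B")
        out["separate"] = {
            "phased": {"A": ph_a, "B": ph_b},
            "dosage": {"A": impute_side(ph_a, in_a), "B": impute_side(ph_b, in_b)},
        }

    for name in ("intersection", "union"):
        if name not in cfg.protocols:
            continue
        merged = prot.inputs[name]
        ph = _phase_maybe_consensus(merged, reference, cfg, setting, name)
        dm = impute_side(ph, merged)
        side = split_rows(merged.sample_ids)
        out[name] = {"phased": {"AB": ph}, "dosage": {"AB": dm}, "side": side}

    if "two_stage" in cfg.protocols:
        in_a, in_b = prot.inputs["separate"]
        base = out.get("separate")
        if base is not None:
            ph_a, ph_b = base["phased"]["A"], base["phased"]["B"]
        else:
            ph_a = _phase_maybe_consensus(in_a, reference, cfg, setting, "separate:A")
            ph_b = _phase_maybe_consensus(in_b, reference, cfg, setting, "separate:B")
        union_sites = np.union1d(in_a.site_indices, in_b.site_indices)
        dm_a = lshmm.impute(ph_a, reference, params, target_sites=union_sites, cohort=in_a)
        dm_b = lshmm.impute(ph_b, reference, params, target_sites=union_sites, cohort=in_b)
        st_a = integrate.stage1_fill(ph_a, in_a, dm_a.hard_calls, union_sites)
        st_b = integrate.stage1_fill(ph_b, in_b, dm_b.hard_calls, union_sites)
        merged = integrate.merge_stage1(st_a, st_b,
                                        offspring_ids=prot.offspring_a.sample_ids,
                                        seed=stage_seed(cfg.seed, "trio_choice"))
        ph2 = _phase_maybe_consensus(merged, reference, cfg, setting, "two_stage")
        # split back to each cohort's genotyped markers before final imputation
        side = split_rows(merged.sample_ids)
        ids_a = merged.sample_ids[side != "B"]
        ids_b = merged.sample_ids[side != "A"]
        back_a = integrate.split_back(ph2, ids_a, in_a.site_indices)
        back_b = integrate.split_back(ph2, ids_b, in_b.site_indices)
        out["two_stage"] = {
            "phased": {"AB": ph2},
            "dosage": {"A": impute_side(back_a, in_a), "B": impute_side(back_b, in_b)},
        }
    return out


def truth_genotypes(sim: SimData, sample_ids: np.ndarray, sites: np.ndarray,
                    cohorts: list[CohortDataset] | None = None) -> np.ndarray:
    """True genotypes at arbitrary panel sites from the underlying haplotypes."""
    cohorts = cohorts if cohorts is not None else [sim.cohort_a, sim.cohort_b]
    pair_of = {}
    for c in cohorts:
        if c.hap_pair is None:
            continue
        for sid, pair in zip(c.sample_ids, c.hap_pair):
            pair_of[sid] = pair
    trio_row = {tid: t for t, tid in enumerate(sim.trios.trio_ids)}
    sites = np.asarray(sites)
    out = np.empty((len(sample_ids), len(sites)), dtype=np.int8)
    H = sim.panel.haplotypes
    for i, sid in enumerate(np.asarray(sample_ids)):
        if sid in pair_of:
            a, b = pair_of[sid]
            out[i] = H[a][sites] + H[b][sites]
        elif sid in trio_row:
            t = trio_row[sid]
            out[i] = sim.trios.offspring_pat[t][sites] + sim.trios.offspring_mat[t][sites]
        else:
            raise KeyError(f"no truth haplotypes for sample {sid}")
    return out


def _dosage_by_side(result: dict, masked_sites: np.ndarray) -> dict:
    """Per original cohort side: (sample_ids, DS at masked sites, DR2 per side)."""
    out = {}
    if "side" in result:  # merged protocol
        dm = result["dosage"]["AB"]
        cols = pd.Index(dm.site_indices).get_indexer(masked_sites)
        for key in ("A", "B"):
            rows = np.flatnonzero(result["side"] == key)
            ds = dm.ds[np.ix_(rows, cols)]
            dr2 = np.array([lshmm.dr2_quality(ds[:, j]) for j in range(ds.shape[1])])
            out[key] = {"ids": dm.sample_ids[rows], "ds": ds, "dr2": dr2}
    else:
        for key in ("A", "B"):
            dm = result["dosage"][key]
            cols = pd.Index(dm.site_indices).get_indexer(masked_sites)
            ids = dm.sample_ids
            keep = ~np.char.startswith(ids.astype(str), "trio")
            ds = dm.ds[np.ix_(np.flatnonzero(keep), cols)]
            dr2 = np.array([lshmm.dr2_quality(ds[:, j]) for j in range(ds.shape[1])])
            out[key] = {"ids": ids[keep], "ds": ds, "dr2": dr2}
    return out


def evaluate_protocols(sim: SimData, qcd: QCData, prot: ProtocolData, results: dict,
                       cfg: RunConfig, setting: str = "small") -> dict:
    """SER, r2 by MAF bin and ancestry, lambda_GC per DR2 threshold."""
    masked = prot.mask.site_indices
    shared_sites = np.intersect1d(prot.cohort_a.site_indices, prot.cohort_b.site_indices)
    truth_phase = evalmetrics.trio_resolve_phase(sim.trios, sim.design_a.name,
                                                 eval_sites=shared_sites)
    bins = evalmetrics.MafBins()
    ref_panel = lshmm.ReferencePanel.from_panel(sim.panel, sim.ref_rows)

    hom = set(qcd.homogeneous_ids)
    unrel = set(qcd.unrelated_ids)
    ser_rows, r2_frames, lam_frames = [], [], []
    for protocol, result in results.items():
        # --- SER on trio offspring at shared resolvable het sites
        for set_key, ph in result["phased"].items():
            s = evalmetrics.ser_for_trios(ph, truth_phase)
            ser_rows.append({"protocol": protocol, "setting": setting, "ser": s})
        # --- r2 and lambda from per-side dosages at masked sites
        sides = _dosage_by_side(result, masked)
        ids = np.concatenate([sides["A"]["ids"], sides["B"]["ids"]])
        ds = np.vstack([sides["A"]["ds"], sides["B"]["ds"]])
        truth = truth_genotypes(sim, ids, masked)
        cols = pd.Index(ref_panel.site_indices).get_indexer(masked)
        pooled_dr2 = np.array([lshmm.dr2_quality(ds[:, j]) for j in range(ds.shape[1])])
        dm = DosageMatrix(sample_ids=ids, site_indices=masked, ds=ds,
                          dr2=pooled_dr2, ref_maf=ref_panel.maf[cols])
        meta = pd.concat([qcd.cohort_a.samples, qcd.cohort_b.samples], ignore_index=True)
        pop_of = dict(zip(meta["id"], meta["pop_label"]))
        groups = np.array([pop_of.get(s, "trio") for s in ids])
        r2 = evalmetrics.imputation_r2_by_maf(dm, truth, bins)
        r2["stratum"] = "all"
        r2_by_pop = evalmetrics.imputation_r2_by_maf(dm, truth, bins, group_labels=groups)
        r2_by_pop["stratum"] = "by_pop"
        for f in (r2, r2_by_pop):
            f["protocol"] = protocol
            f["setting"] = setting
        r2_frames += [r2, r2_by_pop]

        # --- lambda_GC on unrelated homogeneous controls.
        # Mixed arms run at array-exclusive markers: sites genotyped on one
        # array only, where the other cohort's values are necessarily
        # imputed — the locus of cross-array batch artifacts. The
        # imputed-vs-imputed arm runs at the masked (held-out) sites.
        a_only = np.setdiff1d(prot.cohort_a.site_indices, prot.cohort_b.site_indices)
        b_only = np.setdiff1d(prot.cohort_b.site_indices, prot.cohort_a.site_indices)
        scan_rows = {}
        for key in ("A", "B"):
            sids = sides[key]["ids"]
            meta_k = (qcd.cohort_a if key == "A" else qcd.cohort_b).samples
            ctrl = set(meta_k.loc[~meta_k["case"], "id"])
            ok = np.array([(s in ctrl) and (s in hom) and (s in unrel) for s in sids])
            scan_rows[key] = np.flatnonzero(ok)
        lam_rows = []
        arm_specs = (
            ("genoA_vs_impB", a_only, ["B"]),
            ("impA_vs_genoB", b_only, ["A"]),
            ("impA_vs_impB", masked, ["A", "B"]),
        )
        for arm, arm_sites, imputed_sides in arm_specs:
            arm_data = _dosage_by_side(result, arm_sites)
            rows = evalmetrics.membership_scan_arm(
                arm_data["A"]["ds"][scan_rows["A"]],
                arm_data["B"]["ds"][scan_rows["B"]],
                [arm_data[s]["dr2"] for s in imputed_sides],
                cfg.dr2_thresholds, allow_empty=True)
            for r in rows:
                r.update({"arm": arm, "protocol": protocol, "setting": setting})
            lam_rows += rows
        lam_frames.append(pd.DataFrame(lam_rows))

    ser_df = (pd.DataFrame(ser_rows)
              .groupby(["protocol", "setting"], as_index=False)["ser"].mean())
    return {"ser": ser_df, "r2": pd.concat(r2_frames, ignore_index=True),
            "lambda": pd.concat(lam_frames, ignore_index=True),
            "masked_sites": masked}


def pgs_experiment(sim: SimData, qcd: QCData, prot: ProtocolData, results: dict,
                   cfg: RunConfig, setting: str = "small") -> tuple[pd.DataFrame, PhenotypeSet]:
    """Cross-cohort PGS arms over protocols, on the simulated trait."""
    masked = prot.mask.site_indices
    all_ids = np.concatenate([qcd.cohort_a.sample_ids, qcd.cohort_b.sample_ids])
    truth_all = truth_genotypes(sim, all_ids, masked)
    pheno = simcore.simulate_phenotype(truth_all, all_ids, masked, h2=cfg.h2,
                                       seed=stage_seed(cfg.seed, "phenotype"))
    y_of = dict(zip(pheno.sample_ids, pheno.y))

    subsets, truth, dosages, phenotype, covariates = {}, {}, {}, {}, {}
    hom = set(qcd.homogeneous_ids)
    unrel = set(qcd.unrelated_ids)
    sizes = {}
    for key, cohort in (("A", qcd.cohort_a), ("B", qcd.cohort_b)):
        meta = cohort.samples
        keep_ids = [sid for sid, pop in zip(meta["id"], meta["pop_label"])
                    if pop == "pop0" and sid in hom and sid in unrel]
        subsets[key] = np.asarray(keep_ids)
        sizes[key] = len(keep_ids)
    # covariates: age, sex and up to 10 PCs — fewer when the unrelated
    # subset is small, so the per-site OLS stays identifiable
    if min(sizes.values()) < 10:
        # too few unrelated homogeneous samples for any meaningful GWAS
        empty = pd.DataFrame(columns=["direction", "protocol", "arm", "delta_r2",
                                      "top5_overlap", "diag_mass"])
        return empty, pheno
    n_pcs = int(min(10, max(0, min(sizes.values()) // 10 - 3)))
    for key, cohort in (("A", qcd.cohort_a), ("B", qcd.cohort_b)):
        meta = cohort.samples
        truth[key] = truth_genotypes(sim, subsets[key], masked).astype(float)
        phenotype[key] = np.array([y_of[s] for s in subsets[key]])
        rows = qcd.pcs.index.get_indexer(subsets[key])
        meta_idx = meta.set_index("id").loc[subsets[key]]
        covariates[key] = np.column_stack([
            meta_idx["age"].to_numpy(float), meta_idx["sex"].to_numpy(float),
            qcd.pcs.to_numpy()[rows][:, :n_pcs],
        ])

    for protocol, result in results.items():
        sides = _dosage_by_side(result, masked)
        dosages[protocol] = {}
        for key in ("A", "B"):
            idx = pd.Index(sides[key]["ids"]).get_indexer(subsets[key])
            if (idx < 0).any():
                raise KeyError(f"PGS subset samples missing from {protocol} dosages")
            dosages[protocol][key] = sides[key]["ds"][idx]

    table = pgsassoc.run_pgs_arms(truth, dosages, phenotype, covariates)
    table["setting"] = setting
    return table, pheno


def run_all(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run the full experiment and write tidy TSV reports into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_biobank(cfg)
    qcd = run_qc(sim, cfg)
    prot = build_protocols(sim, qcd, cfg)

    ser_all, r2_all, lam_all, pgs_all = [], [], [], []
    for setting in cfg.engine_settings:
        results = phase_impute_protocols(sim, prot, cfg, setting)
        ev = evaluate_protocols(sim, qcd, prot, results, cfg, setting)
        pgs_table, _ = pgs_experiment(sim, qcd, prot, results, cfg, setting)
        ser_all.append(ev["ser"])
        r2_all.append(ev["r2"])
        lam_all.append(ev["lambda"])
        pgs_all.append(pgs_table)

    tables = {
        "ser.tsv": pd.concat(ser_all, ignore_index=True),
        "imputation_r2.tsv": pd.concat(r2_all, ignore_index=True),
        "lambda_gc.tsv": pd.concat(lam_all, ignore_index=True),
        "pgs.tsv": pd.concat(pgs_all, ignore_index=True),
        "qc_summary.tsv": pd.concat(
            [qcd.report_a.to_frame().assign(cohort="A"),
             qcd.report_b.to_frame().assign(cohort="B")], ignore_index=True),
    }
    manifest = {"seed": cfg.seed, "files": {}}
    for fname, df in tables.items():
        path = outdir / fname
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest["files"][fname] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return {"sim": sim, "qc": qcd, "protocols": prot, "tables": tables,
            "manifest": manifest}
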