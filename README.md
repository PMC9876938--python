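# haplomerge

When two cohorts are genotyped on different SNP arrays, they must be merged
before haplotype phasing and genotype imputation — and *how* they are merged
decides how much imputation accuracy is lost, how strong the resulting
array batch artifacts are, and how much polygenic-score (PGS) power
survives. `haplomerge` implements that whole evaluation as a reproducible
pipeline on a synthetic biobank: two wave-structured cohorts on two arrays
with partial marker overlap, parent–offspring trios genotyped on both
arrays, multiple ancestries with a reference panel skewed toward one of
them, and a heritable trait whose causal loci are the held-out markers.

Four pre-phasing integration protocols are compared:

| protocol | construction | cost |
|---|---|---|
| separate | phase and impute each cohort on its own markers | none up front |
| intersection | merge at the markers on *both* arrays | sparse scaffold |
| union | merge at the markers on *either* array | ~50% missingness |
| two-stage | impute each phased cohort to the union markers, merge at 0% missingness, re-phase, split back | extra imputation round |

Phasing and imputation run through a single Li–Stephens haplotype-copying
HMM: a target haplotype is modelled as a mosaic of K conditioning
haplotypes with switch probability 1−exp(−4NeΔM/K) per interval and a
symmetric per-allele copying error; imputed dosage is
DS = p(RA) + 2·p(AA) with a MaCH-Rsq style per-site quality (DR2 =
var(DS)/2p̂(1−p̂)). Protocols are scored by trio switch-error rate
(SER = phase switches / possible switches at trio-resolved heterozygous
sites), masked-site imputation r² per reference-MAF bin and ancestry group,
the genomic inflation factor λ_GC of array-membership scans
(median χ²/0.4549), and cross-cohort PGS experiments (ΔR², percentile rank
concordance, top-5% overlap).

## Worked example

```python
from haplomerge.pipeline import RunConfig, run_all

result = run_all(RunConfig(seed=1), "out/")
print(result["tables"]["ser.tsv"])
```

prints the trio switch-error rate per protocol on the default desk-scale
biobank (2,000 sites, cohorts of 600 + 400, arrays of 840/1,510 markers
with 400 shared, 100 masked markers, 40 trios):

```
       protocol setting       ser
0  intersection   small  0.309413
1      separate   small  0.157210
2     two_stage   small  0.180908
3         union   small  0.163885
```

The intersection protocol phases on a ~4× sparser scaffold and pays for it
with roughly twice the switch errors of the separate protocol. The same run
writes `imputation_r2.tsv` (masked-site r² — e.g. 0.61 for separate vs 0.33
for intersection in the 0.2 < MAF ≤ 0.5 bin, with the minority population
below the reference-matched majority), `lambda_gc.tsv` (cross-array
inflation, strongest for the union protocol's genotyped-vs-imputed arms)
and `pgs.tsv` (PGS ΔR² attenuation per error arm and top-5% rank overlap
per protocol). The numbered scripts under `analysis/` run the same stages
one at a time and narrate what each finds; the `haplomerge` CLI
(`haplomerge run-all --seed 1 --out out/`) drives everything from a shell
or a YAML config.

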