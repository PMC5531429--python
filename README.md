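# paleoweave

Haplotype-based population-structure analysis for low-coverage ancient
genomes, with a synthetic-cohort simulator for end-to-end validation.

Ancient-DNA studies of prehistoric transitions (e.g. the spread of farming,
or later Steppe-related migrations) lean on a small set of statistical
tools: pseudo-haploid genotype calls from sparse damaged reads,
D/f-statistics for formal admixture tests, Li–Stephens chromosome painting
for fine-scale haplotype sharing, polygenic scores for trait change through
time, and extended haplotype homozygosity for selection. `paleoweave`
implements that toolchain as a tested Python library plus CLI, for
population geneticists who want the methods reusable, inspectable and
verifiable against simulated truth rather than locked inside one-off
pipelines.

## What is implemented

- **`simdata`** — synthetic cohorts with the structure the analyses assume:
  Balding–Nichols differentiated sources with founder-mosaic haplotype
  sharing, Markov-process admixed individuals with recorded truth tracts,
  Poisson low-coverage reads with sequencing error and 5′ C→T deamination,
  imputation-like diploid calls with MAF-dependent error and GP posteriors,
  and a polygenic trait with known effects.
- **`calls`** — pseudo-haploid calling, GP/transversion/completeness/MAF
  filters, missing-aware allele frequencies, imputation-accuracy evaluation
  by MAF bin and genotype class, and a reference-bias D-test harness.
- **`qc`** — Ry-based sex determination, mtDNA and X-chromosome
  contamination estimators, damage-profile fitting.
- **`fstats`** — D, f3 (outgroup, with finite-sample correction), f4 and
  F4-ratio admixture proportions, all with weighted block-jackknife errors.
  Convention: D > 0 means excess P1–P3 / P2–P4 sharing,

      D = Σ (p1−p2)(p3−p4) / Σ (p1+p2−2p1p2)(p3+p4−2p3p4),
      α = f4(O, A1; X, Out2) / f4(O, A1; A2, Out2).

- **`painting`** — Li–Stephens copying model (forward–backward, exact
  against path enumeration), coancestry matrices of expected chunk counts
  and copied lengths, donation differentials with Mann–Whitney contrasts,
  total variation distance between group donation profiles, coancestry PCA,
  and greedy marginal-likelihood clustering.
- **`traits`** — polygenic scores (average per-allele effect, PLINK-style),
  ln(OR)/1.81 effect conversion, centering, permutation group tests,
  ancestry–score regression.
- **`ehh`** — EHH decay curves (pair-counting definition, no carrier
  frequency floor) and haplotype furcation trees.
- **`pipeline` / `paleoweave` CLI** — scenario orchestration (simulate →
  filter → paint → donation → D/f → scores → EHH) with a machine-readable
  JSON report, plus VCF (GT+GP), EIGENSTRAT and IMPUTE2 hap/sample I/O.

## Worked example

The bundled scenario emulates a Neolithic→Bronze Age question: five
differentiated sources, a Neolithic-analog population (75% Anatolian-analog
+ 25% hunter-gatherer-analog), a BronzeAge-analog carrying 15%
Steppe-analog ancestry, and a CordedWare-analog control with 50%.

```python
from paleoweave.pipeline import iberia_analog_config, run_scenario

report = run_scenario(iberia_analog_config(seed=1), out_dir="out")
d  = report["stages"]["fstats"]["d"][0]
a  = report["stages"]["fstats"]["f4_ratio"][0]
tv = report["stages"]["painting"]["tvd"]
print(f"D(Outgroup, Steppe; Neolithic, BronzeAge) = {d['estimate']:+.4f}  Z = {d['z']:+.2f}")
print(f"F4-ratio alpha(BronzeAge) = {a['estimate']:.3f} +- {a['se']:.3f}")
print(f"TVD(Neolithic vs BronzeAge)  = {tv[0]['tvd']:.3f}")
print(f"TVD(Neolithic vs CordedWare) = {tv[1]['tvd']:.3f}")
```

prints

```
D(Outgroup, Steppe; Neolithic, BronzeAge) = +0.0572  Z = +7.23
F4-ratio alpha(BronzeAge) = 0.185 +- 0.025
TVD(Neolithic vs BronzeAge)  = 0.229
TVD(Neolithic vs CordedWare) = 0.372
```

Reading the numbers: the positive, strongly significant D (Z = +7.2 at
8,000 sites) detects excess allele sharing between the Steppe-analog and the
BronzeAge-analog relative to the Neolithic-analog — gene flow the simulator
really put there. The F4-ratio estimates that introgression at
0.185 ± 0.025, bracketing the simulated 15% within two standard errors. The
painting-based total variation distance between donation profiles shows the
Neolithic→BronzeAge haplotype-sharing shift (0.229) is markedly smaller
than the shift to the 50%-Steppe control (0.372): a detectable but modest
introgression, distinguishable from a wholesale turnover.

The same run from the shell:

```sh
paleoweave run --scenario iberia-analog --seed 1 --out out/
```

Other subcommands (`simulate`, `filter`, `qc`, `impacc`, `biastest`,
`fstat`, `paint`, `donation`, `cluster`, `score`, `ehh`) wrap the
corresponding library calls; see `paleoweave --help`.

## Documentation

`docs/methods.md` describes the models, their assumptions, parameter
defaults, numerical choices, and what the synthetic cohorts do and do not
emulate about real ancient-DNA data.
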