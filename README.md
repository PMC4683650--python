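# indelmark

Tools for developing gel-readable insertion/deletion (INDEL) markers from
whole-genome resequencing variant calls, and for using those markers to map
a recessive mutation in an F2 population — the standard low-cost mapping
workflow for inbred crops such as soybean.

## What it does

Resequencing an inbred line against a reference genome yields tens of
thousands of INDEL calls. Only a fraction make useful PCR markers: the call
must be trustworthy (read depth ≥ 5, mapping quality ≥ 20), homozygous,
anchored to a chromosome, and long enough (5–50 bp) that the two allele
products separate on a polyacrylamide gel. `indelmark` covers that whole
desk-side workflow:

* **`indelmark.simulate`** — synthetic genomes, variant calls, cultivar
  panels, and F2 populations, each paired with a ground-truth ledger so
  every downstream stage can be verified against truth.
* **`indelmark.filtering`** — the retention criteria and genome-wide
  bookkeeping (per-chromosome counts, density per Mb, pericentromeric
  fraction, size histogram), with conservation identities asserted on every
  run: `homozygous = detected − heterozygous`,
  `retained = homozygous − unanchored`.
* **`indelmark.markers`** — candidate selection and deterministic primer
  design under the classic constraint box (primer 18–30 nt, GC 40–60 %,
  ΔTm ≤ 3 °C, product 100–600 bp on both alleles, using
  Tm = 64.9 + 41·(n_GC − 16.4)/N), plus evenly spaced genome-wide anchor
  sets and fine-scale densification of a target region.
* **`indelmark.diversity`** — `PanelDiversity(genotypes).fit()` scores a
  marker × cultivar amplicon-size table into pairwise polymorphic-marker
  counts and percentages, and clusters the cultivars by UPGMA (polymorphic
  fraction as distance, node height = merge distance / 2).
* **`indelmark.mapping`** — `F2LinkageModel(population, marker_map).fit()`
  runs the recessive-class analysis: a 3:1 segregation χ² (no continuity
  correction), per-marker recombinant-gamete counts over the mutant class
  (A = 0, H = 1, B = 2 recombinant gametes per plant), and interval
  delimitation between the innermost flanking markers that still carry a
  recombinant. A run of consecutive amplification failures inside the
  interval is reported as a candidate genomic deletion.
* **`indelmark.cli` / `indelmark.pipeline`** — the `indelmark` command
  orchestrates `simulate → filter → design → diversity → map` from one YAML
  configuration with a fixed seed; all intermediates are plain VCF / FASTA /
  BED / TSV / Newick files.

## Worked example

```python
from indelmark.mapping import segregation_chi_square
print(segregation_chi_square(124, 511).summary())
```

```
124 mutants of 511 plants; expected 3:1 -> chi2 = 0.147 (df 1, p = 0.702): consistent with a single recessive locus
```

124 mutants among 511 F2 plants sits almost exactly on the 3:1 expectation
(127.75), so the phenotype behaves as a single recessive locus and the
mutant class can be used for recombinant counting.

Clustering the bundled 14-cultivar soybean panel (165 markers; polymorphic
fraction as distance):

```python
from indelmark.datasets import soybean14_panel
from indelmark.diversity import upgma

counts, _ = soybean14_panel()
print(upgma((counts / 165).fillna(0.0)).newick())
```

```
(Hedou 12:0.295804,((Shidou 111:0.2,((Jindou 21:0.0818182,Fendou 33:0.0818182):0.0984848,
(Wandou 28:0.139394,Zhoudou 17:0.139394):0.0409091):0.019697):0.0244697,(Zhonghuang 30:0.219913,
((Andou 1311:0.168182,(Essex:0.145455,Forrest:0.145455):0.0227273):0.030303,(Jilin 35:0.188889,
(HVE:0.115152,(Williams 82:0.0939394,Jack:0.0939394):0.0212121):0.0737374):0.00959596):0.0214286):0.00455628):0.0713345);
```

The least-diverged pair is Jindou 21 / Fendou 33 (27 of 165 markers
polymorphic, height 0.082 = 27/165/2), and the American cultivars
(Williams 82, Jack, HVE, Essex, Forrest) cluster together with a subset of
the Chinese cultivars.

An end-to-end synthetic run — simulate a 2 × 5 Mb genome, call and filter
variants, design 30 anchor markers, genotype an F2 of 511 plants, densify
and map:

```python
from indelmark.pipeline import PipelineConfig, run_pipeline

results = run_pipeline(PipelineConfig(out_dir="demo", seed=1))
print(results["linkage"].interval.summary())
print(results["deletion"].summary())
```

```
chr01: MK0041 (1,899,513 bp) .. MK0043 (2,173,540 bp), 274,027 bp (274 kb)
1 consecutive failed markers on chr01 (1,971,501-1,971,501 bp); sequenced boundaries 1,873,407-2,126,594 bp, span 253,187 bp (~253 kb)
```

The delimited 274 kb interval contains the simulated causal locus
(chr01:2,000,000), and the injected 253,187 bp deletion is recovered from
the amplification-failure pattern of the fine-scale markers. The same run
is available from the shell as `indelmark run --seed 1 --out demo`.

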