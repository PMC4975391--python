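# secondhit

Somatic "second-hit" analysis for *TSC1*/*TSC2*-driven tumors (renal
angiomyolipoma and lymphangioleiomyomatosis, the PEComa family), built for
tumor–normal exome cohorts.

Knudson's two-hit model holds that a tumor-suppressor-driven tumor needs both
alleles inactivated: a first hit (often germline) plus a somatic second hit.
In this tumor class the second hit is frequently **copy-neutral LOH
(CN-LOH)** — mitotic recombination replaces the wild-type haplotype with the
mutant one, so heterozygosity is lost from the telomere down to the crossover
breakpoint while total copy number stays 2. The only footprint in sequencing
data is B-allele-frequency skew: at a germline heterozygous SNP with tumor
purity $p$, the expected variant allele fraction is

$$\mathrm{E}[\mathrm{AF}] = \frac{p\,m_t + (1-p)\,m_n}{2}$$

with $m_t, m_n$ the mutant copy numbers in tumor and normal cells — $(1+p)/2$
for the retained allele, $(1-p)/2$ for the lost one, $p/2$ for a clonal
somatic heterozygous mutation. The package turns this arithmetic into a
tested pipeline:

- **variant_io** — canonical TSV (and VCF) I/O for variant calls and per-SNP
  allele counts; the review filter (≥3 variant reads, bidirectional support,
  AF ≥ 5%); packaged transcriptions of the 32-specimen study cohort.
- **af_model** — closed-form purity ⇄ AF maps and single-variant purity
  estimates with exact binomial intervals.
- **loh_mapper** — germline-het SNP selection (normal depth > 19, AF
  0.40–0.60), tumor skew calls (AF < 0.4 or > 0.6), LOH region delineation
  with confident spans and uncertainty flanks, copy-neutrality assessment
  and homozygous-deletion detection from windowed depth ratios.
- **tsc_status** — HGVS variant typing and the per-specimen biallelic
  mechanism verdict (two mutations / mutation + CN-LOH / homozygous
  deletion / CN-LOH only / none).
- **burden_stats** — coding-mutation burden per tumor–normal pair,
  mutations/Mb over the 33 Mb capture territory, mutation spectrum,
  subclonality tallies, and the sporadic-vs-TSC mechanism contingency with a
  two-sided Fisher exact test (point-probability method, log-space).
- **clonality** — clonal phylogeny of multifocal tumors from shared somatic
  mutations and LOH-boundary concordance; newick/JSON export.
- **synthetic_data** — truth-tracked simulator of paired SNP tracks,
  coverage windows, and multifocal patients.
- **pipeline / cli** — end-to-end runner and the `secondhit` command.

## Worked example

Run the packaged cohort through the whole pipeline:

```sh
$ secondhit run --out out/
30/32 biallelic (94%), 20 CN-LOH, median burden 4 (0.12/Mb), Fisher p=0.049
report written to out/
```

Reading: 30 of the 32 specimens show biallelic *TSC2*/*TSC1* inactivation
(94%); 20 carry copy-neutral LOH as the second hit; the cohort median is 4
somatic coding mutations per tumor outside the driver locus — 4/33 Mb ≈ 0.12
mutations/Mb, far below adult-carcinoma rates — and two-event mechanisms
(two point hits or a homozygous deletion) are enriched in sporadic versus
TSC-diagnosed patients (7/13 vs 3/19, Fisher p ≈ 0.049). `out/report.json`
carries the per-sample verdicts, burden summary, and one clone tree per
multifocal patient, e.g. the 16-tumor patient's newick

```
((S20,S23,S24)'truncal_2',S14,S15,...,S29)P13;
```

whose internal node marks three tumors sharing two identical somatic
mutations — a definite common truncal precursor.

The same machinery runs on synthetic data with known truth:

```sh
$ secondhit simulate --preset sporadic_two_hit --seed 3 --out sim/
{"mechanisms_correct": 1, "n_tumors": 1, "all_mechanisms_correct": true,
 "partition_correct": true, "success": true}
```

Library use mirrors the CLI: `secondhit.load_fixtures()`,
`secondhit.delineate_loh_regions(...)`, `secondhit.classify_sample_status(...)`,
`secondhit.fixture_report()`.

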