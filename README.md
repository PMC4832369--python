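# ampmeth

Per-read CpG methylation pattern analysis for multiplexed bisulfite
amplicon sequencing.

## The problem

Regulatory T cells (Tregs) that stably express FOXP3 are the only immune
cells demethylated at the Treg-specific demethylated region (TSDR) in
intron 1 of *FOXP3*, which makes TSDR demethylation a molecular tally of
Tregs in a mixed sample. qPCR and Sanger-trace methods report only an
average methylation per region or per site; amplicon NGS instead reads
every CpG of the region on each individual DNA molecule, so a single read
reports one complete epiallele — the joint methylation state of all
interrogated sites on one copy of the gene — and rare demethylated
molecules can be counted directly.

`ampmeth` implements the desk side of such an assay:

- **panel model** — amplicons defined by genomic reference, primers
  synthesized against bisulfite-converted template, CpG sites (with
  exclusion flags) and auto-derived non-CpG cytosine QC positions;
- **demultiplexer** — a single index placed on either the forward or
  reverse adaptor, so a pool of k index oligos addresses 2k samples
  (480 → 960); Hamming matching with ambiguity rejection;
- **caller** — primer-anchored ungapped placement, per-site calls
  C → M (methylated), T → U (demethylated), other → N, plus per-read
  identity and conversion QC fields;
- **quantification** — epiallele frequency tables, k-of-n demethylation
  distributions, the Treg-like fraction (reads with ≥ min_k of n sites
  demethylated; 8-of-9 at the TSDR, 7-of-7 at CTLA4 exon 2),
  replicate median-with-range, titration OLS regression, and a ×2
  X-dosage adjustment for female samples;
- **simulator** — molecule-level generative model (cell-type mixtures,
  female X-inactivation dosage, bisulfite conversion failure, sequencing
  error) emitting FASTQ plus a truth table, so the whole pipeline is
  testable end to end without sequencing data.

Bisulfite treatment converts unmethylated cytosine to uracil (read T)
and leaves 5-methylcytosine as C. For a read *r* aligned to amplicon *a*
with included CpG sites *s₁ < … < sₙ*, the called pattern is
*p ∈ {M,U,N}ⁿ* with *k = #{i : pᵢ = U}*; the Treg-like fraction of a
read set *R* is `100 · |{r : k(r) ≥ min_k}| / |R|`. Conversion
efficiency is `100 · converted / (converted + unconverted)` over the
non-CpG (non-methylatable) cytosines of passed reads.

## Worked example

Simulate one male sample containing 25% Tregs (2000 reads, bisulfite
conversion success 0.995, per-base error 0.001) against the bundled
synthetic two-amplicon panel, then run the full pipeline:

```bash
ampmeth simulate --out sim --seed 42 --reads 2000 --treg-fraction 0.25 --sex male
ampmeth run --fastq sim/reads.fastq --sheet sim/sample_sheet.tsv \
            --panel sim/panel.yaml --out results --seed 42
```

The run prints the stage counts

```
pipeline done: {'total_reads': 2000, 'assigned': 2000, 'unassigned': 0,
 'amplicon_unmatched': 0, 'called': 2000, 'called_passed': 1991}
```

and `results/summary.tsv` holds the headline statistic per sample ×
amplicon (median with range over PCR replicates):

```
sample_id  amplicon    statistic              median   max      min      n_replicates
S1         CTLA4_ex2   treg_like_pct_min_k_6  23.7154  23.7154  23.7154  1
S1         FOXP3_TSDR  treg_like_pct_min_k_8  23.6977  23.6977  23.6977  1
```

i.e. 23.7% of TSDR reads are demethylated at ≥ 8 of 9 sites — the input
Treg fraction of 25% recovered within binomial sampling error.
`results/qc_report.tsv` shows the bisulfite conversion QC recovered from
non-CpG cytosines:

```
sample_id  amplicon    replicate_id  reads_in  passed  ...  noncpg_c_observations  conversion_efficiency_pct
S1         CTLA4_ex2   r1            1015      1012    ...  23259                  99.5142
S1         FOXP3_TSDR  r1            985       979     ...  26417                  99.4928
```

matching the simulated conversion rate of 99.5%. The pattern table
(`results/pattern_table.tsv`) lists each epiallele with its count and
percentage; the 9 reads that failed did so with an N at a CpG site
(`failed_too_many_n`), and are excluded from all frequency denominators.

The bundled panel is **synthetic**: it mirrors the structure of a
TSDR/CTLA4 assay (ten declared TSDR-style CpGs with site "sA" excluded,
nine reported per read; seven CTLA4-style sites) but its sequences are
randomly generated stand-ins, not the genomic loci. Supply your own
panel YAML for real data (`ampmeth make-panel` writes a template).

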