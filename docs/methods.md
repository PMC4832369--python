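# Methods

## Assay model

`ampmeth` models a two-stage-PCR multiplexed bisulfite amplicon assay.
A gene-specific first-round PCR (primers carrying an adaptor tail)
amplifies each targeted region from bisulfite-converted DNA; a second
round adds one sample index synthesized on either the forward or the
reverse adaptor, so a pool of k index oligos distinguishes 2k samples
on one run. Sequencing yields single-end reads that span an amplicon
starting at its forward primer.

Only the bisulfite top strand is modelled. The primers of such an assay
select a single converted strand, so strand is a panel property, not a
per-read one; bottom-strand and both-strand designs are out of scope.

### Panel

Each amplicon is defined by its pre-conversion top-strand reference, the
primers as synthesized against the converted template (lowercase adaptor
tails in config are stripped), and its CpG sites as 0-based offsets of
the CpG cytosine. Validation enforces: every declared site is a CG
dinucleotide lying between the primer regions; every interior CG is
declared (included or excluded), so the interior cytosines partition
cleanly into CpG sites and non-CpG QC positions; and each primer equals
the converted reference end (checked against both the methylated and the
unmethylated conversion, since primer regions should be CpG-free).
Non-CpG cytosine positions — every interior reference C not followed by
G — are derived automatically and, if supplied, cross-checked.

Sites can be declared but excluded (the TSDR assay declares ten CpGs and
excludes site "sA", reporting nine per read). Excluded sites never
appear in pattern output, and because their methylation state is
unknown they are also omitted from the conversion-QC numerator and
denominator; counting them as convertible would bias the efficiency
estimate downward whenever they are methylated.

### Demultiplexing

A read is assigned to the unique sample-sheet entry whose index is
within `max_mismatch` (default 1) Hamming distance of the read's index
region; ties at the minimum distance and reads beyond the threshold are
UNASSIGNED and counted. The physical index location is configurable
because sequencer layouts differ: by default the index region is the
first `index_length` bases of the read; reverse-placement entries are
matched against a separate header index when one is provided. With
pairwise index distances > 2·max_mismatch (the simulator's sheet
builder enforces ≥ 3) assignment on error-free index regions has zero
cross-talk. Index and primer regions are trimmed before calling.

### Amplicon assignment and pattern calling

Reads are assigned to the unique amplicon whose forward primer matches
the read prefix within `max_primer_mismatch` (default 2) mismatches;
the reverse complement is tried only when no forward-orientation primer
fits, and ties are UNMATCHED. Calling then places the primer-trimmed
read against the reference by ungapped anchoring at the primer:
amplicons are short and of fixed length, so a gapped aligner would add
failure modes without benefit, and indel-bearing or chimeric reads are
instead rejected by the identity filter (fraction of aligned non-CpG,
non-primer positions matching the converted reference; default
threshold 0.90).

At each included CpG the read base maps C → M, T → U, anything else →
N. A substitution error therefore yields a wrong M/U call only when it
hits a site position *and* produces the one specific wrong pyrimidine
(≈ ε/3 per site); other substitutions give N, so the per-site miscall
probability is bounded by the per-base error rate. A read ending before
the last included CpG fails as TOO_SHORT. `passed` requires identity ≥
`min_identity` and at most `max_N` no-calls; the default `max_N = 0`
keeps any N-bearing read out of pattern tables while the QC report
retains its fail reason. Base qualities are not used for calling (a
mean-quality filter could be added upstream; the simulator emits
constant high qualities).

Conversion efficiency is aggregated over passed reads as
`100 · converted / (converted + unconverted)` at non-CpG cytosine
positions; read bases other than C/T at those positions (sequencing
errors) contribute to neither count. Efficiency is a QC statistic, not
a read filter: reads are not discarded for unconverted cytosines, and
no per-read conversion cutoff is applied by default.

### Quantification

All frequencies are over *eligible* reads — passed and N-free — so
every table normalizes exactly (pattern frequencies to 100%, k-of-n
distributions to 1). The Treg-like fraction is the percentage of reads
with ≥ `min_k` of n included sites demethylated. The pipeline default
is `min_k = n − 1` per amplicon (the "eight or nine of nine" TSDR
reporting convention); amplicons quantified as fully demethylated only
(e.g. CTLA4 exon 2, all 7 of 7) are set via a per-amplicon override.
Replicate summaries report median (mean of the central pair for even
counts — the standard convention; replicate counts of six are typical)
with min/max range. Titration series are summarized by OLS of the
estimated demethylated fraction on the known mixture fraction; r² is
the coefficient of determination, defined as 0 (with a warning) for a
zero-variance response.

Because *FOXP3* is X-linked and the TSDR is demethylated only on the
active X, a pure female Treg sample still reads ~50% demethylated
molecules. `sex_adjusted_treg_estimate` doubles female fractions
(factor configurable) and caps at 1 to place them on the male scale;
it is exposed as an explicit post-hoc adjustment rather than applied
silently anywhere.

## Simulator

The generator draws, per read: an amplicon (uniform over the panel); a
cell-type profile by the sample's mixture weights; for female samples,
with probability ½ the template molecule is the fully methylated
inactive-X copy regardless of profile (molecule-level X-dosage); then
per-site methylation states from the profile's probabilities. Chemistry
and sequencing are applied base by base: an unmethylated cytosine reads
T with probability `conversion_rate` (default 0.995, matching a
well-run assay's > 99% QC), a methylated cytosine reads T with
probability `inappropriate_conversion` (default 0; real chemistry has a
small rate, exposed for sensitivity studies), and every base is then
substituted uniformly at `seq_error_rate` (default 0.001). The sample
index is prepended (both placements) and primer regions are emitted as
the synthesized primers, which are fully converted by construction.
All randomness flows through one `numpy` generator seeded from the
design, so FASTQ output is byte-identical across reruns.

What the simulator does **not** emulate: PCR amplification bias and
duplicates, indel errors, quality-score structure, index hopping, and
primer cross-hybridization. Passing recovery tests therefore shows the
pipeline's logic is correct under substitution-type noise and known
mixtures; it does not certify performance on degraded clinical DNA.

The bundled `synthetic_panel()` mirrors the production panel's
structure — a 170-bp TSDR-like amplicon with ten declared sites ("sA"
excluded) and a 150-bp seven-site CTLA4-like amplicon, 22-bp primers —
but its sequences are seeded random stand-ins, deliberately not the
genomic loci (which this repository does not claim to reproduce).

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `max_index_mismatch` | 1 | bases | standard demultiplexing tolerance; ambiguity always rejected |
| `max_primer_mismatch` | 2 | bases | tolerates sequencing errors in a 22-bp primer without cross-amplicon risk |
| `min_identity` | 0.90 | fraction | rejects indels/chimeras while passing reads with ~0.5% conversion failure + 0.1% error |
| `max_N` | 0 | sites | any no-call removes a read from frequency denominators (QC still counts it) |
| `treg_min_k` | n − 1 | sites | TSDR convention (8 of 9); override to n for all-sites amplicons |
| `conversion_rate` | 0.995 | probability | matches the > 99% efficiency a passing assay shows |
| `seq_error_rate` | 0.001 | probability/base | typical short-read substitution rate |
| `reads_per_replicate` | 2000 | reads | titration-scale depth; ample for percent-level fractions |

## Numerical and edge-case choices

Pattern tables order rows by descending count with lexicographic
tie-break, making report bytes deterministic. TSVs are written at six
significant digits with `#`-prefixed provenance headers; per-stratum
frequencies therefore sum to 100 within ~1e-4 of formatting round-off.
Zero eligible reads yield empty tables with warnings, not errors; a
zero conversion-QC denominator reports the statistic as missing.
Replicate summaries of a single replicate degenerate to min = median =
max. Per-point titration seeds are spawned from the master seed via
`numpy.random.SeedSequence`, keeping points independent yet
reproducible.

## Problem sizes

Simulation-based checks use the depths at which the statistics are
well-resolved: 6 × 2000 reads for titration linearity (binomial SE of a
point estimate ≈ 1%), ≥ 10,000 non-CpG cytosine observations for
conversion QC (SE ≈ 0.07 points), and 10,000 reads for the Treg-like
error floor, where the expected artefact rate — requiring ≥ 8
independent failures on one read — is far below one read in 10,000.

## Known limitations

- Ungapped anchoring cannot rescue reads with real indels; they are
  discarded by identity, slightly reducing yield rather than biasing calls.
- Hemimethylation and non-CpG methylation are out of scope.
- The female ×2 dosage adjustment assumes balanced X-inactivation;
  skewed inactivation in real donors violates it.
- Quality-aware index/base calling is not implemented; with the default
  constant-quality simulator it would be untestable anyway.
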