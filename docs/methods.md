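# Methods

`cap6am` implements the computational side of a cap-m⁶Am profiling
experiment: calling methylated transcription start sites from antibody
pull-down sequencing, classifying external peaks into cap (m⁶Am) versus
internal (m⁶A) signal, summarizing the genomic consensus around called
starts, relating methylation status to expression and protein
measurements, and quantifying proteins from peptide intensities. All
stages are deterministic given their inputs; the only stochastic
component is the synthetic-data generator.

## The site-calling model

m⁶Am sits on the first transcribed adenosine, so an
immunoprecipitation (IP) library is enriched for read 5′ ends at
methylated TSSs relative to an untreated input library. For every
annotated TSS the caller:

1. **Caps duplicates.** Each per-position end count is clamped at 5
   (`dup_cap`), removing PCR amplification spikes. The cap is positional
   cleaning only: library sizes stay at the pre-cap totals.
2. **Counts the TSS window.** Capped 5′-end counts are summed over the
   25 transcribed positions starting at the TSS base (`window`),
   strand-matched, half-open downstream: `[pos, pos+25)` on plus,
   `(pos−25, pos]` on minus. "Within 25 nt" is read as including the TSS
   base; the far edge is exclusive.
3. **Filters on input coverage.** TSSs with zero input ends within 100
   transcribed positions of the start (`cov_span`, the typical RNA
   fragment length) are removed — the fold change would be supported by
   no local input evidence.
4. **Computes the fold change**
   `fc = (ip_count / input_count) · (lib_input / lib_ip)`,
   i.e. the window ratio normalized by total library sizes. A window
   with input coverage in the 100-nt span but zero input count inside
   the 25-nt window has an undefined fold change; it is reported with an
   `undefined_fc` flag and can never pass.
5. **Tests enrichment.** A one-sided Fisher exact test on
   `[[ip_count, lib_ip − ip_count], [input_count, lib_input −
   input_count]]` — window versus remainder-of-library per sample,
   alternative: IP enriched. One-sidedness matches the direction of the
   fold-change gate. Degenerate tables give p = 1. The implementation
   rides the hypergeometric survival function and is verified against
   exhaustive tail enumeration on every 2×2 table with total ≤ 200.
6. **Adjusts for multiplicity.** Benjamini–Hochberg across the tested
   set. By default (`fdr_universe="all"`) every TSS that survived the
   coverage filter is tested and adjusted, then the count/fold gates are
   applied. The alternative (`"gated"`) adjusts only over the gate
   survivors; because those are pre-selected for large fold changes,
   BH has almost nothing to correct there and the q-gate loses its
   specificity value — measured on planted-null data, the gated variant
   passes ~0.9 % of null TSSs where the default passes essentially none.
7. **Gates and selects.** Passing requires ip_count > 5 (strictly),
   fc > 2 (strictly), q ≤ 0.05 (inclusive), no overlap of the 25-nt
   window with a supplied m¹A site list (absence of the list means no
   exclusions), and per gene only the best TSS is kept: lowest p, ties
   broken by higher fold change, then the 5′-most coordinate.

**Replicate consensus** keeps genes passing in ≥ 2 of 3 replicates
(`min_reps`). **The negative control** reruns the identical pipeline
with IP and input roles swapped; with real enrichment the swapped run
should call almost nothing.

Defaults (`Thresholds`): window 25 nt, coverage span 100 nt, duplicate
cap 5, minimum IP count 6, minimum fold change 2, maximum FDR 0.05,
consensus 2 replicates.

## Peak classification

External-caller peaks (narrowPeak) are classified by the signed
distance from the peak start (configurable to the summit) to the
nearest annotated TSS, measured in that TSS's transcription direction:
0–25 nt downstream is m⁶Am; more than 50 nt away (either side) is
internal m⁶A; the 26–50 nt zone falls between the two defining rules
and is kept as "ambiguous", excluded from both classes. Upstream peaks
are not m⁶Am unless an `upstream_slack` is configured. The m⁶A/m⁶Am
ratio is reported raw and rounded half-up to one decimal; two
conditions' splits are compared with a Pearson chi-square without
continuity correction (df = 1). The %A-at-TSS versus peak-score
relation uses five equal-count score bins by default.

## Consensus motif

Flanks of 46 nt (40 upstream, the start base, 5 downstream, transcribed
orientation; minus-strand flanks reverse-complemented) are collapsed
into a position probability matrix with per-column information content
2 − H (bits), N bases dropped per column. The summary reports the A
fraction at offset 0, C and pyrimidine fractions at −1, the non-A
fraction at −2 (the "B" of the BCA cap consensus), and the TATA
tetramer frequency for starts in −35..−25 — exact scan when the flank
sequences are available, otherwise a PPM product approximation that
understates variable-anchor TATAs.

## Association statistics

Between two conditions' consensus gene sets: gained = B∖A, lost = A∖B,
common = A∩B, specificity = |gained ∪ lost| / |A ∪ B|. Methylated-gene
fractions are computed across equal-count expression percentile bins
(universe: genes with nonzero expression, configurable). Group
comparisons use the Mann-Whitney U test (exact for tie-free groups of
≤ 20, tie-corrected normal approximation otherwise; two-tailed
throughout) and ANCOVA — OLS of `response ~ 1 + covariate + group`,
reporting the group term's F with (1, n−3) df. The
differential-expression contingency test restricts to gained/lost genes
whose fold change exceeds 1.5 (or falls below 1/1.5), cross-tabulates
{gained, lost} × {up, down}, and compares against expected proportions
taken from the up/down split of *all* genes passing the same threshold
(the uncategorized sample; configurable to all genes). The default is a
goodness-of-fit chi-square against those external proportions (df = 2,
one constraint per row); a 2×2 independence test (df = 1) is available.
With few differentially expressed genes the chi-square is discrete and
conservative — calibration claims should be checked in regimes with
adequate counts, as the test suite does via label permutation.

## Proteomics quantification

Peptide tables are normalized to the total ion current — each sample
scaled so its total equals the mean of the raw sample totals. Any
common target would differ only by a global constant, which is why
rescaling one sample changes all post-TIC abundances by exactly one
shared factor and no ratio or rank. Protein abundance is the per-sample
sum of the three most intense *unique* peptides (per-sample ranking;
proteins with 1–2 unique peptides are quantified from what exists,
proteins with none are omitted). Log2 is applied last; zeros become
missing rather than −∞ so downstream rank tests stay honest.

## The synthetic-data generator

The generator emulates a two-condition (lean/fat), three-replicate
liver study at desk scale, with full ground truth:

- **Annotation**: 1,000 genes by default, 1-kb bodies, 100-bp spacing,
  50 genes per chromosome, alternating strands; a second TSS 20–200 bp
  downstream with probability 0.2.
- **Truth**: 10 % of genes methylated per condition
  (`frac_methylated`); condition B retains 46 % of A's set, which
  makes ~30 % of the union common and ~70 % condition-specific — the
  regime the method is meant to resolve.
- **Counts**: Poisson per transcribed position, background rate scaled
  so the expected library is 10⁶ ends (`depth_ip`, `depth_input`); the
  planted TSS's 25-nt window in IP is multiplied by the gene's
  enrichment fold (mean 8); 1 % of covered positions get a duplicate
  spike of 6 + Poisson(10) extra ends to exercise the cap; the recorded
  library size is the pre-cap sum.
- **Genome**: uniform random bases with the cap consensus planted at
  methylated starts (transcribed A at 0, C at −1, G/C/T at −2) and a
  TATA tetramer 25–35 bp upstream with probability 0.9.
- **Measurement tables**: log-normal per-gene levels (σ = 1 between
  genes, σ = 0.25 between samples); genes methylated in a condition
  have that condition's draws multiplied by the effect size (2 for
  expression-like tables and protein).
- **Peptides**: 2–10 peptides per protein, intensities proportional to
  true abundance with multiplicative log-normal noise (σ = 0.2), 10 %
  flagged non-unique, deliberately unequal per-sample totals. Setting
  the noise to zero also fixes ionization efficiencies at 1, making
  intensities exactly proportional to abundance.
- **External peaks**: one cap peak starting at each methylated TSS plus
  internal peaks > 50 nt downstream for half the genes.

Randomness: one master seed; each output draws from a child stream
keyed by a CRC32 label hash, so a fixed configuration is byte-identical
across runs and files are independent of generation order.

What the generator does *not* model: read-level errors, alignment and
mappability artifacts, over-dispersion beyond the duplicate spikes,
fragment-length effects, isoform structure, or correlated
expression/protein noise. Passing tests therefore demonstrate the
pipeline's correctness and calibration under a clean Poisson world with
planted truth — not performance on real libraries, where annotation
error and over-dispersion will erode recall and inflate the ambiguous
classes first.

## Problem sizes and numerical choices

The test and acceptance workloads use 200–1,000 genes and 10⁶-end
libraries, sizes at which every stage runs in seconds on one core
while keeping per-window counts (~25 ends) in the regime where the
Fisher test's discreteness is mild. Fisher p-values are clamped into
(0, 1]; BH is the statsmodels step-up; chi-squares use no continuity
correction (counts are large in intended use); Mann-Whitney switches
to the exact distribution only for small tie-free groups. Tie-breaks
(best TSS, nearest TSS) are total orders, so all outputs are
permutation-invariant in their inputs.

## Known limitations

- The caller is single-nucleotide-window based and not isoform-aware;
  closely spaced alternative TSSs within 25 nt are not separated.
- The 26–50 nt classification gap is inherent to the two distance
  rules; peaks there are reported but never counted in either class.
- TIC normalization to the mean of totals fixes ratios, not absolute
  scale; cross-dataset comparisons need a shared reference.
- The ANCOVA is an ordinary linear model; heavy-tailed responses
  should be log-transformed first (the pipeline's protein path does
  this by construction).
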