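# cap6am

Analysis toolkit for **cap m⁶Am epitranscriptomics**: calling
m⁶Am-methylated transcription start sites from antibody pull-down
(IP/input) sequencing, separating cap m⁶Am from internal m⁶A peaks,
summarizing the genomic consensus around methylated starts, relating
methylation to expression/translation/protein measurements, and
quantifying proteins from peptide intensities. It is aimed at
epitranscriptomics and regulatory-genomics analysts who have aligned
m⁶A-seq-style libraries (or the bundled synthetic data) and want a
tested, deterministic reimplementation of this analysis stack.

m⁶Am is the N⁶,2′-O-dimethyladenosine carried by the first transcribed
adenosine next to the mRNA m⁷G cap, installed in a genomic B·C·A
context (B = G/C/T) and distinguished from internal m⁶A by position:
cap signal sits at the TSS, internal m⁶A starts well downstream.

## The caller

For each annotated TSS, read 5′-end counts (per-position counts capped
at 5 to remove PCR duplicates) are summed over the 25 transcribed
positions starting at the TSS in IP and input. After removing TSSs
with zero input coverage within 100 nt, the enrichment is

    fc = (ip_count / input_count) · (lib_input / lib_ip)

and significance comes from a one-sided Fisher exact test of the
window against the remainder of each library, Benjamini–Hochberg
adjusted. A site passes with ip_count > 5, fc > 2 and q ≤ 0.05, no
overlapping m¹A site, one best TSS per gene (lowest p), and — across
animals — membership in ≥ 2 of 3 replicates. A negative control reruns
everything with IP and input swapped. Peaks from an external caller
are classed m⁶Am when they start within 25 nt downstream of a TSS and
m⁶A when they start more than 50 nt away.

Every input the pipeline consumes can be generated by the bundled
synthetic module with known ground truth (planted methylated genes,
enrichment folds, consensus motif, effect sizes, protein abundances),
which is what the test suite and acceptance script run against. See
`docs/methods.md` for the full model, parameter and design notes.

## Worked example

Simulate a 300-gene, three-replicate study (read tracks, TSS catalog,
genome, tables, truth), call sites per replicate, take the 2-of-3
consensus, and summarize the consensus motif:

```sh
printf 'n_genes: 300\ndepth_ip: 300000\ndepth_input: 300000\nn_replicates: 3\n' > sim.yaml
cap6am simulate --config sim.yaml --outdir sim --seed 11
for r in 1 2 3; do
  cap6am call --ip sim/ends_lean_rep${r}_ip.tsv \
              --input sim/ends_lean_rep${r}_input.tsv \
              --tss sim/tss.bed --out calls$r.tsv
done
cap6am consensus --calls calls1.tsv --calls calls2.tsv --calls calls3.tsv \
                 --min-reps 2 --out lean_genes.txt
cap6am motif --genes lean_genes.txt --tss sim/tss.bed \
             --genome sim/genome.fa --out ppm.tsv
```

prints

```
wrote 23 files to sim
30 genes passed (forward)
30 genes passed (forward)
33 genes passed (forward)
30 consensus genes
a_at_0=1.000  pyrimidine_at_-1=1.000  c_at_-1=1.000  non_a_at_-2=1.000  ...
```

The three per-replicate runs call 30–33 genes; the 2-of-3 consensus
keeps 30, which here are exactly the 30 genes planted as methylated in
`sim/truth.tsv` (recall 1.0, no false discoveries). The motif line
shows the recovered cap consensus at the called starts: every flank
has A at the TSS (offset 0), C at −1 and a non-A base at −2. A passing
row in `calls1.tsv` looks like

```
gene   tss_id  pos    ip_count  input_count  fold_change  p          q          passed
G0011  t1      13199  124       23           5.34         5.1e-18    2.0e-16    True
```

— 124 capped IP ends versus 23 input ends in the 25-nt window, a
5.3-fold library-normalized enrichment. The swapped negative control
(`cap6am call ... --swap`) passes 0 genes on the same data.

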