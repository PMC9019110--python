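# asnmd

Quantitative analysis of how cassette-exon splicing coupled to
nonsense-mediated decay (AS-NMD) and protein-stability control amplify the
tissue specificity of a gene's functional output, built around the mouse
*Trim46* two-exon system: an NMD exon ("E8") whose inclusion introduces a
premature termination codon, and a coding exon ("E10") whose
inclusion/skipping switches between a stable long and an unstable short
protein isoform.

The package is aimed at transcriptomics analysts who start from
splice-junction read counts (STAR `SJ.out.tab`-style tables) and gene-level
TPM, and want isoform-resolved *effective* expression rather than
steady-state totals.

## The model

**PSI from junction reads.** Each exon-inclusion molecule contributes two
inclusion junction reads (upstream→cassette and cassette→downstream) while a
skipping molecule contributes one exclusion read, so with inclusive reads
*I* and exclusive reads *E*:

    PSI = 100 · (0.5·I) / (0.5·I + E),        exclusion = 100 − PSI

**Isoform-level effective expression.** Steady-state TPM is decomposed with
the two PSIs: `productive = TPM · exclusion(E8)/100` (the translatable
NMD-exon-skipping isoform), `nmd = TPM − productive`, and
`coding_long = TPM · PSI(E10)/100`.

**NMD-corrected transcriptional output.** The PTC-bearing isoform is
degraded λ-fold faster than the productive one; λ is estimated as the
geometric mean of NMD-pathway-knockout vs control fold-changes of the
NMD/non-NMD isoform ratio. The transcription the gene *actually* performs is

    corrected = productive + λ · nmd

**Tissue specificity.** τ = Σᵢ(1 − x̂ᵢ)/(n − 1) with
x̂ᵢ = xᵢ/max(xᵢ) and xᵢ = log₂(TPMᵢ + 1), after replicate averaging and
collapsing brain sub-regions by their mean on the log scale. τ = 1 means
single-tissue expression, τ = 0 uniform expression.

**Protein kinetics and polarity.** Cycloheximide-chase courses are fit by
log-linear OLS (half-life t½ = ln2/k); relative steady-state protein
abundance is `synthesis_ratio · t½ₐ/t½_b`; the axonal polarity index is
P = (Iₐ − I_d)/(Iₐ + I_d).

A seeded generative simulator (`asnmd.simulate`) produces every input the
pipeline consumes — a 12-tissue adult panel with 2 replicates, paired
WT/NMD-knockout contrasts, a 5-stage differentiation course with opposing
PSI trajectories, and decay courses — with the ground truth recorded for
parameter-recovery testing.

## Worked example

```sh
asnmd demo-reference
```

reconstructs the published adult-tissue arithmetic for *Trim46* from the
reported group means alone (total TPM 68.5 brain / 8.0 non-neural,
productive 35.6 / 0.9, coding-long 66 / 1.5, knockout fold-changes 8.7 and
6.8):

```
                   quantity      value  reported_precision
  degradation_factor_lambda   7.691554                 7.7
    corrected_output_neural 288.930000               289.0
corrected_output_non_neural  55.570000                56.0
             fold_total_tpm   8.562500                 9.0
        fold_productive_tpm  39.555556                40.0
       fold_coding_long_tpm  44.000000                44.0
      fold_corrected_output   5.199388                 5.0
```

Read: NMD degrades the PTC isoform ≈7.7-fold, so the brain's true
transcriptional output is ≈289 TPM (not the 68.5 TPM seen at steady state)
versus ≈56 TPM in non-neural tissues — only a ~5-fold transcriptional
difference, which splicing amplifies to ~40-fold (productive isoform) and
44-fold (coding-long isoform) at the level of functional output.

A full simulated run:

```sh
asnmd run --seed 1 --out report/
```

writes `psi.csv`, `isoform_output.csv`, `group_comparison.csv`, `tau.csv`,
`decay_fit.csv`, a `summary.json` with the headline quantities (group means,
λ, fold-changes, τ per metric) and a `manifest.json` with checksums of every
output. On the default configuration the τ values come out ordered
productive > coding-long > steady-state > corrected output (≈0.86, 0.75,
0.52, 0.32 at seed 1), i.e. every layer of post-transcriptional control
*increases* tissue specificity relative to transcription.

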