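# scarnakit

A tested, reusable implementation of the quantitative analysis chain used in
CRISPR disruption studies of small Cajal body-associated RNAs (scaRNAs) —
noncoding guides for pseudouridylation of spliceosomal snRNAs. Starting from
a guide design against a scaRNA locus, such a study measures, in edited
clones versus wild type:

1. **Editing efficiency and indel spectrum** from Sanger traces, by
   TIDE-style decomposition: the edited four-channel chromatogram is fitted
   as a non-negative mixture of shifted copies of the control trace
   (a deletion of *k* bases shifts downstream signal *k* positions left);
   efficiency = 100 × (1 − c₀) for the zero-shift coefficient c₀.
2. **Relative scaRNA expression** by the ΔΔCt method: ΔCt = Ct(target) −
   Ct(reference gene) per biological replicate, ΔΔCt against the wild-type
   calibrator, ratio 2^−ΔΔCt, reported as a signed fold change
   (r if r ≥ 1, else −1/r), with a nested replicate t test.
3. **Site-specific pseudouridylation** (e.g. U2 snRNA Ψ89) by the CMC
   reverse-transcription-stop qPCR index
   R = 2^(C̄t(untreated,long) − C̄t(CMC,long)) / 2^(C̄t(untreated,short) − C̄t(CMC,short)),
   %Ψ = 100 × (1 − R), where the "long" amplicon spans the Ψ site and the
   "short" amplicon downstream of it is the internal control.
4. **Transcript-level isoform switches** from a count matrix: TMM
   normalization, per-transcript Poisson regression (log link, library-size
   offset) with a 1-df likelihood-ratio test, Benjamini–Hochberg step-up
   FDR, a ±1.5 signed fold-change split, and the switch rule — a gene is
   called when it has at least one significantly up- and one significantly
   down-regulated transcript.
5. **Over-representation** of the switch-gene list against category
   annotations via the hypergeometric upper tail, scored as −ln(p) with
   step-up FDR.

Because such studies typically deposit no raw data, a first-class
synthetic-data module generates every input with planted ground truth
(mixed-allele traces, Ct tables with planted ratios and stop fractions,
count matrices with planted reciprocal switches, annotations with a planted
enriched category), so the whole chain is testable offline.

## Worked example

Generate a synthetic study bundle and run the stages:

```sh
scarnakit simulate all --seed 7 --out demo
scarnakit decompose --control demo/trace_control.tsv --edited demo/trace_edited.tsv --out demo/decomp.json
scarnakit ddct --ct demo/ct.tsv --target scaRNA1 --normalizer RN7SL --calibrator WT
scarnakit psi --ct demo/psi_ct.tsv
```

prints

```
efficiency 66.1% (r2 0.992, interpretable=True)
scaRNA1  3B2  ratio=0.551  fold_change=-1.81  p=0.00231  n=3
scaRNA1  6A1  ratio=0.530  fold_change=-1.89  p=0.00472  n=3
3B2  percent_psi=89.1  n=6
6A1  percent_psi=68.6  n=5
WT   percent_psi=92.5  n=9
3B2 vs WT  p=0.000213
6A1 vs WT  p=1.43e-05
```

The generator's defaults plant the study conditions, and the estimates
recover them: the default allele spectrum leaves 34% unedited (truth 66%
efficiency; estimated 66.1% with fit R² = 0.992 above the 0.90
interpretability gate); planted expression ratios of 0.60 and 0.53 come
back as signed fold changes near −1.67 and −1.9; planted Ψ stop fractions
of 0.93 / 0.88 / 0.70 are recovered as 92.5% / 89.1% / 68.6% with the
clone-versus-control Welch tests strongly significant.

The full pipeline (`scarnakit run --config pipeline.yaml`) chains
decomposition, ΔΔCt, Ψ quantification, switch calling and enrichment
through files, writing per-stage outputs plus a consolidated
`report.json` with provenance. Every operation is also importable:

```python
import scarnakit as sk
control, edited, truth = sk.gen_traces(sk.SimConfig(seed=17))
result = sk.decompose(control, edited)
result.efficiency_pct, result.r2
```

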