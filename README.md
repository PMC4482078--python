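# silacodon

Differential proteomics from SILAC label-switch peptide ratios, with
codon-usage bias analysis of the regulated protein sets.

The package implements a complete, reproducible analysis pipeline:

1. **synthdata** — simulation of ground truth, coding sequences and
   peptide-level SILAC observations (3 biological replicates with
   alternating heavy labelling, abundances spanning ~5 decades, peptide
   counts growing with abundance, measurement noise, a contaminating
   fraction of erroneous low-probability quantifications, and a gene
   subset enriched for AAA/GAA/CAA codons with a coupled fold-change
   effect).
2. **formats** — strict TSV/FASTA readers and writers for every artefact.
3. **quantfilter** — identification-probability thresholding at a target
   FDR, orientation to the log2(30°C/37°C) convention, the cross-design
   peptide consistency filter `|m(+1) − m(−1)| < √2·c`, protein retention
   (≥ 2 high-confidence peptides covering both designs) and aggregation
   to a protein × replicate ratio matrix.
4. **diffstats** — empirical-Bayes moderated one-sample t-test with a
   moment-matched scaled-inverse-chi-square variance prior,
   Benjamini–Hochberg adjustment, directional calls, fold-change
   reporting and cross-dataset sign concordance.
5. **codonbias** — per-gene codon frequencies over the 61 sense codons,
   random-forest out-of-bag permutation importance of codons for the
   up/down classes with the lowest-predictor selection threshold,
   top-percentile codon-frequency gene subsets, volcano-ready tables and
   the tRNA-overexpression rescue comparison.
6. **pipeline** — orchestration, per-stage seed derivation, stage counts
   and coverage reporting, flat YAML run configs.

## CLI

```sh
silacodon simulate --n-proteins 2000 --seed 7 --outdir run/
silacodon filter --in run/peptides.tsv --out run/matrix.tsv
silacodon test --in run/matrix.tsv --out run/results.tsv
silacodon codons --fasta run/orfs.fasta --out run/profiles.tsv
silacodon importance --profiles run/profiles.tsv --results run/results.tsv \
    --seed 7 --out run/importance.tsv
silacodon subset --profiles run/profiles.tsv --codon AAA --percentile 2
silacodon rescue --results-normal run/results.tsv \
    --results-rescue run2/results.tsv --profiles run/profiles.tsv \
    --out rescue.tsv
```

or everything at once from a flat YAML config:

```sh
silacodon all --config run.yaml --outdir run/ --seed 7
```

where `run.yaml` is a flat mapping, e.g.

```yaml
n_proteins: 2000
frac_biased: 0.15
bias_effect: 1.0
codon_bias_multiplier: 3.0
fdr_target: 0.01
alpha: 0.01
n_trees: 1000
```

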