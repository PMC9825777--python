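# difftf

Prediction and characterization of cell-type-specific and shared
transcription-factor binding sites from differential ChIP-seq peaks.

Given a binding factor's peak calls and read placements in two cell types,
the package

1. **selects differential sites** — merges the two peak sets, counts reads
   per merged peak, runs a negative-binomial Wald-style differential test
   (or imports externally computed results), classifies each peak as
   A-specific / B-specific / shared / abandoned by q-value and log2
   fold-change thresholds, trims every peak to 600 bp and splits by
   chromosome (chr8 + chr16 = test, chr18 = validation, chrY excluded);
2. **generates four feature families** per peak — gapped k-mer sequence
   counts, top-3 PWM scan scores per cofactor motif (both strands),
   min/mean/max of 15 chromatin landscapes in both cell types plus
   between-cell differences (135 features), and top-20 Hi-C contact-partner
   statistics plus differences (18 features);
3. **trains two classifiers** for three tasks (A: A-specific vs B-specific,
   B: specific vs shared, C: three-way) — a gradient-boosted-trees model
   with a 5×5 grid search (max depth × learning rate) and validation-based
   early stopping, and a three-block CNN over L×C channel encodings
   (sequence one-hot, optionally ± accessibility channels and their
   difference: plain L×4, "plus" L×7, "all" L×49) with a
   warm-up/re-train protocol;
4. **interprets the models** — exact TreeSHAP values with per-family
   summaries, rescale-rule attribution profiles against sequence-zeroed or
   chromatin-zeroed references (with an exact completeness guarantee),
   per-peak accessibility correlations, base-pair Jaccard distances, and
   cross-factor / leave-one-factor-out evaluation protocols.

Everything runs on synthetic fixtures with known ground truth
(`difftf.synth`): planted motifs in shared sites, cell-type-specific
accessibility enrichment, negative-binomial counts with class-dependent
fold changes and distance-decaying contacts.

The neural network is implemented directly on NumPy (deterministic,
CPU-only) and the boosted-trees protocol is backed by scikit-learn's
`GradientBoostingClassifier`, whose tree structures feed the exact SHAP
computation.

## CLI

```bash
difftf simulate --seed 1 --out bundle/          # synthetic input bundle
difftf select-peaks --peaks-a bundle/peaks_cellA.bed --peaks-b bundle/peaks_cellB.bed \
    --reads-a bundle/reads_cellA.bed --reads-b bundle/reads_cellB.bed --out labeled.tsv
difftf features --peaks labeled.tsv --genome bundle/genome.fa \
    --pwms bundle/pwms.jaspar --signals manifest.tsv \
    --contacts-a bundle/contacts_cellA.tsv --contacts-b bundle/contacts_cellB.tsv \
    --families motif,chrom,hic --out features.tsv
difftf train-xgb --features features.tsv --task B --out model.joblib
difftf train-cnn --bundle bundle/ --peaks labeled.tsv --variant plus --task B --out cnn.npz
difftf evaluate --task B --scores scores.tsv
difftf extract-features --model cnn.npz --encoded encoded.npz --out feats.tsv
difftf interpret --method shap --model model.joblib --features features.tsv --out shap.tsv
difftf interpret --method attribution --model cnn.npz --encoded encoded.npz \
    --reference chromatin --out contrib.tsv
difftf cross-factor f1=feat1.tsv f2=feat2.tsv --task B --out prauc.tsv
difftf unified f1=feat1.tsv f2=feat2.tsv --held-out f2 --out unified.json
```

The signal manifest is a TSV of `assay<TAB>cell<TAB>bedGraph-path` rows.
Formats: BED3+/narrowPeak peaks, FASTA genome, bedGraph signal, triplet-text
contact maps (`chrom bin_i bin_j count` at 5 kb resolution), JASPAR PWM
text. All coordinates are 0-based half-open.

## Layout

- `src/difftf/io_formats.py` — format readers/writers, core domain types
- `src/difftf/peak_selection.py` — merge/count/test/classify/trim/split
- `src/difftf/feature_gen.py` — the four feature families
- `src/difftf/models/` — encodings, NumPy CNN, boosted trees, metrics
- `src/difftf/interpret/` — attribution, TreeSHAP, comparative analyses
- `src/difftf/synth.py` — synthetic fixture generator
- `src/difftf/pipeline.py` — in-memory glue (task labels, bundle encoding)
- `src/difftf/cli.py` — the `difftf` command
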