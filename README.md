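# m5u

Multi-view sequence features and SVM classification for RNA
5-methyluridine (m5U) site prediction.

5-Methyluridine is a post-transcriptional RNA modification produced by
methylation at the C5 position of uridine. Identifying which uridines in
a transcript carry the modification from sequence alone is a binary
classification problem over short sequence windows: a 41-nt fragment
centered on a candidate U, labeled modified or unmodified. This package
implements the full modeling stack for that problem, for
bioinformaticians building or auditing site predictors:

* **Windows** — FASTA IO, extraction of uridine-centered fixed-length
  windows from transcripts (no padding; DNA `T` mapped to `U`), and a
  seeded synthetic generator that plants a consensus motif (e.g. `UUC`
  at positions 0–2) into positives over a uniform background.
* **Physicochemical encoders** — Kmer, ENAC, CKSNAP and PseDNC:

  - Kmer: f(t) = N_t / (L − k + 1) over all 4^k k-mers;
  - ENAC: mononucleotide frequencies in a length-5 window sliding 5'→3';
  - CKSNAP: frequencies of ordered pairs (x, y) separated by k bases,
    N_xy / (L − k − 1), for k = 0…5;
  - PseDNC: dinucleotide frequencies f_1…f_16 extended with λ
    correlation factors θ_j = mean_i Θ(R_iR_{i+1}, R_{i+j}R_{i+j+1}),
    where Θ is the mean squared difference of six standardized
    dinucleotide indices (rise, roll, shift, slide, tilt, twist), all
    normalized by Σf + w·Σθ so the vector sums to 1.

* **Distributed representation** — windows tiled into overlapping
  k-mers, a skip-gram (negative-sampling) embedding trained on the
  k-mer corpus, and each window represented by the mean of its k-mer
  vectors (default 100 dimensions).
* **Two-step feature selection** — importance ranking (ANOVA F,
  F-score, LightGBM or XGBoost gain) followed by accuracy-based
  incremental feature selection under seeded stratified k-fold CV,
  keeping the smallest prefix with maximal accuracy.
* **SVM + metrics** — grid-searched C/γ (RBF default) under stratified
  tenfold CV; Sn, Sp, Acc, precision, F1, MCC from the confusion matrix
  and trapezoidal AUC from the decision-score ROC sweep.
* **Interpretation** — exact Shapley values by coalition enumeration
  (p ≤ 15) or a seeded permutation sampler, with mean-|φ| top-20
  summaries; and a two-sample-logo-style per-position nucleotide
  enrichment table (Welch t-test on presence indicators, p < 0.05).

The pipeline composes these in the method's order: the four
physicochemical views are fused (CKSNAP + ENAC + Kmer + PseDNC) and
optimized by the two-step selection; the embedding features are then
concatenated with the *selected* physicochemical features (they never
pass through selection) before SVM training.

## Worked example

Simulate motif-bearing positives and background negatives, check the
position-wise composition signal, encode, and select features:

```bash
m5u simulate --n-pos 150 --n-neg 0 --motif-prob 0.9 --seed 1 --out pos.fa
m5u simulate --n-pos 0 --n-neg 150 --seed 2 --out neg.fa
m5u logo --pos pos.fa --neg neg.fa --out enrichment.tsv
# -> 17 significant (position, nucleotide) cells at alpha=0.05
m5u encode --pos pos.fa --neg neg.fa --out features.tsv
# -> wrote 300 x 347 feature matrix to features.tsv
m5u select --matrix features.tsv --method gbdt_lightgbm --folds 5 --step 10 --seed 1 --out selection.tsv
# -> best subset: 20 features, CV accuracy 0.8867
```

The strongest enrichment cells are exactly the planted motif positions
(`U` at +1 and `C` at +2; position 0 is uninformative because every
window centers on U):

```
position nucleotide  freq_pos  freq_neg  difference      p_value
       2          C  0.933333  0.200000    0.733333 2.304584e-50
       1          U  0.926667  0.246667    0.680000 1.452104e-41
```

and the top-ranked feature is the UUC 3-mer frequency, followed by ENAC
windows covering the motif (window starts 18–23 cover signed positions
−3…+7):

```
rank    feature      score
   1  kmer3_UUC 346.968412
   2 enac_w23_C 234.932138
   3 enac_w19_C 155.289577
```

`m5u run --pos pos.fa --neg neg.fa --out rundir` executes the whole
pipeline (encode → select → embed → fuse → SVM grid search → tenfold CV
→ enrichment → Shapley top-20) and writes every intermediate artifact
plus a reproducibility manifest; see `m5u --help` for all verbs.

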