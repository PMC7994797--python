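# petweak

Weak supervision and multi-task attention modeling for anatomically-resolved
abnormality detection in whole-body FDG-PET/CT, built to run end-to-end on
synthetic data with no GPU and no external downloads.

The pipeline:

1. **Ontology** (`petweak.ontology`) — a DAG of anatomical regions with
   pattern-based tagging functions; mention probabilities propagate upward as
   `P(region abnormal) = 1 - prod(1 - p_i)` over the region and its
   descendants. Includes corpus-driven k-gram candidate mining.
2. **Tagging** (`petweak.tagging`) — splits reports into the four standard
   sections, segments sentences, and locates region mentions in the findings
   and impression sections.
3. **Report labeler** (`petweak.report_labeler`) — a greedy merge-based
   wordpiece vocabulary, a token-level abnormality classifier (pluggable
   sequence encoder + sigmoid head, trained with masked cross-entropy and
   early stopping on validation AUROC), mention probabilities as mean token
   probability, and a keyword rule baseline.
4. **Weak-label engine** (`petweak.weak_labels`) — report → mentions →
   probabilities → per-exam region probability map; task-region selection by
   prevalence (main ≥ 10%, rare < 3%); binary mortality labels from dates.
5. **Scan model** (`petweak.scan_model`) — a strided 3D CNN encoder with a
   declared shape-reduction contract (paper scale: d = 1024, 7 × 7 × ⌈l/6⌉
   from 2 × 224 × 224 × l; desk scale: d = 32, 8×/2× reductions), per-region
   soft-attention heads (dot-product scores, joint softmax, weighted-sum
   pooling, linear sigmoid classifier), soft-target multi-task cross-entropy,
   bilinear preprocessing, crop/brightness augmentation, multi-task training
   and single-task fine-tuning.
6. **Interpretation** (`petweak.interpretation`) — guided-backpropagation
   saliency volumes (abs → channel max → min–max normalize → optional
   clipping) and nearest-neighbor attention overlays.
7. **Evaluation** (`petweak.evaluation`) — AUROC/F1/sensitivity/specificity,
   worklist sensitivity curves, percentile bootstrap CIs over per-seed
   scores, paired sign-flip permutation tests (exact when 2^n ≤ n_iter) with
   Bonferroni correction, and median-of-seeds ensembling.
8. **Synthetic data** (`petweak.synthetic`) — paired templated reports and
   blob phantoms with full ground truth (region states, token labels, masks,
   optional mortality link), driving every test.

All neural components run on a small numpy reverse-mode autograd engine
(`petweak.nn`) — no deep-learning framework is required.

## CLI

```bash
petweak ontology validate src/petweak/data/ontology_94.yaml
petweak simulate --config sim.yaml --out cohort/        # synthetic cohort
petweak tag --reports cohort/reports.jsonl --ontology src/petweak/data/ontology_demo.yaml --out mentions.jsonl
petweak label-reports --reports cohort/reports.jsonl --ontology src/petweak/data/ontology_demo.yaml --labeler rule --out labels.csv
petweak report-model train --sentences sentences.jsonl --out report.npz --vocab-out vocab.txt
petweak train-scan --labels labels.csv --volumes cohort/volumes --out scan.npz
petweak evaluate --pred pred.csv --labels cohort/truth.csv
petweak interpret --model scan.npz --volume cohort/volumes/exam0000.npz --region liver --mode 2d --out saliency.npz
```

`sim.yaml` keys: `n_exams`, `volume_shape`, `prevalences`, `blob_intensity`,
`noise_sd`, `neutral_sentence_rate`, `seed`.

## Layout

```
src/petweak/           package (one module per pipeline stage, nn/ = autograd)
src/petweak/data/      ontology fixtures (94-region and 14-region demo)
tests/                 pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py  acceptance report
```
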