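# trialcorr

Correlative and design analytics for a biomarker-driven single-arm phase II
trial, exercisable end-to-end on bundled synthetic data with known ground
truth. The package covers:

- **IHC screening** (`trialcorr.ihc`) — additive T-score from percent stained
  cells and staining intensity, interpretive categories, eligibility, and
  screening-funnel summaries.
- **Two-stage design** (`trialcorr.design`) — exact operating characteristics
  (type I error, power, probability of early termination, expected sample
  size) of a two-stage single-arm binomial design, by exact binomial
  summation.
- **Immuno-FISH imaging** (`trialcorr.imaging`) — nuclear segmentation, FISH
  spot counting via difference-of-Gaussians local maxima, and per-cell
  pSTAT3-positivity / JAK2-amplification calls from 4-channel section images
  (DAPI, JAK2, CEP9, pSTAT3).
- **Intratumor heterogeneity** (`trialcorr.heterogeneity`) — four-population
  fractions, Shannon diversity, exact small-sample Wilcoxon comparisons,
  chi-square pooled-count tests, diversity–CD8 regression with confidence
  bands, and spatial topology maps.
- **Expression pharmacodynamics** (`trialcorr.expression`) — tumor-content
  QC, TPM conversion, per-gene pre/post tests, signature scoring (mean
  per-gene z of log2 TPM), and hypergeometric gene-set enrichment with BH
  adjustment.
- **Clinical endpoints** (`trialcorr.endpoints`) — objective response /
  stable disease / clinical benefit rates, Kaplan–Meier medians with log-log
  CIs, and worst-grade adverse-event tables.
- **Synthetic data** (`trialcorr.synthetic`) — deterministic generators for
  slide images + cell tables (four-population mixtures with optional spatial
  clustering and immune-infiltrate flags), trial cohorts (binomial response,
  exponential censored survival, AE profiles), and pre/post count matrices
  with a planted pathway contrast.

## Command line

```bash
# exact design operating characteristics
trial-oc --n1 21 --r1 2 --n 41 --r 5 --p0 0.05 --p1 0.20

# full pipeline on synthetic fixtures
trialcorr --outdir out --seed 3 all --n-cells 200 --n-slides 4

# individual stages
trialcorr --outdir out simulate --kind slide --n-cells 300
trialcorr --outdir out call-cells --image out/slide01.tif
trialcorr --outdir out diversity --cells out/slide01_cells.csv \
    --cells out/slide02_cells.csv --sheet out/slide_sheet.csv
trialcorr --outdir out expression --counts out/counts.csv \
    --lengths out/gene_lengths.csv --sheet out/expression_sheet.csv
trialcorr --outdir out endpoints --patients out/patients.csv \
    --ae out/adverse_events.csv
trialcorr --outdir out score-ihc --input out/ihc_input.csv
```

Global flags `--config` (YAML, flags take precedence), `--seed`, `--outdir`.
Every run writes `resolved_config.json` and an append-only `run_log.jsonl`
with versions, seeds, parameters and input digests. Exit codes: 0 ok,
2 missing input, 3 schema violation. Fixed seeds give bit-identical outputs.

Slide images are multi-page TIFFs, one page per channel in the order DAPI,
JAK2, CEP9, pSTAT3; cell tables are CSV with columns (cell_id, x, y,
jak2_spots, cep9_spots, pstat3_intensity, pstat3_pos, jak2_amp, cd8, gzmb,
population). Pixel coordinates are 0-based with x = column, y = row.

## Notes

- The T-score uses the standard Allred-style additive convention
  (intensity 0–3 + proportion 0–5); bin edges, category anchors and the
  eligibility threshold are configurable.
- Small-sample Wilcoxon tests use the exact conditional distribution of the
  midrank statistic (verified against full enumeration in the tests); large
  samples use the normal approximation.
- The synthetic spot-count law defaults to mean ± 1 jitter rather than
  Poisson so that the conventional ratio-2 amplification call is consistent
  with the generated ground-truth labels; a Poisson option exists.
- Per-gene differential expression is a plain t-test on log2(TPM+1);
  shrinkage-based DE machinery is intentionally out of scope. The bundled
  pathway signature lists are editable placeholders
  (`src/trialcorr/data/stat3_signatures.gmt`).
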