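# tumorevo

Tools for studying chromosome-arm copy-number evolution in tumors, exercised
end-to-end on synthetic data with known ground truth:

- **`tumorevo.simulate`** — generators for clone-structured scRNA-seq count
  matrices with planted arm-scale CNAs (plus a normal-cell baseline and
  cycling cells), clonal-SNV accrual on allele-specific copy-number histories
  with known gain/WGD times, and cohorts of per-tumor event timelines.
- **`tumorevo.cna`** — expression pipeline: trimmed-mean-of-M normalization
  against a reference, genome-ordered expression bins, cross-cell Z-scores,
  rolling-median smoothing (window 5), winsorization to [−3, 3], cell-cycle
  scoring, PCA fitted on non-cycling cells, a 1/(1+D)-weighted KNN cell
  graph, and Louvain community detection with Rand-index-based resolution
  selection.
- **`tumorevo.segmentation`** — per-community meta-cells, a 3-state
  (loss/neutral/gain) Gaussian HMM decoded by Viterbi per chromosome,
  removal of runs shorter than 5 bins, Wilcoxon rank-sum segment tests
  (exact enumeration for small samples), and community × cluster
  hypergeometric enrichment.
- **`tumorevo.timing`** — WGD calling from ploidy vs LOH fraction, SNV
  multiplicity likelihoods for gain/WGD routes, MCMC timing posteriors
  (30 chains × 2000 steps, 1000 burn-in), joint WGD timing across segments,
  pre/post-WGD route classification, eligibility filters, PDX-based
  clonality refinement, and league-model event ordering across tumors.
- **`tumorevo.clones`** — SNV quality filters (TLOD ≥ 40, ≥ 10 genotyped
  cells, no indels), rule-based clone assignment over the
  PT/PDX/single-cell sample quartet, and MRCA allele-specific copy-number
  reconstruction heuristics.
- **`tumorevo.io` / `tumorevo.cli`** — MTX/TSV/BED/YAML readers and writers,
  run configuration with strict key validation, and the pipeline driver.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (HMM vs exhaustive
path enumeration, planted-CNA recovery, timing-parameter recovery vs grid
quadrature, WGD joint timing, league vs Condorcet, clone truth table, MRCA
rules, statistical oracles, filter boundaries). The full suite takes a few
minutes; the timing-recovery criterion (450 MCMC runs) dominates.

## CLI

Everything hangs off one entry point:

```bash
tumorevo run --out out/ --seed 1                  # simulate -> cna -> segment -> enrich
tumorevo simulate expression --out sim/ --seed 1  # default planted scenario
tumorevo simulate snvs --config snvs.yaml --out snvs/ --seed 1
tumorevo simulate cohort --config cohort.yaml --out cohort/ --seed 1
tumorevo cna prepare --mtx m.mtx --genes genes.tsv --cells cells.tsv --out z.tsv
tumorevo cna communities ... --k 100 --gamma-grid 0.4,0.8,1.2 --runs 10 --seed 1
tumorevo cna segment ... --partition partition.tsv --baseline 1 --out segments.tsv
tumorevo cna enrich --communities partition.tsv --clusters clusters.tsv --out enrich.tsv
tumorevo evo time-gains --segments seg.tsv --multiplicity mult.tsv --wgd --out timing.tsv
tumorevo evo league --timelines timelines.tsv --iters 100 --seed 1 --out league.tsv
tumorevo clones assign --snvs presence.tsv --out assign.tsv
tumorevo clones mrca --profile1 p1.tsv --profile2 p2.tsv --out mrca.tsv
```

All coordinates are 0-based half-open (BED convention); TSVs are
tab-separated with a header row and `.` for missing values.

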