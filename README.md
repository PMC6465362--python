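# pmdscape

Segmentation and cohort-level analysis of **partially methylated domains
(PMDs)** in WGBS methylomes, plus a seeded synthetic-cohort generator used to
validate every stage against planted ground truth.

The pipeline covers:

* **Simulation** (`pmdscape.simulate`) — seeded synthetic WGBS-like cohorts:
  shared PMD-permissive domains with per-sample Bernoulli activation and
  boundary jitter, hypermethylated polarized background, hypomethylated CGIs
  that gain intermediate methylation inside PMDs (default probability 0.92),
  solo-WCGW context labels, negative-binomial coverage, and full ground truth
  (planted intervals, CGI states, TSG placement, per-sample PMD depth).
* **PMD calling** (`pmdscape.caller`) — sliding 101-CpG windows scored with a
  mean-constrained beta-binomial polarization parameter alpha (ML in
  log-alpha); a 1- vs 2-component Gaussian mixture on log-alpha decides
  whether PMDs are present; a two-state Gaussian-emission HMM decodes PMD
  intervals (posterior decoding, CpG-level boundary refinement, centromere
  clipping, length/CpG filters). Solo-WCGW-only mode and an aggregate
  cross-sample caller (100-kb bin methylation s.d.) are included.
* **Cohort statistics** (`pmdscape.stats`) — genome fractions, per-tile PMD
  frequency tracks (coverage and border modes), cumulative frequency-fraction
  curves, length-preserving interval shuffles with analytic-checked nulls,
  bp-level overlap/Jaccard, boundary metaprofiles, feature density by PMD
  frequency.
* **CGI / CIMP analysis** (`pmdscape.cimp`) — CGI x sample weighted
  methylation matrices, element-stratified methylation distributions, B-CIMP
  (fraction of CGIs > 30% methylated), and a from-scratch logit-link beta
  regression (ML, Wald inference, pseudo-R²) of B-CIMP on the fraction of
  CGIs inside PMDs.
* **Gene-level statistics** (`pmdscape.genes`) — gene PMD frequencies and
  exact hypergeometric exclusion tests for gene sets (e.g. tumor-suppressor
  genes).
* **Profiles** (`pmdscape.profiles`) — 10-kb tiled methylation maps,
  ward/1-Pearson and complete/1-Jaccard hierarchical clustering (explicit
  Lance-Williams agglomeration with deterministic tie-breaks), and PCA of
  top-variable CpGs with covariate association tests.

All genomic coordinates are 0-based half-open (BED convention). Region means
are weighted methylation levels (pooled M/T), with CGI/shore/promoter CpGs
excluded from PMD and tile means.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (PMD recovery on a
15-sample 3x20-Mb cohort, HMM/alpha oracles, shuffle-null analytics, beta
regression calibration, hypergeometric enumeration, clustering/PCA
structure, interval-algebra per-bp oracles). The full suite takes ~8 minutes
on one CPU; everything else finishes in ~2.

## CLI

```sh
pmdscape simulate --out cohort/ --seed 1 --samples 8
pmdscape call --input cohort/methylomes/S000.tsv --layout cohort/layout.yaml \
              --mode all --out S000.pmds.bed
pmdscape stats frequency --layout cohort/layout.yaml --pmds S000.pmds.bed \
              --pmds S001.pmds.bed --out freq.tsv
pmdscape cimp --cohort cohort/ --pmds-dir calls/ --out cimp.tsv
pmdscape genes --layout cohort/layout.yaml --pmds-dir calls/ --out genes.tsv
pmdscape map --cohort cohort/ --out tiles.tsv --tree tree.nwk
pmdscape pca --cohort cohort/ --out scores.tsv
pmdscape cluster-pmds --layout cohort/layout.yaml --pmds-dir calls/ --out t.nwk
pmdscape run --config pipeline.yaml            # full pipeline, one config
```

`pmdscape run` consumes a single YAML file (`outdir`, `seed`, plus optional
`simulate:`/`call:`/`stats:`/`profiles:` parameter blocks; unknown keys are
rejected) and writes a manifest with the config hash and per-stage timings.

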