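# xpqtl — cross-platform plasma pQTL analysis toolkit

Affinity-based plasma proteomics platforms disagree: an aptamer reagent and
an antibody assay targeting the same protein often report weakly correlated
values, and genetic analysis is one of the few ways to tell *why*. A protein
quantitative trait locus (pQTL) found by both platforms at the same variant
with the same direction of effect anchors both measurements to the protein's
biology; a pQTL found by only one platform — especially one sitting inside
the target's own gene — is a fingerprint of a binding artifact, such as a
protein-altering allele that changes an epitope rather than the protein's
abundance.

`xpqtl` implements the full analysis chain for this comparison on
individual-level data from two platforms measured in nested samples of one
cohort (a large aptamer-assayed sample and a small antibody-assayed
subsample):

* **Synthetic cohort generator** (`xpqtl.synthetic`) — LD-structured
  genotypes, a shared true protein abundance, per-platform measurement
  layers with optional epitope artifacts, a phenotype wired to either
  abundance or a protein-altering allele, and an aptamer-style technical
  layer (per-sample/per-dilution-bin scale factors, buffer blanks, floor
  censoring). Five named scenarios encode the competing causal structures.
* **Assay QC** (`xpqtl.qc`) — adaptive median normalisation with an
  acceptance window of 0.25–4 on scale factors, robust limits of detection
  from blanks (median + 4.9×MAD), median±5×MAD outlier flags, rank-based
  inverse-normal transformation, covariate residualisation.
* **pQTL mapping** (`xpqtl.mapping`) — additive single-variant GWAS,
  fixed-effects inverse-variance meta-analysis with allele harmonisation,
  reagent-count Bonferroni thresholds, ±500 kb region merging with the
  extended MHC collapsed to one region, cis/trans classification, and
  forward-stepwise conditionally independent signals.
* **Cross-platform consistency** (`xpqtl.crossplatform`) — the reciprocal
  decision tree (power filter via predicted p-values at the smaller sample
  size, LD/sign test over lead and conditional signals, cross-platform
  look-up) yielding shared / platform-specific / distinct-signals /
  underpowered calls; genotype-stratified correlation with an interaction
  test; Benjamini–Hochberg discovery at a permissive FDR.
* **Colocalisation and network** (`xpqtl.coloc`) — Wakefield approximate
  Bayes factors, five-hypothesis posteriors in log space, a phenome screen
  with secondary-signal conditional reruns, and a genetically anchored
  protein–phenotype network with per-edge direction and cross-platform
  consistency classes.
* **Determinants of specificity** (`xpqtl.determinants`) — shadow-feature
  random-forest (Boruta-style) selection of measurement determinants,
  univariate logistic odds ratios with robust (HC1) intervals for
  platform-specificity factors, and fixed-effect variance decomposition of
  between-platform differences.

## Worked example

Simulate a cohort in which one cis variant drives true protein abundance —
so both platforms should see the same signal — then run the consistency
decision tree and colocalise the protein against the simulated phenotype:

```python
from xpqtl import coloc, mapping, pipeline, synthetic

cohort = synthetic.simulate_cohort("shared-pqtl", n_individuals=2000,
                                   n_subsample=485, seed=7)
call, sumstats, pair = pipeline.evaluate_pair(cohort)
print(f"category       : {call.category}")
print(f"lead r^2       : {call.proxy_r2:.3f}")
print(f"sign concordant: {call.sign_concordant}")
print(f"predicted p    : {call.predicted_p:.2e}")

lead = pair.signal_A[0]
print(f"platform A lead: {lead.lead} (cis={lead.cis}, "
      f"p={lead.stats['p']:.2e})")

scores = pipeline.prepare_scores(cohort)
positions, prot = scores["A"]
phe = cohort.phenotypes["pheno1"].to_numpy()[positions]
results = coloc.coloc_screen(
    {"A_aptamer": mapping.gwas_linear(prot, cohort.genotypes)},
    {"pheno1": mapping.gwas_linear(phe, cohort.genotypes)},
    cohort.genotypes, "target1",
)
for r in results:
    print(f"coloc {r.phenotype_id}: PP4={r.pp4:.3f}, "
          f"lead r^2={r.lead_r2:.3f}, direction={r.direction:+d}")
```

Output:

```text
category       : shared
lead r^2       : 1.000
sign concordant: True
predicted p    : 5.70e-35
platform A lead: chr1_v8 (cis=True, p=1.08e-120)
coloc pheno1: PP4=1.000, lead r^2=1.000, direction=+1
```

Swapping the scenario name for `"epitope-a-only"` flips the call to
`specific_A` (an artifact visible to one reagent only) and
`"distinct-signals"` yields `distinct_signals`; `"proteoform-phenotype"`
demonstrates a phenotype association that survives conditioning on
abundance.

The same chain is available as a CLI:

```bash
xpqtl simulate --scenario shared-pqtl --seed 7 --out cohort/
xpqtl qc --assay cohort/assay_A.tsv --samples cohort/samples_A.tsv \
         --blanks cohort/blanks_A.tsv \
         --blanks-samples cohort/samples_blanks_A.tsv --out qc/
xpqtl consistency --cohort cohort/ --out call.tsv
```

## Reproduction

All headline quantities are recomputed from scratch by the acceptance
script (no fixtures, all randomness from the seed):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This reports, as `{"name": {"value": ..., "n": ...}}` JSON: the
reagent-count significance thresholds, the unique-protein panel count, the
colocalisation engine's maximum deviation from brute-force enumeration and
its shared-limit PP4, GWAS effect-size recovery and meta-vs-pooled
agreement, conditional two-signal recovery, per-scenario consistency
classifier accuracy, interaction-test calibration and power, QC
scale-factor recovery and the LOD worked example, and the determinants
models' planted-feature confirmation rate and odds-ratio recovery. A full
run takes about five minutes on one CPU. The test suite
(`python -m pytest -q tests/`) includes `tests/test_acceptance.py`, one
test per release criterion, alongside the unit and property suites.

See `docs/methods.md` for the statistical methods, default parameters and
known limitations.
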