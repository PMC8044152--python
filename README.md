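# bestgene

Screening drug targets for **bidirectional allelic effects** and validating
them with rare-variant association, polygenic-score stratification, and
functional-assay integration.

A gene in which some variants raise a phenotype and others lower it — high
vs. low LDL cholesterol, long vs. short QT, tall vs. short stature — is a
natural drug target: human genetics has already demonstrated, in both
directions, that modulating that gene moves the phenotype. `bestgene`
implements that idea as a tested pipeline for statistical geneticists and
target-discovery teams:

1. **Screen** a gene–disease mutation catalog for bidirectional-effect
   (BEST) genes with an explicit direction lexicon and a human-review queue.
2. **Quantify** how much more often clinical programs against supported
   targets advance: for each phase transition X→Y the risk ratio
   `RR = [a/(a+b)] / [c/(c+d)]` of supported vs. unsupported
   target–indication pairs, with the Katz log-method CI, swept over
   indication–trait similarity thresholds, plus category sensitivity
   analyses.
3. **Validate** a bidirectional gene set in an exome cohort: the published
   sample/variant QC cascade; protein-altering and protein-truncating
   variant masks (within-cohort MAF < 1e-4, per-gene cumulative AC ≥ 20);
   burden regressions of standardized height and idiopathic short stature
   (ISS, z < −2) and SKAT with Davies-method p-values
   (`P(Σλᵢχ²₁ ≥ q)` by characteristic-function inversion) over all 32
   annotation intersections; an infinitesimal-model polygenic score with
   quintile stratification, Cochran's Q / I² heterogeneity of carrier
   effects, and ISS odds ratios against the middle-quintile non-carrier
   reference; and regression of carrier heights on a cellular activity
   readout (cGMP relative to wild type) against an in-silico deleteriousness
   score.

Every input the pipeline consumes can be generated synthetically with
planted truth (`bestgene.simulate`), so the whole analysis is testable
without licensed or access-controlled data. The generator's defaults encode
the study conditions the pipeline is designed to recover: a ~34k-sample
cohort, a five-gene bidirectional set with mean −0.20 SD height effect per
rare allele and ISS odds ratio 2.75, a polygenic score explaining 20% of
height variance, and a 4× planted Phase I→Approval risk ratio for supported
targets. See `docs/methods.md` for the models, calibration, and limitations.

## Worked example

```python
from bestgene import SimulationConfig, call_bidirectional, relative_risk
from bestgene.simulate import simulate_catalog

cfg = SimulationConfig(seed=1, n_genes=12, n_best_genes=3,
                       n_samples=1000, mean_variants_per_gene=10,
                       n_common_snps=50)
catalog = simulate_catalog(cfg)          # gene-disease records, 3 planted
best, review = call_bidirectional(catalog)
for b in best:
    print(f"{b.gene}  axis={b.axis}  n_up={b.n_up}  n_down={b.n_down}")
print(f"{len(review)} labels queued for review")

est = relative_risk(8, 2, 5, 5)          # supported: 8/10, unsupported: 5/10
print(f"RR = {est.rr:.2f}  95% CI [{est.ci_low:.2f}, {est.ci_high:.2f}]"
      f"  OR = {est.odds_ratio:.2f}")
```

prints

```
GENE0000  axis=LDL cholesterol  n_up=1  n_down=1
GENE0001  axis=QT interval  n_up=1  n_down=1
GENE0002  axis=blood glucose  n_up=1  n_down=1
6 labels queued for review
RR = 1.60  95% CI [0.80, 3.20]  OR = 4.00
```

The screen recovered exactly the three planted bidirectional genes, each on
its axis with one up- and one down-direction disease label; six
negative-control labels (benign/molecular phenotypes and unmatched
syndromes) went to the review queue instead of being silently classified.
The 2×2 example: targets supported by genetic evidence succeeded in 8 of 10
programs against 5 of 10 for unsupported ones — a 1.6-fold risk ratio whose
CI still spans 1, illustrating why the real analysis needs tens of thousands
of pairs.

The full pipeline — simulate → screen → approval odds → QC → association →
polygenic stratification → functional — runs from the shell:

```bash
bestgene run --seed 1 --out run1            # full pipeline, TSV outputs + manifest.json
bestgene screen --catalog catalog.tsv --out screen_out
bestgene approval-odds --table pairs.tsv --evidence ev.tsv \
    --similarity sim.tsv --threshold-sweep --out odds_out
bestgene run --stages simulate,qc,assoc --out partial   # stage subsets
```

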