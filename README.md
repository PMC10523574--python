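# fluidsim

Federated learning by label distillation for secondary-pharmacology
QSAR, exercised end to end on a synthetic multi-partner world.

## The problem

Pharmaceutical companies hold private assay data for safety-relevant
off-targets (hERG, 5-HT₂B, AChM₁R, GABA_A, COX2, ...). Each company's
model is limited to its own chemical space, and the data cannot be
pooled. Federated learning by *label distillation* sidesteps sharing
structures or labels: each partner's local **teacher** model labels a
large shared pool of unlabeled molecules, the per-partner predictions
are consolidated, and a global **student** model is trained on the
distilled pseudo-labels. Two confidence attributes govern which
pseudo-labels survive:

* **decidability** `= |2p − 1|` — how far a predicted probability `p`
  is from equivocal;
* **reliability** — mean Tanimoto similarity between a molecule's
  2048-bit Morgan fingerprint (radius 3) and its k nearest training
  fingerprints, i.e. how close the molecule sits to the chemistry the
  model was trained on.

The **federated set** is built by discarding consolidated predictions
below a reliability threshold, ranking each class by decreasing
decidability, taking up to N per class (nominally 10,000), and filling
any shortfall from the other class's ranking. The **applicability
domain (AD)** of a model is the conjunction of thresholds on both
attributes; the fraction of a test set inside the AD measures how much
chemistry the model can assess with confidence.

Because the original partner data are proprietary, this package ships a
synthetic-world generator with the same statistical structure — partner
private sets with temporal train/test splits, partly overlapping
chemical-series clusters, configurable inactive/active ratios, a public
labeled set, and a large unlabeled pool — so every stage of the
workflow is testable and reproducible.

## Worked example

```python
from fluidsim.synthetic_data import WorldConfig
from fluidsim.workflow import RunConfig, run_experiment

cfg = RunConfig(world=WorldConfig(), seed=0,
                student_variants=("T", "HI", "HF", "F", "RF"))
ctx = run_experiment(cfg, "runs/demo")
r = ctx.metrics[ctx.metrics.ad_restricted]
print(r.groupby("variant").ad_coverage.mean().round(3))
```

On the default desk-scale world (3 partners × 2,000 training molecules,
20,000-molecule pool, 500+500 federated set, seed 0) this prints the
partner-averaged AD coverage of each variant:

```
variant
F     1.000
HF    1.000
HI    1.000
RF    1.000
T     0.886
```

The teacher (T), trained on one partner's chemistry alone, can assess
only ~89% of the temporally shifted test set with confidence; adding
the shared public set (HI), the federated set (HF), or refining a
federated model with internal data (RF) expands the applicability
domain to cover it fully — the qualitative federation benefit the
workflow demonstrates. The same run writes per-variant sensitivity,
specificity, balanced accuracy and MCC (unrestricted and AD-restricted)
to `runs/demo/metrics/variant_metrics.csv`.

The numbered drivers under `analysis/` tell the full story in order:
world generation and imbalance audit, teacher training and
cross-validation, pool distillation and the federated-set fill rule,
the student ladder with AD trends, and the joint t-SNE chemical-space
map. Each writes its tables under `results/`.

A command-line interface mirrors the pipeline stages:

```bash
fluidsim run-all --config run.yaml --out runs/demo
fluidsim generate --config run.yaml --out runs/demo
```

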