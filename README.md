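# omicsformer

Attention-based multi-omics risk classification, blood-panel deep
clustering and longitudinal risk-trajectory analysis.

## The problem

Chronic non-communicable diseases develop slowly, and their pre-onset
("sub-health") state is hard to characterize from any single assay.
This package implements a workflow for cohort studies that combine
several quantified omics layers (transcriptome, proteome, blood and
urine metabolome) with routine 25-parameter blood panels:

1. **Risk groups from routine blood data.** An attention autoencoder
   maps the standardized blood panel `B ∈ R^(n×d_B)` to a latent space
   `H_B = softmax(B W_Q^B (B W_K^B)ᵀ / √d_HB) B W_V^B`, trained by
   reconstruction `L_B = ‖B − g(H_B)‖²_F`.  K-means on `H_B` yields k
   risk clusters (default 3); within-cluster mean latent vectors are the
   **risk centroids**, ranked into levels 1 (low) … k (high) by their
   decoded panel magnitude.  New records are assigned the level of the
   nearest centroid by Euclidean distance.
2. **Multi-omics classification of those groups.** Each omics layer
   `X^(i) ∈ R^(n×d_i)` passes through a self-attention encoder
   `H^(i) = softmax(Q^(i)K^(i)ᵀ/√d_H) V^(i)` with
   `Q,K,V = X W_Q, X W_K, X W_V`; the concatenation
   `H^mul = [H^(1) … H^(v)]` is fused by a second attention block into a
   fixed-width representation `H_F`, classified by a softmax head.
   Training is two-phase: reconstruction pretraining
   (`L_re = Σ_i ‖X̂^(i) − X^(i)‖²_F` through per-layer affine decoders),
   then joint optimization of `L = L_re + a·L_Cross`.
3. **Feature-nullification importance.** After training, each feature
   column is zeroed at evaluation and the macro-F1 drop on the held-out
   split is recorded; drops are averaged over 10 seeded training runs
   and features ranked by mean drop.
4. **Trajectory validation.** Dated pre-onset blood records are binned
   by years-to-onset, each record is risk-assigned, and the slope of the
   high-risk proportion toward onset summarizes the expected rising
   pre-onset pattern.

A seeded synthetic-cohort generator (planted group structure, 25-column
blood mixture panels, drifting longitudinal records) makes the entire
pipeline testable offline; performance is reported as ACC, macro-F1 and
cluster Purity.

## Worked example

```python
import numpy as np
from omicsformer import (CohortSpec, generate_multiomics_cohort, cohort_recipe,
                         preprocess_dataset, TrainingConfig, fit_classifier)
from omicsformer.synthetic import generate_blood_panel, DriftSpec, generate_longitudinal
from omicsformer.blood_risk import BloodRiskConfig, build_risk_model
from omicsformer.trajectory import bin_by_time_to_onset, risk_proportions, trend_test

# 160-sample cohort, groups 80/41/39, four omics layers, 5% missing
dataset, truth = generate_multiomics_cohort(CohortSpec(seed=0))
pre = preprocess_dataset(dataset, cohort_recipe()).dataset
fit = fit_classifier(pre, TrainingConfig(seed=0))
m = fit.test_metrics
print(f"test ACC={m.acc:.3f}  macro-F1={m.f1_macro:.3f}  Purity={m.purity:.3f}")

panel, labels = generate_blood_panel(seed=0)          # 25-parameter panel
risk = build_risk_model(panel, BloodRiskConfig(seed=0))
print("cluster sizes:", np.bincount(risk.cluster_labels)[1:].tolist(),
      " risk order:", risk.risk_order.tolist())

records = generate_longitudinal(DriftSpec(seed=0))    # 5y pre-onset drift
table = risk_proportions(bin_by_time_to_onset(records, [0, 1, 2, 3, 4, 5]), risk)
slope, rising = trend_test(table)
print(table.to_frame())
print(f"high-risk slope toward onset: {slope:.3f} (rising={rising})")
```

prints

```
test ACC=0.906  macro-F1=0.895  Purity=0.906
cluster sizes: [41, 39, 80]  risk order: [2, 3, 1]
   bin  midpoint_years   n   risk_1   risk_2   risk_3
[4,5)y             4.5 214 0.714953 0.056075 0.228972
[3,4)y             3.5 201 0.641791 0.039801 0.318408
[2,3)y             2.5 203 0.527094 0.029557 0.443350
[1,2)y             1.5 185 0.416216 0.021622 0.562162
[0,1)y             0.5 197 0.121827 0.010152 0.868020
high-risk slope toward onset: 0.152 (rising=True)
```

The classifier recovers the three planted groups on held-out samples;
the blood model recovers the planted 80/41/39 partition (cluster 3 —
the 80-sample group with the smallest panel values — is ranked risk
level 1); and the fraction of records assigned high risk climbs from
0.23 five years before onset to 0.87 in the final year, a positive
trend slope.

The same pipeline is exposed as a CLI:

```sh
omicsformer simulate --out-dir data --seed 1
omicsformer train --data-dir data --out metrics.json --seed 1
omicsformer fit-risk --panel data/blood_panel.csv --out risk.npz --seed 1
omicsformer assign --model risk.npz --records data/blood_panel.csv --out assigned.csv
omicsformer trajectory --model risk.npz --records data/longitudinal.csv --out traj.csv
```

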