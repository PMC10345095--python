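# mmmi — multi-modal multi-instance prediction of breast-cancer lymph-node status

Preoperative knowledge of axillary lymph-node status — negative, isolated
tumor cells (ITC), micrometastasis, or macrometastasis — guides surgical
decisions in breast cancer. This package implements a multi-modal
multi-instance (MMMI) deep model that predicts the 4-class nodal status of a
patient from (a) the structured clinicopathological record of the core-needle
biopsy and (b) the whole-slide image (WSI), represented as bags of patch
feature vectors at three magnifications (5x/10x/20x). It is aimed at
computational-pathology researchers who want a fully testable, CPU-runnable
reference implementation of the architecture and its surrounding pipeline:
preprocessing (rule-based record extraction, categorical encoding,
chained-equation imputation, grid tiling, augmentation, pluggable color
normalization and feature backbones), training (label-smoothing loss,
class-balanced sampling, stratified 60/20/20 splitting, per-group Adam), and
evaluation (one-vs-rest ROC/AUC with DeLong or bootstrap CIs, the DeLong
test, Youden-optimal cutpoints, cohort-homogeneity chi-square, and
attention-based feature importance). A seeded synthetic-cohort generator
with a planted, cross-modally coupled signal stands in for clinical data so
every stage is verifiable offline.

## The model

Treat one slide as a bag of instances: patch feature vectors
`x_1..x_n (n varies from <10 to >800)` per scale `s in {5,10,20}`. With a
tabular embedding `t` from a sequential-attention (TabNet-style) encoder:

    p_s  = mean_i x_i^(s)                         (per-scale pooling)
    f    = tanh(W_f [p_5 ; p_10 ; p_20 ; t])      (cross-modal fusion)
    a_i  = softmax_i MLP_s([x_i^(s) ; f])         (instance attention)
    e_s  = sum_i a_i * (g_s ⊙ x_i^(s))            (gated scale embedding)
    t'   = sigmoid(W_r f) ⊙ t                     (tabular recalibration)
    q    = softmax MLP([t' ; e_5 ; e_10 ; e_20])  (4-class probabilities)

trained with label-smoothing cross entropy
`L = (1-eps)·(-log q_y) + (eps/K)·Σ_k(-log q_k)`, `eps = 0.1`, `K = 4`,
class-balanced sampling, and per-group learning rates (tabular 1e-2,
classifier 1e-3, rest 1e-4). The fusion vector lets the tabular modality
guide which patches the image branch attends to; tabular-only and image-only
ablation heads share the same parameter object. The network runs on a small
NumPy reverse-mode autodiff core — no GPU or deep-learning framework
required. See `docs/methods.md` for the full account.

## Worked example

```python
from mmmi import CohortSpec, MMMIModel
from mmmi.training import OptimSchedule

spec = CohortSpec(n_patients=300, seed=3)       # 53/3/15/29% prevalences
model = MMMIModel.from_spec(spec)               # simulate + bind + impute
res = model.fit(schedule=OptimSchedule(max_epochs=5, patience=3), seed=3)
print(res.summary())
print(res.tabular_importance().head(3))
```

prints (exact numbers depend only on the seeds):

    Multi-modal multi-instance nodal status model
    =============================================================
    modality head : mmmi
    parameters    : 68261   config hash aa12282fe48f
    epochs run    : 5   best val metric 0.955
    partitions    : train=180 / val=61 / test=59
    -------------------------------------------------------------
    class          AUC            95% CI    ACC    SEN    SPE
    negative       0.994     (0.984-1.000)  0.966  1.000  0.933
    itc            0.754     (0.561-0.912)  0.661  1.000  0.649
    micro          0.988     (0.965-1.000)  0.966  0.917  0.979
    macro          0.985     (0.960-1.000)  0.966  0.938  0.977
    =============================================================
    mitosis            0.214106
    gland_formation    0.110090
    stroma_change      0.106747

Reading it: each row binarizes one nodal class against the rest and scores
it by that class's predicted probability — AUC with a 95% CI (DeLong, or a
seeded bootstrap when a class has few positives, as for ITC at 3%
prevalence), plus accuracy, sensitivity and specificity at the
Youden-optimal cutpoint. At this deliberately small size (300 patients, 5
epochs) the rare ITC class is the weakest; the acceptance study at 1000
patients recovers it above 0.9. The importance ranking recovers the
planted signal: the generator gives the mitosis score the largest log-odds
shift, and the encoder's attention masks rank it first.

The same pipeline is scriptable from the shell (`mmmi simulate`,
`mmmi preprocess-tabular`, `mmmi preprocess-wsi`, `mmmi train`,
`mmmi predict`, `mmmi evaluate`).

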