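# Methods

## Overview

`gcnsp` classifies subjects (patient vs control) from functional-connectome
graphs using a graph convolutional network with *trainable sparse pooling*,
and evaluates it under three multi-site regimes: pooled cross-validation,
leave-site-out testing, and transfer learning by fine-tuning on a small
target site. An interpretability suite reconstructs what the trained model
uses: per-layer feature maps, their overlap with functional networks, and
class activation maps (CAM) pushed down to individual connectivity edges.

## Connectome representation

Each subject is an N x N Fisher-z connectivity matrix
`z_ij = atanh(pearson(ts_i, ts_j))`. The diagonal is fixed at 0 (atanh(1)
diverges) and |r| is clipped at 0.999999 before the transform; artifactual
correlations outside [-1, 1] are assumed excluded upstream. Additive
per-site effects are removed by *site regression*: per edge, an OLS fit of
z on one-hot site indicators estimated on training subjects only; the
fitted effect (per-site mean minus grand mean over the fit set) is
subtracted from every subject of that site. Fitting on the training fold
only prevents leakage; the operation is idempotent.

All subjects share one population graph: nodes are ROIs, and node i's
feature vector is its connectivity profile (row i of z). The graph is a
K-NN graph (default k = 10) over the *training-fold mean* connectivity.
Node distance is the correlation distance `1 - pearson(row_i, row_j)` with
the two self-connection entries masked; each node keeps its k nearest
neighbours (ties to the lower index), and the edge set is union-symmetrized
with binary weights (a similarity-weighted mode is available). Whether the
K-NN graph should be directed or symmetrized, and the exact distance, are
genuinely open choices; union symmetrization and masked-row correlation
distance were chosen for symmetry of the propagation operator and
determinism. Convolution uses the renormalized adjacency
`A_hat = D^-1/2 (A + I) D^-1/2`, whose spectrum lies in [-1, 1].

## Model

Two graph-convolution layers (`Z = ReLU(A_hat ReLU(A_hat X W0) W1)`)
produce node embeddings; a chain of pooling layers `Z_G^i = Theta_i
Z_G^{i-1}` (pure linear maps, `n_i = ceil(0.5 n_{i-1})`, two layers by
default) produces hierarchical graph embeddings whose flattened
concatenation feeds a bias-free dense softmax head. The loss is

    L = cross-entropy + lambda * sum_i ||Theta_i||_1 + l2 * (||W0||^2 + ||W1||^2 + ||W_dense||^2)

so the pooling weights start dense and are driven sparse by the L1 term —
sparsity is learned, not imposed. The L2 penalty applies to the dense
weight matrices only. Defaults: learning rate 1e-4, hidden size 64 (16 for
interpretability runs), 100 epochs, lambda = 5e-4, l2 = 1e-4, dropout 0.5
(after the first GCN layer and on the graph embedding; placement is a
design choice), batch 32 for pooled multi-site training and 16 for
single-site fine-tuning. The optimizer is Adam; gradients of the small,
fully linear-plus-ReLU architecture are computed in closed form and checked
against central finite differences in the test suite. All randomness
(init, shuffling, dropout) is seeded; training histories are
bit-reproducible. A plain-GCN ablation (`readout="mean"`) replaces the
pooling stack with a node-mean readout.

The front end follows the model/results convention of statistical
modelling libraries: `GCNSPModel(dataset, graph, hyper).fit()` returns a
`GCNSPResults` with parameters, history, `predict_proba` and a `summary()`
table.

## Evaluation protocols

*Pooled CV*: stratified 10-fold (label within site, one global round-robin
pointer so fold sizes and per-class counts stay within +/-1). Site
regression, the population graph, feature scaling and RFE are all refit
inside each training fold; metrics are computed on pooled out-of-fold
scores. Every fitted object records the subject ids that influenced it,
and the tests assert these audits are disjoint from test folds.

*Leave-site-out*: train on all other sites; nothing fitted sees the
held-out site. The held-out site's own additive site effect is left
uncorrected — the protocol deliberately measures generalization without
site-specific information.

*Transfer*: pre-train on the source sites (with an internal 10% stratified
holdout logged for sanity), then 10-fold within the target site: fine-tune
all parameters (batch 16) on the 90% portion minus a stratified ninth
carved out as validation, test on the 10%. Fixed-epoch metrics use the
final epoch; the optimal-epoch variant re-reads test scores at the epoch
with the highest validation accuracy (ties -> earliest). Accuracy is
averaged over folds; ROC/AUC use pooled scores. Site inclusion requires at
least 20 subjects per group (configurable); zero fine-tuning epochs
reduces exactly to pretrained evaluation, and a random start reduces to
non-transfer training.

*Baselines*: recursive feature elimination ranked by two-sample t-score
(drop the lowest-|t| 10% per round, recompute, until max(1, ceil(r*d))
remain; r = 1e-4 by default, matching a ~1.5M-edge feature space — at
synthetic scale a dimension-matched ratio is used instead) feeding a
linear SVM, LDA or logistic regression.

*Metrics*: accuracy/sensitivity/specificity at probability threshold 0.5,
ROC by threshold sweep, AUC as the trapezoidal ROC area (equal to the
Mann-Whitney concordance, verified against that oracle). Single-class test
sets yield AUC = NaN with a warning, never a fabricated value.

## Interpretability

Because the dense head has no bias, `S_c = sum_x w_x^c z_g[x]` exactly;
the embedding-level CAM is that per-entry decomposition and the
conservation identity is asserted to 1e-8. Node-level maps backproject
each pooled block through the transposed Theta chain. Edge-level maps use
gradient-times-input on the input connectivity, symmetrized, which is
exact (sums to S_c) whenever the network operates in its linear regime.
Channel-network association uses the top 10% of nodes per channel by
absolute activation; a network's share is divided by its node-count
fraction before the argmax (size correction). Group differences are
elementwise pooled-variance two-sample t statistics with a Gaussian KDE
(Scott's rule, bandwidth floored at 1e-6).

## Synthetic data

The generator emulates the statistical skeleton the method assumes:
block-structured z-connectivity by functional network (within-block r vs
between-block r), a planted set of group-discriminative edges carrying an
additive z-space effect in patients, per-site additive shift and
log-normal multiplicative scale (drawn once per site), and symmetric
per-subject edge noise. A time-series mode maps each subject's z-matrix
through tanh to a correlation matrix, repairs it to positive definite by
eigenvalue clipping at 1e-6, draws T multivariate-normal timepoints and
pipes them through the package's own connectivity estimator. It does not
emulate hemodynamics, autocorrelated noise, head motion, or missing data,
so passing tests demonstrate correct mechanics and calibration of the
pipeline, not clinical performance.

Presets (the study conditions used by tests and the acceptance script):

- `separable` — N=60 ROIs, 6 networks, 2 sites, 100 patients + 100
  controls, effect 0.3 z-units on one within-network block (45 edges)
  against subject noise 0.2, mild site effects. The pipeline should
  recover the effect (pooled-CV accuracy >= 0.85) and the CAM should
  concentrate on the planted block.
- `null` — same skeleton, effect 0; any systematic departure of
  cross-validated accuracy from chance indicates leakage.
- `transfer_benefit` — N=30, 5 sites with strong site effects
  (shift sd 0.25, scale sd 0.1), four source sites of 60 and one target of
  40 subjects, effect 0.25 against noise 0.25: the regime where
  pre-training should beat target-only training.
- `deep_vs_shallow` — N=30, 100+100 subjects, effect 0.4 on a
  within-network block plus between-network edges. Sized so the model
  actually trains to high accuracy: the layer-contrast property (larger
  group |t| in deeper feature maps) is a property of a *trained*
  hierarchy; an undertrained model shows no contrast.
- `shuffle_control` — magnitude-uniform background (within = between
  r = 0.3) with a weak effect (0.05). Design note: gradient-times-input
  attribution contains the input as a factor, so wherever planted edges
  have elevated mean input magnitude they are recovered regardless of the
  graph, and a graph-shuffling control would be uninformative. On this
  preset the input factor is uniform and attribution is driven by the
  learned gradient; training on adjacency-shuffled graphs then leaves
  planted-edge precision statistically indistinguishable from chance.

## Numerical choices and problem sizes

Probabilities are floored at 1e-12 inside the log; |r| clipped at
0.999999 before atanh; KDE bandwidth floored at 1e-6; neighbour and edge
ties broken by node index for determinism. The synthetic studies use
N = 60 ROIs with 200 subjects for the main recovery experiment and N = 30
with 100–280 subjects for the transfer, null, layer-contrast and shuffle
studies — sizes chosen so a full multi-seed battery of end-to-end
cross-validated runs remains comfortably reproducible on a single CPU
while keeping every protocol (10-fold CV, pretraining, fine-tuning with
validation carving) at its full-sized logic.

## Known limitations

- The cross-entropy uses the standard orientation; one printed source
  formula orients it the other way, which we treat as a typo.
- The site model is additive shift + multiplicative scale in z-space;
  richer scanner effects (covariance shifts, frequency content) are out
  of scope.
- The held-out site in leave-site-out receives no harmonization at all;
  alternatives (unsupervised re-centering) would change the protocol's
  meaning.
- Edge-level CAM has no unique definition from node-level maps; linear
  backprojection and gradient-times-input are two defensible realizations
  and both are exposed.
- Hyperparameters are fixed defaults, not searched.
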