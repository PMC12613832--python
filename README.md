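# omicsgcn

Feature-level graph-convolutional integration of multi-omics data for
supervised biomedical classification.

## The problem

Paired omics profiles of the same cohort — mRNA expression, miRNA
expression, DNA methylation, copy number — carry complementary signal,
and much of it flows through *regulatory* relationships between
features of different modalities (a miRNA repressing its target mRNAs,
say). Sample-similarity integration methods never see those feature-level
links. `omicsgcn` instead builds graphs whose nodes are the molecular
features themselves: one intra-omics network per modality (thresholded
cosine/Pearson/RBF affinity, or a curated network) and one bipartite
network per modality pair (e.g. a TargetScan-style miRNA→mRNA edge
list), and trains a graph-convolutional classifier that propagates
information along both kinds of edges in every layer.

## The model

With `H_m^(0) = X_m^T` (features × samples), each of L layers computes,
per omics block and in parallel,

    Z_m      = σ(W_m Â_m H_m)                (intra-omics GCN)
    Z_{o→m}  = σ(W_{o→m} B̂_{m,o} H_o)        (bipartite GCN, per other block o)
    H_m'     = k·Z_m + (1−k)·mean_o Z_{o→m}  (weighted message passing)

where `Â = D^{−1/2}(A+I)D^{−1/2}` is the renormalized adjacency,
`B̂_{m,o}` the corresponding block of the jointly normalized bipartite
adjacency, σ LeakyReLU, and `k ∈ [0,1]` the intra/inter fusion weight.
The final-layer blocks are concatenated and fed to a linear head
(sigmoid or softmax), trained end-to-end on cross-entropy ("WMP"), or
first pretrained without labels on `α·L_align + (1−α)·L_recon` and then
fine-tuned ("dual alignment"). Weight matrices are square, so every
output coordinate stays identified with an input feature, and the
pre-head representations can be exported as interpretable embeddings.

The evaluation protocol is repeated stratified 80/20 splitting (with an
inner 80/20 validation split and per-subset z-scoring), AUROC on
probabilities, Youden-index thresholding, and MCC. A synthetic-cohort
generator with planted cross-omics signal makes the whole pipeline
testable offline; see `docs/methods.md` for the full model and protocol
description.

## Worked example

Simulate a cohort in which the class signal enters the small
"regulator" block and reaches the large "target" block only through a
known sparse bipartite graph, then train and evaluate:

```sh
omicsgcn simulate --seed 5 --out cohort/
omicsgcn train \
    --omics u=cohort/omics_u.tsv --omics v=cohort/omics_v.tsv \
    --labels cohort/labels.tsv \
    --bipartite u:v=cohort/bipartite_edges.tsv \
    --repeats 5 --seed 7 --out run/
```

which prints

```
wrote synthetic cohort (n=300, p=200, q=50) to cohort
mean AUROC 0.9971, mean MCC 0.9674 over 5 repeats -> run
```

Per-repeat metrics and the aggregate mean/SD land in
`run/metrics.json`; `run/embeddings.tsv` holds the pre-head
representations (samples × 250 features, one column per input feature);
`run/model.npz` stores the trained weights and graphs for
`omicsgcn evaluate`. A mean test AUROC of ~0.998 over the repeated
splits says the model recovers essentially all of the planted
cross-omics signal; the MCC of ~0.97 is the agreement after Youden
thresholding. Other subcommands: `build-networks` (graph construction
with degree summaries), `ablate` (both / intra-only / inter-only on
identical splits), `sweep-k`, `rewire-test` (robustness to bipartite
edge noise), `evaluate`.

The same run is available from Python via `omicsgcn.repeated_eval`,
`omicsgcn.run_ablation`, `omicsgcn.run_k_sweep` and friends.

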