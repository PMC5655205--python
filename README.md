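# dbncs — multiple time-delayed gene regulatory network inference

`dbncs` reconstructs **time-delayed gene regulatory networks (GRNs)** from a
single time-series gene expression matrix (genes × time points). It is aimed
at systems biologists working with small-to-medium time-course experiments
(DREAM-style in-silico benchmarks, pathway-scale modules such as the
*E. coli* SOS DNA-damage response) who want not just *which* gene regulates
which, but the *direction* of each regulation and its *transcriptional
delay* in sampling-interval units.

## The method

The pipeline is a hybrid dynamic-Bayesian-network (DBN) learner. A DBN
structure is a pair (prior network, transition network); here the prior
network is the directed regulator→target graph and the transition network is
the integer delay matrix — an edge connects slice *t* to slice *t + delay*,
never within a slice. Inference runs in five stages:

1. **Skeleton learning (CMI2NI).** Starting from the complete graph, edges
   are removed order by order with conditional mutual inclusive information
   under a Gaussian model. Order 0 tests plain mutual information
   `MI(X;Y) = −½ ln(1 − r²)` against an independence threshold θ; order
   L ≥ 1 tests `CMI2(X;Y|K)` aggregated (max, or geometric mean) over all
   order-L subsets K of the genes adjacent to both endpoints. CMI2 augments
   conditional MI with two non-negative Kullback–Leibler terms measuring the
   effect of removing each directed edge,

   `CMI2(X;Y|Z) = CMI(X;Y|Z) + ½ D_KL(P‖P_{X→Y}) + ½ D_KL(P‖P_{Y→X})`,

   which counteracts CMI's tendency to underestimate direct regulation.
2. **Recursive optimization (RO).** Each gene's series is regressed on its
   skeleton neighbours by least-absolute-deviation + L1 regression,
   `min_β Σ|y − Xβ| + λΣ|β|`, solved exactly as a linear program; strengths
   below θ₀ are zeroed and the survivors re-fit until stable. Edges with no
   surviving strength in either direction are redundant and removed.
3. **Delay estimation.** For each surviving pair, both directed delays are
   the shift m ∈ {1..k} maximizing the MI of the recombined series
   `(x[0..T−m−1], y[m..T−1])`.
4. **Orientation.** The skeleton decomposes losslessly into pair cliques;
   each clique's two candidate directions are scored with the comprehensive
   score `CS = σ(ω|β^RO| + (1−ω)β^MI)² + (1−σ)·TRS²` — linear (RO),
   non-linear (delay-aligned MI) and dynamic (transcriptional regulation
   score, a sign-consistency statistic over regulator-change/target-change
   events) evidence, each min–max standardized over the candidate-edge
   population. The higher-scoring direction wins.
5. **Assembly.** Oriented subnetworks merge into the final time-delayed GRN.

A synthetic-data module generates delayed linear-Gaussian time courses from
random DAGs with known edges, signs and delays, so the whole pipeline is
testable without any external download. An evaluation module provides
confusion counts, TPR/FPR/PPV/ACC/MCC and ROC-AUC against a gold standard.

## Worked example

Simulate a 10-gene, 10-edge benchmark, infer, and score it:

```sh
$ dbncs simulate --seed 7 --out ex
wrote ex_expression.tsv, ex_gold.tsv, ex_network.tsv

$ dbncs infer --expr ex_expression.tsv --out pred
dbncs: inference: N=10 genes, T=50 time points, theta=0.15, k=5, lambda=1, sigma=0.6, omega=0.5, aggregation=max
dbncs: skeleton: 5 edges, order reached 1
dbncs: after RO pruning: 5 edges
dbncs: final GRN: 5 directed edges
wrote pred.tsv and pred.sif (5 edges)

$ cat pred.tsv
regulator	target	delay	score
G1	G8	2	0.270685
G4	G5	1	0.850043
G7	G9	4	0.168047
G8	G4	1	0.604869
G9	G1	2	0.34725

$ dbncs evaluate --pred pred.tsv --gold ex_gold.tsv --out metrics.tsv
$ cat metrics.tsv
TPR	FPR	PPV	ACC	MCC	AUC
0.200	0.065	0.400	0.804	0.181	0.570
```

Each `pred.tsv` row is one inferred regulation: `G8 → G4` with delay 1 means
G4's expression responds to G8 one sampling interval later; `score` is the
edge's comprehensive score (its confidence). Here the run recovered two of
the ten planted edges with their exact delays (`G8→G4`, `G9→G1`) and made
three false calls, giving the directed-evaluation metrics in the last block
(TPR = 2/10; MCC balances all four confusion counts). Recovering delayed
edges from 50 zero-lag-screened time points is genuinely hard — see
`docs/methods.md` for what limits recall.

The same functionality is available as a library:

```python
from dbncs import SimSpec, sample_network, simulate_expression, infer_grn

spec = SimSpec(seed=7)
expr = simulate_expression(sample_network(spec), spec)
result = infer_grn(expr)
print(result.grn.prior.edges)
```

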