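# elca — model-based clustering of random hypergraphs

`elca` fits the **extended latent class analysis (ELCA)** model to binary
hypergraph data: co-authorship of papers, co-appearance of characters in
scenes, co-mention of entities in documents — any data where each observation
(a *hyperedge*) is an arbitrary subset of a fixed vertex set. The package is
aimed at statisticians and network scientists who want an interpretable
probabilistic clustering of the hyperedges, together with principled model
selection and full control of the simulation machinery.

## The model

A hypergraph on N vertices with M hyperedges is stored as the binary
incidence matrix X with x_ij = 1 iff vertex v_i belongs to hyperedge e_j.
Standard latent class analysis (LCA) treats each hyperedge as a draw from a
G-component mixture of independent Bernoulli profiles,

    P(e_j) = Σ_g π_g Π_i p_ig^{x_ij} (1 − p_ig)^{1 − x_ij}.

ELCA adds a second, a-priori independent clustering that captures variation
in hyperedge *size*: each hyperedge also draws a label k ~ Categorical(τ)
over K "size" clusters, and its membership probabilities are rescaled by a
multiplier a_k ∈ (0, 1]:

    P(e_j) = Σ_g Σ_k π_g τ_k Π_i (a_k φ_ig)^{x_ij} (1 − a_k φ_ig)^{1 − x_ij}.

For identifiability the multipliers are kept ascending with a_K = 1 (the
likelihood is invariant under a → C·a, φ → φ/C). ELCA(G, K) is exactly an
LCA with G·K classes whose profiles are proportional within groups, but with
only G·N + 2(K − 1) + (G − 1) free parameters instead of G·K·N + (G·K − 1);
K = 1 recovers plain LCA.

Estimation is by expectation–conditional-maximization: the E-step yields the
joint posterior of (g, k) per hyperedge in closed form; the conditional
updates for φ and a have no closed form (the log(1 − a_k φ_ig) coupling) and
are solved by minorize–maximize steps with quadratic lower bounds, which
preserves the monotone-ascent guarantee of EM. The number of clusters is
chosen by BIC, −2 log L + (G·N + 2(K − 1) + (G − 1)) log M, minimized over a
(G, K) grid.

## Worked example

```python
from elca import ELCAModel, simulate
from elca.fixtures import study_theta

theta = study_theta(2, 2, 8, a=[0.3, 1.0])   # 2 primary x 2 size clusters
X, labels = simulate(theta, 400, seed=5)      # 400 hyperedges on 8 vertices
res = ELCAModel(X, n_primary=2, n_additional=2).fit(n_restarts=5, seed=0)
print(res.summary())
```

```
Extended Latent Class Analysis results
======================================================
vertices (N):        8
hyperedges (M):      400
primary clusters G:  2
additional K:        2
free parameters:     19
log-likelihood:      -1535.6722
BIC:                 3185.1822
converged:           True (45 iterations)
------------------------------------------------------
pi  (primary weights):    [0.513 0.487]
tau (additional weights): [0.573 0.427]
a   (size multipliers):   [0.329 1.   ]
------------------------------------------------------
phi (vertex membership probabilities by primary cluster):
    cluster 1  cluster 2
v1      0.879      0.072
v2      0.811      0.042
v3      0.815      0.117
v4      0.814      0.063
v5      0.072      0.819
v6      0.088      0.801
v7      0.133      0.825
v8      0.081      0.799
```

The fit recovers the generating structure: vertices v1–v4 load on primary
cluster 1 and v5–v8 on cluster 2 (true φ was 0.8 on the own block, 0.1
elsewhere), and roughly half the hyperedges (τ̂ ≈ 0.57) were shrunk by
â₁ ≈ 0.33 (true a₁ = 0.3) — these are the systematically smaller hyperedges.
`res.primary_posterior` and `res.additional_posterior` give per-hyperedge
membership probabilities; `elca.select_model(X, range(1, 4), range(1, 4))`
runs the BIC grid.

A command-line interface mirrors the library:

```sh
elca simulate --params theta.json -m 400 --out x.tsv --labels-out labels.tsv
elca fit --incidence x.tsv -g 2 -k 2 --out fit.json
elca select --incidence x.tsv --g-max 3 --k-max 3 --out grid.tsv
elca moments --params theta.json
```

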