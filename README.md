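# lemnet

Local Bayesian inference of gene regulatory edges from time-series
expression data, with an ODE benchmark simulator and signed-edge
evaluation metrics.

## The problem

Given trajectories of N genes, X_i(t_1..t_T), which regulator — and which
regulatory logic, activation or repression — best explains each gene's
dynamics? `lemnet` answers this gene by gene. Each candidate regulation
is a Hill-kinetics ODE

    dX/dt = α · f(Y) − β·X + γ,   f(Y) = Yⁿ/(Kⁿ+Yⁿ)  or  Kⁿ/(Kⁿ+Yⁿ)

whose five parameters θ = (α, β, γ, n, K) are fitted by minimizing an
integral-equation loss: the modeled derivative is integrated
(cumulative trapezoid) and compared with the observed series up to an
additive shift, ℓ = min_c (1/T) Σ_j (X(t_j) − X̂(t_j) − c)². Each edge E
is then scored by a Gibbs posterior with a maximum-entropy prior on its
parameter box R_E,

    p(E | D) ∝ ∫_{R_E} exp(−ℓ(θ)/λ) dθ / (s · Vol(R_E)),

approximated by Laplace's method at the fitted optimum — no MCMC. The
result is one probability distribution over candidate edges per gene,
from which a network is extracted (argmax or probability threshold) and a
complete, fully parameterized ODE system can be assembled and
re-simulated. Known activator/repressor roles enter as priors that zero
out contrary-signed candidates. See `docs/methods.md` for the details and
numerical choices.

The package is aimed at systems-biology practitioners with
moderately sized candidate gene sets (tens of genes) and high-quality
time-course data, and at methodologists who need a transparent
benchmark: the simulator generates oscillatory and relaxation dynamics
from known networks (including AND/OR multi-input nodes the inference
class deliberately excludes) with truncated-Gaussian noise, and the
evaluation module scores rankings with AUC-ROC, AUPR, and MCC over the
signed directed edge universe.

## A worked example

```python
from lemnet import (build_fixture, default_config, simulate,
                    gold_standard_edges, infer_network, InferenceSettings,
                    extract_network, GoldStandard, ranking_from_posteriors,
                    roc_auc, mcc)

spec = build_fixture("repressilator3")          # A -| B -| C -| A
data = simulate(spec, default_config("repressilator3"))
result = infer_network(data, settings=InferenceSettings(seed=0))

for post in result.posteriors:
    top = post.top_edge()
    print(post.target, "<-", top.regulator, top.sign.value,
          f"p={post.probabilities[top]:.3f}")

gold = GoldStandard(spec.nodes, set(gold_standard_edges(spec)))
net = extract_network(result.posteriors, mode="argmax")
print("AUC-ROC:", roc_auc(ranking_from_posteriors(result.posteriors), gold))
print("MCC:", mcc(net, gold))
```

prints

```
A <- C r p=1.000
B <- A r p=1.000
C <- B r p=1.000
AUC-ROC: 1.0
MCC: 1.0
```

i.e. every node's posterior concentrates on its true regulator and sign
(p ≈ 1.000), the extracted network is exactly the generating cycle of
repressions, and the ranking separates true from false edges perfectly
(AUC-ROC = 1) as does the one-edge-per-node binary prediction (MCC = 1).
The scripts in `examples/` walk through each capability — simulation,
inference, noise robustness, role priors, and re-simulating the fitted
ODE system — and print the numbers they compute.

The same pipeline is available from the shell:

```bash
lemnet simulate --fixture repressilator3 --out-expression expr.tsv --out-gold gold.tsv
lemnet infer --expression expr.tsv --out-posteriors post.tsv --out-network net.tsv
lemnet evaluate --posteriors post.tsv --gold gold.tsv --out metrics.json
lemnet fit-dynamics --expression expr.tsv --out resimulated.tsv
```

All artifacts are tab-separated text with a comment header recording the
tool version, seed, and configuration hash.

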