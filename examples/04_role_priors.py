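"""Use biological role priors to restrict the candidate edges.

A gene known to act only as an activator (or only as a repressor) can be
declared so; all candidate edges with the contrary sign then get prior —
and hence posterior — probability zero. Here every repressilator gene is
correctly declared a repressor, halving each node's candidate set from 6
to 3 and concentrating the posterior further.
"""

from lemnet import (
    InferenceSettings,
    PriorSpec,
    build_fixture,
    default_config,
    infer_network,
    simulate,
)

spec = build_fixture("repressilator3")
data = simulate(spec, default_config("repressilator3"))

prior = PriorSpec({g: "repressor" for g in spec.nodes})
result = infer_network(data, prior=prior, settings=InferenceSettings(seed=0))

for post in result.posteriors:
    print(f"node {post.target}: {len(post.probabilities)} candidates "
          f"(6 without the prior)")
    top = post.top_edge()
    print(f"  most probable: {top}  p = {post.probabilities[top]:.3f}")
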