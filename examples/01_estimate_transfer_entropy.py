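"""Estimate transfer entropy on one simulated trial with all five estimators.

Simulates the coupled linear AR model (driver x influences target y at lag 1
with strength a=0.5), then estimates TE in both directions.  TE x->y should
be clearly positive, TE y->x near zero: no reverse influence is imposed.
"""

from tebench import EmbeddingSpec, SimConfig, estimate_te, simulate

x, y = simulate(SimConfig(model="linear", a=0.5, N=200, seed=42))
spec = EmbeddingSpec(tau=1, m=1, n=1)

print(f"{'estimator':>9}  {'TE x->y':>8}  {'TE y->x':>8}   (nats)")
for est, params in [("LIN", {}), ("KNN", {"k": 5}), ("FBR", {"Q": 4}),
                    ("KDE", {"alpha": 1.5}), ("DVP", {})]:
    fwd = estimate_te(x, y, spec, est, params).value
    rev = estimate_te(y, x, spec, est, params).value
    print(f"{est:>9}  {fwd:8.4f}  {rev:8.4f}")

print("\nA positive forward TE with a near-zero reverse TE recovers the"
      "\nimposed direction of coupling; FBR/KDE run a little high on both"
      "\ndirections because their plug-in entropies are positively biased.")
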