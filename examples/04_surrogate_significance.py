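"""Separate linear from nonlinear coupling with surrogate tests.

Two surrogate ensembles are compared on one coupled linear-model trial:
IRS surrogates destroy all cross-dependence (testing for any interaction),
IMS surrogates preserve the cross-spectrum, i.e. the linear part (testing
for a nonlinear component).  The original TE is significant iff it exceeds
all 20 surrogate TEs (a one-sided 1/21 test).
"""

from tebench import (
    EmbeddingSpec,
    SimConfig,
    classify_interaction,
    simulate,
    test_significance,
)

x, y = simulate(SimConfig(model="linear", a=0.5, N=200, seed=0))
spec = EmbeddingSpec(tau=1)

irs = test_significance(x, y, spec, "DVP", surrogate_kind="IRS", seed=10)
ims = test_significance(x, y, spec, "DVP", surrogate_kind="IMS", seed=110)
cls = classify_interaction(irs, ims)

for name, res in [("IRS", irs), ("IMS", ims)]:
    print(f"{name}: original TE = {res.original_te:.4f}, max surrogate TE = "
          f"{res.surrogate_te.max():.4f} -> "
          f"{'significant' if res.significant else 'not significant'}")
print(f"classification: linear = {cls.linear}, nonlinear = {cls.nonlinear}")

print("\nThe purely linear coupling survives in the IMS surrogates, so only"
      "\nthe IRS test fires: the interaction is classified as linear with no"
      "\ndetectable nonlinear component.")
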