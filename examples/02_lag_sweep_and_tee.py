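"""Find the interaction lag with a lag sweep and score it with TEE.

The nonlinear model couples the driver into the target at lag 2 only.
Sweeping the embedding lag over 1..5 on 50 fresh trials, the median TE
profile should peak at tau=2; the Transfer Entropy Excess (TEE) — the sum
of the profile divided by its value at the true lag — is 1 for a perfectly
lag-specific estimator and grows with spurious TE at the wrong lags.
"""

from tebench import SimConfig, compute_tee, lag_sweep

cfg = SimConfig(model="nonlinear", b=0.4, N=200)
for est, params in [("DVP", {}), ("FBR", {"Q": 4})]:
    profile = lag_sweep(cfg, est, params, lags=(1, 2, 3, 4, 5),
                        trials=50, seed=1)
    tee = compute_tee(profile, interaction_lag=2)
    meds = "  ".join(f"{m:6.3f}" for m in profile.median_te)
    print(f"{est}: median TE per lag [{meds}]  TEE = {tee:.2f}")

print("\nBoth estimators peak at tau=2.  DVP's TEE of ~1 means it reports"
      "\nessentially no transfer at the wrong lags, while FBR's binning bias"
      "\nputs a constant positive floor under every lag, inflating its TEE.")
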