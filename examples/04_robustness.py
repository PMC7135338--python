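"""Robustness of learning and the Poisson baseline.

Trains small EI networks under perturbations — deleted connections and
synaptic delays — and compares the decoding error of the learnt
spike-by-spike code with rate-matched Poisson populations (same neurons,
same rates, independent spikes).  Takes ~2 minutes.
"""

from spikecoding.experiments import ExperimentConfig, run_robustness

cfg = ExperimentConfig(t_joint=1500.0, checkpoint_every=1500.0, n_inh=15, seed=0)

table = run_robustness(cfg, {"densities": [1.0, 0.5], "seeds": [0]})
print("connection density sweep (N_I = 15):")
print(table[["value", "trained_mse", "poisson_mse"]].to_string(index=False))

table = run_robustness(cfg, {"delays": [0.0, 0.1], "seeds": [0]})
print("\nsynaptic delay sweep (time-to-peak in tau; 0.1 tau = 1 ms):")
print(table[["value", "trained_mse", "poisson_mse"]].to_string(index=False))
print("\nThe trained code beats the Poisson baseline by an order of magnitude;")
print("delays degrade it (delayed inhibition limits spike-by-spike precision).")
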