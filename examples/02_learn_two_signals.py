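"""Learning to encode two signals from scratch.

A 20-neuron population starts with a lopsided feedforward map (no neuron
responds positively to the first signal) and no recurrent connections.
Recurrent plasticity first balances the network (error and rates drop);
feedforward plasticity then spreads the weights over the input space,
closing the gap in direction coverage.  Takes ~1 minute.
"""

import numpy as np

from spikecoding import LearnConfig, coverage_gap, evaluate_coding, train, tuning_curves
from spikecoding.experiments import make_network, smooth_noise_source

src = smooth_noise_source()          # 2 channels, smoothed noise
cfg = LearnConfig(seed=0)
net0 = make_network(N=20, M=2, seed=0, lopsided=True)

ev0 = evaluate_coding(net0, src, 99, duration=100.0)
print(f"untrained        : mse={ev0['mse']:.3f}  rate={100*ev0['rate']:.0f} Hz")

rec = train(net0, src, 600.0, cfg, checkpoint_every=600.0, learn_ff=False)
ev1 = evaluate_coding(rec.final_network, src, 99, duration=100.0)
print(f"recurrent-only   : mse={ev1['mse']:.3f}  rate={100*ev1['rate']:.0f} Hz")

joint = train(rec.final_network, src, 2000.0, cfg, checkpoint_every=500.0)
ev2 = evaluate_coding(joint.final_network, src, 99, duration=100.0)
print(f"joint training   : mse={ev2['mse']:.3f}  rate={100*ev2['rate']:.0f} Hz")

angles = np.arange(-180.0, 180.0, 15.0)
for tag, nn in (("recurrent-only", rec.final_network), ("joint", joint.final_network)):
    tc = tuning_curves(nn, 1.5, angles, duration_per_angle=8.0)
    pref = angles[np.argmax(tc, axis=1)]
    active = tc.max(axis=1) > 0.01
    print(f"coverage gap {tag:15s}: {coverage_gap(pref[active]):.0f} deg "
          "(largest arc of input directions no neuron prefers)")
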