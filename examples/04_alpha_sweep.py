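"""Ergodic selection of the entropy order alpha.

Sweeps alpha from 0.1 to 5.0 in 0.1 steps (alpha = 1 evaluated through
the Shannon limit), scoring each value by the mean CV correct rate of the
entropy features it produces on the PAF vs distant-from-PAF pairing.
"""

import numpy as np

import pafentropy as pe

records = pe.make_benchmark(seed=1)
signals = [pe.resample_uniform(pe.clean_rr(r)) for r in records
           if r.label in ("PAF", "DISTANT")]
res = pe.sweep_alpha(signals, positive_label="PAF", grid_lo=0.1,
                     grid_hi=5.0, step=0.1, folds=5, repeats=5, seed=0)

print("alpha  correct-rate(%)")
for a, m, s in zip(res.grid[::5], res.correct_rate_mean[::5],
                   res.correct_rate_std[::5]):
    print(f"{a:4.1f}   {m:6.2f} +/- {s:.2f}")
print(f"\nbest alpha = {res.best_alpha:.1f} "
      f"(mean correct rate {res.correct_rate_mean.max():.2f}%)")
# Ties in the curve resolve toward the smaller alpha. On strongly
# separable synthetic data the curve is flat near 100% at small alpha and
# degrades for large alpha, where the entropy saturates.
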