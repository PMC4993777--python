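"""Dual-channel valuation of a partially rewarded cue.

Trains the critic on a single stimulus rewarded with probability lambda at
unit magnitude and prints the converged magnitude valuation, omission
valuation, and optimistic expectancy E1 against the closed-form product
valuation Q = lambda * R.  The magnitude channel should approach R regardless
of lambda (it never unlearns), the omission channel should approach 1 - lambda,
and E1 = R - (1 - lambda) should coincide with Q at R = 1.
"""

import numpy as np

from affatp import (
    CriticParams,
    CriticState,
    compute_expectancies,
    product_valuation,
    run_conditioning_trial,
)
from affatp.schedules import TrialTiming

timing = TrialTiming()
params = CriticParams()

print("lambda   v_mag   v_om     E1      Q=lam*R   label")
for lam in (0.25, 0.5, 0.75, 1.0):
    e1s, voms, mags, labels = [], [], [], []
    for seed in range(3):
        rng = np.random.default_rng(seed)
        state = CriticState(stimuli=("S1",), n_taps=timing.n_steps)
        for i in range(500):
            reward = 1.0 if rng.random() < lam else 0.0
            run_conditioning_trial(state, params, "S1", reward, timing)
            if i >= 400:  # average the converged tail
                exp = compute_expectancies(state, params, "S1")
                e1s.append(exp.E1)
                voms.append(exp.v_om_out)
                mags.append(exp.v_mag_out)
                labels.append(exp.label)
    label = max(set(labels), key=labels.count)  # modal affective judgment
    print(
        f"{lam:5.2f}   {np.mean(mags):5.3f}  {np.mean(voms):5.3f}   "
        f"{np.mean(e1s):5.3f}   {product_valuation(lam, 1.0):5.3f}     {label}"
    )
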