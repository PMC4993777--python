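"""Social transfer of control: extended common currency vs. a dedicated
social value circuit.

The pavlovian pairing phase is *observed on another agent* rather than
self-experienced.  Under the extended-common-currency wiring
(SOCIAL_AFF_ATP) the observed stimulus-outcome events are valued by the same
circuit that drives the agent's own expectancy-response associations, so the
transfer test succeeds just as in the individual protocol.  Under the
social-valuation-specific wiring (SVS_ATP) the observed events build a
separate social value function whose sE1/sE2 outputs have no response
associations, so transfer stays at chance — vicarious knowledge exists but
cannot reach the response system.
"""

import numpy as np

from affatp import run_social_toc
from affatp.schedules import build_toc_protocol, default_toc_config

accs = {}
for variant in ("social_aff_atp", "svs_atp"):
    accs[variant] = []
    for seed in range(10):
        protocol = build_toc_protocol(default_toc_config(social=True, seed=seed))
        result = run_social_toc(variant, protocol, seed=seed)
        accs[variant].append(result.metrics["transfer_accuracy"])
    print(
        f"{variant:16s} social transfer accuracy: "
        f"median {np.median(accs[variant]):.2f} over 10 seeds"
    )
gap = np.median(accs["social_aff_atp"]) - np.median(accs["svs_atp"])
print(f"median accuracy gap (ECC - SVS): {gap:.2f}  (dissociation if > 0.2)")
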