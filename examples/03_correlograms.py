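"""Spike-based vs rate-based cross-correlograms and their difference.

The CCG counts target spikes in lagged windows after reference spikes; the
ECCG predicts the same quantity from the latent model's rate estimate.  Both
carry the slow shared dynamics, so their difference (DCCG) isolates the
transient pairwise effect: it is elevated at short lags for a coupled pair
and flat for an uncoupled one.
"""

import numpy as np

from dona import (
    Coupling,
    SessionConfig,
    bin_spikes,
    compute_ccg,
    compute_dccg,
    compute_eccg,
    estimate_sna,
    fit_edlds,
    generate_session,
)
from dona.edlds import FitConfig

session, truth = generate_session(
    SessionConfig(
        n_neurons=6,
        n_trials=80,
        n_latent=2,
        couplings=(Coupling(ref=0, target=3, gain=2.0),),
    ),
    seed=2,
)
counts = bin_spikes(session)
params = fit_edlds(counts, n_latent=2, config=FitConfig(max_iter=40))
sna = estimate_sna(params, counts)

ccg = compute_ccg(session, tau=0.025, n_lags=5)
eccg = compute_eccg(sna, session, tau=0.025, n_lags=5)
dccg = compute_dccg(ccg, eccg)

lags_ms = dccg.lag_seconds() * 1e3
print("lags (ms):            ", np.round(lags_ms).astype(int))
print("DCCG coupled 0->3 (Hz):", np.round(dccg.values[0, 3], 2))
print("DCCG uncoupled 1->2   :", np.round(dccg.values[1, 2], 2))
# The coupled pair shows a clear positive DCCG at lag +1 (the 25 ms window
# right after the reference spike) that decays to ~0 within a few lags; the
# uncoupled pair fluctuates around zero everywhere.
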