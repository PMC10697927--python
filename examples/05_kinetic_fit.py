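"""Reversible two-tissue-compartment fit of a brain region TAC.

Simulates a cortex-like tissue curve from the phantom's true LV plasma
input with known micro-parameters, adds 2% noise, refits, and reports the
recovered rates, the total volume of distribution V_T = K1/k2 (1 + k3/k4)
and the frame-duration-weighted fit error (wsMAPE).
"""

import numpy as np

from nmfidif import Tac, TcmParams, fit_2tcm, simulate_2tcm, vt
from nmfidif.io import frame_mid_times
from nmfidif.phantom import _DEFAULT_TACS, default_framing, make_region_tac

framing = default_framing()
mids = frame_mid_times(framing)
plasma = Tac(mids, framing[:, 1], make_region_tac(_DEFAULT_TACS["LV"], mids))

true_params = TcmParams(K1=0.60, k2=0.25, k3=0.10, k4=0.015)
clean = simulate_2tcm(plasma, true_params, mids)
rng = np.random.default_rng(0)
tissue = plasma.with_values(np.clip(clean + 0.02 * clean.max() * rng.standard_normal(len(mids)), 0, None))

fit = fit_2tcm(tissue, plasma, seed=0)
print(f"{'':>10} {'true':>8} {'fitted':>8}")
for name in ("K1", "k2", "k3", "k4"):
    print(f"{name:>10} {getattr(true_params, name):>8.4f} {getattr(fit.params, name):>8.4f}")
print(f"{'V_T':>10} {vt(true_params):>8.2f} {fit.V_T:>8.2f}  mL/cm^3")
print(f"wsMAPE: {fit.wsmape_pct:.2f} %   converged: {fit.converged}")

# V_T is the macro-parameter of interest; individual micro-parameters are
# less identifiable from a 60-minute scan, but their V_T combination is
# recovered to within a few percent at this noise level.
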