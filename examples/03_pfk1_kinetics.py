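"""Allosteric PFK1 enzymology: Hill saturation, activator EC50, NETosis IC50.

Generates noisy titrations from reference parameters for liver-type
phosphofructokinase-1 (PFKL) and refits them: the cooperative F6P
saturation curve, relief of ATP inhibition by a small-molecule
activator, and the cellular dose-response of NETosis inhibition.
"""

import numpy as np

from thermotarget import fit_activation, fit_hill, fit_ic50, simulate_kinetics

# --- F6P saturation (Hill): vmax 13.28 umol/min/mg, K_M 1.97 mM, h 3.16
df = simulate_kinetics(
    "hill",
    dict(vmax=13.28, k_half=1.97, h=3.16),
    dict(x=list(np.geomspace(0.25, 8, 8)), n_replicates=3, noise_cv=0.05),
    seed=1,
)
h = fit_hill(df["conc"], df["response"])
print(
    f"F6P saturation: Vmax={h.vmax:.2f} umol/min/mg, "
    f"K_M={h.k_half:.2f} mM, h={h.hill_h:.2f} (truth 13.28 / 1.97 / 3.16)"
)

# --- activator EC50 under inhibitory ATP (floor = 15% of ceiling)
df = simulate_kinetics(
    "activation",
    dict(floor=1.8, ceiling=12.0, ec50=14.0, h=1.0),
    dict(x=[0.0] + list(np.geomspace(1, 1000, 10)), n_replicates=3, noise_cv=0.05),
    seed=2,
)
a = fit_activation(df["conc"], df["response"])
print(
    f"Activation: EC50={a.ec50:.1f} nM (truth 14.0), "
    f"ATP inhibition depth at zero activator = "
    f"{100 * a.fractional_inhibition_at_zero:.0f}%"
)

# --- cellular NETosis dose-response (spontaneous 7%, stimulated 75%)
df = simulate_kinetics(
    "dose_response",
    dict(floor=7.0, ceiling=75.0, ic50=4.0, h=1.0),
    dict(x=[0.0] + list(np.geomspace(0.1, 1000, 8)), n_replicates=3, noise_cv=0.05),
    seed=3,
)
d = fit_ic50(df["conc"], df["response"])
print(
    f"NETosis inhibition: IC50={d.ic50:.2f} nM (truth 4.0), "
    f"floor={d.floor:.1f}% ceiling={d.ceiling:.1f}%"
)
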