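"""Simulate the in-vitro factorial design and recover its parameters.

Draws one synthetic replicate dataset (3 % replicate noise) from the
packaged 100-us truth, fits the sigmoid per pulse-count stratum, refits the
double-exponential E_c(n), and prints recovered vs. generating values.
"""

import warnings

from irepf import (
    ExperimentDesign,
    eval_double_exponential,
    fit_double_exponential,
    fit_peleg_fermi,
    pulse_count_family,
    simulate_viability,
)
from irepf.errors import IrepfError

warnings.simplefilter("ignore")

truth = pulse_count_family(100.0)
design = ExperimentDesign(pulse_lengths_us=(100.0,))
obs = simulate_viability(design, truth, noise_sd=3.0, seed=42)

groups = {}
for o in obs:
    groups.setdefault(o.pulse_count, []).append(o)

print("Per-protocol sigmoid fits (kV/cm):")
ec_hat = {}
for n, group in sorted(groups.items()):
    p_true = truth.params_at(n)
    try:
        fit = fit_peleg_fermi(group)
    except IrepfError as exc:
        print(f"  n={n:2d}: not identifiable ({exc})")
        continue
    ec_hat[n] = fit.params.ec
    print(
        f"  n={n:2d}: Ec {fit.params.ec:6.3f} (truth {p_true.ec:6.3f})  "
        f"A {fit.params.a_steep:6.3f} (truth {p_true.a_steep:6.3f})  "
        f"R^2 {fit.r_squared:.4f}"
    )

if len(ec_hat) >= 4:
    ns = sorted(ec_hat)
    refit = fit_double_exponential(ns, [ec_hat[n] for n in ns])
    print(f"\nDouble-exponential refit of Ec(n): R^2 = {refit.r_squared:.4f}")
    for n in (30, 60, 90):
        print(
            f"  Ec({n}) refit {eval_double_exponential(n, refit.params):.3f} "
            f"vs truth {eval_double_exponential(n, truth.ec_fn):.3f} kV/cm"
        )

print(
    "\nStrata whose field grid brackets Ec recover it to ~1 %; the one-pulse"
    "\nstratum (Ec ~ 7.8 kV/cm, far above the 4.5 kV/cm maximum field) is an"
    "\nextrapolation and correspondingly unreliable."
)
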