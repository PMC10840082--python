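"""Why the conventional per-component meta-analysis overstates effects.

Two truly active components are made to co-occur in most intervention
arms. The conventional approach — one DerSimonian-Laird random-effects
pool per component of the experimental-vs-control mean differences, with
no adjustment for the other components — attributes the *joint* effect to
each component. The response-surface model fits all components at once and
recovers the individual associations.
"""

import rsmeta as rs
from rsmeta.dataio import select_extreme_arms

truth = {"comp1": -0.5, "comp2": -0.3}
cfg = rs.SimConfig(
    n_studies=150, m=3, beta=(-0.5, -0.3, 0.0), tau=0.1, tau0=0.3,
    component_prevalence=(0.55, 0.35, 0.3),
    co_occur={("comp1", "comp2"): 0.85, ("comp2", "comp1"): 0.85},
    control_arm_prob=1.0, seed=314,
)
ds, _ = rs.simulate_dataset(cfg)
extreme = select_extreme_arms(ds)

draws = rs.fit_base_model(
    ds, rs.ModelConfig(chains=2, burnin=1000, iterations=2500, seed=2),
    store_study=False,
)
summ = rs.summarize_posterior(draws)

print(f"{'component':<10}{'truth':>8}{'conventional':>16}{'response surface':>22}")
for comp, true_val in truth.items():
    conv = rs.fit_conventional_pairwise(extreme, comp)
    row = summ.loc[f"beta[{comp}]"]
    print(
        f"{comp:<10}{true_val:>8.2f}"
        f"{conv.estimate:>10.2f} ({conv.ci_low:.2f},{conv.ci_high:.2f})"
        f"{row['median']:>10.2f} ({row['lo2.5']:.2f},{row['hi97.5']:.2f})"
    )
print(
    "\nThe conventional pooled mean differences exceed the true component\n"
    "effects in magnitude (each absorbs its co-occurring partner), while the\n"
    "response-surface CrIs cover the truth."
)
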