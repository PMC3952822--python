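"""Simulated labelled-ApoA-I tracer study.

Introduces a trace dose into the lipid-poor pool at steady state and follows
the fraction of the dose remaining in plasma, comparing the complex-step
(sensitivity) curve with the classical frozen-coefficient radiolabel.
"""

import rctsim

model = rctsim.RctModel()
params = rctsim.load_fixtures("posterior_nominal")
steady = model.steady_state(params)

sens = rctsim.simulate_tracer(model, params, steady=steady)
label = rctsim.simulate_tracer(model, params, mode="label", horizon=60.0,
                               n_points=301, steady=steady)

print("Labelled-ApoA-I tracer at the nominal-subject steady state")
print("  day   fraction remaining (complex-step)")
for day in (0, 1, 2, 4, 7, 14, 21, 28):
    i = int(day / 28.0 * (len(sens.times) - 1))
    print(f"  {sens.times[i]:4.0f}   {sens.fraction_remaining[i]:.3f}")
print(f"\n  complex-step MRT  {sens.mrt:.2f} days  (FCR {sens.fcr:.3f} pool/day)")
print(f"  radiolabel MRT    {label.mrt:.2f} days  "
      f"(= total ApoA-I / synthesis rate)")
print()
print("The decay is biphasic: a fast early phase while the dose redistributes")
print("between the lipid-poor and alpha-HDL pools, then a slow terminal phase")
print("set by holo-particle uptake. The two MRT variants differ by the")
print("model's size-feedback contribution, discussed in docs/methods.md.")
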