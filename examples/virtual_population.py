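"""Virtual population: biomarker correlations and a treatment simulation.

Draws 2000 virtual subjects (15% uncorrelated parameter variation), simulates
their steady-state phenotypes, and treats the low-HDL-C subgroup with a
hypothetical CETP inhibitor.
"""

import numpy as np

import rctsim

spec = rctsim.PopulationSpec(n_subjects=2000, relative_sd=0.15, seed=1)
table = rctsim.simulate_population(rctsim.sample_population(spec))
ok = table.dropna(subset=["hdl_c"])

r_rct = np.corrcoef(ok["rct_rate"], ok["hdl_c"])[0, 1]
r_clr = np.corrcoef(ok["hdl_ce_clearance"], ok["hdl_c"])[0, 1]
print(f"n = {len(ok)} virtual subjects")
print(f"  r(RCT rate, HDL-C)          = {r_rct:+.3f}")
print(f"  r(HDL-CE clearance, HDL-C)  = {r_clr:+.3f}")
print("HDL-C variation in the population tracks the RCT rate, not clearance —")
print("a mechanistic reading of the epidemiological HDL-C/risk association.\n")

treated = rctsim.treat_subpopulation(
    table, rctsim.InterventionSpec("cetp_scale", 0.2, hdl_c_max=40.0))
d_hdl = (treated["treated_hdl_c"] - treated["hdl_c"]).mean()
d_ldl = 100.0 * (treated["treated_ldl_c"] / treated["ldl_c"] - 1.0).mean()
d_rct = 100.0 * (treated["treated_rct_rate"] / treated["rct_rate"] - 1.0).mean()
print(f"80% CETP inhibition in the {len(treated)} subjects with HDL-C <= 40:")
print(f"  HDL-C  {d_hdl:+.1f} mg/dL on average")
print(f"  LDL-C  {d_ldl:+.1f}%")
print(f"  RCT    {d_rct:+.1f}%")
print("HDL-C rises sharply but cholesterol efflux is unchanged; the modest")
print("LDL-C drop is the only mechanistic benefit the model predicts.")

rep = rctsim.biomarker_analysis(table)
print(f"\nABCA1-activity biomarkers: r(ABCA1, lipid-poor ApoA-I) = "
      f"{rep['r_abca1_lipid_poor']:+.2f}, "
      f"r(ABCA1, % lipid-poor) = {rep['r_abca1_frac_lipid_poor']:+.2f}")
print("The percentage, not the absolute concentration, is the usable readout.")
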