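"""Forward-simulate one volume-controlled breath and its safety outcomes.

A 65 kg patient with stiff lungs (E_rs 43.5 cmH2O/L, R_rs 26.2 cmH2O.s/L,
PEEP 13 cmH2O) ventilated with a square flow profile: 4 mL/kg tidal volume
at 30 L/min peak flow, 0.5 s plateau, 20 breaths/min.
"""

from sivent import RespiratoryMechanics, VCSettings, build_vc_profile, compute_outcomes, simulate_pressure

mech = RespiratoryMechanics(E_rs=43.5, R_rs=26.2, PEEP=13.0)
settings = VCSettings(RR=20, VT_perkg=4, peak_flow=30, T_plat=0.5, waveform="square")

wf = simulate_pressure(mech, build_vc_profile(settings, weight=65.0))
out = compute_outcomes(mech, settings, weight=65.0)

print(f"inspiration: {out.T_insp:.2f} s flow+plateau, expiration {out.T_exp:.2f} s "
      f"(I:E = 1:{out.IE_denom:.2f})")
print(f"peak pressure P_MAX   = {out.P_MAX:.2f} cmH2O  (sampled max {wf.pressure.max():.2f})")
print(f"plateau pressure      = {out.P_PLAT:.2f} cmH2O")
print(f"driving pressure dP   = {out.dP:.2f} cmH2O  (= E_rs * V_T)")
# P_MAX/P_PLAT against the clinical limits (40 / 30 cmH2O) decide whether
# this combination would survive the protocol's elimination stage.
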