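"""The pharmacokinetic relations on bulk numbers, without any imaging.

Shows the two equivalent routes to Kp,uu — the combinatory mapping
approach (Kp / (Vu · fu,plasma)) and the in vivo / in vitro concentration
ratio — plus the buffer-film correction used when the adherent aECF layer
is not removed before slice measurement.
"""

import kpuumap as km

# brain-slice assay: slice content and final buffer concentration
a_slice, c_buffer = 500.0, 50.0          # ng/g and ng/mL
v_u_film = km.v_u_brain_from_amount(a_slice, c_buffer)   # film-corrected
v_u = km.v_u_brain_from_conc(a_slice, c_buffer)          # film removed
print(f"Vu,brain = {v_u_film:.4f} mL/g (film-corrected, Vi = "
      f"{km.V_I_DEFAULT}) vs {v_u:.2f} mL/g (plain ratio)")

# in vivo study: total brain and plasma levels, plasma free fraction
# (the buffer was dosed to match the unbound plasma level: 50 ng/mL)
c_tot_brain, c_tot_plasma, f_u = 250.0, 500.0, 0.10
k_p = km.kp_total(c_tot_brain, c_tot_plasma)
kpuu_via_cma = km.kpuu_cma(k_p, v_u, f_u)
print(f"Kp = {k_p:.3f};  Kp,uu via CMA = {kpuu_via_cma:.3f}")

# same quantity as the imaging ratio (buffer matched to unbound plasma)
c_slice_total = v_u * c_buffer
cf = km.correction_factor(c_buffer, f_u * c_tot_plasma)
kpuu_via_ratio = km.kpuu_ratio(c_tot_brain, c_slice_total, cf)
print(f"Kp,uu via in vivo/in vitro ratio (CF = {cf:.2f}) = "
      f"{kpuu_via_ratio:.3f}")
print(f"transport class: {km.classify_transport(kpuu_via_ratio)}")
print(f"unbound ISF concentration = "
      f"{km.unbound_isf_conc(c_tot_brain, v_u):.1f} ng/mL")
print("\nBoth routes give the same Kp,uu for consistent inputs; values "
      "well below 1 indicate net efflux at the BBB.")
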