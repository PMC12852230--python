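# Default healing-kinetics parameters (calibrated; see docs/methods.md).
# Units: rates 1/day, diffusivities mm^2/day, speeds mm/day; fields are
# dimensionless, normalized to the healthy-tissue baseline of 1.

# fibroblast diffusivity
d_rho_phi = 1.0    # day; scales collagen-dependent motility
v_max = 3.0        # mm/day; peak crawling speed
K_v = 1.0          # collagen level of peak motility
d_rho_c = 1.2      # mm^2/day; chemokinetic ceiling
K_rho_c = 0.5      # cytokine saturation (shared with source term)
d_rho_0 = 0.05     # mm^2/day; baseline motility

# cytokine diffusivity
D_c = 1.2          # mm^2/day

# fibroblast source
p_rho = 0.6        # 1/day; baseline proliferation
p_rho_c = 1.0      # 1/day; cytokine-boosted proliferation
p_rho_e = 0.12     # 1/day; mechanosensing-gated proliferation
K_rho_rho = 1.25   # carrying capacity
d_rho = 0.12       # 1/day; apoptosis (homeostasis at rho = 1, c = 0)

# cytokine source
p_c_rho = 0.06     # 1/day; autocrine production
p_c_e = 0.05       # 1/day; mechanosensing-gated production
K_c_c = 0.5        # saturation
d_c = 0.3         # 1/day; clearance

# collagen
p_phi = 0.12       # 1/day; baseline deposition
p_phi_c = 0.1      # 1/day; cytokine-boosted deposition
K_phi_c = 0.3      # cytokine saturation
p_phi_e = 0.1      # 1/day; mechanosensing-gated deposition
K_phi_rho = 2.5    # deposition crowding constant
d_phi = 0.0343       # 1/day; baseline degradation (homeostasis at phi = 1)
d_phi_c = 0.3     # 1/day; inflammation-enhanced degradation

# plastic stretch (dead-zone remodeling law)
tau_lambda_p = 0.35        # relaxation scale dividing phi_dot_plus
delta_crit = 0.05          # lambda_crit_± = 1 ± delta_crit
one_sided_plasticity = false

# fiber reorientation / dispersion
tau_omega = 10.0
tau_kappa = 4.0
gamma_kappa = 2.0

phi_plus_is_production = true
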