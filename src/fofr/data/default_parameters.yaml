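# Calibrated default cell parameters (nM, s); see docs/methods.md
kon_L: 0.01
koff_L: 0.01
koff_LG: 0.001
kon_g_r: 0.0001
kon_g_lr: 0.001
koff_g: 0.3
DE: 0.0211
kact: 0.0364
kact0: 2.0e-05
khyd: 0.066
krea: 0.01
kon_ac: 0.001
koff_ac: 1.0
khyd_ac: 0.066
kon_atp: 1.0e-05
koff_atp: 10.0
kcat_ac: 10.0
kon_atp_b: 1.0e-07
koff_atp_b: 10.0
kcat_ac_b: 0.0366
kon_pde: 0.005
koff_pde: 5.0
kcat_pde: 0.5
kcat_pdep: 4.37
kon_kpde: 0.00122
koff_kpde: 0.1
kcat_kpde: 0.5
kdeph_pde: 0.002
k_amp: 0.02
kon_pka: 0.001
koff_pka1: 0.6
koff_pka2: 0.4
koff_pka3: 0.2
koff_pka4: 0.1
krel1: 1.0
krb1: 0.001
krel2: 0.5
krb2: 0.001
kreln: 0.2
kasm: 0.001
kasm2: 0.001
kdis0: 1.0e-05
kon_pki: 0.01
koff_pki: 0.01
kin_n: 0.002
kout_n: 0.01
kon_grk: 0.001
koff_grk: 0.1
k_61: 0.2
k_62: 0.0166
kon_grkr: 0.001
koff_grkr: 0.1
k_63: 1.14
k_64: 0.0001
k_42: 0.005
k_deph_int: 0.01
k_70: 0.000531
k_71: 1.0e-08
kon_creb: 0.001
koff_creb: 0.1
kcat_creb: 0.1
k_crebd: 0.001
g_CNG0: 1.0
K_CNG: 77.0
n_CNG: 3.0
per_independent_fraction: 0.0
K_per: 12.0
n_per: 2.0
I_threshold: 0.078
I_sat: 0.377
F_max: 10.0
VIP_0: 0.05
k_L: 0.005
k_sec: 0.0031
atp_clamped: 1.0
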