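# Circadian clock basal parameter regime (nM, h) and CREB coupling
k1: 0.4
k2: 0.2
k3: 0.4
k4: 0.2
k5: 0.4
k6: 0.2
k7: 0.5
k8: 0.1
KAP: 0.7
KAC: 0.6
KIB: 2.2
kdmb: 0.01
kdmc: 0.01
kdmp: 0.01
kdn: 0.01
kdnc: 0.12
Kd: 0.3
Kdp: 0.1
Kp: 0.1
KmB: 0.4
KmC: 0.4
KmP: 0.31
ksB: 0.12
ksC: 1.6
ksP: 0.6
m: 2.0
n: 4.0
V1B: 0.5
V1C: 0.6
V1P: 0.4
V1PC: 0.4
V2B: 0.1
V2C: 0.1
V2P: 0.3
V2PC: 0.1
V3B: 0.5
V3PC: 0.4
V4B: 0.2
V4PC: 0.1
vdBC: 0.5
vdBN: 0.6
vdCC: 0.7
vdIN: 0.8
vdPC: 0.7
vdPCC: 0.7
vdPCN: 0.7
vmB: 0.8
vmC: 1.0
vmP: 1.1
vsB: 1.0
vsC: 1.1
vsP: 1.5
v_creb: 0.8
K_pkan: 0.6
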