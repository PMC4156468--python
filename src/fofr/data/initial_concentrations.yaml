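# Canonical initial concentrations (nM) of a resting cell; species not
# listed start at zero and fill during the relaxation transient
R: 250.0
RGs: 50.0
Gs: 950.0
Gbg: 10.0
AC: 100.0
ATP: 2000000.0
cAMP: 30.0
PDE: 200.0
R2C2: 395.0
R2C: 10.0
PKI: 50.0
GRK: 150.0
CREB: 100.0
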