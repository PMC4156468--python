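# Bath VIP step: 30 min at 1 uM, then 1 h washout (autocrine release off)
segments:
- {duration: 1800, vip_clamp: 1000.0, secretion_on: false}
- {duration: 3600, vip_clamp: 0.0, secretion_on: false}
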