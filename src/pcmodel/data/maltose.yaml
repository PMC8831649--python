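name: maltose
transporter_capacity: 3.5
carbon_ngam: 0.0
min_up_fraction: 0.34
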