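name: galactose
transporter_capacity: 3.0
carbon_ngam: 3.0
min_up_fraction: 0.49
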