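name: glucose
transporter_capacity: 7.5
carbon_ngam: 0.0
min_up_fraction: 0.245
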