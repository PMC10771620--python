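# Resting-length expansin action across pre-plateau strain rates.
# Compare against the same sweep with E = 0 to see the resultant drop
# while the hotspot density rises (loosening without weakening).
[params]
E = 5.0
enzyme_mode = "expansin_rest_length"
a1 = 0.1

[scenario]
name = "expansin_rest"
sweep = "alpha"
start = 0.3
stop = 10.0
num = 15
spacing = "log"
outputs = ["Sigma_steady"]
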