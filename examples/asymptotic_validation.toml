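# Error of the reduced steady resultant against full quadrature
# across the strain-rate range (enzyme off).
[params]
beta_hot = 0.01
gamma = 0.05

[scenario]
name = "asymptotic_check"
sweep = "alpha"
start = 1.0
stop = 100.0
num = 13
spacing = "log"
outputs = ["asymptotic_comparison"]
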