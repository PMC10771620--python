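# Hotspot-targeting hydrolysis (Cel12A-style): raising beta_hot collapses
# the hotspot density far earlier in the wall.  Rerun with gamma raised
# instead (XTH-style) to see the much smaller shift.
[params]
alpha = 10.0
beta_hot = 0.5
gamma = 0.05

[scenario]
name = "hotspot_cutting"
sweep = "y"
start = 0.001
stop = 0.99
num = 120
spacing = "log"
outputs = ["n_hot_profile"]
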