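# Transient resultant while the initially present material thins away;
# the wall reaches its steady state once exp(-alpha t) falls below the
# outer cut-off.
[params]
alpha = 20.0

[scenario]
name = "transient"
sweep = "t"
start = 0.005
stop = 0.7
num = 60
spacing = "linear"
outputs = ["Sigma_time"]
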