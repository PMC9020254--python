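[slab]
ne = 1.0

[[slab.layer]]
s = 2.5
n = 1.2
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 2.5
n = 1.4
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 2.5
n = 1.6
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 2.5
n = 1.8
mus = 1.0
phase = "hg"
g = 0.0
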