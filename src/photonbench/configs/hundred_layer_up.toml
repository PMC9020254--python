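[slab]
ne = 1.0

[[slab.layer]]
s = 0.1
n = 1.01
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.02
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.03
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.04
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.05
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.06
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.07
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.08
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.09
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.1
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.11
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.12
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.13
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.1400000000000001
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.15
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.16
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.17
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.18
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.19
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.2
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.21
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.22
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.23
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.24
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.25
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.26
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.27
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.28
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.29
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.3
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.31
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.32
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.33
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.34
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.35
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.3599999999999999
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.37
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.38
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.3900000000000001
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.4
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.41
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.42
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.43
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.44
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.45
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.46
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.47
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.48
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.49
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.5
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.51
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.52
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.53
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.54
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.55
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.56
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.5699999999999998
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.58
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.5899999999999999
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.6
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.6099999999999999
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.62
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.63
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.6400000000000001
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.65
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.6600000000000001
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.67
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.6800000000000002
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.69
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.7
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.71
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.72
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.73
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.74
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.75
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.76
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.77
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.78
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.79
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.8
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.81
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.8199999999999998
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.83
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.8399999999999999
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.85
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.8599999999999999
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.87
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.88
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.8900000000000001
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.9
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.9100000000000001
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.92
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.9300000000000002
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.94
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.95
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.96
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.97
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.98
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 1.99
mus = 1.0
phase = "hg"
g = 0.0

[[slab.layer]]
s = 0.1
n = 2.0
mus = 1.0
phase = "hg"
g = 0.0
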