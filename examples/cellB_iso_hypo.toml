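[medium]
na_o = 140.0
k_o = 5.8
cl_o = 116.0
b_o = 48.2

[cell]
na_i = 38.0
k_i = 147.0
cl_i = 45.0
v = 1.0
a_over_v = 80.0
z = -1.75

[params]
beta = 0.039
gamma = 1.5
ikc = 8e-05
inc = 7e-05
inkcc = 8e-09
p_cl = 0.011
p_k = 0.0115
p_na = 0.0017

[closure]
U = -45.0

[protocol]
duration = 120.0
out_dt = 1.0
hp = 1

[[protocol.events]]
time = 0.0
action = "set_medium"
value = { na_o = 65.0, k_o = 5.8, cl_o = 41.0, b_o = 48.2 }
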