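[medium]
na_o = 140.0
k_o = 5.8
cl_o = 116.0
b_o = 48.2

[cell]
na_i = 35.0
k_i = 156.0
cl_i = 70.0
v = 1.0
a_over_v = 49.0
z = -2.4693877551020407

[params]
beta = 0.039
gamma = 1.5
ikc = 3e-05
inc = 7e-05
inkcc = 8e-09
p_cl = 0.004
p_k = 0.01
p_na = 0.0019

[closure]
U = -45.2

[protocol]
duration = 240.0
out_dt = 1.0
hp = 1

[[protocol.events]]
time = 0.0
action = "set_beta"
value = 0.0
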