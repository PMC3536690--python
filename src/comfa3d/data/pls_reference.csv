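id,pic50,comfa,pre_pic50,residual
D1,0.0810,140,0.089,-0.008
D2,-0.1340,142,0.052,-0.186
D3,-0.3400,146,0.035,-0.375
D4,0.4700,146,0.194,0.276
D5,1.1500,146,1.196,-0.046
D6,0.5230,140,0.244,0.279
D7,-0.4900,156,-0.476,-0.014
D8,-0.7200,134,-0.828,0.108
D9,-0.5900,138,-0.597,0.007
D10,-0.6200,138,-0.597,-0.023
D11,-0.8000,134,-0.805,0.005
D12,-0.8000,136,-0.842,0.042
D13,-0.8400,140,-0.856,0.016
D14,-0.8700,142,-0.691,-0.179
D15,-0.7600,142,-0.605,-0.155
D16,-0.7200,136,-0.648,-0.072
D17,-0.8900,142,-0.848,-0.042
D18,-0.8200,136,-1.412,0.892
D19,-0.8600,136,-0.771,-0.089
D20,-0.8100,138,-0.679,-0.131
D21,-0.9500,136,-1.127,0.177
D22,-0.9100,138,-1.164,0.254
D23,-1.0000,142,-1.178,0.178
D24,-0.9400,144,-1.013,0.073
D25,-0.9100,144,-0.968,0.058
D26,-1.1000,138,-0.972,0.128
D27,-1.0300,144,-1.170,0.14
D28,-2.5300,138,-1.735,-0.795
D29,-1.135,138,-1.1000,-0.035
D30,-1.042,140,-1.0400,-0.002
F1,-1.2600,134,-1.384,-0.124
F2,-1.2100,134,-1.480,-0.27
F3,-1.2700,138,-1.514,-0.244
F4,-1.2800,144,-1.342,-0.062
F5,-1.2000,146,-0.814,0.386
F6,-1.3800,134,-1.440,-0.06
F7,-1.4600,132,-1.602,-0.142
F8,-1.4100,156,-0.918,0.492
F9,-1.2000,136,-0.811,0.389
F10,-1.3000,136,-0.906,0.494
F11,-1.3100,140,-0.944,0.366
F12,-1.2400,146,-0.780,0.46
F13,-1.1800,148,-0.247,0.933
F14,-1.3300,136,-0.851,0.479
F15,-1.3000,134,-1.028,0.272
F16,-1.2400,158,-0.346,0.894
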