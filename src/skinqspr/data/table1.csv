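skin_source,skin_layer,donor_concentration,temperature_bin,n,r_squared,intercept,coef_logp,coef_tpsa,coef_mv
breast,epidermis,diluted,36-40,9,0.9839,-2.869,-0.406,-0.143,0.021
breast,epidermis+dermis,concentrated,36-40,6,0.8321,-3.083,-0.728,-0.168,0.043
breast,epidermis+dermis,diluted,20-25,4,0.9703,-4.993,-0.808,-0.168,0.033
breast,epidermis+dermis,diluted,31-35,20,0.5464,-4.406,-0.514,-0.004,-0.006
breast,epidermis+dermis,diluted,36-40,5,0.8747,-6.297,-3.151,-0.424,0.128
abdomen,epidermis,concentrated,20-25,10,0.9595,-5.203,7.125,0.525,-0.236
abdomen,epidermis,concentrated,26-30,8,0.9772,-6.875,1.410,0.206,-0.059
abdomen,epidermis,diluted,20-25,36,0.8545,-6.052,0.777,-0.004,-0.008
abdomen,epidermis,diluted,26-30,2,,-6.477,1.467,0.220,-0.051
abdomen,epidermis,diluted,31-35,36,0.7102,-5.788,0.099,-0.028,0.008
abdomen,epidermis,diluted,36-40,43,0.1619,-6.231,0.211,-0.006,-0.001
abdomen,dermis,concentrated,20-25,8,0.9737,-6.277,1.778,0.226,-0.077
abdomen,dermis,diluted,20-25,16,0.8334,-4.584,0.931,0.019,-0.020
abdomen,dermis,diluted,31-35,6,0.9393,-1.784,2.499,0.040,-0.081
abdomen,epidermis+dermis,concentrated,26-30,4,0.5268,-7.599,-1.743,-0.113,0.045
abdomen,epidermis+dermis,diluted,20-25,4,0.9916,-2.586,2.453,-0.082,-0.053
abdomen,epidermis+dermis,diluted,26-30,8,0.8166,-5.361,0.400,-0.025,-0.001
abdomen,epidermis+dermis,diluted,31-35,45,0.1422,-6.129,0.193,0.004,-0.006
abdomen,epidermis+dermis,diluted,36-40,14,0.9734,-6.960,0.975,-0.004,-0.005
abdomen,stratum_corneum,diluted,26-30,3,1,-5.695,-1.147,-0.137,0.047
abdomen,stratum_corneum,diluted,31-35,3,1,-6.009,-0.043,-0.036,0.008
thigh,epidermis,diluted,31-35,3,1,-13.211,-1.366,0.031,0.031
thigh,epidermis,diluted,36-40,3,1,-11.084,-1.472,-0.144,0.043
thigh,epidermis+dermis,diluted,20-25,5,0.9344,2.734,3.503,0.007,-0.088
thigh,epidermis+dermis,diluted,26-30,17,0.6139,-6.826,0.656,0.006,-0.006
thigh,epidermis+dermis,diluted,31-35,3,1,-4.001,0.309,-0.085,0.031
thigh,epidermis+dermis,diluted,36-40,21,0.3329,-6.876,0.566,-0.002,-0.002
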