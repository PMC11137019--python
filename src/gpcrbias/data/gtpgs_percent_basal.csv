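drug,subunit,arm,genotype,mean,sem,n,n_alt,printed_p,printed_between_p
Nitro-I,Gi1,drug,human,114.9,3.5,6,,0.008,
Nitro-I,Gi1,drug+antagonist,human,100.0,1.8,6,5,ns,0.006
Nitro-I,Gi2,drug,human,99.2,4.8,6,,ns,
Nitro-I,Gi2,drug+antagonist,human,101.5,3.2,6,,ns,ns
Nitro-I,Gi3,drug,human,123.4,3.4,4,,0.006,
Nitro-I,Gi3,drug+antagonist,human,127.9,1.0,4,,<0.001,ns
Nitro-I,Gq/11,drug,human,141.3,2.9,4,,0.001,
Nitro-I,Gq/11,drug+antagonist,human,123.5,1.5,4,,0.001,0.004
Met-I,Gi1,drug,human,88.7,1.6,6,,0.001,
Met-I,Gi1,drug+antagonist,human,98.2,1.8,5,,ns,0.004
Met-I,Gi2,drug,human,99.5,1.4,5,,ns,
Met-I,Gi2,drug+antagonist,human,99.0,1.6,4,,ns,ns
Met-I,Gi3,drug,human,121.6,3.2,6,,0.001,
Met-I,Gi3,drug+antagonist,human,98.0,3.8,5,,ns,0.001
Met-I,Gq/11,drug,human,114.4,2.1,6,,0.001,
Met-I,Gq/11,drug+antagonist,human,97.2,2.7,5,,ns,0.001
OTV1,Gi1,drug,human,80.6,4.6,6,,0.008,
OTV1,Gi1,drug+antagonist,human,97.0,4.2,5,,ns,0.027
OTV1,Gi2,drug,human,117.2,2.7,6,,0.001,
OTV1,Gi2,drug+antagonist,human,113.3,4.7,6,,0.036,ns
OTV1,Gi3,drug,human,114.7,2.8,4,,0.013,
OTV1,Gi3,drug+antagonist,human,100.3,4.6,4,,ns,0.044
OTV1,Gq/11,drug,human,117.6,2.3,4,,0.005,
OTV1,Gq/11,drug+antagonist,human,100.0,2.8,4,,ns,0.003
OTV2,Gi1,drug,human,105.9,0.5,6,,<0.0001,
OTV2,Gi1,drug+antagonist,human,95.0,3.2,6,,ns,0.018
OTV2,Gi2,drug,human,120.8,1.2,6,,<0.0001,
OTV2,Gi2,drug+antagonist,human,118.2,2.3,6,,0.001,ns
OTV2,Gi3,drug,human,124.9,4.1,4,,0.009,
OTV2,Gi3,drug+antagonist,human,95.7,7.8,4,,ns,0.024
OTV2,Gq/11,drug,human,141.7,2.6,4,,0.001,
OTV2,Gq/11,drug+antagonist,human,107.2,2.2,4,,0.045,<0.0001
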