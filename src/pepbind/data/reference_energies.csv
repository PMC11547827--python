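complex,e_ele,e_vdw,g_pb,g_nonp,g_bind_reported
TNFa-TNFR1,-33.51,-88.74,80.73,-9.28,-50.80
aCC8-TNFR1,-220.28,-39.82,230.90,-5.90,-35.10
L16R-TNFR1,-162.11,-45.50,174.56,-6.00,-39.03
L16H-TNFR1,-218.54,-40.05,231.22,-5.80,-33.17
L16K-TNFR1,-374.62,-43.31,388.43,-5.50,-35.00
L16D-TNFR1,-168.32,-34.33,181.74,-5.10,-26.01
L16E-TNFR1,-176.26,-36.65,191.16,-5.38,-27.13
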