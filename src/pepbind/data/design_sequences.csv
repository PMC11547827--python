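source,region,serial,sequence,role
R1,region1,1,ASENHLRHCL,design
R1,region1,2,FTASENH,design
R1,region1,3,GSFTASENHLR,design
R1,region1,4,ESGSFTASENHLRH,design
R1,region2,5,CRKEMGQV,design
R1,region2,6,SKCRKEMGQVEI,design
R1,region2,7,SKCRKEMGQVEISS,design
alpha,region1,8,TISRIAVSYQTKVNLLS,design
alpha,region2,9,THVLLTN,design
alpha,region2,10,THVLLTI,design
alpha,region2,11,THVLLTNI,design
R1,region3,0,HYWSENLFQ,external_control_gp
R1,region3,0,YCWSQYLCY,external_control_cc
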