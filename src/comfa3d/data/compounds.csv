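id,role,smiles,ic50_uM,pic50_reported
D1,train,NC(=S)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccc(F)cc2,0.88,0.0810
D2,train,NC(=S)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccc(Cl)cc2,1.87,-0.1340
D3,train,NC(=S)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccc(Br)cc2,2.39,-0.3400
D4,train,NC(=S)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccc(C)cc2,0.54,0.4700
D5,train,NC(=S)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccc(OC)cc2,0.09,1.1500
D6,train,NC(=S)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccc(O)cc2,0.19,0.5230
D7,train,NC(=S)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccc([N+](=O)[O-])cc2,3.09,-0.4900
D8,train,NC(=S)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccccc2F,5.28,-0.7200
D9,train,NC(=S)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccccc2Cl,3.99,-0.5900
D10,train,NC(=S)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccccc2Br,4.44,-0.6200
D11,train,NC(=S)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccc(F)cc2,6.64,-0.8000
D12,train,NC(=S)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccc(Cl)cc2,7.54,-0.8000
D13,train,NC(=S)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccc(Br)cc2,6.77,-0.8400
D14,train,NC(=S)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccc(C)cc2,7.68,-0.8700
D15,train,NC(=S)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccc(OC)cc2,5.88,-0.7600
D16,train,NC(=S)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccc(O)cc2,5.33,-0.7200
D17,train,NC(=S)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccc([N+](=O)[O-])cc2,7.89,-0.8900
D18,train,NC(=S)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccccc2F,6.66,-0.8200
D19,train,NC(=S)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccccc2Cl,7.32,-0.8600
D20,train,NC(=S)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccccc2Br,6.56,-0.8100
D21,train,NC(=S)N1N=C(-c2ccc(Br)c(Br)c2)CC1-c2ccc(F)cc2,8.99,-0.9500
D22,train,NC(=S)N1N=C(-c2ccc(Br)c(Br)c2)CC1-c2ccc(Cl)cc2,8.26,-0.9100
D23,train,NC(=S)N1N=C(-c2ccc(Br)c(Br)c2)CC1-c2ccc(Br)cc2,10.09,-1.0000
D24,train,NC(=S)N1N=C(-c2ccc(Br)c(Br)c2)CC1-c2ccc(C)cc2,9.88,-0.9400
D25,train,NC(=S)N1N=C(-c2ccc(Br)c(Br)c2)CC1-c2ccc(OC)cc2,8.19,-0.9100
D26,train,NC(=S)N1N=C(-c2ccc(Br)c(Br)c2)CC1-c2ccc(O)cc2,11.24,-1.1000
D27,train,NC(=S)N1N=C(-c2ccc(Br)c(Br)c2)CC1-c2ccc([N+](=O)[O-])cc2,10.77,-1.0300
D28,train,NC(=S)N1N=C(-c2ccc(Br)c(Br)c2)CC1-c2ccccc2F,13.48,-2.5300
D29,train,NC(=S)N1N=C(-c2ccc(Br)c(Br)c2)CC1-c2ccccc2Cl,12.35,-1.135
D30,train,NC(=S)N1N=C(-c2ccc(Br)c(Br)c2)CC1-c2ccccc2Br,11.09,-1.042
F1,test,CC(=O)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccc(F)cc2,18.45,-1.2600
F2,test,CC(=O)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccc(Cl)cc2,16.16,-1.2100
F3,test,CC(=O)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccc(Br)cc2,18.47,-1.2700
F4,test,CC(=O)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccc(C)cc2,19.34,-1.2800
F5,test,CC(=O)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccc(OC)cc2,17.21,-1.2000
F6,test,CC(=O)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccccc2Cl,24.21,-1.3800
F7,test,CC(=O)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2ccccc2,28.71,-1.4600
F8,test,CC(=O)N1N=C(-c2ccc(Cl)c(Cl)c2)CC1-c2cc(OC)cc(OC)c2,25.52,-1.4100
F9,test,CC(=O)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccc(F)cc2,15.61,-1.2000
F10,test,CC(=O)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccc(Cl)cc2,19.74,-1.3000
F11,test,CC(=O)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccc(Br)cc2,20.64,-1.3100
F12,test,CC(=O)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccc(C)cc2,17.52,-1.2400
F13,test,CC(=O)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccc(OC)cc2,15.34,-1.1800
F14,test,CC(=O)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccccc2Cl,21.48,-1.3300
F15,test,CC(=O)N1N=C(-c2ccc(C)c(C)c2)CC1-c2ccccc2,20.06,-1.3000
F16,test,CC(=O)N1N=C(-c2ccc(C)c(C)c2)CC1-c2cc(OC)cc(OC)c2,17.33,-1.2400
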