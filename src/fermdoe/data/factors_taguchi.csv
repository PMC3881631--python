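symbol,name,unit,coded,actual
x1,orange peel,w/%,-1,0.25
x1,orange peel,w/%,0,0.50
x1,orange peel,w/%,1,1.0
x2,bactopeptone,w/%,-1,0.2
x2,bactopeptone,w/%,0,0.3
x2,bactopeptone,w/%,1,0.5
x3,MgCl2,w/%,-1,0.3
x3,MgCl2,w/%,0,0.59
x3,MgCl2,w/%,1,0.75
x4,ferric citrate,w/%,-1,0.005
x4,ferric citrate,w/%,0,0.01
x4,ferric citrate,w/%,1,0.03
x5,CaCl2,w/%,-1,0.1
x5,CaCl2,w/%,0,0.18
x5,CaCl2,w/%,1,0.24
x6,NaCl,w/%,-1,0.8
x6,NaCl,w/%,0,1.2
x6,NaCl,w/%,1,1.4
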