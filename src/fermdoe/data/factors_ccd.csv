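symbol,name,unit,coded,actual
x1,orange peel,w/%,-2,0.50
x1,orange peel,w/%,-1,0.75
x1,orange peel,w/%,0,1.00
x1,orange peel,w/%,1,1.25
x1,orange peel,w/%,2,1.50
x2,bactopeptone,w/%,-2,0.10
x2,bactopeptone,w/%,-1,0.15
x2,bactopeptone,w/%,0,0.20
x2,bactopeptone,w/%,1,0.25
x2,bactopeptone,w/%,2,0.30
x3,MgCl2,w/%,-2,0.65
x3,MgCl2,w/%,-1,0.70
x3,MgCl2,w/%,0,0.75
x3,MgCl2,w/%,1,0.80
x3,MgCl2,w/%,2,0.90
x6,NaCl,w/%,-2,0.60
x6,NaCl,w/%,-1,0.70
x6,NaCl,w/%,0,0.80
x6,NaCl,w/%,1,1.00
x6,NaCl,w/%,2,1.10
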