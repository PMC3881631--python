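# Level rows for A, C and D are garbled in the source table; the values below
# are the natural reading (flagged uncertain in fermdoe.datasets). Coded-unit
# analysis is unaffected.
symbol,name,unit,coded,actual
A,crude enzyme extract volume,mL,-2,15
A,crude enzyme extract volume,mL,-1,20
A,crude enzyme extract volume,mL,0,25
A,crude enzyme extract volume,mL,1,35
A,crude enzyme extract volume,mL,2,40
B,temperature,degC,-2,10
B,temperature,degC,-1,15
B,temperature,degC,0,20
B,temperature,degC,1,25
B,temperature,degC,2,30
C,banana fiber amount,mg,-2,25
C,banana fiber amount,mg,-1,30
C,banana fiber amount,mg,0,35
C,banana fiber amount,mg,1,40
C,banana fiber amount,mg,2,45
D,incubation time,min,-2,30
D,incubation time,min,-1,45
D,incubation time,min,0,90
D,incubation time,min,1,120
D,incubation time,min,2,150
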