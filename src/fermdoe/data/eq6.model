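# PGase (U/mL) quadratic response-surface model, coded units.
# Coefficients as tabulated (three decimals) in the source coefficient table;
# the published equation rounds the same values to two decimals.
const 24.753
x1 -0.185
x2 0.952
x3 -0.662
x6 -0.914
x1^2 -1.634
x2^2 0.408
x3^2 -0.392
x6^2 -0.224
x1*x2 0.109
x1*x3 0.971
x1*x6 -0.107
x2*x3 0.517
x2*x6 -0.023
x3*x6 -0.044
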