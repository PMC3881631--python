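# Reducing sugar (mg/mL) quadratic model in coded units, stored VERBATIM from
# the source equation.  CORRUPTED: several coefficients (e.g. 1.958C, 1.88A^2,
# -1.844AC, 2.531AD) have lost their 10^-x exponents in print and are orders of
# magnitude too large for the tabulated predictions.  Flagged corrupted in
# fermdoe.datasets; refit the model from the bundled CCD table instead.
const 0.12
A 0.058
B -0.015
C 1.958
D 0.021
A^2 1.88
B^2 -0.010
C^2 0.019
D^2 0.022
A*B -0.016
A*C -1.844
A*D 2.531
B*C -1.844
B*D -2.46
C*D 0.025
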