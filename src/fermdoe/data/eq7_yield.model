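# Pectin yield (%) quadratic model in coded units, banana-fiber hydrolysis CCD.
const 1.49
A -0.64
B 0.33
C 0.060
D -0.15
A^2 0.40
B^2 0.50
C^2 0.066
D^2 0.052
A*B -0.041
A*C 0.017
A*D -0.071
B*C 0.15
B*D 0.076
C*D -0.35
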