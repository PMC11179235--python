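# Shannon effective ionic radii (Angstrom), octahedral (VI) coordination
# unless chemistry dictates otherwise. Curated subset covering the elements
# used by the bundled fixtures and common oxide/halide chemistries.
# columns: symbol  formal_charge  radius_A
Li   1   0.76
Na   1   1.02
K    1   1.38
Rb   1   1.52
Cs   1   1.67
Ag   1   1.15
Cu   1   0.77
Cu   2   0.73
Be   2   0.45
Mg   2   0.72
Ca   2   1.00
Sr   2   1.18
Ba   2   1.35
Zn   2   0.74
Cd   2   0.95
Fe   2   0.78
Fe   3   0.645
Mn   2   0.83
Ni   2   0.69
Co   2   0.745
Pb   2   1.19
Al   3   0.535
Ga   3   0.62
In   3   0.80
Sc   3   0.745
Y    3   0.90
La   3   1.032
Cr   3   0.615
Si   4   0.40
Ge   4   0.53
Sn   4   0.69
Ti   4   0.605
Zr   4   0.72
Hf   4   0.71
Ce   4   0.87
O   -2   1.40
S   -2   1.84
Se  -2   1.98
F   -1   1.33
Cl  -1   1.81
Br  -1   1.96
I   -1   2.20
N   -3   1.46
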