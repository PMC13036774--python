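# Monoisotopic atomic masses (Da) of the most abundant isotope, NIST/CODATA values.
# columns: element	mass
H	1.0078250319
C	12.0
N	14.0030740052
O	15.9949146221
P	30.97376151
S	31.97207069
F	18.99840320
Cl	34.96885271
Br	78.9183376
I	126.904468
Na	22.98976928
K	38.9637069
Se	79.9165218
Si	27.9769265327
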