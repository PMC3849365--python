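# Minimal DNA nearest-neighbor free-energy tables, kcal/mol at 37 C.
# Watson-Crick stack values follow the published unified (SantaLucia)
# parameters; G-T wobble stacks are neutral placeholders (wobble pairing
# is admitted structurally but earns no stacking stabilisation here).
# Loop tables carry initiation penalties only; sizes beyond the table are
# extrapolated with the Jacobson-Stockmayer 1.75*RT*ln(n/nmax) term.
[stacks]
pairs  AT     TA     CG     GC     GT     TG
AT    -1.00  -0.88  -1.44  -1.28   0.00   0.00
TA    -0.58  -1.00  -1.30  -1.45   0.00   0.00
CG    -1.45  -1.28  -1.84  -2.17   0.00   0.00
GC    -1.30  -1.44  -2.24  -1.84   0.00   0.00
GT     0.00   0.00   0.00   0.00   0.00   0.00
TG     0.00   0.00   0.00   0.00   0.00   0.00

[hairpin]
3  3.5
4  3.5
5  3.3
6  4.0
7  4.2
8  4.3
9  4.5

[bulge]
1  4.0
2  2.9
3  3.1
4  3.2
5  3.3
6  3.5

[internal]
2  2.0
3  3.2
4  3.6
5  4.0
6  4.4

[multiloop]
a  3.4
b  0.4
c  0.0
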