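# Minimal RNA nearest-neighbor free-energy tables, kcal/mol at 37 C.
# Watson-Crick stack values follow the published Turner/Xia measurements;
# wobble-stack entries are approximate. Loop tables carry initiation
# penalties only (no mismatch/bonus terms); sizes beyond the table are
# extrapolated with the Jacobson-Stockmayer 1.75*RT*ln(n/nmax) term.
#
# [stacks]: entry (row P, column Q) is the stack of inner pair Q=(s[i+1],s[j-1])
# on outer pair P=(s[i],s[j]), i.e. the 5'-P1 Q1-3' / 3'-P2 Q2-5' doublet.
[stacks]
pairs  AU     UA     CG     GC     GU     UG
AU    -0.93  -1.10  -2.24  -2.08  -0.60  -1.40
UA    -1.33  -0.93  -2.35  -2.11  -1.00  -1.30
CG    -2.11  -2.08  -3.26  -2.36  -1.40  -2.10
GC    -2.35  -2.24  -3.42  -3.26  -1.50  -2.50
GU    -1.30  -1.40  -2.50  -2.10   1.30  -0.50
UG    -1.00  -0.60  -1.50  -1.40   0.30   1.30

[hairpin]
3  5.4
4  5.6
5  5.7
6  5.4
7  6.0
8  5.5
9  6.4

[bulge]
1  3.8
2  2.8
3  3.2
4  3.6
5  4.0
6  4.4

[internal]
2  1.5
3  1.6
4  1.1
5  2.0
6  2.0
7  2.2
8  2.3
9  2.4

[multiloop]
a  3.4
b  0.4
c  0.0
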