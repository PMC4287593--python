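REMARK synthetic 3-residue fixture; CA coordinates asserted in the test suite
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.990   2.833   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       5.504   2.705   0.000  1.00  0.00           C
ATOM      8  N   SER A   3       6.191   3.839   0.000  1.00  0.00           N
ATOM      9  CA ASER A   3       7.646   3.841   0.000  0.50  0.00           C
ATOM     10  CA BSER A   3       7.700   3.900   0.100  0.50  0.00           C
ATOM     11  C   SER A   3       8.185   5.264   0.000  1.00  0.00           C
END
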