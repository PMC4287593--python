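REMARK synthetic two-chain fixture; terminal CA coordinates asserted in the test suite
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       4.000   2.800   0.000  1.00  0.00           C
ATOM      6  C   GLY A   2       5.500   2.700   0.000  1.00  0.00           C
TER       7      GLY A   2
ATOM      8  N   LEU B   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      9  CA  LEU B   1      11.500  10.000  10.000  1.00  0.00           C
ATOM     10  C   LEU B   1      12.000  11.400  10.000  1.00  0.00           C
ATOM     11  N   VAL B   2      13.300  11.500  10.000  1.00  0.00           N
ATOM     12  CA  VAL B   2      14.000  12.800  10.000  1.00  0.00           C
ATOM     13  C   VAL B   2      15.500  12.700  10.000  1.00  0.00           C
END
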