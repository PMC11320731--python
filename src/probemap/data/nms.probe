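# N-methylthiophene-2-sulfonamide (NMS) rigid probe template; placeholder Gasteiger charges (override via your own table)
name element x y z charge epsilon rmin_half mass
C1   C    -2.3320   -0.2831    1.0347  -0.00073  0.0780  1.990  12.0110
N1   N    -1.9689   -0.8465   -0.2675  -0.21354  0.1700  1.850  14.0070
S1   S    -0.9593    0.0945   -1.2401   0.24929  0.4500  2.000  32.0600
O1   O    -0.8495   -0.5796   -2.5137  -0.20626  0.1200  1.700  15.9990
O2   O    -1.4150    1.4644   -1.1438  -0.20626  0.1200  1.700  15.9990
C2   C     0.6723    0.0973   -0.5424   0.13436  0.0780  1.990  12.0110
C3   C     1.5459    1.1229   -0.2331  -0.03111  0.0780  1.990  12.0110
C4   C     2.7683    0.6459    0.3220  -0.05010  0.0780  1.990  12.0110
C5   C     2.7869   -0.7280    0.4169  -0.00790  0.0780  1.990  12.0110
S2   S     1.3375   -1.4321   -0.1602  -0.13100  0.4500  2.000  32.0600
H1   H    -2.8425   -1.0534    1.6201   0.04031  0.0300  1.340   1.0080
H2   H    -3.0204    0.5573    0.9117   0.04031  0.0300  1.340   1.0080
H3   H    -1.4472    0.0332    1.5929   0.04031  0.0300  1.340   1.0080
H4   H    -2.7591   -1.1803   -0.8200   0.14054  0.0300  1.340   1.0080
H5   H     1.3079    2.1666   -0.4044   0.06459  0.0300  1.340   1.0080
H6   H     3.5926    1.2770    0.6323   0.06319  0.0300  1.340   1.0080
H7   H     3.5826   -1.3560    0.7946   0.07399  0.0300  1.340   1.0080
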