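# 4-methoxy-1-methylindazole (MMI) rigid probe template; placeholder Gasteiger charges (override via your own table)
name element x y z charge epsilon rmin_half mass
C1   C    -3.6281    0.1749   -0.6577   0.07754  0.0780  1.990  12.0110
O1   O    -2.4602   -0.5968   -0.4113  -0.49599  0.1200  1.700  15.9990
C2   C    -1.2896    0.0849   -0.2169   0.12937  0.0780  1.990  12.0110
C3   C    -1.1480    1.4817   -0.2410  -0.01913  0.0780  1.990  12.0110
C4   C     0.0935    2.0904   -0.0307  -0.05641  0.0780  1.990  12.0110
C5   C     1.2423    1.3339    0.2115  -0.03587  0.0780  1.990  12.0110
C6   C     1.0953   -0.0576    0.2343   0.07160  0.0780  1.990  12.0110
C7   C    -0.1320   -0.6833    0.0274   0.06188  0.0780  1.990  12.0110
C8   C     0.1567   -2.0635    0.1313   0.06056  0.0780  1.990  12.0110
N1   N     1.4453   -2.3102    0.3812  -0.18043  0.1700  1.850  14.0070
N2   N     1.9912   -1.0798    0.4389  -0.26779  0.1700  1.850  14.0070
C9   C     3.4042   -0.9411    0.6982   0.03038  0.0780  1.990  12.0110
H1   H    -3.5300    0.7563   -1.5803   0.06686  0.0300  1.340   1.0080
H2   H    -4.4648   -0.5180   -0.7891   0.06686  0.0300  1.340   1.0080
H3   H    -3.8621    0.8205    0.1952   0.06686  0.0300  1.340   1.0080
H4   H    -1.9988    2.1308   -0.4236   0.06622  0.0300  1.340   1.0080
H5   H     0.1664    3.1760   -0.0563   0.06248  0.0300  1.340   1.0080
H6   H     2.2023    1.8125    0.3738   0.06456  0.0300  1.340   1.0080
H7   H    -0.5309   -2.8932    0.0326   0.08678  0.0300  1.340   1.0080
H8   H     3.8618   -0.4264   -0.1503   0.04789  0.0300  1.340   1.0080
H9   H     3.8542   -1.9301    0.8185   0.04789  0.0300  1.340   1.0080
H10  H     3.5314   -0.3618    1.6160   0.04789  0.0300  1.340   1.0080
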