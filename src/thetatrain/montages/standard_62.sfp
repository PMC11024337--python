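Fp1 -24.981 76.883 26.266
Fp2 24.981 76.883 26.266
AF7 -47.516 65.401 26.266
AF3 -25.015 70.632 40.130
AF4 25.015 70.632 40.130
AF8 47.516 65.401 26.266
F7 -65.401 47.516 26.266
F5 -52.592 52.679 41.036
F3 -36.807 54.860 53.484
F1 -18.940 53.937 62.905
Fz 0.000 49.962 68.766
F2 18.940 53.937 62.905
F4 36.807 54.860 53.484
F6 52.592 52.679 41.036
F8 65.401 47.516 26.266
FT9 -80.840 26.266 0.000
FT7 -76.883 24.981 26.266
FC5 -64.300 29.138 47.345
FC3 -46.199 30.795 64.361
FC1 -24.135 29.809 75.854
FC2 24.135 29.809 75.854
FC4 46.199 30.795 64.361
FC6 64.300 29.138 47.345
FT8 76.883 24.981 26.266
FT10 80.840 26.266 0.000
T7 -80.840 0.000 26.266
C5 -68.766 0.000 49.962
C3 -49.962 0.000 68.766
C1 -26.266 0.000 80.840
Cz 0.000 0.000 85.000
C2 26.266 0.000 80.840
C4 49.962 0.000 68.766
C6 68.766 0.000 49.962
T8 80.840 0.000 26.266
TP9 -80.840 -26.266 0.000
TP7 -76.883 -24.981 26.266
CP5 -64.300 -29.138 47.345
CP3 -46.199 -30.795 64.361
CP1 -24.135 -29.809 75.854
CPz 0.000 -26.266 80.840
CP2 24.135 -29.809 75.854
CP4 46.199 -30.795 64.361
CP6 64.300 -29.138 47.345
TP8 76.883 -24.981 26.266
TP10 80.840 -26.266 0.000
P7 -65.401 -47.516 26.266
P5 -52.592 -52.679 41.036
P3 -36.807 -54.860 53.484
P1 -18.940 -53.937 62.905
Pz 0.000 -49.962 68.766
P2 18.940 -53.937 62.905
P4 36.807 -54.860 53.484
P6 52.592 -52.679 41.036
P8 65.401 -47.516 26.266
PO9 -49.962 -68.766 0.000
PO7 -47.516 -65.401 26.266
POz 0.000 -68.766 49.962
PO8 47.516 -65.401 26.266
PO10 49.962 -68.766 0.000
O1 -24.981 -76.883 26.266
Oz 0.000 -80.840 26.266
O2 24.981 -76.883 26.266
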