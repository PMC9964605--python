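name,x,y,z
FP1,3.060644,0.994463,1.045641
FPZ,3.218151,0.000000,1.045641
FP2,3.060644,-0.994463,1.045641
AF3,2.811778,0.995815,1.597535
AF4,2.811778,-0.995815,1.597535
F7,1.891582,2.603539,1.045641
F5,2.097097,2.093641,1.633620
F3,2.183937,1.465263,2.129152
F1,2.147187,0.753965,2.504194
FZ,1.988927,0.000000,2.737523
F2,2.147187,-0.753965,2.504194
F4,2.183937,-1.465263,2.129152
F6,2.097097,-2.093641,1.633620
F8,1.891582,-2.603539,1.045641
FT7,0.994463,3.060644,1.045641
FC5,1.159948,2.559712,1.884743
FC3,1.225908,1.839155,2.562132
FC1,1.186684,0.960796,3.019688
FCZ,1.045641,0.000000,3.218151
FC2,1.186684,-0.960796,3.019688
FC4,1.225908,-1.839155,2.562132
FC6,1.159948,-2.559712,1.884743
FT8,0.994463,-3.060644,1.045641
T7,0.000000,3.218151,1.045641
C5,0.000000,2.737523,1.988927
C3,0.000000,1.988927,2.737523
C1,0.000000,1.045641,3.218151
CZ,0.000000,0.000000,3.383764
C2,0.000000,-1.045641,3.218151
C4,0.000000,-1.988927,2.737523
C6,0.000000,-2.737523,1.988927
T8,0.000000,-3.218151,1.045641
TP7,-0.994463,3.060644,1.045641
CP5,-1.159948,2.559712,1.884743
CP3,-1.225908,1.839155,2.562132
CP1,-1.186684,0.960796,3.019688
CPZ,-1.045641,0.000000,3.218151
CP2,-1.186684,-0.960796,3.019688
CP4,-1.225908,-1.839155,2.562132
CP6,-1.159948,-2.559712,1.884743
TP8,-0.994463,-3.060644,1.045641
P7,-1.891582,2.603539,1.045641
P5,-2.097097,2.093641,1.633620
P3,-2.183937,1.465263,2.129152
P1,-2.147187,0.753965,2.504194
PZ,-1.988927,0.000000,2.737523
P2,-2.147187,-0.753965,2.504194
P4,-2.183937,-1.465263,2.129152
P6,-2.097097,-2.093641,1.633620
P8,-1.891582,-2.603539,1.045641
PO7,-2.603539,1.891582,1.045641
PO5,-2.773296,1.310264,1.428950
PO3,-2.818636,0.670165,1.748152
POZ,-2.737523,0.000000,1.988927
PO4,-2.818636,-0.670165,1.748152
PO6,-2.773296,-1.310264,1.428950
PO8,-2.603539,-1.891582,1.045641
CB1,-3.007612,1.532455,0.236039
O1,-3.060644,0.994463,1.045641
OZ,-3.218151,0.000000,1.045641
O2,-3.060644,-0.994463,1.045641
CB2,-3.007612,-1.532455,0.236039
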