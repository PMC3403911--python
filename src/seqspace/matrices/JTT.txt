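# JTT substitution matrix (20 standard amino acids)
      A     R     N     D     C     Q     E     G     H     I     L     K     M     F     P     S     T     W     Y     V
A   0.2  -0.1   0.0   0.0  -0.1  -0.1  -0.1   0.1  -0.2   0.0  -0.1  -0.1  -0.1  -0.3   0.1   0.1   0.2  -0.4  -0.3   0.1
R  -0.1   0.5   0.0  -0.1  -0.1   0.2   0.0   0.0   0.2  -0.3  -0.3   0.4  -0.2  -0.4  -0.1  -0.1  -0.1   0.0  -0.2  -0.3
N   0.0   0.0   0.3   0.2  -0.1   0.0   0.1   0.0   0.1  -0.2  -0.3   0.1  -0.2  -0.3  -0.1   0.1   0.1  -0.5  -0.1  -0.2
D   0.0  -0.1   0.2   0.5  -0.3   0.1   0.4   0.1   0.0  -0.3  -0.4   0.0  -0.3  -0.5  -0.2   0.0  -0.1  -0.5  -0.2  -0.2
C  -0.1  -0.1  -0.1  -0.3   1.1  -0.3  -0.4  -0.1   0.0  -0.2  -0.3  -0.3  -0.2   0.0  -0.2   0.1  -0.1   0.1   0.2  -0.2
Q  -0.1   0.2   0.0   0.1  -0.3   0.5   0.2  -0.1   0.2  -0.3  -0.2   0.2  -0.2  -0.4   0.0  -0.1  -0.1  -0.3  -0.2  -0.3
E  -0.1   0.0   0.1   0.4  -0.4   0.2   0.5   0.0   0.0  -0.3  -0.4   0.1  -0.3  -0.5  -0.2  -0.1  -0.1  -0.5  -0.4  -0.2
G   0.1   0.0   0.0   0.1  -0.1  -0.1   0.0   0.5  -0.2  -0.3  -0.4  -0.1  -0.3  -0.5  -0.1   0.1  -0.1  -0.2  -0.4  -0.2
H  -0.2   0.2   0.1   0.0   0.0   0.2   0.0  -0.2   0.6  -0.3  -0.2   0.1  -0.2   0.0   0.0  -0.1  -0.1  -0.3   0.4  -0.3
I   0.0  -0.3  -0.2  -0.3  -0.2  -0.3  -0.3  -0.3  -0.3   0.4   0.2  -0.3   0.3   0.0  -0.2  -0.1   0.1  -0.4  -0.2   0.4
L  -0.1  -0.3  -0.3  -0.4  -0.3  -0.2  -0.4  -0.4  -0.2   0.2   0.5  -0.3   0.3   0.2   0.0  -0.2  -0.1  -0.2  -0.1   0.2
K  -0.1   0.4   0.1   0.0  -0.3   0.2   0.1  -0.1   0.1  -0.3  -0.3   0.5  -0.2  -0.5  -0.2  -0.1  -0.1  -0.3  -0.3  -0.3
M  -0.1  -0.2  -0.2  -0.3  -0.2  -0.2  -0.3  -0.3  -0.2   0.3   0.3  -0.2   0.6   0.0  -0.2  -0.1   0.0  -0.3  -0.2   0.2
F  -0.3  -0.4  -0.3  -0.5   0.0  -0.4  -0.5  -0.5   0.0   0.0   0.2  -0.5   0.0   0.8  -0.3  -0.2  -0.2  -0.1   0.5   0.0
P   0.1  -0.1  -0.1  -0.2  -0.2   0.0  -0.2  -0.1   0.0  -0.2   0.0  -0.2  -0.2  -0.3   0.6   0.1   0.1  -0.4  -0.3  -0.1
S   0.1  -0.1   0.1   0.0   0.1  -0.1  -0.1   0.1  -0.1  -0.1  -0.2  -0.1  -0.1  -0.2   0.1   0.2   0.1  -0.3  -0.1  -0.1
T   0.2  -0.1   0.1  -0.1  -0.1  -0.1  -0.1  -0.1  -0.1   0.1  -0.1  -0.1   0.0  -0.2   0.1   0.1   0.2  -0.4  -0.3   0.0
W  -0.4   0.0  -0.5  -0.5   0.1  -0.3  -0.5  -0.2  -0.3  -0.4  -0.2  -0.3  -0.3  -0.1  -0.4  -0.3  -0.4   1.5   0.0  -0.3
Y  -0.3  -0.2  -0.1  -0.2   0.2  -0.2  -0.4  -0.4   0.4  -0.2  -0.1  -0.3  -0.2   0.5  -0.3  -0.1  -0.3   0.0   0.9  -0.3
V   0.1  -0.3  -0.2  -0.2  -0.2  -0.3  -0.2  -0.2  -0.3   0.4   0.2  -0.3   0.2   0.0  -0.1  -0.1   0.0  -0.3  -0.3   0.4
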