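# BLOSUM45 substitution matrix (20 standard amino acids)
      A     R     N     D     C     Q     E     G     H     I     L     K     M     F     P     S     T     W     Y     V
A     5    -2    -1    -2    -1    -1    -1     0    -2    -1    -1    -1    -1    -2    -1     1     0    -2    -2     0
R    -2     7     0    -1    -3     1     0    -2     0    -3    -2     3    -1    -2    -2    -1    -1    -2    -1    -2
N    -1     0     6     2    -2     0     0     0     1    -2    -3     0    -2    -2    -2     1     0    -4    -2    -3
D    -2    -1     2     7    -3     0     2    -1     0    -4    -3     0    -3    -4    -1     0    -1    -4    -2    -3
C    -1    -3    -2    -3    12    -3    -3    -3    -3    -3    -2    -3    -2    -2    -4    -1    -1    -5    -3    -1
Q    -1     1     0     0    -3     6     2    -2     1    -2    -2     1     0    -4    -1     0    -1    -2    -1    -3
E    -1     0     0     2    -3     2     6    -2     0    -3    -2     1    -2    -3     0     0    -1    -3    -2    -3
G     0    -2     0    -1    -3    -2    -2     7    -2    -4    -3    -2    -2    -3    -2     0    -2    -2    -3    -3
H    -2     0     1     0    -3     1     0    -2    10    -3    -2    -1     0    -2    -2    -1    -2    -3     2    -3
I    -1    -3    -2    -4    -3    -2    -3    -4    -3     5     2    -3     2     0    -2    -2    -1    -2     0     3
L    -1    -2    -3    -3    -2    -2    -2    -3    -2     2     5    -3     2     1    -3    -3    -1    -2     0     1
K    -1     3     0     0    -3     1     1    -2    -1    -3    -3     5    -1    -3    -1    -1    -1    -2    -1    -2
M    -1    -1    -2    -3    -2     0    -2    -2     0     2     2    -1     6     0    -2    -2    -1    -2     0     1
F    -2    -2    -2    -4    -2    -4    -3    -3    -2     0     1    -3     0     8    -3    -2    -1     1     3     0
P    -1    -2    -2    -1    -4    -1     0    -2    -2    -2    -3    -1    -2    -3     9    -1    -1    -3    -3    -3
S     1    -1     1     0    -1     0     0     0    -1    -2    -3    -1    -2    -2    -1     4     2    -4    -2    -1
T     0    -1     0    -1    -1    -1    -1    -2    -2    -1    -1    -1    -1    -1    -1     2     5    -3    -1     0
W    -2    -2    -4    -4    -5    -2    -3    -2    -3    -2    -2    -2    -2     1    -3    -4    -3    15     3    -3
Y    -2    -1    -2    -2    -3    -1    -2    -3     2     0     0    -1     0     3    -3    -2    -1     3     8    -1
V     0    -2    -3    -3    -1    -3    -3    -3    -3     3     1    -2     1     0    -3    -1     0    -3    -1     5
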