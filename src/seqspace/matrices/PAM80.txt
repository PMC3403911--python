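# PAM80 substitution matrix (20 standard amino acids)
      A     R     N     D     C     Q     E     G     H     I     L     K     M     F     P     S     T     W     Y     V
A     4    -4    -1    -1    -4    -2    -1     0    -4    -2    -4    -4    -3    -5     0     1     1    -8    -5     0
R    -4     7    -2    -5    -5     0    -4    -6     0    -3    -5     2    -2    -6    -2    -1    -3     0    -7    -5
N    -1    -2     5     3    -6    -1     0    -1     2    -3    -5     0    -4    -5    -3     1     0    -5    -3    -4
D    -1    -5     3     6    -9     0     4    -1    -1    -4    -7    -2    -6    -9    -4    -1    -2   -10    -7    -5
C    -4    -5    -6    -9     9    -9    -9    -6    -5    -4    -9    -9    -8    -8    -5    -1    -4   -10    -2    -3
Q    -2     0    -1     0    -9     7     2    -4     2    -4    -3    -1    -2    -8    -1    -3    -3    -8    -7    -4
E    -1    -4     0     4    -9     2     6    -2    -2    -3    -6    -2    -4    -9    -3    -2    -3   -11    -6    -4
G     0    -6    -1    -1    -6    -4    -2     6    -5    -6    -7    -4    -5    -6    -3     0    -2   -10    -8    -3
H    -4     0     2    -1    -5     2    -2    -5     8    -5    -4    -3    -5    -3    -2    -3    -4    -4    -1    -4
I    -2    -3    -3    -4    -4    -4    -3    -6    -5     7     1    -4     1     0    -5    -4    -1    -8    -3     3
L    -4    -5    -5    -7    -9    -3    -6    -7    -4     1     6    -5     2     0    -4    -5    -4    -3    -4     0
K    -4     2     0    -2    -9    -1    -2    -4    -3    -4    -5     6     0    -9    -4    -2    -1    -7    -6    -5
M    -3    -2    -4    -6    -8    -2    -4    -5    -5     1     2     0     9    -2    -5    -3    -2    -7    -6     1
F    -5    -6    -5    -9    -8    -8    -9    -6    -3     0     0    -9    -2     8    -7    -4    -5    -2     4    -4
P     0    -2    -3    -4    -5    -1    -3    -3    -2    -5    -4    -4    -5    -7     7     0    -2    -9    -8    -3
S     1    -1     1    -1    -1    -3    -2     0    -3    -4    -5    -2    -3    -4     0     4     2    -3    -4    -3
T     1    -3     0    -2    -4    -3    -3    -2    -4    -1    -4    -1    -2    -5    -2     2     5    -8    -4    -1
W    -8     0    -5   -10   -10    -8   -11   -10    -4    -8    -3    -7    -7    -2    -9    -3    -8    13    -2   -10
Y    -5    -7    -3    -7    -2    -7    -6    -8    -1    -3    -4    -6    -6     4    -8    -4    -4    -2     9    -5
V     0    -5    -4    -5    -3    -4    -4    -3    -4     3     0    -5     1    -4    -3    -3    -1   -10    -5     6
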