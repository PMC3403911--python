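# PAM160 substitution matrix (20 standard amino acids)
      A     R     N     D     C     Q     E     G     H     I     L     K     M     F     P     S     T     W     Y     V
A     2    -2     0     0    -2    -1     0     1    -2    -1    -2    -2    -1    -3     1     1     1    -5    -3     0
R    -2     6    -1    -2    -3     1    -2    -3     1    -2    -3     3    -1    -4    -1    -1    -1     1    -4    -3
N     0    -1     3     2    -4     0     1     0     2    -2    -3     1    -2    -3    -1     1     0    -4    -2    -2
D     0    -2     2     4    -5     1     3     0     0    -3    -4     0    -3    -6    -2     0    -1    -6    -4    -3
C    -2    -3    -4    -5     9    -5    -5    -3    -3    -2    -6    -5    -5    -5    -3     0    -2    -7     0    -2
Q    -1     1     0     1    -5     5     2    -2     2    -2    -2     0    -1    -5     0    -1    -1    -5    -4    -2
E     0    -2     1     3    -5     2     4     0     0    -2    -3    -1    -2    -5    -1     0    -1    -7    -4    -2
G     1    -3     0     0    -3    -2     0     4    -3    -3    -4    -2    -3    -4    -1     1    -1    -7    -5    -2
H    -2     1     2     0    -3     2     0    -3     6    -3    -2    -1    -3    -2    -1    -1    -2    -3     0    -2
I    -1    -2    -2    -3    -2    -2    -2    -3    -3     5     2    -2     2     0    -2    -2     0    -5    -2     3
L    -2    -3    -3    -4    -6    -2    -3    -4    -2     2     5    -3     3     1    -3    -3    -2    -2    -2     1
K    -2     3     1     0    -5     0    -1    -2    -1    -2    -3     4     0    -5    -2    -1     0    -4    -4    -3
M    -1    -1    -2    -3    -5    -1    -2    -3    -3     2     3     0     7     0    -2    -2    -1    -4    -3     1
F    -3    -4    -3    -6    -5    -5    -5    -4    -2     0     1    -5     0     7    -4    -3    -3    -1     5    -2
P     1    -1    -1    -2    -3     0    -1    -1    -1    -2    -3    -2    -2    -4     5     1     0    -5    -5    -2
S     1    -1     1     0     0    -1     0     1    -1    -2    -3    -1    -2    -3     1     2     1    -2    -3    -1
T     1    -1     0    -1    -2    -1    -1    -1    -2     0    -2     0    -1    -3     0     1     3    -5    -3     0
W    -5     1    -4    -6    -7    -5    -7    -7    -3    -5    -2    -4    -4    -1    -5    -2    -5    12    -1    -6
Y    -3    -4    -2    -4     0    -4    -4    -5     0    -2    -2    -4    -3     5    -5    -3    -3    -1     8    -3
V     0    -3    -2    -3    -2    -2    -2    -2    -2     3     1    -3     1    -2    -2    -1     0    -6    -3     4
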