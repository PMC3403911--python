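# PAM250 substitution matrix (20 standard amino acids)
      A     R     N     D     C     Q     E     G     H     I     L     K     M     F     P     S     T     W     Y     V
A     2    -2     0     0    -2     0     0     1    -1    -1    -2    -1    -1    -3     1     1     1    -6    -3     0
R    -2     6     0    -1    -4     1    -1    -3     2    -2    -3     3     0    -4     0     0    -1     2    -4    -2
N     0     0     2     2    -4     1     1     0     2    -2    -3     1    -2    -3     0     1     0    -4    -2    -2
D     0    -1     2     4    -5     2     3     1     1    -2    -4     0    -3    -6    -1     0     0    -7    -4    -2
C    -2    -4    -4    -5    12    -5    -5    -3    -3    -2    -6    -5    -5    -4    -3     0    -2    -8     0    -2
Q     0     1     1     2    -5     4     2    -1     3    -2    -2     1    -1    -5     0    -1    -1    -5    -4    -2
E     0    -1     1     3    -5     2     4     0     1    -2    -3     0    -2    -5    -1     0     0    -7    -4    -2
G     1    -3     0     1    -3    -1     0     5    -2    -3    -4    -2    -3    -5     0     1     0    -7    -5    -1
H    -1     2     2     1    -3     3     1    -2     6    -2    -2     0    -2    -2     0    -1    -1    -3     0    -2
I    -1    -2    -2    -2    -2    -2    -2    -3    -2     5     2    -2     2     1    -2    -1     0    -5    -1     4
L    -2    -3    -3    -4    -6    -2    -3    -4    -2     2     6    -3     4     2    -3    -3    -2    -2    -1     2
K    -1     3     1     0    -5     1     0    -2     0    -2    -3     5     0    -5    -1     0     0    -3    -4    -2
M    -1     0    -2    -3    -5    -1    -2    -3    -2     2     4     0     6     0    -2    -2    -1    -4    -2     2
F    -3    -4    -3    -6    -4    -5    -5    -5    -2     1     2    -5     0     9    -5    -3    -3     0     7    -1
P     1     0     0    -1    -3     0    -1     0     0    -2    -3    -1    -2    -5     6     1     0    -6    -5    -1
S     1     0     1     0     0    -1     0     1    -1    -1    -3     0    -2    -3     1     2     1    -2    -3    -1
T     1    -1     0     0    -2    -1     0     0    -1     0    -2     0    -1    -3     0     1     3    -5    -3     0
W    -6     2    -4    -7    -8    -5    -7    -7    -3    -5    -2    -3    -4     0    -6    -2    -5    17     0    -6
Y    -3    -4    -2    -4     0    -4    -4    -5     0    -1    -1    -4    -2     7    -5    -3    -3     0    10    -2
V     0    -2    -2    -2    -2    -2    -2    -1    -2     4     2    -2     2    -1    -1    -1     0    -6    -2     4
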