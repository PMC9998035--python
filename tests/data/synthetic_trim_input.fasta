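>seq1
K--K--I-----
>seq2
C--AA-F---V-
>seq3
C-IN--I---S-
>seq4
V--F--M-----
>seq5
Q--L--C-C--W
>seq6
T-----M---L-
>seq7
W---E-LG----
>seq8
D--L--I---D-
>seq9
D--A--Y---W-
>seq10
G-----Y---C-
>seq11
S--H--W-K---
>seq12
E-----G-----
>seq13
I--A-RS-----
>seq14
Y-----A-----
>seq15
G-----SM--Y-
>seq16
V--E--C-----
>seq17
M-----A-----
>seq18
I--Y--Q-Y---
>seq19
Q-----N-----
>seq20
C--V--A----A
>seq21
I-----P-----
>seq22
I-----H---L-
>seq23
W-----H--H--
>seq24
R-----G-Y---
>seq25
M-----Q-----
>seq26
D-EE--W-----
>seq27
I--A--M---Y-
>seq28
RG--D-M---R-
>seq29
G-----L-H-N-
>seq30
S--K--T---I-
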