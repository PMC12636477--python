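>FB0001.1 bcd
A  [ 12   2  88  90   2   4 ]
C  [  8   4   2   2  80  78 ]
G  [  6   4   4   2  10  12 ]
T  [ 74  90   6   6   8   6 ]
>FB0002.1 cad
A  [  8  10  80  84  82   6 ]
C  [  6   4   6   4   6  10 ]
G  [  8   6   8   6   6   8 ]
T  [ 78  80   6   6   6  76 ]
>FB0003.1 dl
A  [  4  80  80  80   6   4   6   4 ]
C  [ 10   6   4   6  78  80   8   8 ]
G  [ 78   8  10   8   8   6  10   6 ]
T  [  8   6   6   6   8  10  76  82 ]
>FB0004.1 vfl
A  [  6   4  82   8   6  84   4 ]
C  [ 78  82   4   8  80   6   8 ]
G  [  8   8   8  78   6   4  80 ]
T  [  8   6   6   6   8   6   8 ]
>FB0005.1 hb
A  [  6   8   4   6   6   8 ]
C  [  8   6   6   8  10   8 ]
G  [  8   6   8   6   6   6 ]
T  [ 78  80  82  80  78  78 ]
>FB0006.1 Kr
A  [ 82   6   8  80   4   8   6 ]
C  [  6  10  78   6   8  80  10 ]
G  [  6  78   6   6  82   4   6 ]
T  [  6   6   8   8   6   8  78 ]
>FB0007.1 run
A  [  8  80   6   4  82   8 ]
C  [ 80   6   8  82   6   8 ]
G  [  6   8  80   8   6   6 ]
T  [  6   6   6   6   6  78 ]
>FB0008.1 odd
A  [  6   8  78   8  80   6   8 ]
C  [  8  80   8   8   6   8  78 ]
G  [ 80   6   8  78   8  80   6 ]
T  [  6   6   6   6   6   6   8 ]
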