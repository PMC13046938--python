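>M01 EGR4
A [ 20 1 20 20 1 20 20 1 20 20 1 20 ]
C [ 20 97 20 20 1 20 20 97 20 20 1 20 ]
G [ 40 1 40 20 97 40 40 1 40 20 97 40 ]
T [ 20 1 20 40 1 20 20 1 20 40 1 20 ]
>M02 NFIB
A [ 20 1 20 20 1 40 40 1 20 20 1 40 ]
C [ 20 1 20 20 97 20 20 1 20 40 97 20 ]
G [ 20 1 40 40 1 20 20 97 20 20 1 20 ]
T [ 40 97 20 20 1 20 20 1 40 20 1 20 ]
>M03 SOX2
A [ 40 97 20 40 97 20 20 1 20 40 1 40 ]
C [ 20 1 40 20 1 20 20 1 40 20 1 20 ]
G [ 20 1 20 20 1 20 40 97 20 20 97 20 ]
T [ 20 1 20 20 1 40 20 1 20 20 1 20 ]
>M04 SPI1
A [ 40 1 40 20 1 40 40 1 20 20 97 20 ]
C [ 20 1 20 20 1 20 20 1 20 20 1 40 ]
G [ 20 97 20 40 97 20 20 97 20 40 1 20 ]
T [ 20 1 20 20 1 20 20 1 40 20 1 20 ]
>M05 CREB1
A [ 20 1 40 20 1 20 20 97 20 20 1 20 ]
C [ 20 1 20 40 1 20 40 1 20 40 1 20 ]
G [ 20 97 20 20 97 20 20 1 20 20 97 20 ]
T [ 40 1 20 20 1 40 20 1 40 20 1 40 ]
>M06 MEF2D
A [ 20 1 40 40 97 40 40 1 40 20 1 20 ]
C [ 40 1 20 20 1 20 20 1 20 20 97 40 ]
G [ 20 1 20 20 1 20 20 1 20 40 1 20 ]
T [ 20 97 20 20 1 20 20 97 20 20 1 20 ]
>M07 RORB
A [ 40 97 40 20 1 40 20 1 20 20 97 20 ]
C [ 20 1 20 20 1 20 20 1 20 40 1 20 ]
G [ 20 1 20 40 1 20 40 97 20 20 1 20 ]
T [ 20 1 20 20 97 20 20 1 40 20 1 40 ]
>M08 FOSL2::JUN
A [ 20 1 40 20 1 20 40 1 20 20 1 40 ]
C [ 20 1 20 20 1 40 20 97 40 20 1 20 ]
G [ 20 97 20 40 1 20 20 1 20 40 1 20 ]
T [ 40 1 20 20 97 20 20 1 20 20 97 20 ]
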