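symbol_or_pattern	kind
^TR[ABDG][VDJC]	regex
FOS	literal
FOSB	literal
JUN	literal
JUNB	literal
JUND	literal
EGR1	literal
HSPA1A	literal
HSPA1B	literal
HSPA8	literal
HSPB1	literal
DNAJB1	literal
DNAJA1	literal
ZFP36	literal
IER2	literal
IER3	literal
DUSP1	literal
KLF6	literal
SOCS3	literal
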