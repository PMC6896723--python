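AURKA	informative
BAG1	informative
BCL2	informative
BIRC5	informative
CCNB1	informative
CD68	informative
CTSV	informative
ERBB2	informative
ESR1	informative
GRB7	informative
GSTM1	informative
MKI67	informative
MMP11	informative
MYBL2	informative
PGR	informative
SCUBE2	informative
ACTB	reference
GAPDH	reference
GUSB	reference
RPLP0	reference
TFRC	reference
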