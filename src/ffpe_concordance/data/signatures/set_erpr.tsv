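ABAT	informative
ADCY1	informative
AZGP1	informative
CA12	informative
CD2	informative
CD3D	informative
DNAJC12	informative
ESR1	informative
KCNE4	informative
MAPT	informative
MRPS30	informative
NAT1	informative
NPY1R	informative
PDZK1	informative
QDPR	informative
SCUBE2	informative
SLC39A6	informative
STC2	informative
AK2	reference
APPBP2	reference
ATP5J2	reference
DARS	reference
LDHA	reference
TRIM2	reference
UBE2Z	reference
UGP2	reference
VDAC2	reference
WIPF2	reference
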