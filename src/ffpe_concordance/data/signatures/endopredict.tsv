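AZGP1	informative
BIRC5	informative
DHCR7	informative
IL6ST	informative
MGP	informative
RBBP8	informative
STC2	informative
UBE2C	informative
CALM2	reference
OAZ1	reference
RPL37A	reference
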