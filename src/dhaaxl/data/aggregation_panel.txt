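# Curated panel of proteins reported to aggregate in neurodegenerative
# disorders, used to build the small targeted database for crosslink
# searches.  One gene symbol per line; edit freely — this list is
# configuration, not ground truth.
MAPT
APP
SNCA
GFAP
CRMP1
DPYSL2
DPYSL3
GAPDH
VDAC2
PLP1
CNP
DLAT
APOE
CLU
VIM
NEFL
NEFM
NEFH
UCHL1
SOD1
TARDBP
SQSTM1
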