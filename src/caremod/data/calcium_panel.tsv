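gene	category
CAV1.1	VOCC
CAV1.2	VOCC
CAV1.3	VOCC
CAV1.4	VOCC
CAV2.1	VOCC
CAV2.2	VOCC
CAV2.3	VOCC
CAV3.1	VOCC
CAV3.2	VOCC
CAV3.3	VOCC
ORAI1	SOCE
ORAI2	SOCE
ORAI3	SOCE
STIM1	SOCE
STIM2	SOCE
STIMATE	SOCE
CRACR2A	SOCE
CRACR2B	SOCE
ORMDL3	SOCE
SARAF	SOCE
MBP	SOCE
SEPTIN1	SOCE
SEPTIN2	SOCE
SEPTIN3	SOCE
SEPTIN4	SOCE
SEPTIN5	SOCE
SEPTIN6	SOCE
SEPTIN7	SOCE
SEPTIN8	SOCE
SEPTIN9	SOCE
SEPTIN10	SOCE
SEPTIN11	SOCE
SEPTIN12	SOCE
TRPC1	TRP
TRPC3	TRP
TRPC4	TRP
TRPC5	TRP
TRPC6	TRP
TRPC7	TRP
TRPV1	TRP
TRPV2	TRP
TRPV3	TRP
TRPV4	TRP
TRPV5	TRP
TRPV6	TRP
TRPM2	TRP
TRPM3	TRP
TRPM4	TRP
TRPM5	TRP
TRPM6	TRP
TRPM7	TRP
TRPM8	TRP
TRPA1	TRP
TRPML1	TRP
TRPML2	TRP
TRPML3	TRP
TRPP1	TRP
TRPP2	TRP
TRPP3	TRP
TRPP5	TRP
IP3R1	release
IP3R2	release
IP3R3	release
RYR1	release
RYR2	release
RYR3	release
PMCA1	pump_exchanger
PMCA2	pump_exchanger
PMCA3	pump_exchanger
PMCA4	pump_exchanger
SERCA1	pump_exchanger
SERCA2	pump_exchanger
SERCA3	pump_exchanger
SPCA1	pump_exchanger
SPCA2	pump_exchanger
NCX1	pump_exchanger
NCX2	pump_exchanger
NCX3	pump_exchanger
MCU	mitochondrial
MCUB	mitochondrial
MICU1	mitochondrial
MICU2	mitochondrial
MICU3	mitochondrial
MCUR1	mitochondrial
EMRE	mitochondrial
VDAC1	mitochondrial
VDAC2	mitochondrial
VDAC3	mitochondrial
NCLX	mitochondrial
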