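# Curated gene-lipid association table (synthetic stand-in, version default-1).
# Selectors resolve against the packaged panel: 'species' matches one
# canonical name, 'class' matches every species of a headgroup class,
# 'subclass' matches a LIPID MAPS subclass code. Pairings follow standard
# enzyme-substrate class annotations; each row states its basis.
gene	selector_type	selector_value	provenance
ABHD3	class	PC	phospholipase selective for medium-chain phosphatidylcholines
CPT2	class	CAR	carnitine palmitoyltransferase 2: acylcarnitine/acyl-CoA interconversion
LPCAT1	class	LPC	lysophosphatidylcholine acyltransferase, Lands-cycle LPC reacylation
LPCAT2	class	LPC	lysophosphatidylcholine acyltransferase, Lands-cycle LPC reacylation
LPCAT3	class	LPC	lysophosphatidylcholine acyltransferase, Lands-cycle LPC reacylation
LPCAT4	class	LPC	lysophosphatidylcholine acyltransferase, Lands-cycle LPC reacylation
PNPLA6	class	LPC	neuropathy target esterase: lysophospholipase activity
ENPP6	class	LPC	choline-specific glycerophosphodiesterase acting on lyso lipids
ENPP6	class	PC O-	activity toward choline ether lipids
PLA2G4F	class	PC	cytosolic phospholipase A2 family member, sn-2 deacylation of PC
PLA2G15	class	PC	lysosomal phospholipase A2
LYPLA2	class	LPC	lysophospholipase 2
PLAAT3	class	PC	phospholipase A/acyltransferase 3
PNPLA8	class	PC	calcium-independent phospholipase A2 gamma
ABHD16A	class	PC	phospholipid hydrolase
SMPD3	class	SM	neutral sphingomyelinase 2, sphingomyelin turnover
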