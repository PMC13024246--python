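# Qualitative membrane-biophysics rule table, version default-1.
# First matching row wins; '*' is a wildcard bound. Labels follow coarse
# empirical headgroup/chain relationships; carbon and double-bond bin edges
# are approximate and documented per row in the provenance column.
lipid_class	c_min	c_max	db_min	db_max	bilayer_thickness	lateral_diffusion	intrinsic_curvature	function	cellular_component	provenance
CAR	*	*	*	*	very low	very high	positive	lipid-mediated signaling	mitochondrion	single-chain carnitine ester; beta-oxidation shuttle, not a bilayer former
LPC	*	*	*	*	very low	very high	positive	lipid-mediated signaling	ER	lyso headgroup: inverted-cone geometry promotes positive curvature; single chain thins and mobilises the leaflet
PC	*	30	0	0	very low	low	neutral	membrane component	ER	short saturated diacyl PC: thin, tightly packed
PC	*	30	1	2	very low	average	neutral	membrane component	ER	short diacyl PC with low unsaturation
PC	*	30	3	*	very low	high	neutral	membrane component	ER	short polyunsaturated diacyl PC: disordered, mobile
PC	31	34	0	0	low	low	neutral	membrane component	ER	medium saturated diacyl PC
PC	31	34	1	2	low	average	neutral	membrane component	ER	medium diacyl PC, low unsaturation
PC	31	34	3	*	low	high	neutral	membrane component	ER	medium polyunsaturated diacyl PC
PC	35	38	0	0	average	low	neutral	membrane component	ER	long saturated diacyl PC: thickening, ordered
PC	35	38	1	2	average	average	neutral	membrane component	ER	long diacyl PC, low unsaturation
PC	35	38	3	*	average	high	neutral	membrane component	ER	long polyunsaturated diacyl PC
PC	39	42	0	0	high	low	neutral	membrane component	ER	very long saturated diacyl PC: thick ordered bilayer
PC	39	42	1	2	high	average	neutral	membrane component	ER	very long diacyl PC, low unsaturation
PC	39	42	3	*	high	high	neutral	membrane component	ER	very long polyunsaturated diacyl PC
PC	43	*	0	2	very high	low	neutral	membrane component	ER	ultra-long diacyl PC
PC	43	*	3	*	very high	average	neutral	membrane component	ER	ultra-long polyunsaturated diacyl PC
PC O-	*	30	*	2	very low	very low	neutral	membrane component	other	ether bond rigidifies and slows lateral mobility; peroxisome-initiated synthesis
PC O-	*	30	3	*	very low	low	neutral	membrane component	other	short polyunsaturated ether PC
PC O-	31	34	*	2	low	very low	neutral	membrane component	other	medium ether PC: rigid, slow-diffusing
PC O-	31	34	3	*	low	low	neutral	membrane component	other	medium polyunsaturated ether PC
PC O-	35	38	*	2	average	very low	neutral	membrane component	other	long ether PC: rigid, slow-diffusing
PC O-	35	38	3	*	average	low	neutral	membrane component	other	long polyunsaturated ether PC
PC O-	39	*	*	2	high	very low	neutral	membrane component	other	very long ether PC: thick and rigid
PC O-	39	*	3	*	high	low	neutral	membrane component	other	very long polyunsaturated ether PC
SM	*	38	*	*	average	very low	neutral	membrane component	plasma membrane	sphingomyelin partitions to ordered plasma-membrane domains
SM	39	42	*	*	high	very low	neutral	membrane component	plasma membrane	long-chain sphingomyelin thickens ordered domains
SM	43	*	*	*	very high	very low	neutral	membrane component	plasma membrane	ultra-long-chain sphingomyelin
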