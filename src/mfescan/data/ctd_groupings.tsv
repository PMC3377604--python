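# CTD residue-property groupings, version 1
# Each of the eight physicochemical properties partitions the 20 standard
# residues into three disjoint groups; group order is fixed and determines
# feature-vector element order.
#property	group1	group2	group3
hydrophobicity	RKEDQN	GASTPHY	CLVIMFW
normalized_vdw_volume	GASTPDC	NVEQIL	MHKFRYW
polarity	LIFWCMVY	PATGS	HQRKNED
polarizability	GASDT	CPNVEQIL	KMHFRYW
charge	KR	ANCQGHILMFPSTWYV	DE
surface_tension	GQDNAHR	KTSEC	ILMFPWYV
secondary_structure	EALMQKRH	VIYCWFT	GNPSD
solvent_accessibility	ALFCGIVW	RKQEND	MSPTHY
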