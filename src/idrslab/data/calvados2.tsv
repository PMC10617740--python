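# Residue-level parameters for the single-bead-per-residue hydropathy model.
# lambda (stickiness) values transcribed from the CALVADOS 2 publication
# (Tesei & Lindorff-Larsen, 2022); sigma are the standard residue van der
# Waals diameters of the HPS family of models; masses are average residue
# masses. Charges follow the rule R/K = +1, D/E = -1, all others 0.
# External provenance: lambda/sigma/mass are literature constants, not fitted here.
aa	lambda	sigma_nm	q	mass_Da
A	0.2743297969040348	0.504	0	71.0788
R	0.7307624767517166	0.656	1	156.1875
N	0.4255859009787713	0.568	0	114.1038
D	0.0416040480605567	0.558	-1	115.0886
C	0.5615435099141777	0.548	0	103.1388
Q	0.3934318551056041	0.602	0	128.1307
E	0.0006935460962935	0.592	-1	129.1155
G	0.7058843733666401	0.450	0	57.0519
H	0.4663667290557992	0.608	0	137.1411
I	0.5423623610671892	0.618	0	113.1594
L	0.6440005007782226	0.618	0	113.1594
K	0.1790211738990582	0.636	1	128.1741
M	0.5308481134337497	0.618	0	131.1926
F	0.8672358982062975	0.636	0	147.1766
P	0.3593126576364644	0.556	0	97.1167
S	0.4625416811611541	0.518	0	87.0782
T	0.3713162976273964	0.562	0	101.1051
W	0.9893764740371644	0.678	0	186.2132
Y	0.9774611449343455	0.646	0	163.1760
V	0.2083769608174481	0.586	0	99.1326
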