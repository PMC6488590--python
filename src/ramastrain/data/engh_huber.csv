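# Reference backbone covalent geometry (Engh & Huber style target values).
# Bond lengths in Angstrom, valence angles in degrees, sigma = reference
# standard deviation. Class 'other' covers all non-Gly, non-Pro residues;
# parameters absent for a class fall back to 'other'. The carbonyl angles
# are kept internally consistent (CaCO + CaCN_next + OCN_next = 360) so
# that an ideal planar carbonyl reproduces the table exactly.
residue_class,parameter,mean,sigma
other,N_CA,1.458,0.019
other,CA_C,1.525,0.021
other,C_N,1.329,0.014
other,C_O,1.231,0.020
other,CA_CB,1.530,0.020
other,NCaC,111.2,2.8
other,NCaCb,110.4,1.5
other,CbCaC,110.1,1.9
other,CaCO,120.8,1.7
other,CaCN_next,116.2,2.0
other,OCN_next,123.0,1.6
other,Cprev_N_Ca,121.7,1.8
other,delta_omega,0.0,6.0
GLY,N_CA,1.451,0.016
GLY,CA_C,1.516,0.018
GLY,NCaC,112.5,2.9
GLY,Cprev_N_Ca,120.6,1.7
PRO,NCaC,111.8,2.5
PRO,NCaCb,103.0,1.1
PRO,CbCaC,111.7,2.1
PRO,Cprev_N_Ca,122.6,5.0
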