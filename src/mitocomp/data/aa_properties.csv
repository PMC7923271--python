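# Amino-acid physicochemical property table, v1.
# Sources (standard compilations of the protein-property literature):
#   pK1_cooh          - equilibrium (ionization) constant of the alpha-COOH group,
#                       standard free-amino-acid pKa1 values (CRC Handbook compilations).
#   isoelectric_point - pI of the free amino acid (CRC Handbook compilations).
#   solvent_reduction_ratio - reduction in solvent accessibility on folding
#                       (accessibility ratio scale after Chothia 1976).
#   buriedness        - proportion of residues at least 95% buried (Chothia 1976).
#   surrounding_hydrophobicity - Manavalan & Ponnuswamy 1978 (kcal/mol).
#   total_nonbonded_energy - mean total non-bonded interaction energy per residue
#                       (Oobatake & Ooi-type scale; approximate compilation).
#   surrounding_residues - average number of residues within 8 A
#                       (Ponnuswamy-type scale; approximate compilation).
# The last two columns are approximate literature compilations; downstream
# category baselines are recomputed from whatever values are shipped here.
aa,pK1_cooh,isoelectric_point,solvent_reduction_ratio,buriedness,surrounding_hydrophobicity,total_nonbonded_energy,surrounding_residues
A,2.34,6.00,0.74,0.38,12.97,-1.18,6.05
R,2.17,10.76,0.64,0.01,11.72,-0.84,5.70
N,2.02,5.41,0.63,0.12,11.42,-0.93,5.04
D,1.88,2.77,0.62,0.15,10.85,-0.94,4.95
C,1.96,5.07,0.91,0.45,14.63,-1.45,7.86
Q,2.17,5.65,0.62,0.07,11.76,-0.96,5.45
E,2.19,3.22,0.62,0.18,11.89,-0.90,5.10
G,2.34,5.97,0.72,0.36,12.43,-1.12,6.16
H,1.82,7.59,0.78,0.17,12.16,-1.09,5.80
I,2.36,6.02,0.88,0.60,15.67,-1.47,7.51
L,2.36,5.98,0.85,0.45,14.90,-1.43,7.37
K,2.18,9.74,0.52,0.03,11.36,-0.79,4.88
M,2.28,5.74,0.85,0.40,14.39,-1.36,6.39
F,1.83,5.48,0.88,0.50,14.00,-1.42,6.62
P,1.99,6.30,0.64,0.18,11.37,-0.99,5.65
S,2.21,5.68,0.66,0.22,11.23,-1.01,5.53
T,2.09,5.60,0.70,0.23,11.69,-1.08,5.81
W,2.83,5.89,0.85,0.27,13.93,-1.38,6.98
Y,2.20,5.66,0.76,0.15,13.42,-1.30,6.73
V,2.32,5.96,0.86,0.54,15.71,-1.45,7.62
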