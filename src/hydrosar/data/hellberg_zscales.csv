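# Hellberg 3-z amino-acid scales (Hellberg, Sjostrom, Skagerberg & Wold,
# J. Med. Chem. 1987, 30, 1126-1135): principal-property scores from 29
# physicochemical variables. z1 ~ hydrophilicity, z2 ~ side-chain bulk /
# molecular size, z3 ~ electronic properties. Substitute an alternative
# 20-residue table with the same columns to use a different scale.
amino_acid,z1,z2,z3
ALA,0.07,-1.73,0.09
VAL,-2.69,-2.53,-1.29
LEU,-4.19,-1.03,-0.98
ILE,-4.44,-1.68,-1.03
PRO,-1.22,0.88,2.23
PHE,-4.92,1.30,0.45
TRP,-4.75,3.65,0.85
MET,-2.49,-0.27,-0.41
LYS,2.84,1.41,-3.14
ARG,2.88,2.52,-3.44
HIS,2.41,1.74,1.11
GLY,2.23,-5.36,0.30
SER,1.96,-1.63,0.57
THR,0.92,-2.09,-1.40
CYS,0.71,-0.97,4.13
TYR,-1.39,2.32,0.01
ASN,3.22,1.45,0.84
GLN,2.18,0.53,-1.14
ASP,3.64,1.13,2.36
GLU,3.08,0.39,-0.07
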