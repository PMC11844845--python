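CC(=O)Oc1ccccc1C(=O)O
CC(C)Cc1ccc(C(C)C(=O)O)cc1
CC(=O)Nc1ccc(O)cc1
Cn1c(=O)c2c(ncn2C)n(C)c1=O
CN1C2CCC1CC(OC(=O)c1ccccc1)C2
NC(=O)c1ccc[nH]1
Clc1ccccc1Cl
OCC(O)CO
NCCc1ccc(O)c(O)c1
CC(N)Cc1ccccc1
O=C(O)c1cc(O)c(O)c(O)c1
Nc1ccc(S(N)(=O)=O)cc1
CC(C)NCC(O)COc1ccccc1
O=C(O)CCc1ccccc1
O=C(O)c1ccccc1O
CN(C)CCOC(c1ccccc1)c1ccccc1
Clc1ccc(C(c2ccccc2)N2CCNCC2)cc1
CC(=O)OCC(=O)C1(O)CCC2C3CCC4=CC(=O)CCC4(C)C3C(O)CC21C
O=c1[nH]c(=O)c2[nH]cnc2[nH]1
Nc1ncnc2[nH]cnc12
Cc1ncc(CO)c(CO)c1O
O=C(O)C1CCCN1
NC(Cc1c[nH]c2ccccc12)C(=O)O
NC(Cc1ccc(O)cc1)C(=O)O
CSCCC(N)C(=O)O
OC1CCCCC1
O=C1CCCCC1
C1CCOC1
c1ccc2[nH]ccc2c1
c1ccc2ncccc2c1
c1ccc2[nH]cnc2c1
c1ccc2occc2c1
c1ccc2sccc2c1
c1cnc2[nH]ccc2c1
O=C(Nc1ccccc1)c1ccccc1
O=S(=O)(Nc1ccccc1)c1ccccc1
CC(C)(C)OC(=O)NC1CCNCC1
O=C(O)c1cccnc1
NC(=O)c1cccnc1
Cn1ccnc1
CC1CCCCN1
OCCN1CCOCC1
ClCc1ccccc1
N#Cc1ccc(F)cc1
FC(F)(F)c1ccccc1
COc1ccc(CCN)cc1
CCOC(=O)c1ccccc1N
O=C1NC(=O)c2ccccc21
O=C1CCC(=O)N1
O=c1cc[nH]c(=O)[nH]1
Cc1cc(=O)[nH]c(=O)[nH]1
Nc1cc(=O)[nH]c(=O)[nH]1
Cc1ccccc1
CCc1ccccc1
CCCc1ccccc1
CC(C)c1ccccc1
CCCCc1ccccc1
COc1ccccc1
CCOc1ccccc1
Nc1ccccc1
CNc1ccccc1
CN(C)c1ccccc1
Fc1ccccc1
Clc1ccccc1
Brc1ccccc1
N#Cc1ccccc1
O=C(O)c1ccccc1
COC(=O)c1ccccc1
NC(=O)c1ccccc1
CC(=O)c1ccccc1
CC(=O)Nc1ccccc1
NS(=O)(=O)c1ccccc1
OCc1ccccc1
NCCc1ccccc1
OCCc1ccccc1
Cc1ccccn1
CCc1ccccn1
CCCc1ccccn1
CC(C)c1ccccn1
CCCCc1ccccn1
COc1ccccn1
CCOc1ccccn1
Nc1ccccn1
CNc1ccccn1
CN(C)c1ccccn1
Fc1ccccn1
Clc1ccccn1
Brc1ccccn1
N#Cc1ccccn1
FC(F)(F)c1ccccn1
O=C(O)c1ccccn1
COC(=O)c1ccccn1
NC(=O)c1ccccn1
CC(=O)c1ccccn1
CC(=O)Nc1ccccn1
NS(=O)(=O)c1ccccn1
OCc1ccccn1
NCCc1ccccn1
OCCc1ccccn1
Cc1ncccn1
CCc1ncccn1
CCCc1ncccn1
CC(C)c1ncccn1
CCCCc1ncccn1
COc1ncccn1
CCOc1ncccn1
Nc1ncccn1
CNc1ncccn1
CN(C)c1ncccn1
Fc1ncccn1
Clc1ncccn1
Brc1ncccn1
N#Cc1ncccn1
FC(F)(F)c1ncccn1
O=C(O)c1ncccn1
COC(=O)c1ncccn1
NC(=O)c1ncccn1
CC(=O)c1ncccn1
CC(=O)Nc1ncccn1
NS(=O)(=O)c1ncccn1
OCc1ncccn1
NCCc1ncccn1
OCCc1ncccn1
Cc1ccoc1
CCc1ccoc1
CCCc1ccoc1
CC(C)c1ccoc1
CCCCc1ccoc1
COc1ccoc1
CCOc1ccoc1
Nc1ccoc1
CNc1ccoc1
CN(C)c1ccoc1
Fc1ccoc1
Clc1ccoc1
Brc1ccoc1
N#Cc1ccoc1
FC(F)(F)c1ccoc1
O=C(O)c1ccoc1
COC(=O)c1ccoc1
NC(=O)c1ccoc1
CC(=O)c1ccoc1
CC(=O)Nc1ccoc1
NS(=O)(=O)c1ccoc1
OCc1ccoc1
NCCc1ccoc1
OCCc1ccoc1
Cc1ccsc1
CCc1ccsc1
CCCc1ccsc1
CC(C)c1ccsc1
CCCCc1ccsc1
COc1ccsc1
CCOc1ccsc1
Nc1ccsc1
CNc1ccsc1
CN(C)c1ccsc1
Fc1ccsc1
Clc1ccsc1
Brc1ccsc1
N#Cc1ccsc1
FC(F)(F)c1ccsc1
O=C(O)c1ccsc1
COC(=O)c1ccsc1
NC(=O)c1ccsc1
CC(=O)c1ccsc1
CC(=O)Nc1ccsc1
NS(=O)(=O)c1ccsc1
OCc1ccsc1
NCCc1ccsc1
OCCc1ccsc1
Cc1ccn(C)c1
CCc1ccn(C)c1
CCCc1ccn(C)c1
CC(C)c1ccn(C)c1
CCCCc1ccn(C)c1
COc1ccn(C)c1
CCOc1ccn(C)c1
Cn1ccc(N)c1
CNc1ccn(C)c1
CN(C)c1ccn(C)c1
Cn1ccc(F)c1
Cn1ccc(Cl)c1
Cn1ccc(Br)c1
Cn1ccc(C#N)c1
Cn1ccc(C(F)(F)F)c1
Cn1ccc(C(=O)O)c1
COC(=O)c1ccn(C)c1
Cn1ccc(C(N)=O)c1
CC(=O)c1ccn(C)c1
CC(=O)Nc1ccn(C)c1
Cn1ccc(S(N)(=O)=O)c1
Cn1ccc(CO)c1
Cn1ccc(CCN)c1
Cn1ccc(CCO)c1
Cc1cccc2ccccc12
CCc1cccc2ccccc12
CCCc1cccc2ccccc12
CC(C)c1cccc2ccccc12
CCCCc1cccc2ccccc12
COc1cccc2ccccc12
CCOc1cccc2ccccc12
Nc1cccc2ccccc12
CNc1cccc2ccccc12
CN(C)c1cccc2ccccc12
Fc1cccc2ccccc12
Clc1cccc2ccccc12
Brc1cccc2ccccc12
N#Cc1cccc2ccccc12
FC(F)(F)c1cccc2ccccc12
O=C(O)c1cccc2ccccc12
COC(=O)c1cccc2ccccc12
NC(=O)c1cccc2ccccc12
CC(=O)c1cccc2ccccc12
CC(=O)Nc1cccc2ccccc12
NS(=O)(=O)c1cccc2ccccc12
OCc1cccc2ccccc12
NCCc1cccc2ccccc12
OCCc1cccc2ccccc12
Cc1ccc2ccccc2n1
CCc1ccc2ccccc2n1
CCCc1ccc2ccccc2n1
CC(C)c1ccc2ccccc2n1
CCCCc1ccc2ccccc2n1
COc1ccc2ccccc2n1
CCOc1ccc2ccccc2n1
Nc1ccc2ccccc2n1
CNc1ccc2ccccc2n1
CN(C)c1ccc2ccccc2n1
Fc1ccc2ccccc2n1
Clc1ccc2ccccc2n1
Brc1ccc2ccccc2n1
N#Cc1ccc2ccccc2n1
FC(F)(F)c1ccc2ccccc2n1
O=C(O)c1ccc2ccccc2n1
COC(=O)c1ccc2ccccc2n1
NC(=O)c1ccc2ccccc2n1
CC(=O)c1ccc2ccccc2n1
CC(=O)Nc1ccc2ccccc2n1
NS(=O)(=O)c1ccc2ccccc2n1
OCc1ccc2ccccc2n1
NCCc1ccc2ccccc2n1
OCCc1ccc2ccccc2n1
CC1CCCCC1
CCC1CCCCC1
CCCC1CCCCC1
CC(C)C1CCCCC1
CCCCC1CCCCC1
COC1CCCCC1
CCOC1CCCCC1
NC1CCCCC1
CNC1CCCCC1
CN(C)C1CCCCC1
FC1CCCCC1
ClC1CCCCC1
BrC1CCCCC1
N#CC1CCCCC1
FC(F)(F)C1CCCCC1
O=C(O)C1CCCCC1
COC(=O)C1CCCCC1
NC(=O)C1CCCCC1
CC(=O)C1CCCCC1
CC(=O)NC1CCCCC1
NS(=O)(=O)C1CCCCC1
OCC1CCCCC1
NCCC1CCCCC1
OCCC1CCCCC1
CN1CCN(C)CC1
CCN1CCN(C)CC1
CCCN1CCN(C)CC1
CC(C)N1CCN(C)CC1
CCCCN1CCN(C)CC1
CON1CCN(C)CC1
CCON1CCN(C)CC1
CN1CCN(N)CC1
CNN1CCN(C)CC1
CN1CCN(N(C)C)CC1
CN1CCN(F)CC1
CN1CCN(Cl)CC1
CN1CCN(Br)CC1
CN1CCN(C#N)CC1
CN1CCN(C(F)(F)F)CC1
CN1CCN(C(=O)O)CC1
COC(=O)N1CCN(C)CC1
CN1CCN(C(N)=O)CC1
CC(=O)N1CCN(C)CC1
CC(=O)NN1CCN(C)CC1
CN1CCN(S(N)(=O)=O)CC1
CN1CCN(CO)CC1
CN1CCN(CCN)CC1
CN1CCN(CCO)CC1
CN1CCOCC1
CCN1CCOCC1
CCCN1CCOCC1
CC(C)N1CCOCC1
CCCCN1CCOCC1
CON1CCOCC1
CCON1CCOCC1
NN1CCOCC1
CNN1CCOCC1
CN(C)N1CCOCC1
FN1CCOCC1
ClN1CCOCC1
BrN1CCOCC1
N#CN1CCOCC1
FC(F)(F)N1CCOCC1
O=C(O)N1CCOCC1
COC(=O)N1CCOCC1
NC(=O)N1CCOCC1
CC(=O)N1CCOCC1
CC(=O)NN1CCOCC1
NS(=O)(=O)N1CCOCC1
OCN1CCOCC1
NCCN1CCOCC1
CN1CCCC1
CCN1CCCC1
CCCN1CCCC1
CC(C)N1CCCC1
CCCCN1CCCC1
CON1CCCC1
CCON1CCCC1
NN1CCCC1
CNN1CCCC1
CN(C)N1CCCC1
FN1CCCC1
ClN1CCCC1
BrN1CCCC1
N#CN1CCCC1
FC(F)(F)N1CCCC1
O=C(O)N1CCCC1
COC(=O)N1CCCC1
NC(=O)N1CCCC1
CC(=O)N1CCCC1
CC(=O)NN1CCCC1
NS(=O)(=O)N1CCCC1
OCN1CCCC1
NCCN1CCCC1
OCCN1CCCC1
Cc1ccc(-c2ccccc2)cc1
CCc1ccc(-c2ccccc2)cc1
CCCc1ccc(-c2ccccc2)cc1
CC(C)c1ccc(-c2ccccc2)cc1
CCCCc1ccc(-c2ccccc2)cc1
COc1ccc(-c2ccccc2)cc1
CCOc1ccc(-c2ccccc2)cc1
Nc1ccc(-c2ccccc2)cc1
CNc1ccc(-c2ccccc2)cc1
CN(C)c1ccc(-c2ccccc2)cc1
Fc1ccc(-c2ccccc2)cc1
Clc1ccc(-c2ccccc2)cc1
Brc1ccc(-c2ccccc2)cc1
N#Cc1ccc(-c2ccccc2)cc1
FC(F)(F)c1ccc(-c2ccccc2)cc1
O=C(O)c1ccc(-c2ccccc2)cc1
COC(=O)c1ccc(-c2ccccc2)cc1
NC(=O)c1ccc(-c2ccccc2)cc1
CC(=O)c1ccc(-c2ccccc2)cc1
CC(=O)Nc1ccc(-c2ccccc2)cc1
NS(=O)(=O)c1ccc(-c2ccccc2)cc1
OCc1ccc(-c2ccccc2)cc1
NCCc1ccc(-c2ccccc2)cc1
OCCc1ccc(-c2ccccc2)cc1
CCCOc1ccccc1
CC(C)Oc1ccccc1
CCCCOc1ccccc1
COOc1ccccc1
CCOOc1ccccc1
NOc1ccccc1
CNOc1ccccc1
CN(C)Oc1ccccc1
FOc1ccccc1
ClOc1ccccc1
BrOc1ccccc1
N#COc1ccccc1
FC(F)(F)Oc1ccccc1
O=C(O)Oc1ccccc1
COC(=O)Oc1ccccc1
NC(=O)Oc1ccccc1
CC(=O)Oc1ccccc1
CC(=O)NOc1ccccc1
NS(=O)(=O)Oc1ccccc1
OCOc1ccccc1
NCCOc1ccccc1
OCCOc1ccccc1
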