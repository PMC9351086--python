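smiles,node_types
Cc1cccc(C(=O)O)c1N,Sc;Zn;Co;Ge
CCc1ccc(-c2ccn[nH]2)cn1,Cr;V;Ge
CCc1c(C#N)c[nH]c1O,Ti;Ga;Ni;Ge;Ge
COc1n[nH]cc1-c1[nH]ncc1C(=O)O,Cr;Cr;Zn;Ni;Ge
CC(=O)Nc1nc(NC(C)=O)c(C#N)[nH]1,Mn;Co;Co;Ni;Ni;Ni;Ge;Ge;Ge
O=C1CC(C(=O)O)(c2nnn[nH]2)C(=O)N1,Fe;Zr;Zn;Ni;Ni
NCCC1CCC(C2CCOCC2)CC1,Tc;Ru;Cu;Ge
CC(=O)NC1(F)OCCCC1CCN,Tc;Cu;Co;Ni;Ge;Ge;Ge
CC1CCNCC1c1nnn[nH]1,Fe;Y;Ge
CC(=O)NC1C(=O)NCC1(O)F,Mo;Ga;Co;Ni;Ni;Ge;Ge
CCC1OCC(C(=O)O)NC1=O,Nb;Zn;Ni;Ge
CC(=O)NC1C(=O)NC(=O)C1(F)CCN,Zr;Cu;Co;Ni;Ni;Ni;Ge;Ge;Ge
CC(=O)Nc1ccccc1,Sc;Co;Ni;Ge
COc1cc(C(=O)O)ncc1CCN,V;Cu;Zn;Ni;Ge;Ge
N#Cc1[nH]cnc1-c1c[nH]c(N)c1,Mn;Ti;Co;Ni;Ge
N#Cc1n[nH]c(CCN)c1C#N,Cr;Cu;Ni;Ni;Ge;Ge;Ge
CC1CC(O)CC(c2cnc[nH]2)N1,Mn;Y;Ga;Ge
Fc1nnn[nH]1,Fe;Ge
CC1CCCCC1,Ru;Ge
NCCC1CCCCO1,Tc;Cu;Ge
N#CC1CCCNC1,Y;Ni;Ge
CCC1NC(=O)C(O)C1C(=O)O,Mo;Zn;Ga;Ni;Ge
CCC1(C)NC(=O)COC1OC,Nb;Ni;Ni;Ge;Ge;Ge
COC1CC(=O)NC1=O,Zr;Ni;Ni;Ni;Ge
N#Cc1cccc(-c2nc[nH]c2N)c1C(=O)O,Mn;Sc;Zn;Co;Ni;Ge
Cc1ccncc1,V;Ge
CCc1c(C)c[nH]c1F,Ti;Ge;Ge;Ge
Cc1cn[nH]c1C(=O)O,Cr;Zn;Ge
COc1c(F)ccc(-c2cnc[nH]2)c1N,Mn;Sc;Co;Ni;Ge;Ge
CCc1nnn[nH]1,Fe;Ge
CCC1CCC(C#N)C(CCN)(C2CCCCC2)C1,Ru;Ru;Cu;Ni;Ge;Ge;Ge
N#CC1CCCCO1,Tc;Ni;Ge
CC(=O)NC1CCCNC1,Y;Co;Ni;Ge
CCC1(c2cc[nH]c2)CCC(=O)N1,Ti;Mo;Ni;Ge
O=C1NCC(C(=O)O)OC1F,Nb;Zn;Ni;Ge
O=C1CC(O)C(=O)N1,Zr;Ga;Ni;Ni
O=C(O)c1ccccc1,Sc;Zn
CC(=O)Nc1cccc(NC(C)=O)n1,V;Co;Co;Ni;Ni;Ge;Ge
COc1[nH]c(N)cc1C#N,Ti;Co;Ni;Ni;Ge;Ge
CCc1cn[nH]c1,Cr;Ge
CC(=O)Nc1[nH]c(O)nc1N,Mn;Ga;Co;Co;Ni;Ge
NCCc1nnn[nH]1,Fe;Cu;Ge
COC1CCCCC1,Ru;Ni;Ge
Oc1nc(C2CCOCC2O)c[nH]1,Mn;Tc;Ga;Ga
CCC1OC(C2(C#N)CCCC(C(=O)O)N2)CNC1=O,Y;Nb;Zn;Ni;Ni;Ge;Ge
CC(=O)NC1CNC(=O)C1,Mo;Co;Ni;Ni;Ge
CC1COC(CCN)C(=O)N1,Nb;Cu;Ni;Ge;Ge
CC1CC(=O)NC1=O,Zr;Ni;Ni;Ge
CCc1ccc(NC(C)=O)c(N)c1,Sc;Co;Co;Ni;Ge;Ge
Nc1cncc(C(=O)O)c1N,V;Zn;Co;Co
Oc1[nH]ccc1-c1nnn[nH]1,Fe;Ti;Ga
Cc1cn[nH]c1-c1ccc[nH]1,Cr;Ti;Ge
CC1CCC(c2c[nH]cn2)OC1,Mn;Tc;Ge
Nc1nnn[nH]1,Fe;Co
N#CC1CCCC(CCN)C1,Ru;Cu;Ni;Ge;Ge
O=C1CC(O)(C2CCCCO2)CN1,Mo;Tc;Ga;Ni
CC1CNCC(C)(C(=O)O)C1,Y;Zn;Ge;Ge
COc1[nH]nc(C2(OC)CNC(=O)C2)c1CCN,Cr;Mo;Cu;Ni;Ni;Ni;Ge;Ge;Ge
CCC1(C2NC(=O)C(C#N)C2C(=O)O)COCC(=O)N1,Nb;Mo;Zn;Ni;Ni;Ni;Ge;Ge
CC1C(=O)NC(=O)C1(C#N)CCN,Zr;Cu;Ni;Ni;Ni;Ge;Ge;Ge
COc1ccc(OC)c(C)c1,Sc;Ni;Ni;Ge;Ge;Ge
CCc1cccnc1,V;Ge
NCCc1cc[nH]c1,Ti;Cu;Ge
Nc1n[nH]cc1F,Cr;Co;Ge
Fc1cnc[nH]1,Mn;Ge
CCC1CC(c2nnn[nH]2)C(CCN)OC1CC,Fe;Tc;Cu;Ge;Ge;Ge
NCCC1(C(=O)O)CCCCC1,Ru;Cu;Zn;Ge
Cc1c[nH]c(C2CCCOC2C(=O)O)c1,Ti;Tc;Zn;Ge
CCC1NCCC(O)C1C,Y;Ga;Ge;Ge
CC(=O)Nc1cc(C2CCC(=O)N2)c(C)cn1,V;Mo;Co;Ni;Ni;Ge;Ge
NCCC1OCC(c2cc(N)n[nH]2)NC1=O,Cr;Nb;Cu;Co;Ni;Ge
COC1C(=O)NC(=O)C1OC,Zr;Ni;Ni;Ni;Ni;Ge;Ge
Cc1ccccc1,Sc;Ge
COc1cnc(CCN)cc1OC,V;Cu;Ni;Ni;Ge;Ge;Ge
CCc1c[nH]cc1N,Ti;Co;Ge
CC(=O)Nc1cn[nH]c1,Cr;Co;Ni;Ge
CC(=O)NC1(c2ncc[nH]2)OCCNC1=O,Mn;Nb;Co;Ni;Ni;Ge
N#Cc1nnn[nH]1,Fe;Ni;Ge
CC(=O)NC1CCCC(CCN)C1C,Ru;Cu;Co;Ni;Ge;Ge;Ge
COC1(C2CNC(=O)CO2)CCC(NC(C)=O)C(O)O1,Nb;Tc;Ga;Co;Ni;Ni;Ni;Ge;Ge
COC1CCC(C)CN1,Y;Ni;Ge;Ge
O=C1NC(C(=O)O)CC1F,Mo;Zn;Ni;Ge
O=C1COCC(O)N1,Nb;Ga;Ni
CCC1(C)C(=O)NC(=O)C1NC(C)=O,Zr;Co;Ni;Ni;Ni;Ge;Ge;Ge
COc1cc(-c2ncc[nH]2)c(F)cc1O,Mn;Sc;Ga;Ni;Ge;Ge
CCc1ccncc1,V;Ge
Fc1cc[nH]c1,Ti;Ge
CCc1[nH]nc(C#N)c1F,Cr;Ni;Ge;Ge;Ge
Cc1c[nH]cn1,Mn;Ge
n1n[nH]c(-c2nnn[nH]2)n1,Fe;Fe
N#CC1(c2nnn[nH]2)CCCCC1,Fe;Ru;Ni;Ge
OC1CCCOC1,Tc;Ga
CC1CCC(O)CN1,Y;Ga;Ge
CCc1[nH]cc(C2(C(=O)O)CNC(=O)C2)c1N,Ti;Mo;Zn;Co;Ni;Ge
CCC1OCC(F)(CC)NC1=O,Nb;Ni;Ge;Ge;Ge
CC(=O)NC1(O)C(=O)NC(=O)C1C(=O)O,Zr;Zn;Ga;Co;Ni;Ni;Ni;Ge
CCc1ccc(N)c(NC(C)=O)c1,Sc;Co;Co;Ni;Ge;Ge
Oc1ncc(F)c(O)c1-c1ccccn1,V;V;Ga;Ga;Ge
N#Cc1cc[nH]c1,Ti;Ni;Ge
COc1n[nH]c(NC(C)=O)c1C,Cr;Co;Ni;Ni;Ge;Ge;Ge
Nc1nc(C2CCCCC2)c(N)[nH]1,Mn;Ru;Co;Co
CC(=O)Nc1nnn[nH]1,Fe;Co;Ni;Ge
CC(=O)NC1CC(C2CCCCC2)CCN1,Y;Ru;Co;Ni;Ge
O=C(O)C1CCCOC1,Tc;Zn
O=C(O)C1CCNCC1,Y;Zn
CC1CCNC1=O,Mo;Ni;Ge
CCC1NC(=O)COC1(O)C#N,Nb;Ga;Ni;Ni;Ge;Ge
N#CC1C(=O)NC(=O)C1(O)F,Zr;Ga;Ni;Ni;Ni;Ge;Ge
Nc1ccccc1,Sc;Co
N#Cc1ccnc(O)c1,V;Ga;Ni;Ge
Cc1ccc[nH]1,Ti;Ge
N#Cc1n[nH]cc1C1CCC(C#N)NC1C#N,Cr;Y;Ni;Ni;Ni;Ge;Ge;Ge
Cc1cnc(F)[nH]1,Mn;Ge;Ge
NCCC1OC(c2nnn[nH]2)CNC1=O,Fe;Nb;Cu;Ni;Ge
OC1CCCC(C2CCCCC2)C1,Ru;Ru;Ga
O=C(O)C1CCOCC1,Tc;Zn
CC(=O)NC1CCNC(F)(NC(C)=O)C1,Y;Co;Co;Ni;Ni;Ge;Ge;Ge
COC1(C)CC(=O)NC1CCN,Mo;Cu;Ni;Ni;Ge;Ge;Ge
O=C(O)C1OCCNC1=O,Nb;Zn;Ni
COC1(F)CC(=O)NC1=O,Zr;Ni;Ni;Ni;Ge;Ge
COc1cccc(C(=O)O)c1C,Sc;Zn;Ni;Ge;Ge
CC(=O)Nc1cncc(C)c1,V;Co;Ni;Ge;Ge
COc1cc(NC(C)=O)[nH]c1C,Ti;Co;Ni;Ni;Ge;Ge;Ge
NCCc1cn[nH]c1N,Cr;Cu;Co;Ge
CCc1[nH]cnc1C#N,Mn;Ni;Ge;Ge
O=C(O)c1[nH]nc(-c2nnn[nH]2)c1F,Fe;Cr;Zn;Ge
COC1CCCC(F)C1,Ru;Ni;Ge;Ge
COC1CCCOC1,Tc;Ni;Ge
COC1CCCCN1,Y;Ni;Ge
CCC1NC(=O)COC1C1CNC(=O)C1,Nb;Mo;Ni;Ni;Ge
CCC1NC(=O)COC1C#N,Nb;Ni;Ni;Ge;Ge
COC1(CCN)C(=O)NC(=O)C1C(=O)O,Zr;Cu;Zn;Ni;Ni;Ni;Ge;Ge
CCC1(C(=O)O)CC(C)CCC1c1ccccc1,Sc;Ru;Zn;Ge;Ge
COC1CNC(c2cccnc2)C(O)C1,V;Y;Ga;Ni;Ge
CCc1ccc[nH]1,Ti;Ge
Oc1cc[nH]n1,Cr;Ga
O=C1CC(c2ncc(O)[nH]2)C(=O)N1,Mn;Zr;Ga;Ni;Ni
COc1c(C#N)cc(NC(C)=O)nc1-c1nnn[nH]1,Fe;V;Co;Ni;Ni;Ni;Ge;Ge;Ge
COC1CCCC(NC(C)=O)C1NC(C)=O,Ru;Co;Co;Ni;Ni;Ni;Ge;Ge;Ge
CC1CCCCO1,Tc;Ge
CCC1CCNC(c2nc[nH]c2C#N)C1,Mn;Y;Ni;Ge;Ge
CC1NC(=O)C(O)(C2CC(=O)NC2=O)C1C,Zr;Mo;Ga;Ni;Ni;Ni;Ge;Ge
CCC1(C)OC(C#N)CNC1=O,Nb;Ni;Ni;Ge;Ge;Ge
O=C1CC(C(=O)O)C(=O)N1,Zr;Zn;Ni;Ni
N#Cc1ccccc1,Sc;Ni;Ge
CCc1cccnc1CCN,V;Cu;Ge;Ge
COc1c[nH]cc1CCN,Ti;Cu;Ni;Ge;Ge
COc1cc(NC(C)=O)n[nH]1,Cr;Co;Ni;Ni;Ge;Ge
Nc1c[nH]cn1,Mn;Co
Nc1cncc(-c2nnn[nH]2)c1,Fe;V;Co
COC1CCCCC1(F)CCN,Ru;Cu;Ni;Ge;Ge;Ge
CCC1CCC(F)(CCN)CO1,Tc;Cu;Ge;Ge;Ge
NCCC1CCC(C2CCCNC2)CC1,Y;Ru;Cu;Ge
CC(=O)NC1CNC(=O)C1F,Mo;Co;Ni;Ni;Ge;Ge
CCC1(c2nnn[nH]2)OCC(O)NC1=O,Fe;Nb;Ga;Ni;Ge
CC1C(=O)NC(=O)C1O,Zr;Ga;Ni;Ni;Ge
CCc1ccccc1N,Sc;Co;Ge
Fc1cccnc1,V;Ge
CC(=O)Nc1ccc(-c2cccc(O)c2O)[nH]1,Ti;Sc;Ga;Ga;Co;Ni;Ge
COC1CCCC(c2ccn[nH]2)N1,Cr;Y;Ni;Ge
O=C(O)C1OC(c2cnc[nH]2)CNC1=O,Mn;Nb;Zn;Ni
Cc1nnn[nH]1,Fe;Ge
NCCC1CCCCC1,Ru;Cu;Ge
COC1CCCCO1,Tc;Ni;Ge
CC(=O)NC1CNC(NC(C)=O)C(O)C1,Y;Ga;Co;Co;Ni;Ni;Ge;Ge
CCC1C(C#N)NC(=O)C1NC(C)=O,Mo;Co;Ni;Ni;Ni;Ge;Ge;Ge
O=C1COC(O)(F)C(c2c[nH]nc2O)N1,Cr;Nb;Ga;Ga;Ni;Ge
N#CC1CC(=O)NC1=O,Zr;Ni;Ni;Ni;Ge
Nc1ccccc1C1CCCCO1,Sc;Tc;Co
CC(=O)Nc1cnccc1-c1ccc[nH]1,Ti;V;Co;Ni;Ge
Cc1cc(CCN)[nH]c1-c1nc(O)c[nH]1,Mn;Ti;Cu;Ga;Ge;Ge
N#Cc1[nH]nc(-c2ncc(N)[nH]2)c1N,Mn;Cr;Co;Co;Ni;Ge
Nc1nc(F)c[nH]1,Mn;Co;Ge
Oc1nnn[nH]1,Fe;Ga
CC(=O)NC1CCCCC1C,Ru;Co;Ni;Ge;Ge
N#CC1CCCC(F)O1,Tc;Ni;Ge;Ge
CCC1(C)CCNC(C2CC(=O)NC2=O)C1OC,Y;Zr;Ni;Ni;Ni;Ge;Ge;Ge
O=C1CC(C(=O)O)(C(=O)O)CN1,Mo;Zn;Zn;Ni
CC(=O)NC1(C2CNC(=O)CO2)OCCC(C)C1C(=O)O,Nb;Tc;Zn;Co;Ni;Ni;Ge;Ge
CCC1(CC)C(=O)NC(=O)C1(C#N)c1nnn[nH]1,Fe;Zr;Ni;Ni;Ni;Ge;Ge;Ge
CCc1cccc(C(=O)O)c1,Sc;Zn;Ge
N#Cc1ccccn1,V;Ni;Ge
NCCc1ccc[nH]1,Ti;Cu;Ge
O=C(O)c1cc[nH]n1,Cr;Zn
NCCc1ncc[nH]1,Mn;Cu;Ge
CCc1[nH]c(CCN)nc1-c1nnn[nH]1,Mn;Fe;Cu;Ge;Ge
CCC1CCCCC1C1OCC(C#N)(C#N)NC1=O,Nb;Ru;Ni;Ni;Ni;Ge;Ge;Ge
CC(=O)Nc1ccccc1C1CCOCC1(C(=O)O)C(=O)O,Sc;Tc;Zn;Zn;Co;Ni;Ge
O=C(O)C1CCCNC1,Y;Zn
CCC1CC(O)(C#N)NC1=O,Mo;Ga;Ni;Ni;Ge;Ge
CCC1(C#N)OCC(=O)NC1c1nnn[nH]1,Fe;Nb;Ni;Ni;Ge;Ge
CCC1(C#N)CC(=O)NC1=O,Zr;Ni;Ni;Ni;Ge;Ge
O=C1CC(c2ccccc2F)C(=O)N1,Sc;Zr;Ni;Ni;Ge
COc1ccccn1,V;Ni;Ge
COC1CC(c2cc[nH]c2)CCO1,Ti;Tc;Ni;Ge
CC(=O)NC1C(=O)NCC1c1n[nH]cc1N,Cr;Mo;Co;Co;Ni;Ni;Ge
COc1nc(OC)c(C)[nH]1,Mn;Ni;Ni;Ge;Ge;Ge
COc1c(CCN)n[nH]c1-c1nnn[nH]1,Fe;Cr;Cu;Ni;Ge;Ge
CCC1CCC(OC)CC1C1(C#N)CC(=O)NC1=O,Zr;Ru;Ni;Ni;Ni;Ni;Ge;Ge;Ge
CC(=O)NC1CCOCC1c1cccnc1,V;Tc;Co;Ni;Ge
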