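ligand,receptor,insulin_effect,glucagon_effect,g_protein,value_um,min_um,max_um
ATP/ADP,P2Y,stimulatory,unknown,Gs,1,0.1,1.9
CCK,CCKA,stimulatory,stimulatory,Gq,1,0.1,1.9
Compound2,GPR142,stimulatory,unknown,Gs,0.036,0.036,0.068
Compound21,GPR142,stimulatory,unknown,Gs,0.036,0.036,0.068
Glucagon,Gcgr,stimulatory,stimulatory,"Gs, Gq",1,0.1,1.9
GLP-1,GLP-1R,stimulatory,inhibitory,Gs,1,0.1,1.9
GIP,GIPR,stimulatory,stimulatory,Gs,1,0.1,1.9
NPY,Y1,inhibitory,stimulatory,Gi,1,0.1,1.9
PACAP,PAC1,stimulatory,stimulatory,Gs,1,0.1,1.9
Ach,Ca2+/K+,stimulatory,stimulatory,Gq,1,0.1,1.9
AC,cAMP,stimulatory,modulating,Gi/o,1,0.1,1.9
PLC,IP3/PIP2/DAG,stimulatory,inhibitory,Gi,1,0.1,1.9
PKA,GPCR,modulating,inhibitory,Gq,1,0.1,1.9
cAMP,Epac,inhibitory,stimulatory,Gi,1,0.1,1.9
DAG analog,PKC,stimulatory,inhibitory,Gi,1,0.1,1.9
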