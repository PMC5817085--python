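{
  "comment": "Default pharmacophore feature definitions. Each entry maps a SMARTS pattern to a feature type (A/D/H/N/P/R) and a geometry rule: 'vector' (single atom with direction), 'point' (single match centroid), 'group' (one site per SMARTS match, centroid of 'centroid_atoms' indices into the match, else of matched heavy atoms), 'cluster' (matched atoms merged into bond-connected components, one site per component), 'ring' (ordered ring match, centroid plus plane normal). Replace this file to change the chemistry.",
  "entries": [
    {"type": "A", "smarts": "[OX1]=[#6,#7,#15,#16]", "geometry": "vector", "centroid_atoms": [0]},
    {"type": "A", "smarts": "[OX2;!$([OX2H0]([#6])[CX3]=[OX1])]", "geometry": "vector", "centroid_atoms": [0]},
    {"type": "A", "smarts": "[NX2;!$([N+]);!$(N=N)]", "geometry": "vector", "centroid_atoms": [0]},
    {"type": "A", "smarts": "[nX2;!$([n+])]", "geometry": "vector", "centroid_atoms": [0]},
    {"type": "A", "smarts": "[NX3;H0;!$([N+]);!$(N[#6,#7,#16]=[O,S,N]);!$([NX3]a)]", "geometry": "vector", "centroid_atoms": [0]},
    {"type": "D", "smarts": "[#7;!H0;!$([N-])]", "geometry": "vector", "centroid_atoms": [0]},
    {"type": "D", "smarts": "[#8;!H0;!$([O-])]", "geometry": "vector", "centroid_atoms": [0]},
    {"type": "D", "smarts": "[#16;!H0]", "geometry": "vector", "centroid_atoms": [0]},
    {"type": "N", "smarts": "[CX3](=[OX1])[OX1H0-]", "geometry": "group", "centroid_atoms": [1, 2]},
    {"type": "N", "smarts": "[SX4](=[OX1])(=[OX1])[OX1H0-]", "geometry": "group", "centroid_atoms": [1, 2, 3]},
    {"type": "N", "smarts": "[PX4](=[OX1])([OX1H0-])[OX2,OX1H0-]", "geometry": "group", "centroid_atoms": [1, 2]},
    {"type": "N", "smarts": "[O-;!$([O-][C,S,P]=O);!$([O-][SX4,PX4])]", "geometry": "point"},
    {"type": "N", "smarts": "[S-;X1]", "geometry": "point"},
    {"type": "P", "smarts": "[NX4+]", "geometry": "point"},
    {"type": "P", "smarts": "[NX3+;!$(N=*);!$([N+][O-])]", "geometry": "point"},
    {"type": "P", "smarts": "[NX3][CX3](=[NX2+])[NX3]", "geometry": "group"},
    {"type": "P", "smarts": "[NX3][CX3]=[NX2+]", "geometry": "group"},
    {"type": "H", "smarts": "[CX4;!$([CX4][#7,#8,#9,#15,#16,Cl,Br,I]);!$([CX4][#6]=[O,S,N])]", "geometry": "cluster"},
    {"type": "H", "smarts": "[Cl,Br,I;X1]", "geometry": "point"},
    {"type": "H", "smarts": "[SX2]([#6])[#6]", "geometry": "point", "centroid_atoms": [0]},
    {"type": "R", "smarts": "a1aaaaa1", "geometry": "ring"},
    {"type": "R", "smarts": "a1aaaa1", "geometry": "ring"}
  ]
}
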