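{
  "comment": "GPR142 signaling network, agonist Compound2. Concentrations in uM, time in s. Topology: ligand binding activates the receptor complex, which activates Gq and Gi. Gq-active activates PLC; PLC-active hydrolyses PIP2 into DAG + IP3 (Michaelis-Menten); DAG activates PKC; IP3 gates Ca2+ release from stores; PKC-active, cytosolic Ca2+ and PKA-active each drive secretion of the insulin granule pool into the cumulative Insulin_secreted readout. Gi-active inhibits adenylyl-cyclase cAMP synthesis (factor 1/(1+[Gi_a]/Ki)); cAMP activates PKA and Epac. Every active form deactivates first-order. Rate constants are design parameters chosen so the network reproduces the qualitative direction table (insulin up, cAMP down under Gq-dominant agonism); they are documented here, per reaction, and never hard-coded.",
  "species": [
    {"name": "Compound2", "init_um": 0.0, "compartment": "membrane"},
    {"name": "GPR142", "init_um": 0.1, "compartment": "membrane"},
    {"name": "GPR142_active", "init_um": 0.0, "compartment": "membrane"},
    {"name": "Gq", "init_um": 1.0, "compartment": "cell"},
    {"name": "Gq_a", "init_um": 0.0, "compartment": "cell"},
    {"name": "Gi", "init_um": 1.0, "compartment": "cell"},
    {"name": "Gi_a", "init_um": 0.0, "compartment": "cell"},
    {"name": "PLC", "init_um": 1.0, "compartment": "cell"},
    {"name": "PLC_a", "init_um": 0.0, "compartment": "cell"},
    {"name": "PIP2", "init_um": 10.0, "compartment": "cell"},
    {"name": "DAG", "init_um": 0.0, "compartment": "cell"},
    {"name": "IP3", "init_um": 0.0, "compartment": "cell"},
    {"name": "PKC", "init_um": 1.0, "compartment": "cell"},
    {"name": "PKC_a", "init_um": 0.0, "compartment": "cell"},
    {"name": "Ca_store", "init_um": 10.0, "compartment": "cell"},
    {"name": "Ca_cyt", "init_um": 0.05, "compartment": "cell"},
    {"name": "Granules", "init_um": 100.0, "compartment": "cell"},
    {"name": "Insulin_secreted", "init_um": 0.0, "compartment": "cell"},
    {"name": "ATP", "init_um": 100.0, "compartment": "cell"},
    {"name": "cAMP", "init_um": 0.0, "compartment": "cell"},
    {"name": "AMP", "init_um": 0.0, "compartment": "cell"},
    {"name": "AC", "init_um": 0.1, "compartment": "cell"},
    {"name": "PKA", "init_um": 1.0, "compartment": "cell"},
    {"name": "PKA_a", "init_um": 0.0, "compartment": "cell"},
    {"name": "Epac", "init_um": 1.0, "compartment": "cell"},
    {"name": "Epac_a", "init_um": 0.0, "compartment": "cell"}
  ],
  "reactions": [
    {"id": "r_bind", "reactants": [{"species": "Compound2"}, {"species": "GPR142"}],
     "products": [{"species": "GPR142_active"}], "law": {"type": "mass_action", "params": {"k": 10.0}}},
    {"id": "r_unbind", "reactants": [{"species": "GPR142_active"}],
     "products": [{"species": "Compound2"}, {"species": "GPR142"}], "law": {"type": "mass_action", "params": {"k": 0.01}}},
    {"id": "r_gq_act", "reactants": [{"species": "Gq"}], "products": [{"species": "Gq_a"}],
     "modifiers": ["GPR142_active"], "law": {"type": "mass_action", "params": {"k": 5.0}}},
    {"id": "r_gq_deact", "reactants": [{"species": "Gq_a"}], "products": [{"species": "Gq"}],
     "law": {"type": "mass_action", "params": {"k": 0.1}}},
    {"id": "r_gi_act", "reactants": [{"species": "Gi"}], "products": [{"species": "Gi_a"}],
     "modifiers": ["GPR142_active"], "law": {"type": "mass_action", "params": {"k": 5.0}}},
    {"id": "r_gi_deact", "reactants": [{"species": "Gi_a"}], "products": [{"species": "Gi"}],
     "law": {"type": "mass_action", "params": {"k": 0.1}}},
    {"id": "r_plc_act", "reactants": [{"species": "PLC"}], "products": [{"species": "PLC_a"}],
     "modifiers": ["Gq_a"], "law": {"type": "mass_action", "params": {"k": 5.0}}},
    {"id": "r_plc_deact", "reactants": [{"species": "PLC_a"}], "products": [{"species": "PLC"}],
     "law": {"type": "mass_action", "params": {"k": 0.2}}},
    {"id": "r_pip2_hydrolysis", "reactants": [{"species": "PIP2"}],
     "products": [{"species": "DAG"}, {"species": "IP3"}], "modifiers": ["PLC_a"],
     "law": {"type": "michaelis_menten", "params": {"Vm": 0.5, "Km": 5.0}}},
    {"id": "r_pkc_act", "reactants": [{"species": "PKC"}], "products": [{"species": "PKC_a"}],
     "modifiers": ["DAG"], "law": {"type": "mass_action", "params": {"k": 0.5}}},
    {"id": "r_pkc_deact", "reactants": [{"species": "PKC_a"}], "products": [{"species": "PKC"}],
     "law": {"type": "mass_action", "params": {"k": 0.1}}},
    {"id": "r_ca_release", "reactants": [{"species": "Ca_store"}], "products": [{"species": "Ca_cyt"}],
     "modifiers": ["IP3"], "law": {"type": "mass_action", "params": {"k": 0.5}}},
    {"id": "r_ca_leak", "reactants": [{"species": "Ca_store"}], "products": [{"species": "Ca_cyt"}],
     "law": {"type": "mass_action", "params": {"k": 0.005}}},
    {"id": "r_ca_reuptake", "reactants": [{"species": "Ca_cyt"}], "products": [{"species": "Ca_store"}],
     "law": {"type": "mass_action", "params": {"k": 1.0}}},
    {"id": "r_secrete_pkc", "reactants": [{"species": "Granules"}], "products": [{"species": "Insulin_secreted"}],
     "modifiers": ["PKC_a"], "law": {"type": "mass_action", "params": {"k": 0.002}}},
    {"id": "r_secrete_ca", "reactants": [{"species": "Granules"}], "products": [{"species": "Insulin_secreted"}],
     "modifiers": ["Ca_cyt"], "law": {"type": "mass_action", "params": {"k": 0.002}}},
    {"id": "r_secrete_pka", "reactants": [{"species": "Granules"}], "products": [{"species": "Insulin_secreted"}],
     "modifiers": ["PKA_a"], "law": {"type": "mass_action", "params": {"k": 0.0002}}},
    {"id": "r_camp_synth", "reactants": [{"species": "ATP"}], "products": [{"species": "cAMP"}],
     "modifiers": ["AC"], "inhibitors": [{"species": "Gi_a", "ki_um": 0.05}],
     "law": {"type": "michaelis_menten", "params": {"Vm": 1.0, "Km": 20.0}}},
    {"id": "r_camp_deg", "reactants": [{"species": "cAMP"}], "products": [{"species": "AMP"}],
     "law": {"type": "mass_action", "params": {"k": 0.1}}},
    {"id": "r_pka_act", "reactants": [{"species": "PKA"}], "products": [{"species": "PKA_a"}],
     "modifiers": ["cAMP"], "law": {"type": "mass_action", "params": {"k": 1.0}}},
    {"id": "r_pka_deact", "reactants": [{"species": "PKA_a"}], "products": [{"species": "PKA"}],
     "law": {"type": "mass_action", "params": {"k": 0.1}}},
    {"id": "r_epac_act", "reactants": [{"species": "Epac"}], "products": [{"species": "Epac_a"}],
     "modifiers": ["cAMP"], "law": {"type": "mass_action", "params": {"k": 1.0}}},
    {"id": "r_epac_deact", "reactants": [{"species": "Epac_a"}], "products": [{"species": "Epac"}],
     "law": {"type": "mass_action", "params": {"k": 0.1}}}
  ],
  "readouts": ["Insulin_secreted", "cAMP"]
}
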