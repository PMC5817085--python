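{
  "comment": "Gi-only signaling fixture (NPY acting on the Y1 receptor). The ligand-bound receptor activates Gi only; Gi-active inhibits adenylyl-cyclase cAMP synthesis, cAMP activates PKA, and PKA-active drives granule secretion. With no Gq branch, agonist exposure lowers cAMP and hence insulin secretion (inhibitory direction). Units: uM, s.",
  "species": [
    {"name": "NPY", "init_um": 0.0, "compartment": "membrane"},
    {"name": "Y1", "init_um": 0.1, "compartment": "membrane"},
    {"name": "Y1_active", "init_um": 0.0, "compartment": "membrane"},
    {"name": "Gi", "init_um": 1.0, "compartment": "cell"},
    {"name": "Gi_a", "init_um": 0.0, "compartment": "cell"},
    {"name": "ATP", "init_um": 100.0, "compartment": "cell"},
    {"name": "cAMP", "init_um": 0.0, "compartment": "cell"},
    {"name": "AMP", "init_um": 0.0, "compartment": "cell"},
    {"name": "AC", "init_um": 0.1, "compartment": "cell"},
    {"name": "PKA", "init_um": 1.0, "compartment": "cell"},
    {"name": "PKA_a", "init_um": 0.0, "compartment": "cell"},
    {"name": "Granules", "init_um": 100.0, "compartment": "cell"},
    {"name": "Insulin_secreted", "init_um": 0.0, "compartment": "cell"}
  ],
  "reactions": [
    {"id": "r_bind", "reactants": [{"species": "NPY"}, {"species": "Y1"}],
     "products": [{"species": "Y1_active"}], "law": {"type": "mass_action", "params": {"k": 10.0}}},
    {"id": "r_unbind", "reactants": [{"species": "Y1_active"}],
     "products": [{"species": "NPY"}, {"species": "Y1"}], "law": {"type": "mass_action", "params": {"k": 0.01}}},
    {"id": "r_gi_act", "reactants": [{"species": "Gi"}], "products": [{"species": "Gi_a"}],
     "modifiers": ["Y1_active"], "law": {"type": "mass_action", "params": {"k": 5.0}}},
    {"id": "r_gi_deact", "reactants": [{"species": "Gi_a"}], "products": [{"species": "Gi"}],
     "law": {"type": "mass_action", "params": {"k": 0.1}}},
    {"id": "r_camp_synth", "reactants": [{"species": "ATP"}], "products": [{"species": "cAMP"}],
     "modifiers": ["AC"], "inhibitors": [{"species": "Gi_a", "ki_um": 0.05}],
     "law": {"type": "michaelis_menten", "params": {"Vm": 1.0, "Km": 20.0}}},
    {"id": "r_camp_deg", "reactants": [{"species": "cAMP"}], "products": [{"species": "AMP"}],
     "law": {"type": "mass_action", "params": {"k": 0.1}}},
    {"id": "r_pka_act", "reactants": [{"species": "PKA"}], "products": [{"species": "PKA_a"}],
     "modifiers": ["cAMP"], "law": {"type": "mass_action", "params": {"k": 1.0}}},
    {"id": "r_pka_deact", "reactants": [{"species": "PKA_a"}], "products": [{"species": "PKA"}],
     "law": {"type": "mass_action", "params": {"k": 0.1}}},
    {"id": "r_secrete_pka", "reactants": [{"species": "Granules"}], "products": [{"species": "Insulin_secreted"}],
     "modifiers": ["PKA_a"], "law": {"type": "mass_action", "params": {"k": 0.0002}}}
  ],
  "readouts": ["Insulin_secreted", "cAMP"]
}
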