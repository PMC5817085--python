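# pharmkin

Ligand-based pharmacophore modelling and signaling-network kinetics for
GPR142 agonist discovery in type 2 diabetes research.

GPR142 is an orphan class-A GPCR expressed in pancreatic β-cells whose
agonism enhances glucose-dependent insulin secretion. `pharmkin` implements
the two computational procedures such a discovery campaign rests on:

1. **Common-pharmacophore hypothesis generation and 3D database matching.**
   Active ligands are reduced to typed pharmacophore sites — Acceptor (A),
   Donor (D), Hydrophobic (H), Negative (N), Positive (P), Aromatic ring
   (R) — as points, vectors and groups.  Site arrangements (*variants*,
   e.g. `ADPRR`) common to a required number of actives are discovered via
   binned inter-site distance profiles, aligned by least-squares
   superposition, and ranked by the survival score

   S = W_site·S_site + W_vec·S_vec + W_vol·S_vol + W_sel·S_sel + W_rew·m

   with S_site the alignment score, S_vec the mean cosine of paired vector
   features, S_vol the volume-overlap score, S_sel a selectivity term
   (weight 0 by default) and m the number of matching actives minus one.
   Hypotheses are filtered at max pairwise RMSD < 1.20 Å and vector score
   > 0.50, then used to search a conformer database (≤ 100 conformers per
   structure) on inter-site distances and site types, ranking hits by a
   fitness score in [0, 3].

2. **An ODE model of the GPR142 signaling network.**  Agonist binding
   activates Gq and Gi.  Gq-active drives PLC-catalysed PIP2 hydrolysis
   into DAG and IP3 (irreversible Michaelis–Menten, V = Vm·S/(Km+S)); DAG
   activates PKC, IP3 gates Ca²⁺ mobilisation, and PKC/Ca²⁺ drive insulin
   granule secretion.  Gi-active inhibits adenylyl cyclase, lowering cAMP
   and its PKA/Epac arm (all other steps mass action, V = k·∏Sᵢ;
   concentrations in μM).  The model predicts the direction of insulin and
   cAMP responses to agonist dosing and round-trips through SBML L3V1.

A synthetic-data module generates every input with known ground truth
(planted pharmacophores among decoys, activity tables, noisy kinetic
trajectories), and a contact-annotation utility emits per-residue
hydrogen-bond/hydrophobic interaction tables from receptor–ligand PDB
coordinates.

## Worked example

```python
import numpy as np
from pharmkin import (PlantSpec, ThresholdScheme, plant_pharmacophore,
                      generate_hypotheses, build_screen_db, match_hypothesis,
                      load_fixture, classify_effect, load_effect_table)

# 10 actives carrying a planted ADPRR pharmacophore (0.1 Å jitter) + 20 decoys
actives, decoys, activity, truth = plant_pharmacophore(PlantSpec(seed=0))
scheme = ThresholdScheme(0.036, 0.001, min_match=10)
scored = generate_hypotheses(actives + decoys,
                             list(zip(activity.compound_id, activity.ec50_um)),
                             scheme)
best = scored[0]
print(best.hypothesis.variant, round(best.score.survival, 3),
      round(best.score.s_site, 3), round(best.score.s_vec, 3))
# ADPRR 11.762 0.931 0.98

hits = match_hypothesis(build_screen_db(decoys), best.hypothesis, dist_tol=1.0)
print(len(hits))        # 0 — random decoys do not match the planted geometry

model = load_fixture()  # bundled GPR142 network, agonist Compound2
entry = {e.ligand: e for e in load_effect_table()}["Compound2"]
print(classify_effect(model, entry))   # stimulatory
stim = model.with_initial("Compound2", 0.036).simulate()
base = model.simulate()
print(round(stim.final("Insulin_secreted") / base.final("Insulin_secreted"), 2),
      round(stim.final("cAMP") / base.final("cAMP"), 3))
# 6.56 0.083  — insulin rises ~6.6-fold while cAMP falls to ~8% of baseline
```

The recovered variant is the planted `ADPRR`; its survival score decomposes
into a site score near 0.93 (tight superposition of all ten actives), a
vector score near 0.98, a volume overlap near 0.85 and a matches reward of
9 (ten matching actives).  On the kinetics side the agonist raises the
cumulative insulin readout while suppressing cAMP — the Gq-dominant
direction pattern with simultaneous Gi engagement.

A CLI mirrors the library (`pharmkin perceive / hypothesize / match /
simulate / dose-scan / classify / synth / contacts`); run
`pharmkin --help`.

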