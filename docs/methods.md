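# Methods

## Scope and representation

The package operates on an abstract *site set*: per conformer, a list of
typed pharmacophore sites (A/D/H/N/P/R) given as 3D points, optionally with
a unit direction vector.  Ring (R) sites always carry their plane normal;
H/N/P sites never carry a direction; A/D sites may.  Chemistry perception
(RDKit over a SMARTS table) is an adapter producing site sets; everything
downstream — discovery, scoring, database matching — is chemistry-free, so
the geometric pipeline is testable without a toolkit and users can supply
site sets from any perception software.

The shipped SMARTS table (`data/smarts_default.json`) is a documented
default, not a reconstruction of any proprietary feature set: donors are
N/O/S-H (one vector per hydrogen, heavy atom through H); acceptors are
carbonyl/ether oxygens and sp2/aromatic nitrogens with the lone-pair axis
approximated as the outward direction away from the bonded-neighbour
centroid; negatives are carboxylate/sulfonate/phosphonate groups placed at
their terminal-oxygen centroid; positives are protonated amines and
guanidinium/amidinium groups; hydrophobes are bond-connected components of
apolar carbons (one site per contiguous patch) plus halogens and
thioethers; rings are 5/6-membered aromatics with a Newell plane normal
whose sign follows the ring atom order (hence co-rotates with the
coordinates).  The table is a config file the user can replace wholesale.

## Hypothesis discovery

Compounds are partitioned by EC50 thresholds.  The default comparator
follows the source data sets literally ("active above 0.036"), although
EC50 semantics would suggest the opposite direction; because the intent is
ambiguous the comparator is a configurable field (`direction`) of
`ThresholdScheme` rather than a silent correction.  The three published
scheme presets (high/medium/low affinity) ship as constants.

Variants are sorted type multisets of size 4–7 by default (the published
site-count bounds).  For each variant, discovery enumerates every k-site
subset of each active's best conformer (the first conformer per molecule
in input order, by convention the minimum-energy one) and summarises it by
a canonical binned inter-site distance profile: the sorted multiset of
(type-pair, floor(d / 1.0 Å)) over all site pairs.  Two profiles are
compatible when, per type-pair group, sorted bins differ by at most one —
neighbour-bin probing that removes boundary sensitivity at negligible
cost.  A subset shared by at least `min_match` actives becomes a
hypothesis.  This profile comparison is a deliberate simplification: it is
invariant under rigid motion and site relabelling and is exhaustively
checked against naive enumeration in the tests, but, like any distance-bin
hash, it can in principle admit chirality-mirrored or distance-coincident
false positives; the subsequent alignment scoring demotes those.

## Survival scoring

S = W_site·S_site + W_vec·S_vec + W_vol·S_vol + W_sel·S_sel + W_rew·reward(m),
default weights 1, 1, 1, 0, 1.

* **S_site** — each matching active is superposed onto the hypothesis
  (Kabsch, proper rotations only; the minimum-RMSD type-preserving pairing
  is chosen).  The score is the mean of max(0, 1 − RMSD/2.0 Å): no mapping
  from alignment RMSD to [0, 1] is published, and a linear ramp with a
  2 Å cutoff is the simplest monotone choice.
* **S_vec** — mean cosine between corresponding direction vectors after
  rotation, clipped to [0, 1].  Ring normals compare by absolute cosine (a
  ring plane is invariant under normal flip).  With no vector features the
  score is vacuously 1.
* **S_vol** — mean pairwise Jaccard overlap of the aligned actives'
  site-sphere volumes: 1.7 Å spheres on a 0.25 Å voxel grid.  The abstract
  representation has no atoms, so feature-centred spheres stand in for the
  heavy-atom van der Waals model.
* **S_sel** — −log10 of the fraction of a supplied background set matching
  the hypothesis, floored at 0 and capped at 5 when nothing matches;
  inert under the default weight 0.
* **reward(m)** — m (matching actives minus one) in the default `linear`
  mode, matching the published equation term W_rew·m; a `unit` mode
  (min(m, 1)) is also provided because the published best-score
  decomposition implies a ≈1.0 matches contribution.  Reconstructing the
  published decomposition (0.71 + 0.912 + 0.604 + 1.000 = 3.226) differs
  from the printed 3.224 total by 0.002; the exact reward functional form
  is not disclosed, so the acceptance check uses a ±0.01 tolerance.

Filtering retains hypotheses with max pairwise alignment RMSD strictly
below 1.20 Å and vector score strictly above 0.50 (the published
thresholds), sorted by survival, ties broken by site score then variant.

**Parsimony rule.** The pipeline drops a hypothesis whose variant is a
strict sub-multiset of another discovered variant with at least as many
matched actives.  A k-site arrangement common to all actives makes every
(k−1)-subset common too, and the fragment aligns marginally *better*
(fewer constraints), so without this rule fragments tie or beat the full
arrangement.  The most specific common pharmacophore is the scientifically
meaningful one; fragments carry no additional information.

## Database matching

The screening database holds all conformers (cap 100 per structure, and
10 per rotatable bond when rotatable-bond counts are supplied — the
abstract representation has no bonds, so that cap applies only through the
chemistry adapter).  A per-type-pair sorted-distance index prunes
conformers that cannot contain some hypothesis pair distance within
tolerance; the condition is necessary, never sufficient, so indexed
matching returns exactly the brute-force match set (asserted in tests).
Surviving conformers are searched by backtracking over type-preserving
assignments requiring every inter-site distance within `dist_tol` (default
2.0 Å — distance matching is published without a tolerance, so it is an
exposed parameter).  Matches score

fitness = max(0, 1 − RMSD/dist_tol) + clip(vec_cos, 0, 1) + clip(vol_jaccard, 0, 1) ∈ [0, 3]

(no fitness formula is published; this mirrors the survival components at
per-ligand level).  The best conformer per molecule is kept; ties break by
lower RMSD then molecule id.  The published hit list is cut "by number"
without stating the cutoff, so `top_n` is a user parameter.

## Kinetic model

Deterministic ODEs dC/dt = N·v(C) over μM concentrations; LSODA with
rtol 1e-9 / atol 1e-12 defaults (halving the tolerances moves readouts by
< 1e-6 relative; stoichiometric conservation then holds to ~1e-13 μM,
comfortably under the 1e-8 μM acceptance bound).  Output concentrations
are floored at zero; the pre-floor minimum is reported in `solver_stats`
and stays above −1e-9 μM.  Steady state is flagged when ‖dC/dt‖∞ <
1e-9 μM/s at the horizon.

Rate laws: irreversible Michaelis–Menten V = Vm·[E]·S/(Km+S) with [E] the
product of modifier concentrations (Vm is then per unit catalyst), and
mass action V = k·∏Sᵢ^nᵢ, likewise modifier-multiplied.  Inhibition is
the minimal saturating factor 1/(1 + [I]/Ki) — used for Gi-active bound to
adenylyl cyclase, where only the binding, not a law, is published.

The bundled GPR142 fixture encodes: reversible agonist binding
(ligand + receptor ⇌ active complex); complex-catalysed Gq and Gi
activation; Gq-active → PLC activation; PLC-active-catalysed PIP2 → DAG +
IP3 (Michaelis–Menten, the reaction used for parameter-recovery studies);
DAG → PKC activation; IP3-gated Ca²⁺ release from stores with first-order
reuptake and a small constitutive leak (setting the basal Ca²⁺ tone);
PKC-active-, Ca²⁺- and PKA-active-driven secretion of a 100 μM insulin
granule pool into a cumulative `Insulin_secreted` sink; Gi-inhibited
AC-catalysed ATP → cAMP with first-order cAMP degradation; cAMP-driven
PKA and Epac activation; and first-order deactivation of every active
form.  The readout is the cumulative secreted insulin at t = 600 s —
monotone and insensitive to oscillation phase.  No rate constants are
published; the fixture's values are design parameters chosen once so that
the printed direction table reproduces (insulin up, cAMP down for the
Gq+Gi agonist; insulin down for the Gi-only ligand), documented reaction
by reaction in the JSON and never hard-coded.  The directions are robust
to ±20 % perturbation of every constant.  The PKA arm of secretion is an
order of magnitude weaker than the PKC/Ca²⁺ arms, which is what makes the
network Gq-dominant and produces the published insulin/cAMP dissociation.

The published effect table lists the two test agonists under G_s while the
accompanying text argues Gq+Gi signaling; the bundled CSV mirrors the
printed table verbatim and the fixtures follow the text.  Glucagon-side
effects are stored in the table but not modelled (the network has no
glucagon branch).  The published dose wording ("optimum concentration …
0.036 μM") could mean a biphasic curve peaking there or simply the chosen
test dose; the default fixture is monotone over the printed 0.036–0.068 μM
range, which the dose-scan property asserts.

SBML L3V1 export writes explicit kinetic-law MathML with local parameters;
law types travel as SBO terms (28 Michaelis–Menten, 12 mass action),
modifier roles as SBO 13 (catalyst) / 20 (inhibitor, with `Ki_<species>`
local parameter), and readouts in the model notes, so import reconstructs
a structurally identical model and the round-trip simulation matches to
machine precision.

## Synthetic data

`plant_pharmacophore` places k typed sites (pairwise separation ≥ 2 Å)
inside an 8 Å cube, then gives each active a random proper rotation, a
random translation within the 20 Å box, i.i.d. Gaussian positional noise
(default σ = 0.1 Å, also applied to direction vectors before
renormalisation), and 0–3 random extra sites near the planted centroid.
Decoys carry the same type multiset uniformly in the box.  EC50 values are
drawn so the high-affinity scheme labels actives (0.036–0.93 μM, the
published active range) and decoys (10⁻⁴–10⁻³ μM) correctly.  Noise is
positional, not torsional — the abstract representation has no bonds, and
positional noise tests the geometric pipeline directly.  What the
generator does *not* emulate: real conformational flexibility,
property-matched decoys (DUD-E style), or perception noise; passing
recovery tests therefore demonstrates the geometric discovery/scoring
machinery, not robustness to medicinal-chemistry confounders.

`generate_trajectories` applies multiplicative Gaussian noise to a clean
simulation; `fit_parameters` minimises relative residuals (with a 5 %
per-species floor so near-zero early samples do not dominate) over
log-parameters — rate constants span decades and must stay positive —
with 5 seeded multi-starts (first start at the model's current values).
Non-convergence on all starts is flagged, not raised.  Recovery studies
use the full GPR142 fixture observing PIP2/DAG/IP3 at 40 time points over
200 s (the window in which PIP2 hydrolysis actually progresses), a size
chosen to keep the 10-seed study inexpensive while leaving both
parameters identifiable.

## Contact annotation

PDB complexes are parsed with Biopython; the ligand is selected by residue
name or chain id, and elements missing from the element column are
inferred from atom names.  Hydrogen bonds use heavy-atom distance ≤ 3.5 Å
with D–H···A angle ≥ 120°; when the structure carries no explicit
hydrogens at all, polar–polar interface pairs within the distance cutoff
are reported once per pair with a `no-H` flag (requiring hydrogens that
deposited coordinates do not contain would report nothing).  Hydrophobic
contacts are apolar C/S pairs within 4.5 Å, with polar-adjacent carbons
excluded via a 1.9 Å covalent-distance heuristic, aggregated per receptor
residue.  All cutoffs are standard field values exposed as parameters.
No "strong" versus ordinary hydrogen-bond tiering is attempted — no
criterion for the distinction is published.  The module reproduces the
*style* of published interaction tables on user-supplied coordinates; the
original docking poses are not deposited, so their values are not
reproducible.

## Problem sizes and determinism

Recovery studies use 20 seeded replicates of 10 actives + 20 decoys;
oracle-equivalence checks use 100 random instances with ≤ 8 sites per
conformer; direction-robustness uses 20 perturbation draws; parameter
recovery uses 10 seeds × 5 starts.  Every stochastic component takes an
explicit seed and is a pure function of it.

## Known limitations

* Distance-profile discovery is not chirality-aware before alignment.
* The survival and fitness RMSD ramps (2.0 Å cutoff, dist_tol
  normalisation) are design choices, not published constants.
* The kinetic fixture is a direction-calibrated minimal network, not a fit
  to islet data; absolute concentrations and time courses are not
  predictive.
* Conformer generation, tautomer/protonation enumeration and conformational
  energy windows are upstream concerns: a conformer set's 10 kcal/mol
  relative-energy filter is treated as a property of the input, never
  recomputed.
* No spatial compartments, stochastic (Gillespie) dynamics, or glucagon
  secretion modelling.
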