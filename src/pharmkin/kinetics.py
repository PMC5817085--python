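"""ODE kinetics of the GPR142 signaling network.

The model is a deterministic reaction network ``dC/dt = N v(C)`` over
species concentrations in micromolar.  Two rate laws are supported:

* irreversible Michaelis-Menten, ``v = Vm [E] S / (Km + S)`` with ``S`` the
  single substrate and ``[E]`` the product of modifier (catalyst)
  concentrations (1 when there is none; ``Vm`` is then per unit catalyst,
  uM s^-1 per uM);
* mass action, ``v = k prod_i S_i^n_i`` times the product of modifier
  concentrations.

Either law is attenuated by ``prod_j 1 / (1 + [I_j]/Ki_j)`` over declared
inhibitors — the minimal saturating form for, e.g., Gi-bound adenylyl
cyclase.

The bundled fixture ``data/gpr142_network.json`` wires agonist binding to
GPR142, Gq and Gi activation by the ligand-receptor complex, PLC-catalysed
PIP2 hydrolysis into DAG and IP3, DAG-driven PKC activation, IP3-gated
Ca2+ mobilisation, PKC/Ca2+/PKA-driven secretion of an insulin granule pool
into a cumulative ``Insulin_secreted`` readout, Gi-inhibited cAMP synthesis
by adenylyl cyclase, and cAMP-driven PKA and Epac activation, with
first-order deactivation of every active form.  All rate constants live in
the JSON, never in code.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

DEFAULT_T_END = 600.0  # s
DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-12
STEADY_STATE_TOL = 1e-9  # uM/s, max |dC/dt| threshold


class ModelError(ValueError):
    """Invalid network specification."""


def mm_rate(Vm: float, Km: float, S: float) -> float:
    """Irreversible Michaelis-Menten rate ``Vm S / (Km + S)`` (uM/s)."""
    if Vm <= 0 or Km <= 0:
        raise ValueError("Vm and Km must be positive")
    if S < 0:
        raise ValueError("substrate concentration must be non-negative")
    return Vm * S / (Km + S)


def mass_action_rate(k: float, substrate_concs) -> float:
    """Mass-action rate ``k prod_i S_i`` (empty product = 1)."""
    if k <= 0:
        raise ValueError("rate constant must be positive")
    rate = k
    for s in substrate_concs:
        if s < 0:
            raise ValueError("concentrations must be non-negative")
        rate *= s
    return rate


@dataclass(frozen=True)
class Species:
    name: str
    init_um: float
    compartment: str = "cell"

    def __post_init__(self) -> None:
        if self.init_um < 0:
            raise ModelError(f"initial concentration of {self.name} must be >= 0")


@dataclass
class KineticLaw:
    law_type: str  # michaelis_menten | mass_action
    params: dict[str, float]
    modifiers: list[str] = field(default_factory=list)
    inhibitors: dict[str, float] = field(default_factory=dict)  # species -> Ki (uM)

    def __post_init__(self) -> None:
        if self.law_type == "michaelis_menten":
            required = {"Vm", "Km"}
        elif self.law_type == "mass_action":
            required = {"k"}
        else:
            raise ModelError(f"unknown law type {self.law_type!r}")
        missing = required - self.params.keys()
        if missing:
            raise ModelError(f"{self.law_type} law missing parameters {sorted(missing)}")
        for name, val in self.params.items():
            if val <= 0:
                raise ModelError(f"parameter {name} must be positive, got {val}")
        for sp, ki in self.inhibitors.items():
            if ki <= 0:
                raise ModelError(f"Ki for inhibitor {sp} must be positive")


@dataclass
class Reaction:
    id: str
    reactants: list[tuple[str, int]]
    products: list[tuple[str, int]]
    law: KineticLaw

    def __post_init__(self) -> None:
        for _, st in self.reactants + self.products:
            if int(st) != st or st < 1:
                raise ModelError(f"stoichiometries in {self.id} must be positive integers")
        if self.law.law_type == "michaelis_menten" and len(self.reactants) != 1:
            raise ModelError(f"Michaelis-Menten reaction {self.id} needs exactly one substrate")


class KineticModel:
    """Species, reactions and readouts of a signaling network."""

    def __init__(self, species: list[Species], reactions: list[Reaction],
                 readouts: list[str] | None = None):
        names = [s.name for s in species]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ModelError(f"duplicate species names: {sorted(dupes)}")
        self.species = list(species)
        self.reactions = list(reactions)
        self.readouts = list(readouts or [])
        self._index = {s.name: i for i, s in enumerate(self.species)}
        for rxn in self.reactions:
            for name, _ in rxn.reactants + rxn.products:
                if name not in self._index:
                    raise ModelError(f"reaction {rxn.id} references unknown species {name!r}")
            for name in list(rxn.law.modifiers) + list(rxn.law.inhibitors):
                if name not in self._index:
                    raise ModelError(f"reaction {rxn.id} references unknown species {name!r}")
        for r in self.readouts:
            if r not in self._index:
                raise ModelError(f"readout {r!r} is not a model species")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dict(cls, doc: dict) -> "KineticModel":
        species = [Species(s["name"], float(s["init_um"]), s.get("compartment", "cell"))
                   for s in doc.get("species", [])]
        reactions = []
        for r in doc.get("reactions", []):
            law_doc = r.get("law", {})
            inhibitors = {i["species"]: float(i["ki_um"]) for i in r.get("inhibitors", [])}
            law = KineticLaw(law_type=law_doc.get("type", ""),
                             params={k: float(v) for k, v in law_doc.get("params", {}).items()},
                             modifiers=list(r.get("modifiers", [])),
                             inhibitors=inhibitors)
            reactions.append(Reaction(
                id=r["id"],
                reactants=[(x["species"], int(x.get("stoich", 1))) for x in r.get("reactants", [])],
                products=[(x["species"], int(x.get("stoich", 1))) for x in r.get("products", [])],
                law=law))
        return cls(species, reactions, readouts=doc.get("readouts", []))

    @classmethod
    def from_json(cls, path) -> "KineticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "species": [{"name": s.name, "init_um": s.init_um, "compartment": s.compartment}
                        for s in self.species],
            "reactions": [
                {"id": r.id,
                 "reactants": [{"species": n, "stoich": st} for n, st in r.reactants],
                 "products": [{"species": n, "stoich": st} for n, st in r.products],
                 "modifiers": list(r.law.modifiers),
                 "inhibitors": [{"species": n, "ki_um": ki} for n, ki in r.law.inhibitors.items()],
                 "law": {"type": r.law.law_type, "params": dict(r.law.params)}}
                for r in self.reactions],
            "readouts": list(self.readouts),
        }

    def copy(self) -> "KineticModel":
        return KineticModel.from_dict(copy.deepcopy(self.to_dict()))

    # -- parameter & initial-condition access ------------------------------

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ModelError(f"unknown species {name!r}") from None

    def with_initial(self, name: str, value: float) -> "KineticModel":
        m = self.copy()
        i = m.species_index(name)
        m.species[i] = replace(m.species[i], init_um=float(value))
        return m

    def parameter_names(self) -> list[str]:
        out = []
        for r in self.reactions:
            out.extend(f"{r.id}.{p}" for p in sorted(r.law.params))
            out.extend(f"{r.id}.Ki_{sp}" for sp in sorted(r.law.inhibitors))
        return out

    def get_parameter(self, name: str) -> float:
        rid, pname = name.split(".", 1)
        for r in self.reactions:
            if r.id == rid:
                if pname.startswith("Ki_"):
                    return r.law.inhibitors[pname[3:]]
                return r.law.params[pname]
        raise ModelError(f"unknown parameter {name!r}")

    def set_parameter(self, name: str, value: float) -> None:
        if value <= 0:
            raise ModelError(f"parameter {name} must stay positive")
        rid, pname = name.split(".", 1)
        for r in self.reactions:
            if r.id == rid:
                if pname.startswith("Ki_"):
                    r.law.inhibitors[pname[3:]] = float(value)
                else:
                    if pname not in r.law.params:
                        raise ModelError(f"unknown parameter {name!r}")
                    r.law.params[pname] = float(value)
                return
        raise ModelError(f"unknown parameter {name!r}")

    # -- dynamics ----------------------------------------------------------

    def stoichiometry_matrix(self) -> np.ndarray:
        N = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for name, st in r.reactants:
                N[self._index[name], j] -= st
            for name, st in r.products:
                N[self._index[name], j] += st
        return N

    def rates(self, conc: np.ndarray) -> np.ndarray:
        c = np.maximum(conc, 0.0)  # guard against solver micro-negativity
        v = np.zeros(len(self.reactions))
        for j, r in enumerate(self.reactions):
            law = r.law
            if law.law_type == "michaelis_menten":
                s = c[self._index[r.reactants[0][0]]]
                rate = law.params["Vm"] * s / (law.params["Km"] + s)
            else:
                rate = law.params["k"]
                for name, st in r.reactants:
                    rate *= c[self._index[name]] ** st
            for name in law.modifiers:
                rate *= c[self._index[name]]
            for name, ki in law.inhibitors.items():
                rate /= 1.0 + c[self._index[name]] / ki
            v[j] = rate
        return v

    def initial_state(self) -> np.ndarray:
        return np.array([s.init_um for s in self.species])

    def simulate(self, t_end: float = DEFAULT_T_END, n_out: int = 201,
                 rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                 t_eval: np.ndarray | None = None) -> "Trajectory":
        """Stiff-capable integration on a uniform output grid."""
        if t_end <= 0:
            raise ValueError("t_end must be positive")
        N = self.stoichiometry_matrix()
        if t_eval is None:
            t_eval = np.linspace(0.0, t_end, n_out)
        sol = solve_ivp(lambda t, y: N @ self.rates(y), (0.0, float(t_end)),
                        self.initial_state(), method="LSODA",
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message} "
                               f"(nfev={sol.nfev}, last t={sol.t[-1] if len(sol.t) else 0})")
        raw = sol.y.T
        final_dcdt = N @ self.rates(raw[-1])
        stats = {
            "nfev": int(sol.nfev),
            "min_concentration_raw": float(raw.min()),
            "max_abs_dcdt_final": float(np.max(np.abs(final_dcdt))),
            "steady_state": bool(np.max(np.abs(final_dcdt)) < STEADY_STATE_TOL),
        }
        return Trajectory(times=np.asarray(t_eval, dtype=float),
                          concentrations=np.maximum(raw, 0.0),
                          species_names=[s.name for s in self.species],
                          solver_stats=stats)


@dataclass
class Trajectory:
    """Time course on a uniform grid; concentrations floored at zero (the
    pre-floor minimum is recorded in ``solver_stats['min_concentration_raw']``)."""

    times: np.ndarray
    concentrations: np.ndarray  # time x species
    species_names: list[str]
    solver_stats: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.concentrations[:, self.species_names.index(name)]

    def final(self, name: str) -> float:
        return float(self[name][-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations, columns=self.species_names)
        df.insert(0, "time", self.times)
        return df

    def plot(self, species: list[str] | None = None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in species or self.species_names:
            ax.plot(self.times, self[name], label=name)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("concentration (uM)")
        ax.legend(fontsize="small")
        return ax


# ---------------------------------------------------------------------------
# dose scans and direction classification
# ---------------------------------------------------------------------------


def dose_response(model: KineticModel, ligand_species: str, doses, readout: str,
                  t_end: float = DEFAULT_T_END, n_out: int = 201) -> pd.DataFrame:
    """Fixed-horizon readout (concentration at ``t_end``) per dose, in input
    order."""
    if readout not in [s.name for s in model.species]:
        raise ModelError(f"readout {readout!r} is not a model species")
    rows = []
    for dose in doses:
        if dose < 0:
            raise ValueError("doses must be non-negative")
        traj = model.with_initial(ligand_species, dose).simulate(t_end=t_end, n_out=n_out)
        rows.append({"dose_um": float(dose), "response": traj.final(readout)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EffectTableEntry:
    ligand: str
    receptor: str
    insulin_effect: str  # stimulatory | inhibitory | modulating | none | unknown
    glucagon_effect: str
    g_protein: str
    conc_value: float
    conc_min: float
    conc_max: float

    def __post_init__(self) -> None:
        if not self.conc_min <= self.conc_value <= self.conc_max:
            raise ValueError("conc_value must lie within [conc_min, conc_max]")


def load_effect_table(path=None) -> list[EffectTableEntry]:
    """Published effect table (insulin/glucagon secretion directions per
    ligand/receptor/G protein)."""
    if path is None:
        with resources.as_file(resources.files("pharmkin.data") / "effect_table.csv") as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return [EffectTableEntry(r.ligand, r.receptor, r.insulin_effect, r.glucagon_effect,
                             r.g_protein, float(r.value_um), float(r.min_um), float(r.max_um))
            for r in df.itertuples()]


def classify_effect(model: KineticModel, entry: EffectTableEntry, epsilon: float = 0.05,
                    readout: str = "Insulin_secreted", t_end: float = DEFAULT_T_END) -> str:
    """Direction of the readout response to the ligand at its table dose.

    Simulates with the ligand at ``conc_value`` and at zero; the ratio of
    final readouts classifies the effect: > 1+eps stimulatory, < 1-eps
    inhibitory, else none.
    """
    names = [s.name for s in model.species]
    if entry.ligand not in names:
        raise ModelError(f"ligand {entry.ligand!r} is not configured in this model")
    base = model.with_initial(entry.ligand, 0.0).simulate(t_end=t_end).final(readout)
    stim = model.with_initial(entry.ligand, entry.conc_value).simulate(t_end=t_end).final(readout)
    if base <= 0:
        return "stimulatory" if stim > 0 else "none"
    ratio = stim / base
    if ratio > 1.0 + epsilon:
        return "stimulatory"
    if ratio < 1.0 - epsilon:
        return "inhibitory"
    return "none"


def conserved_moieties(model: KineticModel) -> list[dict[str, float]]:
    """Left null-space basis of the stoichiometry matrix as conservation
    relations: each returned dict maps species to a coefficient such that
    ``sum_i c_i [S_i]`` is constant along any trajectory."""
    from scipy.linalg import null_space

    N = model.stoichiometry_matrix()
    basis = null_space(N.T)
    out = []
    for col in basis.T:
        coeffs = {model.species[i].name: float(col[i])
                  for i in range(len(col)) if abs(col[i]) > 1e-10}
        if coeffs:
            out.append(coeffs)
    return out


def fixture_path(name: str):
    """Path to a bundled network fixture (e.g. ``gpr142_network.json``)."""
    return resources.files("pharmkin.data") / name


def load_fixture(name: str = "gpr142_network.json") -> KineticModel:
    with resources.as_file(fixture_path(name)) as p:
        return KineticModel.from_json(p)
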