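"""Pharmacophore feature perception and the abstract site-set representation.

A pharmacophore site is a typed 3D point, optionally carrying a unit direction
vector.  Six feature types are used throughout the package:

====  ==================  ==============================================
code  name                geometry
====  ==================  ==============================================
A     hydrogen-bond       vector (idealised lone-pair axis, outward)
      acceptor
D     hydrogen-bond       vector (heavy atom through attached H; one
      donor               site per H in ambiguous cases)
H     hydrophobic         point/group (centroid of a contiguous apolar
                          carbon group)
N     negative ionisable  point/group (e.g. carboxylate-oxygen centroid)
P     positive ionisable  point/group
R     aromatic ring       vector (ring centroid + plane normal)
====  ==================  ==============================================

The canonical internal representation is the abstract *site set* (JSON on
disk, :class:`FeatureSet` in memory); perception from chemistry (SDF/SMILES
via RDKit) is an optional adapter, so the geometric pipeline downstream never
depends on a chemistry toolkit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

FEATURE_TYPES = ("A", "D", "H", "N", "P", "R")

#: feature types that may carry a direction vector
VECTOR_TYPES = frozenset({"A", "D", "R"})
#: feature types that must never carry a direction vector
POINT_ONLY_TYPES = frozenset({"H", "N", "P"})

_DIR_NORM_TOL = 1e-9


class SiteSetError(ValueError):
    """Malformed or invalid site-set input."""


@dataclass(frozen=True)
class PharmacophoreFeature:
    """One typed pharmacophore site.

    Parameters
    ----------
    type
        One of ``A D H N P R``.
    point
        Cartesian coordinates in angstrom.
    direction
        Optional unit vector.  Required for ``R`` (ring-plane normal),
        forbidden for ``H``/``N``/``P``.
    member_atoms
        Atom indices of the matched group, when perceived from chemistry.
    """

    type: str
    point: tuple[float, float, float]
    direction: tuple[float, float, float] | None = None
    member_atoms: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise SiteSetError(f"unknown feature type {self.type!r}")
        pt = np.asarray(self.point, dtype=float)
        if pt.shape != (3,) or not np.all(np.isfinite(pt)):
            raise SiteSetError(f"feature point must be a finite 3-vector, got {self.point!r}")
        object.__setattr__(self, "point", tuple(float(x) for x in pt))
        if self.direction is not None:
            if self.type in POINT_ONLY_TYPES:
                raise SiteSetError(f"feature type {self.type} must not carry a direction")
            d = np.asarray(self.direction, dtype=float)
            if d.shape != (3,) or abs(float(np.linalg.norm(d)) - 1.0) > _DIR_NORM_TOL:
                raise SiteSetError("direction must be a unit 3-vector (|v| = 1 +/- 1e-9)")
            object.__setattr__(self, "direction", tuple(float(x) for x in d))
        elif self.type == "R":
            raise SiteSetError("aromatic ring (R) features must carry a plane-normal direction")
        if self.member_atoms is not None:
            object.__setattr__(self, "member_atoms", tuple(int(i) for i in self.member_atoms))

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.point, dtype=float)


@dataclass
class FeatureSet:
    """All pharmacophore sites of one conformer of one molecule."""

    molecule_id: str
    conformer_id: int
    features: list[PharmacophoreFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.molecule_id:
            raise SiteSetError("molecule_id must be non-empty")
        if self.conformer_id < 0:
            raise SiteSetError("conformer_id must be >= 0")

    def __len__(self) -> int:
        return len(self.features)

    def points(self, indices: Sequence[int] | None = None) -> np.ndarray:
        feats = self.features if indices is None else [self.features[i] for i in indices]
        if not feats:
            return np.zeros((0, 3))
        return np.array([f.point for f in feats], dtype=float)

    def type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.features:
            counts[f.type] = counts.get(f.type, 0) + 1
        return counts

    def indices_of_type(self, ftype: str) -> list[int]:
        return [i for i, f in enumerate(self.features) if f.type == ftype]


# ---------------------------------------------------------------------------
# site-set JSON I/O
#
# Schema:
# {"molecules": [{"id": str,
#                 "conformers": [{"id": int,
#                                 "sites": [{"type": "A|D|H|N|P|R",
#                                            "xyz": [x, y, z],
#                                            "dir": [x, y, z] | null}]}]}]}
# ---------------------------------------------------------------------------


def load_site_sets(path) -> list[FeatureSet]:
    """Read a site-set JSON file into one :class:`FeatureSet` per conformer.

    Order of molecules and conformers is preserved.  Malformed records raise
    :class:`SiteSetError` naming the offending molecule/conformer.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SiteSetError(f"malformed site-set JSON in {path}: {exc}") from exc
    return site_sets_from_dict(doc)


def site_sets_from_dict(doc: dict) -> list[FeatureSet]:
    if not isinstance(doc, dict) or "molecules" not in doc:
        raise SiteSetError("site-set document must be an object with a 'molecules' list")
    out: list[FeatureSet] = []
    for mol in doc["molecules"]:
        mol_id = mol.get("id")
        if not mol_id:
            raise SiteSetError(f"molecule record without 'id': {mol!r}")
        for conf in mol.get("conformers", []):
            feats = []
            for site in conf.get("sites", []):
                try:
                    feats.append(
                        PharmacophoreFeature(
                            type=site["type"],
                            point=tuple(site["xyz"]),
                            direction=tuple(site["dir"]) if site.get("dir") is not None else None,
                        )
                    )
                except (KeyError, SiteSetError, TypeError) as exc:
                    raise SiteSetError(
                        f"invalid site in molecule {mol_id!r} conformer {conf.get('id')!r}: {exc}"
                    ) from exc
            out.append(FeatureSet(molecule_id=str(mol_id), conformer_id=int(conf.get("id", 0)), features=feats))
    return out


def site_sets_to_dict(sets: Iterable[FeatureSet]) -> dict:
    by_mol: dict[str, list[FeatureSet]] = {}
    order: list[str] = []
    for fs in sets:
        if fs.molecule_id not in by_mol:
            by_mol[fs.molecule_id] = []
            order.append(fs.molecule_id)
        by_mol[fs.molecule_id].append(fs)
    return {
        "molecules": [
            {
                "id": mol_id,
                "conformers": [
                    {
                        "id": fs.conformer_id,
                        "sites": [
                            {
                                "type": f.type,
                                "xyz": list(f.point),
                                "dir": list(f.direction) if f.direction is not None else None,
                            }
                            for f in fs.features
                        ],
                    }
                    for fs in by_mol[mol_id]
                ],
            }
            for mol_id in order
        ]
    }


def write_site_sets(sets: Iterable[FeatureSet], path) -> None:
    with open(path, "w") as fh:
        json.dump(site_sets_to_dict(sets), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# SMARTS table and chemistry adapter (RDKit, optional)
# ---------------------------------------------------------------------------


@dataclass
class SmartsEntry:
    feature_type: str
    smarts: str
    geometry_rule: str  # point | vector | group | ring
    centroid_atoms: tuple[int, ...] | None = None  # indices into the SMARTS match


@dataclass
class SmartsTable:
    """Feature-type -> SMARTS definitions driving perception.

    The table ships as a JSON config (``data/smarts_default.json``) the user
    can replace wholesale; no chemistry is hidden in code.
    """

    entries: list[SmartsEntry]

    def __post_init__(self) -> None:
        present = {e.feature_type for e in self.entries}
        missing = set(FEATURE_TYPES) - present
        if missing:
            raise SiteSetError(f"SMARTS table missing feature types: {sorted(missing)}")
        for e in self.entries:
            if e.geometry_rule not in ("point", "vector", "group", "ring", "cluster"):
                raise SiteSetError(f"unknown geometry rule {e.geometry_rule!r}")


def load_smarts_table(path) -> SmartsTable:
    with open(path) as fh:
        doc = json.load(fh)
    entries = [
        SmartsEntry(
            feature_type=e["type"],
            smarts=e["smarts"],
            geometry_rule=e["geometry"],
            centroid_atoms=tuple(e["centroid_atoms"]) if e.get("centroid_atoms") else None,
        )
        for e in doc["entries"]
    ]
    table = SmartsTable(entries)
    _validate_smarts(table)
    return table


def default_smarts_table() -> SmartsTable:
    with resources.as_file(resources.files("pharmkin.data") / "smarts_default.json") as p:
        return load_smarts_table(p)


def _validate_smarts(table: SmartsTable) -> None:
    from rdkit import Chem

    for e in table.entries:
        if Chem.MolFromSmarts(e.smarts) is None:
            raise SiteSetError(f"invalid SMARTS for type {e.feature_type}: {e.smarts!r}")


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    """Plane normal of an ordered atom ring by Newell's method.

    The sign is fixed by the atom ordering, so the normal co-rotates with the
    coordinates (equivariant under proper rigid motions).
    """
    c = coords - coords.mean(axis=0)
    n = np.zeros(3)
    for i in range(len(c)):
        n += np.cross(c[i], c[(i + 1) % len(c)])
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise SiteSetError("degenerate ring geometry (collinear atoms)")
    return n / norm


def perceive_features(mol, table: SmartsTable | None = None, conformer_id: int = 0,
                      molecule_id: str | None = None) -> FeatureSet:
    """Perceive pharmacophore sites on an RDKit molecule with a 3D conformer.

    Every SMARTS match yields one site (group/ring matches de-duplicated on
    their atom set).  Group features sit at the centroid of the matched heavy
    atoms; ring (R) features carry the ring-plane normal; donor vectors point
    from the heavy atom through each attached hydrogen (one site per H);
    acceptor vectors approximate the lone-pair axis as the outward direction
    away from the centroid of bonded heavy atoms.
    """
    from rdkit import Chem

    if table is None:
        table = default_smarts_table()
    if mol.GetNumConformers() == 0:
        raise SiteSetError("molecule has no 3D conformer; embed coordinates first")
    molh = Chem.AddHs(mol, addCoords=True)
    conf = molh.GetConformer()
    coords = np.array(conf.GetPositions(), dtype=float)
    if molecule_id is None:
        molecule_id = mol.GetProp("_Name") if mol.HasProp("_Name") else "mol"
        molecule_id = molecule_id or "mol"

    feats: list[PharmacophoreFeature] = []
    for entry in table.entries:
        patt = Chem.MolFromSmarts(entry.smarts)
        matches = molh.GetSubstructMatches(patt, uniquify=True)
        if entry.geometry_rule == "cluster":
            # merge matched atoms into bond-connected components: one site per
            # contiguous group (e.g. an apolar carbon patch)
            feats.extend(_cluster_features(entry, matches, molh, coords))
            continue
        if entry.geometry_rule in ("group", "ring"):
            seen: set[frozenset] = set()
            dedup = []
            for m in matches:
                key = frozenset(m)
                if key not in seen:
                    seen.add(key)
                    dedup.append(m)
            matches = dedup
        for match in sorted(matches, key=lambda m: tuple(sorted(m))):
            feats.extend(_features_from_match(entry, match, molh, coords))
    return FeatureSet(molecule_id=molecule_id, conformer_id=conformer_id, features=feats)


def _cluster_features(entry: SmartsEntry, matches, molh, coords: np.ndarray):
    matched = sorted({i for m in matches for i in m})
    matched_set = set(matched)
    seen: set[int] = set()
    out = []
    for start in matched:
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            cur = stack.pop()
            for nbr in molh.GetAtomWithIdx(cur).GetNeighbors():
                j = nbr.GetIdx()
                if j in matched_set and j not in seen:
                    seen.add(j)
                    comp.append(j)
                    stack.append(j)
        comp.sort()
        centroid = coords[comp].mean(axis=0)
        out.append(PharmacophoreFeature(entry.feature_type, tuple(centroid),
                                        member_atoms=tuple(comp)))
    return out


def _features_from_match(entry: SmartsEntry, match: tuple[int, ...], molh, coords: np.ndarray):
    heavy = [i for i in match if molh.GetAtomWithIdx(i).GetAtomicNum() > 1]
    if entry.centroid_atoms is not None:
        pivot = [match[i] for i in entry.centroid_atoms]
    else:
        pivot = heavy or list(match)
    centroid = coords[pivot].mean(axis=0)

    if entry.geometry_rule == "ring":
        normal = _ring_normal(coords[list(match)])
        return [PharmacophoreFeature(entry.feature_type, tuple(centroid), tuple(normal),
                                     member_atoms=tuple(sorted(match)))]
    if entry.geometry_rule == "vector":
        atom_idx = pivot[0]
        atom = molh.GetAtomWithIdx(atom_idx)
        if entry.feature_type == "D":
            out = []
            for nbr in atom.GetNeighbors():
                if nbr.GetAtomicNum() == 1:
                    d = coords[nbr.GetIdx()] - coords[atom_idx]
                    n = np.linalg.norm(d)
                    if n > 1e-9:
                        out.append(PharmacophoreFeature("D", tuple(coords[atom_idx]), tuple(d / n),
                                                        member_atoms=(atom_idx,)))
            return out
        # acceptor: lone-pair bisector approximated as the direction away from
        # the centroid of bonded heavy neighbours
        nbrs = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() > 1]
        if nbrs:
            d = coords[atom_idx] - coords[nbrs].mean(axis=0)
            n = np.linalg.norm(d)
            direction = tuple(d / n) if n > 1e-9 else None
        else:
            direction = None
        return [PharmacophoreFeature(entry.feature_type, tuple(coords[atom_idx]), direction,
                                     member_atoms=(atom_idx,))]
    # point / group
    return [PharmacophoreFeature(entry.feature_type, tuple(centroid),
                                 member_atoms=tuple(sorted(pivot)))]


def perceive_sdf(path, table: SmartsTable | None = None) -> list[FeatureSet]:
    """Perceive features for every molecule/conformer in an SDF file."""
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    out = []
    counters: dict[str, int] = {}
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        cid = counters.get(name, 0)
        counters[name] = cid + 1
        out.append(perceive_features(mol, table, conformer_id=cid, molecule_id=name))
    return out
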