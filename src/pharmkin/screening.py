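"""Conformer database construction and hypothesis matching.

A screening database holds the site sets of every retained conformer of
every screened compound (at most 100 conformers per structure by default,
and at most 10 per rotatable bond when rotatable-bond counts are supplied).
Matching retrieves the conformers possessing a type-preserving site
assignment whose inter-site distances all fall within ``dist_tol`` of the
hypothesis reference, aligns them, and ranks them by a fitness score

    fitness = max(0, 1 - rmsd/dist_tol) + clip(vec_cos, 0, 1) + clip(vol_jaccard, 0, 1)

in [0, 3].  A per-type-pair sorted-distance index prunes conformers that
cannot possibly match (a necessary condition only, so index-accelerated
matching returns exactly the brute-force match set).
"""

from __future__ import annotations

from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureSet
from .geometry import (Alignment, align_to_reference, mean_vector_cosine,
                       volume_jaccard)
from .hypothesis import Hypothesis

DEFAULT_DIST_TOL = 2.0  # A
MAX_CONFS = 100
PER_ROTATABLE = 10


def _pair_distances(fs: FeatureSet) -> dict[str, list[float]]:
    """Sorted inter-site distances per type pair."""
    out: dict[str, list[float]] = {}
    pts = fs.points()
    for i in range(len(fs.features)):
        for j in range(i + 1, len(fs.features)):
            pt = "".join(sorted((fs.features[i].type, fs.features[j].type)))
            out.setdefault(pt, []).append(float(np.linalg.norm(pts[i] - pts[j])))
    for v in out.values():
        v.sort()
    return out


@dataclass
class ScreenDB:
    entries: list[FeatureSet]
    index: list[dict[str, list[float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.index) != len(self.entries):
            self.index = [_pair_distances(fs) for fs in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def rebuild_index(self) -> None:
        self.index = [_pair_distances(fs) for fs in self.entries]


def build_screen_db(sets: list[FeatureSet], max_confs: int = MAX_CONFS,
                    per_rotatable: int = PER_ROTATABLE,
                    rotatable_counts: dict[str, int] | None = None) -> ScreenDB:
    """Cap conformers per molecule (deterministically, in input order) and
    build the distance index.

    The per-rotatable-bond cap applies only when ``rotatable_counts`` maps a
    molecule id to its rotatable-bond count (chemistry adapter); the abstract
    representation has no bonds.
    """
    if max_confs < 1:
        raise ValueError("max_confs must be >= 1")
    kept: list[FeatureSet] = []
    per_mol: Counter = Counter()
    for fs in sets:
        cap = max_confs
        if rotatable_counts and fs.molecule_id in rotatable_counts:
            cap = min(cap, max(1, per_rotatable * rotatable_counts[fs.molecule_id]))
        if per_mol[fs.molecule_id] < cap:
            per_mol[fs.molecule_id] += 1
            kept.append(fs)
    return ScreenDB(entries=kept)


@dataclass
class MatchResult:
    molecule_id: str
    conformer_id: int
    pairing: tuple[int, ...]  # hypothesis site i -> conformer feature index
    alignment: Alignment
    rmsd: float
    vec_cos: float
    vol_jaccard: float
    fitness: float


def fitness_score(alignment: Alignment, vec_cos: float, vol_jaccard: float,
                  dist_tol: float = DEFAULT_DIST_TOL) -> float:
    return (max(0.0, 1.0 - alignment.rmsd / dist_tol)
            + float(np.clip(vec_cos, 0.0, 1.0))
            + float(np.clip(vol_jaccard, 0.0, 1.0)))


def _index_prefilter(h_dists: dict[str, list[float]], conf_index: dict[str, list[float]],
                     dist_tol: float) -> bool:
    """Necessary condition: for every hypothesis pair distance, the conformer
    has some same-type-pair distance within tolerance."""
    for pt, dists in h_dists.items():
        cand = conf_index.get(pt)
        if cand is None:
            return False
        for d in dists:
            i = bisect_left(cand, d - dist_tol)
            if i >= len(cand) or cand[i] > d + dist_tol:
                return False
    return True


def _assignments(h: Hypothesis, fs: FeatureSet, dist_tol: float):
    """All type-preserving site assignments with every inter-site distance
    within ``dist_tol`` of the hypothesis reference (backtracking)."""
    ref = h.points()
    k = h.k
    n = len(fs.features)
    pts = fs.points()
    cands = [[j for j in range(n) if fs.features[j].type == h.reference_sites[i].type]
             for i in range(k)]
    assignment: list[int] = []

    def backtrack(i: int):
        if i == k:
            yield tuple(assignment)
            return
        for j in cands[i]:
            if j in assignment:
                continue
            ok = True
            for prev_slot, prev_j in enumerate(assignment):
                d_ref = np.linalg.norm(ref[i] - ref[prev_slot])
                d_mol = np.linalg.norm(pts[j] - pts[prev_j])
                if abs(d_mol - d_ref) > dist_tol:
                    ok = False
                    break
            if ok:
                assignment.append(j)
                yield from backtrack(i + 1)
                assignment.pop()

    yield from backtrack(0)


def _score_conformer(h: Hypothesis, fs: FeatureSet, dist_tol: float) -> MatchResult | None:
    best_aln: Alignment | None = None
    for pairing in _assignments(h, fs, dist_tol):
        aln = align_to_reference(h.points(), fs.points(list(pairing)), pairing=pairing)
        if best_aln is None or aln.rmsd < best_aln.rmsd:
            best_aln = aln
    if best_aln is None:
        return None
    refs, movs, ring = [], [], []
    for slot, fi in enumerate(best_aln.pairing):
        hv = h.reference_sites[slot].direction
        mv = fs.features[fi].direction
        if hv is not None and mv is not None:
            refs.append(hv)
            movs.append(best_aln.apply_vectors(np.asarray(mv)))
            ring.append(h.reference_sites[slot].type == "R")
    vec_cos = mean_vector_cosine(np.array(refs), np.array(movs), np.array(ring)) if refs else 1.0
    moved = best_aln.apply(fs.points(list(best_aln.pairing)))
    vol = volume_jaccard(h.points(), moved)
    fit = fitness_score(best_aln, vec_cos, vol, dist_tol)
    return MatchResult(molecule_id=fs.molecule_id, conformer_id=fs.conformer_id,
                       pairing=best_aln.pairing, alignment=best_aln, rmsd=best_aln.rmsd,
                       vec_cos=vec_cos, vol_jaccard=vol, fitness=fit)


def match_hypothesis(db: ScreenDB, h: Hypothesis, dist_tol: float = DEFAULT_DIST_TOL,
                     top_n: int | None = None, use_index: bool = True) -> list[MatchResult]:
    """Search the database for conformers matching a hypothesis.

    Returns the best-fitness conformer per molecule, sorted by fitness
    descending (ties: lower RMSD, then molecule id), truncated to ``top_n``.
    """
    if dist_tol <= 0:
        raise ValueError("dist_tol must be positive")
    if h.k < 3:
        raise ValueError("hypothesis must have at least 3 sites (alignment undefined)")
    h_dists = _pair_distances(
        FeatureSet(molecule_id="_h", conformer_id=0, features=list(h.reference_sites)))
    best_per_mol: dict[str, MatchResult] = {}
    for fs, conf_index in zip(db.entries, db.index):
        if use_index and not _index_prefilter(h_dists, conf_index, dist_tol):
            continue
        res = _score_conformer(h, fs, dist_tol)
        if res is None:
            continue
        prev = best_per_mol.get(fs.molecule_id)
        if prev is None or (res.fitness, -res.rmsd) > (prev.fitness, -prev.rmsd):
            best_per_mol[fs.molecule_id] = res
    out = sorted(best_per_mol.values(), key=lambda r: (-r.fitness, r.rmsd, r.molecule_id))
    return out[:top_n] if top_n is not None else out


def matches_to_frame(results: list[MatchResult]):
    """Hits table: molecule_id, conformer_id, rmsd, vec_cos, vol_jaccard, fitness."""
    import pandas as pd

    return pd.DataFrame(
        [{"molecule_id": r.molecule_id, "conformer_id": r.conformer_id, "rmsd": r.rmsd,
          "vec_cos": r.vec_cos, "vol_jaccard": r.vol_jaccard, "fitness": r.fitness}
         for r in results],
        columns=["molecule_id", "conformer_id", "rmsd", "vec_cos", "vol_jaccard", "fitness"])
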