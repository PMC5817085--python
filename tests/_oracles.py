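"""Independent brute-force oracles used only by the tests.

Each oracle re-derives a quantity by naive exhaustive enumeration or dense
search, sharing no code path with the implementation it checks.
"""

import itertools
import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_assignments(hyp_types, hyp_points, fs, dist_tol):
    """All injective type-preserving assignments (hypothesis slot ->
    feature index) with every inter-site distance within dist_tol, by raw
    enumeration over permutations of candidate indices."""
    n = len(fs.features)
    k = len(hyp_types)
    found = []
    for perm in itertools.permutations(range(n), k):
        if any(fs.features[j].type != hyp_types[i] for i, j in enumerate(perm)):
            continue
        ok = True
        for i in range(k):
            for j in range(i + 1, k):
                d_ref = np.linalg.norm(hyp_points[i] - hyp_points[j])
                d_mol = np.linalg.norm(fs.features[perm[i]].xyz - fs.features[perm[j]].xyz)
                if abs(d_mol - d_ref) > dist_tol:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            found.append(perm)
    return found


def brute_force_match_ids(hyp_types, hyp_points, sets, dist_tol):
    """Molecule ids with any conformer admitting a valid assignment."""
    return {fs.molecule_id for fs in sets
            if brute_force_assignments(hyp_types, hyp_points, fs, dist_tol)}


def naive_distance_key(types, points, bin_width):
    pairs = []
    for i in range(len(types)):
        for j in range(i + 1, len(types)):
            d = math.dist(points[i], points[j])
            pairs.append(("".join(sorted((types[i], types[j]))), math.floor(d / bin_width)))
    return tuple(sorted(pairs))


def naive_keys_compatible(ka, kb):
    if len(ka) != len(kb):
        return False
    ga, gb = {}, {}
    for pt, b in ka:
        ga.setdefault(pt, []).append(b)
    for pt, b in kb:
        gb.setdefault(pt, []).append(b)
    if set(ga) != set(gb):
        return False
    for pt in ga:
        if len(ga[pt]) != len(gb[pt]):
            return False
        if any(abs(x - y) > 1 for x, y in zip(sorted(ga[pt]), sorted(gb[pt]))):
            return False
    return True


def naive_common_pharmacophores(mols, variant, min_match, bin_width):
    """Exhaustive re-derivation of common-arrangement discovery: every
    k-subset of every molecule, shared-key counting by pairwise comparison.
    Returns {(source_molecule, subset_indices): frozenset(matched ids)}."""
    from collections import Counter

    want = Counter(variant)
    all_subsets = {}
    for fs in mols:
        subs = []
        idx_by_type = {}
        for i, f in enumerate(fs.features):
            idx_by_type.setdefault(f.type, []).append(i)
        if any(len(idx_by_type.get(t, [])) < c for t, c in want.items()):
            all_subsets[fs.molecule_id] = []
            continue
        pools = [list(itertools.combinations(idx_by_type[t], want[t])) for t in sorted(want)]
        for combo in itertools.product(*pools):
            sub = tuple(itertools.chain.from_iterable(combo))
            key = naive_distance_key([fs.features[i].type for i in sub],
                                     [fs.features[i].point for i in sub], bin_width)
            subs.append((sub, key))
        all_subsets[fs.molecule_id] = subs
    out = {}
    for fs in mols:
        for sub, key in all_subsets[fs.molecule_id]:
            matched = frozenset(
                other.molecule_id for other in mols
                if any(naive_keys_compatible(key, k2) for _, k2 in all_subsets[other.molecule_id]))
            if len(matched) >= min_match:
                out[(fs.molecule_id, sub)] = matched
    return out


def grid_search_rmsd(ref, mov, coarse_deg=8.0):
    """Minimum superposition RMSD by dense rotation-grid search (Euler
    angles) followed by local simplex refinement."""
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    k = len(ref)

    def rmsd_of(euler):
        R = Rotation.from_euler("zyx", euler).as_matrix()
        return float(np.sqrt(np.sum((ref_c - mov_c @ R.T) ** 2) / k))

    best, best_euler = np.inf, None
    step = math.radians(coarse_deg)
    a_grid = np.arange(-math.pi, math.pi, step)
    b_grid = np.arange(-math.pi / 2, math.pi / 2 + 1e-9, step)
    for a in a_grid:
        for b in b_grid:
            for c in a_grid:
                v = rmsd_of((a, b, c))
                if v < best:
                    best, best_euler = v, (a, b, c)
    res = minimize(rmsd_of, best_euler, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    return min(best, float(res.fun))
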