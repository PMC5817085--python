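"""Common-pharmacophore hypothesis generation, scoring and filtering.

Given a set of active ligands (as abstract site sets), the pipeline

1. partitions compounds into active / inactive / unlabeled by EC50 thresholds,
2. enumerates feature-type *variants* (sorted multisets such as ``ADPRR``,
   between 4 and 7 sites by default),
3. finds arrangements of sites common to at least ``min_match`` actives by
   comparing binned inter-site distance profiles,
4. aligns every matching active onto each candidate arrangement and scores it
   with the survival function

   ``S = W_site*S_site + W_vec*S_vec + W_vol*S_vol + W_sel*S_sel + W_rew*reward(m)``

   where ``m`` is the number of matching actives minus one, and
5. filters candidates on alignment spread (max pairwise RMSD < 1.20 A) and
   vector score (> 0.50), returning them sorted by survival score.

Component scores:

* ``S_site``  mean over actives of ``max(0, 1 - rmsd / rmsd_cutoff)`` with a
  2.0 A cutoff (a linear ramp from perfect superposition to no credit);
* ``S_vec``   mean cosine of the angles between corresponding direction
  vectors of the aligned structures, clipped to [0, 1] (ring normals compare
  by absolute cosine, a ring plane being invariant under normal flip);
* ``S_vol``   mean pairwise Jaccard overlap of sphere-union volumes of the
  aligned matched sites;
* ``S_sel``   ``-log10`` of the fraction of a background set matching the
  hypothesis, floored at 0 (weighted 0 by default).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureSet, PharmacophoreFeature
from .geometry import (Alignment, align_to_reference, mean_vector_cosine,
                       volume_jaccard, voxelize_spheres)

RMSD_CUTOFF = 2.0  # A; site-score ramp clamps to 0 beyond this alignment RMSD
FILTER_RMSD = 1.20  # A; retain hypotheses with max pairwise RMSD strictly below
FILTER_VEC = 0.50  # retain hypotheses with vector score strictly above


# ---------------------------------------------------------------------------
# activity partitioning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdScheme:
    """EC50 thresholds defining the active / inactive split of a data set.

    ``direction="above"`` labels compounds with EC50 >= ``active_threshold``
    active (the literal convention of the source data sets);
    ``direction="below"`` inverts the comparators for conventional potency
    semantics.  Strictly-between compounds stay unlabeled.
    """

    active_threshold: float
    inactive_threshold: float
    min_match: int
    n_active_expected: int | None = None
    direction: str = "above"

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ValueError("direction must be 'above' or 'below'")
        lo, hi = ((self.inactive_threshold, self.active_threshold)
                  if self.direction == "above"
                  else (self.active_threshold, self.inactive_threshold))
        if lo > hi:
            raise ValueError("thresholds ordered inconsistently with direction")
        if self.min_match < 1:
            raise ValueError("min_match must be >= 1")


#: the three published data-set schemes (high / medium / low affinity)
SCHEME_HIGH = ThresholdScheme(0.036, 0.001, min_match=35, n_active_expected=38)
SCHEME_MEDIUM = ThresholdScheme(1.060, 1.000, min_match=30, n_active_expected=51)
SCHEME_LOW = ThresholdScheme(0.036, 0.035, min_match=20, n_active_expected=60)


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    ec50: float
    label: str  # active | inactive | unlabeled


def partition_activity(records, scheme: ThresholdScheme) -> list[ActivityRecord]:
    """Label (compound_id, ec50) pairs active / inactive / unlabeled."""
    out = []
    for cid, ec50 in records:
        ec50 = float(ec50)
        if not ec50 > 0:
            raise ValueError(f"EC50 must be positive, got {ec50} for {cid!r}")
        if scheme.direction == "above":
            if ec50 >= scheme.active_threshold:
                label = "active"
            elif ec50 <= scheme.inactive_threshold:
                label = "inactive"
            else:
                label = "unlabeled"
        else:
            if ec50 <= scheme.active_threshold:
                label = "active"
            elif ec50 >= scheme.inactive_threshold:
                label = "inactive"
            else:
                label = "unlabeled"
        out.append(ActivityRecord(str(cid), ec50, label))
    return out


# ---------------------------------------------------------------------------
# variant enumeration
# ---------------------------------------------------------------------------


def enumerate_variants(type_counts: dict[str, int], k_min: int, k_max: int) -> set[str]:
    """All sorted feature-type multisets of size k_min..k_max realisable
    from ``type_counts`` (exhaustive)."""
    if k_min > k_max:
        raise ValueError("k_min must be <= k_max")
    letters = []
    for t in sorted(type_counts):
        c = type_counts[t]
        if c < 0:
            raise ValueError("type counts must be >= 0")
        letters.extend(t * c)
    out: set[str] = set()
    for k in range(k_min, k_max + 1):
        if k > len(letters):
            break
        out.update("".join(c) for c in set(itertools.combinations(letters, k)))
    return out


# ---------------------------------------------------------------------------
# common-arrangement discovery
# ---------------------------------------------------------------------------


@dataclass
class Hypothesis:
    """A k-site candidate arrangement taken from one active ligand."""

    variant: str
    reference_sites: list[PharmacophoreFeature]
    source_molecule: str
    source_conformer: int = 0
    site_indices: tuple[int, ...] = ()  # feature indices in the source set
    matched_actives: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.variant != "".join(sorted(self.variant)):
            raise ValueError("variant string must be sorted alphabetically")
        if Counter(self.variant) != Counter(f.type for f in self.reference_sites):
            raise ValueError("variant letters must equal the multiset of site types")

    @property
    def k(self) -> int:
        return len(self.reference_sites)

    def points(self) -> np.ndarray:
        return np.array([f.point for f in self.reference_sites], dtype=float)

    def distance_key(self, bin_width: float) -> tuple:
        return _distance_key([f.type for f in self.reference_sites], self.points(), bin_width)


def _distance_key(types, points: np.ndarray, bin_width: float) -> tuple:
    """Canonical binned inter-site distance profile: sorted tuple of
    (type-pair, floor(d / bin_width)) over all site pairs.  Invariant under
    site reordering and rigid motion."""
    pairs = []
    n = len(types)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(points[i] - points[j]))
            pt = "".join(sorted((types[i], types[j])))
            pairs.append((pt, int(np.floor(d / bin_width))))
    return tuple(sorted(pairs))


def _keys_compatible(key_a: tuple, key_b: tuple) -> bool:
    """Two distance profiles agree when, per type-pair group, sorted bins
    differ by at most one (neighbour-bin probing removes boundary misses)."""
    if len(key_a) != len(key_b):
        return False
    group_a: dict[str, list[int]] = {}
    group_b: dict[str, list[int]] = {}
    for pt, b in key_a:
        group_a.setdefault(pt, []).append(b)
    for pt, b in key_b:
        group_b.setdefault(pt, []).append(b)
    if group_a.keys() != group_b.keys():
        return False
    for pt, bins_a in group_a.items():
        bins_b = group_b[pt]
        if len(bins_a) != len(bins_b):
            return False
        for x, y in zip(sorted(bins_a), sorted(bins_b)):
            if abs(x - y) > 1:
                return False
    return True


def best_conformers(sets: list[FeatureSet]) -> list[FeatureSet]:
    """One conformer per molecule: the first in input order (by convention
    the minimum-energy conformer leads its molecule's block)."""
    seen: set[str] = set()
    out = []
    for fs in sets:
        if fs.molecule_id not in seen:
            seen.add(fs.molecule_id)
            out.append(fs)
    return out


def _variant_subsets(fs: FeatureSet, variant: str):
    """All index tuples realising the variant multiset, features ordered by
    the variant's letters."""
    counts = Counter(variant)
    per_type = []
    for t in sorted(counts):
        idx = fs.indices_of_type(t)
        if len(idx) < counts[t]:
            return
        per_type.append(list(itertools.combinations(idx, counts[t])))
    for combo in itertools.product(*per_type):
        yield tuple(itertools.chain.from_iterable(combo))


def find_common_pharmacophores(actives: list[FeatureSet], variant: str,
                               min_match: int, bin_width: float = 1.0) -> list[Hypothesis]:
    """Arrangements of ``variant``-typed sites common to >= ``min_match``
    actives (one best conformer per molecule).

    A subset of one active is *shared* by another active when the other has a
    site subset of the same type multiset whose binned inter-site distance
    profile is compatible (see :func:`_distance_key`).  Every qualifying
    subset of every active yields one :class:`Hypothesis`.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mols = best_conformers(actives)
    if min_match > len(mols):
        raise ValueError("min_match exceeds the number of active molecules")
    variant = "".join(sorted(variant))
    subset_keys: list[list[tuple[tuple, tuple]]] = []  # per molecule: (key, subset)
    for fs in mols:
        keys = [( _distance_key([fs.features[i].type for i in sub], fs.points(sub), bin_width), sub)
                for sub in _variant_subsets(fs, variant)]
        subset_keys.append(keys)
    out: list[Hypothesis] = []
    for mi, fs in enumerate(mols):
        for key, sub in subset_keys[mi]:
            matched = [mols[mj].molecule_id
                       for mj in range(len(mols))
                       if any(_keys_compatible(key, other_key) for other_key, _ in subset_keys[mj])]
            if len(matched) >= min_match:
                out.append(Hypothesis(
                    variant=variant,
                    reference_sites=[fs.features[i] for i in sub],
                    source_molecule=fs.molecule_id,
                    source_conformer=fs.conformer_id,
                    site_indices=sub,
                    matched_actives=matched,
                ))
    return out


def best_alignment_to(h: Hypothesis, fs: FeatureSet, bin_width: float = 1.0,
                      require_key: bool = True) -> Alignment | None:
    """Minimum-RMSD superposition of a ligand's sites onto a hypothesis.

    Enumerates type-preserving subsets (optionally restricted to those with a
    compatible distance profile) and within-type permutations; returns the
    alignment with the pairing achieving the lowest RMSD, or None when the
    ligand cannot realise the variant.
    """
    key_h = h.distance_key(bin_width)
    h_types = [f.type for f in h.reference_sites]
    ref = h.points()
    best: Alignment | None = None
    # positions of each variant letter in the hypothesis site order
    type_slots: dict[str, list[int]] = {}
    for pos, t in enumerate(h_types):
        type_slots.setdefault(t, []).append(pos)
    for sub in _variant_subsets(fs, h.variant):
        types = [fs.features[i].type for i in sub]
        if require_key:
            key = _distance_key(types, fs.points(sub), bin_width)
            if not _keys_compatible(key_h, key):
                continue
        by_type: dict[str, list[int]] = {}
        for i in sub:
            by_type.setdefault(fs.features[i].type, []).append(i)
        for perm_combo in itertools.product(
                *[itertools.permutations(by_type[t]) for t in sorted(by_type)]):
            assignment = [0] * h.k
            for t, perm in zip(sorted(by_type), perm_combo):
                for slot, fi in zip(type_slots[t], perm):
                    assignment[slot] = fi
            aln = align_to_reference(ref, fs.points(assignment), pairing=tuple(assignment))
            if best is None or aln.rmsd < best.rmsd:
                best = aln
    return best


# ---------------------------------------------------------------------------
# survival scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeightSet:
    w_site: float = 1.0
    w_vec: float = 1.0
    w_vol: float = 1.0
    w_sel: float = 0.0
    w_rew: float = 1.0
    reward_mode: str = "linear"  # linear: reward(m)=m; unit: reward(m)=min(m,1)

    def reward(self, m: int) -> float:
        if self.reward_mode == "linear":
            return float(m)
        if self.reward_mode == "unit":
            return float(min(m, 1))
        raise ValueError(f"unknown reward_mode {self.reward_mode!r}")


@dataclass(frozen=True)
class HypothesisScore:
    s_site: float
    s_vec: float
    s_vol: float
    s_sel: float
    m: int
    survival: float


def survival_from_components(s_site: float, s_vec: float, s_vol: float,
                             s_sel: float, m: int,
                             weights: WeightSet | None = None) -> float:
    w = weights or WeightSet()
    return (w.w_site * s_site + w.w_vec * s_vec + w.w_vol * s_vol
            + w.w_sel * s_sel + w.w_rew * w.reward(m))


def score_hypothesis(h: Hypothesis, aligned_actives: list[tuple[FeatureSet, Alignment]],
                     weights: WeightSet | None = None,
                     rmsd_cutoff: float = RMSD_CUTOFF,
                     background_match_fraction: float | None = None) -> HypothesisScore:
    """Survival score of a hypothesis over its aligned matching actives."""
    if not aligned_actives:
        raise ValueError("cannot score a hypothesis with no aligned actives")
    weights = weights or WeightSet()

    s_site = float(np.mean([max(0.0, 1.0 - a.rmsd / rmsd_cutoff) for _, a in aligned_actives]))

    # vector score: cosine between hypothesis vectors and the rotated vectors
    # of each aligned active, averaged over actives with any vector feature
    vec_means = []
    transformed_points = []
    for fs, aln in aligned_actives:
        refs, movs, ring = [], [], []
        for slot, fi in enumerate(aln.pairing):
            hv = h.reference_sites[slot].direction
            mv = fs.features[fi].direction
            if hv is not None and mv is not None:
                refs.append(hv)
                movs.append(aln.apply_vectors(np.asarray(mv)))
                ring.append(h.reference_sites[slot].type == "R")
        if refs:
            vec_means.append(mean_vector_cosine(np.array(refs), np.array(movs), np.array(ring)))
        transformed_points.append(aln.apply(fs.points(list(aln.pairing))))
    s_vec = float(np.clip(np.mean(vec_means), 0.0, 1.0)) if vec_means else 1.0

    # volume score: mean pairwise sphere-overlap Jaccard of the aligned sites
    if len(transformed_points) == 1:
        s_vol = 1.0
    else:
        vox = [voxelize_spheres(p) for p in transformed_points]
        jac = []
        for i in range(len(vox)):
            for j in range(i + 1, len(vox)):
                union = vox[i] | vox[j]
                jac.append(len(vox[i] & vox[j]) / len(union) if union else 1.0)
        s_vol = float(np.mean(jac))

    if background_match_fraction is None:
        s_sel = 0.0
    elif background_match_fraction <= 0:
        s_sel = 5.0  # cap: no background molecule matches
    else:
        s_sel = max(0.0, -float(np.log10(background_match_fraction)))

    m = max(0, len(aligned_actives) - 1)
    survival = survival_from_components(s_site, s_vec, s_vol, s_sel, m, weights)
    return HypothesisScore(s_site=s_site, s_vec=s_vec, s_vol=s_vol, s_sel=s_sel,
                           m=m, survival=survival)


# ---------------------------------------------------------------------------
# filtering and the end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class ScoredHypothesis:
    hypothesis: Hypothesis
    score: HypothesisScore
    max_pairwise_rmsd: float


def filter_hypotheses(candidates: list[ScoredHypothesis],
                      rmsd_threshold: float = FILTER_RMSD,
                      vec_threshold: float = FILTER_VEC) -> list[ScoredHypothesis]:
    """Retain candidates with max pairwise RMSD < 1.20 A and vector score
    > 0.50; sort by survival descending (ties: site score, then variant)."""
    kept = [c for c in candidates
            if c.max_pairwise_rmsd < rmsd_threshold and c.score.s_vec > vec_threshold]
    kept.sort(key=lambda c: (-c.score.survival, -c.score.s_site, c.hypothesis.variant))
    return kept


def _is_submultiset(small: str, big: str) -> bool:
    cs, cb = Counter(small), Counter(big)
    return all(cb.get(t, 0) >= c for t, c in cs.items())


def generate_hypotheses(feature_sets: list[FeatureSet], activities, scheme: ThresholdScheme,
                        k_min: int = 4, k_max: int = 7, bin_width: float = 1.0,
                        weights: WeightSet | None = None,
                        min_match: int | None = None,
                        max_per_variant_source: int = 1,
                        apply_filter: bool = True) -> list[ScoredHypothesis]:
    """Full pipeline: partition -> enumerate variants -> discover common
    arrangements -> align & score -> parsimony-prune -> filter & rank.

    Parsimony rule: a hypothesis whose variant is a strict sub-multiset of
    another discovered variant with at least as many matched actives is
    dropped — the more specific common pharmacophore subsumes its fragments.
    """
    labeled = partition_activity(activities, scheme)
    active_ids = {r.compound_id for r in labeled if r.label == "active"}
    actives = [fs for fs in best_conformers(feature_sets) if fs.molecule_id in active_ids]
    if min_match is None:
        min_match = min(scheme.min_match, len(actives)) if actives else scheme.min_match
    if not actives:
        return []

    variant_votes: Counter = Counter()
    for fs in actives:
        for v in enumerate_variants(fs.type_counts(), k_min, k_max):
            variant_votes[v] += 1
    variants = sorted((v for v, n in variant_votes.items() if n >= min_match),
                      key=lambda v: (-len(v), v))

    found: list[Hypothesis] = []
    for variant in variants:
        hyps = find_common_pharmacophores(actives, variant, min_match, bin_width)
        # keep the best-matched few per source molecule to bound scoring cost
        per_source: dict[str, list[Hypothesis]] = {}
        for hyp in hyps:
            per_source.setdefault(hyp.source_molecule, []).append(hyp)
        for source, group in per_source.items():
            group.sort(key=lambda hh: -len(hh.matched_actives))
            found.extend(group[:max_per_variant_source])

    # parsimony pruning
    pruned = [h1 for h1 in found
              if not any(len(h2.variant) > len(h1.variant)
                         and _is_submultiset(h1.variant, h2.variant)
                         and len(h2.matched_actives) >= len(h1.matched_actives)
                         for h2 in found)]

    by_id = {fs.molecule_id: fs for fs in actives}
    scored: list[ScoredHypothesis] = []
    for hyp in pruned:
        aligned = []
        for mid in hyp.matched_actives:
            aln = best_alignment_to(hyp, by_id[mid], bin_width)
            if aln is not None:
                aligned.append((by_id[mid], aln))
        if not aligned:
            continue
        score = score_hypothesis(hyp, aligned, weights)
        pts = [a.apply(fs.points(list(a.pairing))) for fs, a in aligned]
        max_rmsd = 0.0
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                max_rmsd = max(max_rmsd, align_to_reference(pts[i], pts[j]).rmsd)
        scored.append(ScoredHypothesis(hyp, score, max_rmsd))

    return filter_hypotheses(scored) if apply_filter else scored
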