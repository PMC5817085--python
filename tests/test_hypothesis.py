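"""Activity partitioning, variant enumeration, common-arrangement discovery,
alignment, survival scoring and filtering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from _oracles import grid_search_rmsd, naive_common_pharmacophores
from conftest import random_feature_set
from pharmkin.features import FeatureSet, PharmacophoreFeature
from pharmkin.geometry import align_to_reference
from pharmkin.hypothesis import (SCHEME_HIGH, Hypothesis, ScoredHypothesis,
                                 ThresholdScheme, WeightSet, best_alignment_to,
                                 enumerate_variants, filter_hypotheses,
                                 find_common_pharmacophores, generate_hypotheses,
                                 partition_activity, score_hypothesis,
                                 survival_from_components)


class TestPartition:
    def test_printed_thresholds(self):
        recs = partition_activity([("c1", 0.036), ("c2", 0.0005), ("c3", 0.01)], SCHEME_HIGH)
        assert [r.label for r in recs] == ["active", "inactive", "unlabeled"]

    def test_direction_below_inverts_comparators(self):
        scheme = ThresholdScheme(0.036, 1.0, min_match=1, direction="below")
        recs = partition_activity([("c1", 0.01), ("c2", 5.0), ("c3", 0.5)], scheme)
        assert [r.label for r in recs] == ["active", "inactive", "unlabeled"]

    def test_nonpositive_ec50_rejected(self):
        with pytest.raises(ValueError):
            partition_activity([("c1", 0.0)], SCHEME_HIGH)

    def test_inconsistent_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ThresholdScheme(0.001, 0.036, min_match=1)


class TestEnumerateVariants:
    def test_published_variant_counts(self):
        assert enumerate_variants({"A": 1, "D": 1, "P": 1, "R": 2}, 5, 5) == {"ADPRR"}
        assert enumerate_variants({"A": 2}, 2, 2) == {"AA"}
        assert enumerate_variants({"A": 1, "D": 1}, 4, 7) == set()

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            enumerate_variants({"A": 2}, 3, 2)

    @given(counts=st.dictionaries(st.sampled_from("ADHNPR"), st.integers(0, 3), max_size=4),
           k_min=st.integers(1, 4), span=st.integers(0, 2))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_exhaustive_and_sorted(self, counts, k_min, span):
        k_max = k_min + span
        got = enumerate_variants(counts, k_min, k_max)
        # oracle: filter all sorted k-strings over the alphabet
        letters = "".join(sorted(t * c for t, c in sorted(counts.items())))
        expect = set()
        for k in range(k_min, k_max + 1):
            expect.update("".join(c) for c in itertools.combinations(letters, k))
        assert got == expect
        for v in got:
            assert v == "".join(sorted(v))
            assert k_min <= len(v) <= k_max


class TestFindCommon:
    def test_zero_noise_plant_found_by_all(self):
        from pharmkin.synthetic import PlantSpec, plant_pharmacophore

        actives, _, _, _ = plant_pharmacophore(
            PlantSpec(noise_sigma=0.0, extra_sites_range=(0, 0), seed=3))
        hyps = find_common_pharmacophores(actives, "ADPRR", min_match=10)
        assert hyps and all(len(h.matched_actives) == 10 for h in hyps)

    def test_random_sites_share_nothing(self):
        from pharmkin.features import VECTOR_TYPES

        for seed in range(5):
            rng = np.random.default_rng(seed)
            mols = []
            for i in range(10):
                feats = []
                for t in "ADPRR":  # every molecule realises the variant
                    d = None
                    if t in VECTOR_TYPES:
                        v = rng.normal(size=3)
                        d = tuple(v / np.linalg.norm(v))
                    feats.append(PharmacophoreFeature(t, tuple(rng.uniform(0, 20, 3)), d))
                mols.append(FeatureSet(f"m{i}", 0, feats))
            assert find_common_pharmacophores(mols, "ADPRR", min_match=10) == []

    def test_single_molecule_single_pair(self):
        fs = FeatureSet("m", 0, [PharmacophoreFeature("A", (0, 0, 0)),
                                 PharmacophoreFeature("A", (2, 0, 0))])
        hyps = find_common_pharmacophores([fs], "AA", min_match=1)
        assert len(hyps) == 1
        assert hyps[0].matched_actives == ["m"]

    def test_rigid_transform_invariance(self, planted):
        actives = [fs for fs in planted[0]]
        base = find_common_pharmacophores(actives, "ADPRR", min_match=10)
        R = Rotation.from_euler("xyz", [0.5, 1.0, -0.3]).as_matrix()
        t = np.array([3.0, -7.0, 2.0])
        moved = []
        for i, fs in enumerate(actives):
            feats = fs.features
            if i == 0:  # transform one molecule rigidly
                feats = [PharmacophoreFeature(
                    f.type, tuple(R @ f.xyz + t),
                    tuple(R @ np.asarray(f.direction)) if f.direction is not None else None)
                    for f in fs.features]
            moved.append(FeatureSet(fs.molecule_id, fs.conformer_id, feats))
        after = find_common_pharmacophores(moved, "ADPRR", min_match=10)
        assert {(h.source_molecule, h.site_indices) for h in base} == \
               {(h.source_molecule, h.site_indices) for h in after}

    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(99)
        for _ in range(15):
            mols = [random_feature_set(rng, f"m{i}", int(rng.integers(3, 7)), box=8.0,
                                       types="ADH") for i in range(3)]
            variant = "ADH"
            got = find_common_pharmacophores(mols, variant, min_match=2)
            oracle = naive_common_pharmacophores(mols, variant, 2, 1.0)
            assert {(h.source_molecule, h.site_indices): frozenset(h.matched_actives)
                    for h in got} == oracle


class TestAlignment:
    def test_identity(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0], [1, 1, 3]], dtype=float)
        assert align_to_reference(pts, pts).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_pure_rotation(self):
        tri = np.array([[0, 0, 0], [3, 0, 0], [0, 4, 0]], dtype=float)
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        aln = align_to_reference(tri, tri @ Rz.T)
        assert aln.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(aln.rotation @ Rz, np.eye(3), atol=1e-9)
        assert np.linalg.det(aln.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_rotation_grid_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            ref = rng.normal(size=(5, 3)) * 3
            mov = rng.normal(size=(5, 3)) * 3
            assert align_to_reference(ref, mov).rmsd == pytest.approx(
                grid_search_rmsd(ref, mov), abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            align_to_reference(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_flagged_but_aligned(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        aln = align_to_reference(line, line)
        assert aln.degenerate
        assert aln.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rmsd_symmetric(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        assert align_to_reference(a, b).rmsd == pytest.approx(
            align_to_reference(b, a).rmsd, abs=1e-10)


def _scored(variant="ADPRR", survival=1.0, s_site=0.5, s_vec=0.8, max_rmsd=1.0):
    from pharmkin.hypothesis import HypothesisScore

    sites = [PharmacophoreFeature(t, (float(i), 0.0, 0.0),
                                  (0.0, 0.0, 1.0) if t in "ADR" else None)
             for i, t in enumerate(variant)]
    h = Hypothesis(variant=variant, reference_sites=sites, source_molecule="src")
    sc = HypothesisScore(s_site=s_site, s_vec=s_vec, s_vol=0.5, s_sel=0.0, m=1,
                         survival=survival)
    return ScoredHypothesis(h, sc, max_rmsd)


class TestSurvivalScore:
    def test_printed_component_reconstruction(self):
        s = survival_from_components(0.71, 0.912, 0.604, 0.0, m=1,
                                     weights=WeightSet(reward_mode="unit"))
        assert s == pytest.approx(3.226, abs=1e-9)

    def test_zero_case(self):
        assert survival_from_components(0, 0, 0, 0, m=0) == 0.0

    def test_linear_reward_arithmetic(self):
        assert survival_from_components(1, 1, 1, 0, m=2) == pytest.approx(5.0)

    def test_linear_in_each_weight(self):
        comps = (0.3, 0.6, 0.2, 0.4)
        base = WeightSet(w_sel=1.0)
        s0 = survival_from_components(*comps, m=2, weights=base)
        for fld, delta_s in [("w_site", 0.3), ("w_vec", 0.6), ("w_vol", 0.2),
                             ("w_sel", 0.4), ("w_rew", 2.0)]:
            import dataclasses

            w = dataclasses.replace(base, **{fld: getattr(base, fld) + 1.0})
            assert survival_from_components(*comps, m=2, weights=w) - s0 == \
                pytest.approx(delta_s, abs=1e-12)

    def test_score_requires_actives(self):
        with pytest.raises(ValueError):
            score_hypothesis(_scored().hypothesis, [])

    def test_self_score_is_maximal(self, planted):
        actives = planted[0]
        hyps = find_common_pharmacophores(actives[:1], "ADPRR", min_match=1)
        h = hyps[0]
        aln = best_alignment_to(h, actives[0])
        sc = score_hypothesis(h, [(actives[0], aln)])
        assert sc.s_site == pytest.approx(1.0, abs=1e-9)
        assert sc.s_vec == pytest.approx(1.0, abs=1e-9)
        assert sc.s_vol == pytest.approx(1.0)
        assert sc.m == 0

    def test_adding_matching_active_never_decreases_survival(self, planted):
        actives = planted[0]
        hyps = find_common_pharmacophores(actives, "ADPRR", min_match=10)
        h = hyps[0]
        aligned = [(fs, best_alignment_to(h, fs)) for fs in actives]
        prev = None
        for n in range(3, len(aligned) + 1):
            s = score_hypothesis(h, aligned[:n]).survival
            if prev is not None:
                assert s >= prev - 1e-9
            prev = s

    def test_selectivity_ignored_at_default_weight(self, planted):
        actives = planted[0]
        h = find_common_pharmacophores(actives, "ADPRR", min_match=10)[0]
        aligned = [(fs, best_alignment_to(h, fs)) for fs in actives]
        s_without = score_hypothesis(h, aligned)
        s_with = score_hypothesis(h, aligned, background_match_fraction=0.5)
        assert s_with.survival == pytest.approx(s_without.survival, abs=1e-12)
        assert s_with.s_sel > 0


class TestFilter:
    def test_rmsd_threshold(self):
        assert filter_hypotheses([_scored(max_rmsd=1.30)]) == []
        kept = filter_hypotheses([_scored(max_rmsd=1.0, s_vec=0.6)])
        assert len(kept) == 1

    def test_vector_threshold_strict(self):
        assert filter_hypotheses([_scored(s_vec=0.50)]) == []
        assert len(filter_hypotheses([_scored(s_vec=0.501)])) == 1

    def test_empty(self):
        assert filter_hypotheses([]) == []

    def test_sort_order(self):
        a = _scored(survival=3.0, s_site=0.9)
        b = _scored(survival=3.5, s_site=0.1)
        c = _scored(survival=3.0, s_site=0.9, variant="AADPR")
        out = filter_hypotheses([a, b, c])
        assert [x.score.survival for x in out] == [3.5, 3.0, 3.0]
        assert out[1].hypothesis.variant == "AADPR"  # tie broken lexicographically


class TestPipeline:
    def test_recovers_planted_variant(self, planted, scheme_all_actives):
        actives, decoys, activity, truth = planted
        scored = generate_hypotheses(
            actives + decoys, list(zip(activity.compound_id, activity.ec50_um)),
            scheme_all_actives)
        assert scored
        assert scored[0].hypothesis.variant == truth["variant"]
        assert len(scored[0].hypothesis.matched_actives) == 10

    def test_decoy_perturbation_does_not_change_survival(self, planted, scheme_all_actives):
        actives, decoys, activity, _ = planted
        pairs = list(zip(activity.compound_id, activity.ec50_um))
        with_decoys = generate_hypotheses(actives + decoys, pairs, scheme_all_actives)
        without = generate_hypotheses(actives, pairs, scheme_all_actives)
        assert with_decoys[0].score.survival == pytest.approx(
            without[0].score.survival, abs=1e-12)
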