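"""Synthetic generators: planted pharmacophores, noisy trajectories, and
parameter recovery."""

import itertools
import json

import numpy as np
import pytest

from pharmkin.features import site_sets_to_dict
from pharmkin.kinetics import KineticModel
from pharmkin.synthetic import (KineticSimSpec, PlantSpec, fit_parameters,
                                generate_trajectories, plant_pharmacophore)


class TestPlant:
    def test_determinism(self):
        a = plant_pharmacophore(PlantSpec(seed=5))
        b = plant_pharmacophore(PlantSpec(seed=5))
        assert json.dumps(site_sets_to_dict(a[0] + a[1])) == \
               json.dumps(site_sets_to_dict(b[0] + b[1]))
        assert a[2].to_csv() == b[2].to_csv()
        assert a[3] == b[3]

    def test_zero_noise_identical_distances(self):
        actives, _, _, truth = plant_pharmacophore(
            PlantSpec(noise_sigma=0.0, extra_sites_range=(0, 0), seed=2))
        ref = np.array([s["xyz"] for s in truth["reference_sites"]])
        ref_d = np.sort(np.linalg.norm(ref[:, None] - ref[None, :], axis=-1).ravel())
        for fs in actives:
            pts = fs.points()
            d = np.sort(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1).ravel())
            assert np.max(np.abs(d - ref_d)) < 1e-9

    def test_activity_labels_respect_scheme(self):
        from pharmkin.hypothesis import SCHEME_HIGH, partition_activity

        actives, decoys, activity, _ = plant_pharmacophore(PlantSpec(seed=9))
        recs = partition_activity(list(zip(activity.compound_id, activity.ec50_um)),
                                  SCHEME_HIGH)
        labels = {r.compound_id: r.label for r in recs}
        assert all(labels[fs.molecule_id] == "active" for fs in actives)
        assert all(labels[fs.molecule_id] == "inactive" for fs in decoys)

    def test_small_variant_rejected(self):
        with pytest.raises(ValueError):
            PlantSpec(variant="AD")

    def test_decoys_geometrically_separated(self):
        """Monte-Carlo: the planted inter-site distance profile differs from
        every type-preserving decoy assignment by > 2 A nearly always."""
        spec = PlantSpec(n_actives=1, n_decoys=100, extra_sites_range=(0, 0), seed=13)
        _, decoys, _, truth = plant_pharmacophore(spec)
        ref_pts = np.array([s["xyz"] for s in truth["reference_sites"]])
        ref_types = [s["type"] for s in truth["reference_sites"]]
        k = len(ref_types)
        separated = 0
        for fs in decoys:
            best_dev = np.inf
            for perm in itertools.permutations(range(k)):
                if any(fs.features[perm[i]].type != ref_types[i] for i in range(k)):
                    continue
                dev = 0.0
                for i in range(k):
                    for j in range(i + 1, k):
                        d_ref = np.linalg.norm(ref_pts[i] - ref_pts[j])
                        d_dec = np.linalg.norm(fs.features[perm[i]].xyz
                                               - fs.features[perm[j]].xyz)
                        dev = max(dev, abs(d_dec - d_ref))
                best_dev = min(best_dev, dev)
            if best_dev > 2.0:
                separated += 1
        assert separated / len(decoys) >= 0.95


class TestTrajectories:
    def test_zero_noise_equals_clean(self, single_mm_model):
        spec = KineticSimSpec(model=single_mm_model, noise_sigma_rel=0.0,
                              n_timepoints=20, t_end=10.0, seed=1)
        obs = generate_trajectories(spec)
        clean = single_mm_model.simulate(t_end=10.0, n_out=20)
        got = obs[obs.species == "P"].value.to_numpy()
        assert np.allclose(got, clean["P"], atol=1e-12)

    def test_seed_reproducibility(self, single_mm_model):
        spec = KineticSimSpec(model=single_mm_model, noise_sigma_rel=0.05,
                              n_timepoints=20, t_end=10.0, seed=4)
        assert generate_trajectories(spec).equals(generate_trajectories(spec))

    def test_noise_level_calibrated(self, single_mm_model):
        spec = KineticSimSpec(model=single_mm_model, noise_sigma_rel=0.02,
                              n_timepoints=200, t_end=10.0, seed=6)
        obs = generate_trajectories(spec)
        clean = single_mm_model.simulate(t_end=10.0, n_out=200)["P"]
        got = obs[obs.species == "P"].value.to_numpy()
        mask = clean > 1e-6
        rel_sd = np.std(got[mask] / clean[mask] - 1.0)
        assert rel_sd == pytest.approx(0.02, rel=0.20)

    def test_nonpositive_params_rejected(self, single_mm_model):
        with pytest.raises(ValueError):
            KineticSimSpec(model=single_mm_model, true_params={"cat.Vm": -1.0})


class TestFit:
    BOUNDS = {"cat.Vm": (0.01, 10.0), "cat.Km": (0.1, 50.0)}

    def test_noise_free_recovery(self, single_mm_model):
        spec = KineticSimSpec(model=single_mm_model,
                              true_params={"cat.Vm": 1.0, "cat.Km": 2.0},
                              noise_sigma_rel=0.0, n_timepoints=30, t_end=15.0,
                              obs_species=["S", "P"], seed=0)
        obs = generate_trajectories(spec)
        fit = fit_parameters(single_mm_model, obs, list(self.BOUNDS), self.BOUNDS,
                             n_starts=3, seed=0)
        assert fit.converged
        assert fit.estimates["cat.Vm"] == pytest.approx(1.0, rel=1e-4)
        assert fit.estimates["cat.Km"] == pytest.approx(2.0, rel=1e-4)

    def test_noisy_recovery_within_ten_percent(self, single_mm_model):
        errs = []
        for seed in range(3):
            spec = KineticSimSpec(model=single_mm_model,
                                  true_params={"cat.Vm": 1.0, "cat.Km": 2.0},
                                  noise_sigma_rel=0.01, n_timepoints=30, t_end=15.0,
                                  obs_species=["S", "P"], seed=seed)
            obs = generate_trajectories(spec)
            fit = fit_parameters(single_mm_model, obs, list(self.BOUNDS), self.BOUNDS,
                                 n_starts=3, seed=seed)
            errs.append(max(abs(fit.estimates["cat.Vm"] - 1.0),
                            abs(fit.estimates["cat.Km"] / 2.0 - 1.0)))
        assert np.median(errs) <= 0.10

    def test_wrong_topology_fits_worse(self, single_mm_model):
        """Observations from a saturating (MM) process are explained worse
        by a first-order mass-action model at substrate >> Km."""
        first_order = KineticModel.from_dict({
            "species": [{"name": "S", "init_um": 5.0}, {"name": "P", "init_um": 0.0}],
            "reactions": [{"id": "cat", "reactants": [{"species": "S"}],
                           "products": [{"species": "P"}],
                           "law": {"type": "mass_action", "params": {"k": 0.5}}}]})
        worse = 0
        for seed in range(3):
            spec = KineticSimSpec(model=single_mm_model,
                                  true_params={"cat.Vm": 1.0, "cat.Km": 0.5},
                                  noise_sigma_rel=0.01, n_timepoints=30, t_end=8.0,
                                  obs_species=["S", "P"], seed=seed)
            obs = generate_trajectories(spec)
            good = fit_parameters(single_mm_model, obs,
                                  ["cat.Vm", "cat.Km"], self.BOUNDS, n_starts=3, seed=seed)
            bad = fit_parameters(first_order, obs, ["cat.k"],
                                 {"cat.k": (0.001, 10.0)}, n_starts=3, seed=seed)
            if bad.residual > good.residual:
                worse += 1
        assert worse == 3

    def test_unknown_parameter_rejected(self, single_mm_model):
        with pytest.raises(Exception):
            fit_parameters(single_mm_model, None, ["cat.nope"], {"cat.nope": (0.1, 1.0)})

    def test_summary_renders(self, single_mm_model):
        spec = KineticSimSpec(model=single_mm_model, true_params={"cat.Vm": 1.0},
                              noise_sigma_rel=0.0, n_timepoints=10, t_end=5.0,
                              obs_species=["P"], seed=0)
        obs = generate_trajectories(spec)
        fit = fit_parameters(single_mm_model, obs, ["cat.Vm"],
                             {"cat.Vm": (0.1, 10.0)}, n_starts=2, seed=0)
        assert "cat.Vm" in fit.summary()
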