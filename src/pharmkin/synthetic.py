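"""Synthetic inputs with known ground truth.

Two generators cover everything the pipeline consumes without downloads:

* :func:`plant_pharmacophore` builds ligand site sets in which a known
  k-point pharmacophore is planted (rigidly moved, positionally jittered,
  padded with random extra sites) among type-matched random decoys, together
  with an EC50 activity table that the threshold scheme will label
  correctly;
* :func:`generate_trajectories` simulates a kinetic model at known
  parameters and applies multiplicative Gaussian observation noise, and
  :func:`fit_parameters` recovers free parameters from such observations by
  multi-start least squares over log-parameters.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .features import FEATURE_TYPES, VECTOR_TYPES, FeatureSet, PharmacophoreFeature
from .kinetics import KineticModel

#: planted actives draw EC50 in this range (labelled active by the
#: high-affinity scheme); decoys draw below its inactive bound
ACTIVE_EC50_RANGE = (0.036, 0.93)
DECOY_EC50_RANGE = (1e-4, 1e-3)


@dataclass
class PlantSpec:
    """Recipe for a ligand set with a planted common pharmacophore."""

    variant: str = "ADPRR"
    n_actives: int = 10
    n_decoys: int = 20
    noise_sigma: float = 0.1  # A, i.i.d. Gaussian on planted site positions
    extra_sites_range: tuple[int, int] = (0, 3)
    box_size: float = 20.0  # A
    geometry_extent: float = 8.0  # A, edge of the cube holding the planted sites
    min_site_separation: float = 2.0  # A, between planted sites
    reference_geometry: list[PharmacophoreFeature] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.variant) < 3:
            raise ValueError("planted variant needs at least 3 sites")
        if self.n_actives < 1:
            raise ValueError("n_actives must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        self.variant = "".join(sorted(self.variant))


def _random_unit(rng) -> tuple[float, float, float]:
    v = rng.normal(size=3)
    return tuple(v / np.linalg.norm(v))


def _make_reference(spec: PlantSpec, rng) -> list[PharmacophoreFeature]:
    k = len(spec.variant)
    extent = min(spec.geometry_extent, spec.box_size)
    for _ in range(1000):
        pts = rng.uniform(-extent / 2, extent / 2, size=(k, 3))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        if np.min(d[np.triu_indices(k, 1)]) >= spec.min_site_separation:
            break
    else:
        raise RuntimeError("could not place planted sites with the requested separation")
    feats = []
    for t, p in zip(spec.variant, pts):
        direction = _random_unit(rng) if t in VECTOR_TYPES else None
        feats.append(PharmacophoreFeature(t, tuple(p), direction))
    return feats


def _jitter_direction(direction, sigma, rng):
    if direction is None:
        return None
    v = np.asarray(direction) + rng.normal(scale=sigma, size=3)
    return tuple(v / np.linalg.norm(v))


def _random_extra_sites(n: int, center: np.ndarray, rng, spread: float = 8.0):
    feats = []
    for _ in range(n):
        t = FEATURE_TYPES[rng.integers(len(FEATURE_TYPES))]
        p = center + rng.uniform(-spread / 2, spread / 2, size=3)
        direction = _random_unit(rng) if t in VECTOR_TYPES else None
        feats.append(PharmacophoreFeature(t, tuple(p), direction))
    return feats


def plant_pharmacophore(spec: PlantSpec):
    """Generate (actives, decoys, activity table, truth record).

    Each active carries the reference geometry under a random rigid motion
    with i.i.d. Gaussian positional noise, plus random extra sites; decoys
    carry the same site-type multiset at uniform random positions in the
    box.  EC50 values are drawn so the high-affinity threshold scheme labels
    actives active and decoys inactive.
    """
    rng = np.random.default_rng(spec.seed)
    reference = spec.reference_geometry or _make_reference(spec, rng)
    ref_pts = np.array([f.point for f in reference])

    actives: list[FeatureSet] = []
    for i in range(spec.n_actives):
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(0, spec.box_size, size=3)
        feats = []
        for f in reference:
            p = rot @ np.asarray(f.point) + shift + rng.normal(scale=spec.noise_sigma, size=3)
            d = None
            if f.direction is not None:
                d = _jitter_direction(rot @ np.asarray(f.direction), spec.noise_sigma, rng)
            feats.append(PharmacophoreFeature(f.type, tuple(p), d))
        n_extra = int(rng.integers(spec.extra_sites_range[0], spec.extra_sites_range[1] + 1))
        center = rot @ ref_pts.mean(axis=0) + shift
        feats.extend(_random_extra_sites(n_extra, center, rng))
        actives.append(FeatureSet(molecule_id=f"active{i:03d}", conformer_id=0, features=feats))

    decoys: list[FeatureSet] = []
    for i in range(spec.n_decoys):
        feats = []
        for t in spec.variant:
            p = rng.uniform(0, spec.box_size, size=3)
            direction = _random_unit(rng) if t in VECTOR_TYPES else None
            feats.append(PharmacophoreFeature(t, tuple(p), direction))
        n_extra = int(rng.integers(spec.extra_sites_range[0], spec.extra_sites_range[1] + 1))
        feats.extend(_random_extra_sites(n_extra, rng.uniform(0, spec.box_size, size=3), rng))
        decoys.append(FeatureSet(molecule_id=f"decoy{i:03d}", conformer_id=0, features=feats))

    rows = ([{"compound_id": fs.molecule_id,
              "ec50_um": float(rng.uniform(*ACTIVE_EC50_RANGE))} for fs in actives]
            + [{"compound_id": fs.molecule_id,
                "ec50_um": float(rng.uniform(*DECOY_EC50_RANGE))} for fs in decoys])
    activity = pd.DataFrame(rows)

    truth = {
        "variant": spec.variant,
        "seed": spec.seed,
        "reference_sites": [
            {"type": f.type, "xyz": list(f.point),
             "dir": list(f.direction) if f.direction is not None else None}
            for f in reference],
    }
    return actives, decoys, activity, truth


# ---------------------------------------------------------------------------
# kinetic trajectories and parameter recovery
# ---------------------------------------------------------------------------


@dataclass
class KineticSimSpec:
    model: KineticModel
    true_params: dict[str, float] = field(default_factory=dict)
    noise_sigma_rel: float = 0.01
    n_timepoints: int = 50
    t_end: float = 600.0
    obs_species: list[str] | None = None  # default: the model readouts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma_rel < 0:
            raise ValueError("noise_sigma_rel must be >= 0")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        for name, val in self.true_params.items():
            if val <= 0:
                raise ValueError(f"true parameter {name} must be positive")


def generate_trajectories(spec: KineticSimSpec) -> pd.DataFrame:
    """Simulate at the true parameters and apply multiplicative noise
    ``value * (1 + eps)``, ``eps ~ N(0, noise_sigma_rel^2)``.  Long format:
    time, species, value."""
    rng = np.random.default_rng(spec.seed)
    model = spec.model.copy()
    for name, val in spec.true_params.items():
        model.set_parameter(name, val)
    traj = model.simulate(t_end=spec.t_end, n_out=spec.n_timepoints)
    species = spec.obs_species or model.readouts or [s.name for s in model.species]
    rows = []
    for sp in species:
        clean = traj[sp]
        noisy = clean * (1.0 + rng.normal(scale=spec.noise_sigma_rel, size=len(clean)))
        for t, v in zip(traj.times, noisy):
            rows.append({"time": float(t), "species": sp, "value": float(v)})
    return pd.DataFrame(rows)


@dataclass
class FitResult:
    estimates: dict[str, float]
    residual: float  # root-mean-square relative residual at the optimum
    converged: bool
    n_starts: int
    start_costs: list[float] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["parameter          estimate", "-" * 30]
        lines += [f"{k:<18s} {v:.6g}" for k, v in self.estimates.items()]
        lines.append(f"rms relative residual: {self.residual:.4g}")
        lines.append(f"converged: {self.converged} ({self.n_starts} starts)")
        return "\n".join(lines)


def fit_parameters(model: KineticModel, observations: pd.DataFrame,
                   free_params: list[str], bounds: dict[str, tuple[float, float]],
                   n_starts: int = 5, seed: int = 0) -> FitResult:
    """Recover ``free_params`` by least squares on relative residuals over
    log-parameters, with seeded multi-start.

    ``observations`` is the long table produced by
    :func:`generate_trajectories`.  Rate constants span decades and must
    stay positive, hence the log parameterisation and multiplicative-noise
    residual.  Non-convergence on all starts yields ``converged=False``
    rather than an exception.
    """
    for p in free_params:
        model.get_parameter(p)  # raises on unknown names
        lo, hi = bounds[p]
        if lo <= 0 or hi <= lo:
            raise ValueError(f"bounds for {p} must be positive with lo < hi")

    times = np.array(sorted(observations["time"].unique()), dtype=float)
    t_end = float(times.max())
    species = sorted(observations["species"].unique())
    obs_wide = observations.pivot_table(index="time", columns="species", values="value").loc[times, species]
    obs = obs_wide.to_numpy()
    # relative residual with a per-species floor so near-zero early samples
    # do not dominate
    denom = np.abs(obs) + 0.05 * np.maximum(np.max(np.abs(obs), axis=0, keepdims=True), 1e-12)

    work = model.copy()

    def residuals(x):
        for p, val in zip(free_params, np.exp(x)):
            work.set_parameter(p, float(val))
        try:
            traj = work.simulate(t_end=t_end, t_eval=times, rtol=1e-7, atol=1e-10)
        except RuntimeError:
            return np.full(obs.size, 1e3)
        pred = np.column_stack([traj[sp] for sp in species])
        return ((pred - obs) / denom).ravel()

    log_lo = np.log([bounds[p][0] for p in free_params])
    log_hi = np.log([bounds[p][1] for p in free_params])
    rng = np.random.default_rng(seed)
    current = np.log([model.get_parameter(p) for p in free_params])
    starts = [np.clip(current, log_lo, log_hi)]
    starts += [rng.uniform(log_lo, log_hi) for _ in range(n_starts - 1)]

    best = None
    costs = []
    any_converged = False
    for x0 in starts:
        res = least_squares(residuals, x0, bounds=(log_lo, log_hi), method="trf")
        costs.append(float(res.cost))
        if res.success:
            any_converged = True
        if best is None or res.cost < best.cost:
            best = res

    estimates = {p: float(v) for p, v in zip(free_params, np.exp(best.x))}
    rms = float(np.sqrt(np.mean(best.fun ** 2)))
    return FitResult(estimates=estimates, residual=rms,
                     converged=any_converged and bool(best.success),
                     n_starts=len(starts), start_costs=costs)
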