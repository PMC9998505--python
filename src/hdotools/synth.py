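"""Synthetic fMRI signal generator.

Emulates the phenomenology of rodent BOLD time courses recorded under
vasoconstrictive sedation: a baseline with slow polynomial drift, white
scanner noise, an optional vasomotion-driven hemodynamic oscillation (HDO)
near 0.2 Hz whose spectral peak is approximately Gaussian with a
configurable width, an optional narrowband respiration component near
0.9 Hz, and optional BOLD responses to a block stimulation paradigm through
a rat HRF.

The HDO component is a sinusoid with slow Ornstein--Uhlenbeck frequency and
amplitude drift.  In the slow-modulation limit the spectral line shape
approaches the distribution of the instantaneous frequency, so the standard
deviation of the OU frequency excursions is calibrated such that a Gaussian
fitted to the amplitude-spectrum peak recovers ``bandwidth`` as its sigma.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .hrf import HRFParams, hrf_basis
from .timecourse import StimulusParadigm, TimeCourse

__all__ = [
    "OscillationSpec",
    "BoldSpec",
    "SignalRecipe",
    "SyntheticDataset",
    "simulate_time_course",
    "simulate_dataset",
    "simulate_volume",
    "make_block_labels",
    "benchmark_courses",
    "connectivity_benchmark",
    "write_dataset",
]

#: correlation time of the OU frequency drift, seconds.  Long relative to one
#: oscillation period (5 s) so the line shape is set by the frequency
#: excursions (inhomogeneous broadening), not by the drift rate.
_FREQ_DRIFT_TAU = 30.0
#: relative amplitude drift of the oscillation (OU, std and correlation time)
_AMP_DRIFT_STD = 0.2
_AMP_DRIFT_TAU = 60.0


@dataclass(frozen=True)
class OscillationSpec:
    """Narrowband oscillatory component.

    freq : center frequency in Hz.
    bandwidth : Gaussian sigma of the spectral peak, Hz.  0 gives a pure
        sinusoid.
    amplitude : peak amplitude in percent of the recipe baseline.
    phase_locking : optional paradigm; the oscillation phase is reset and
        its amplitude briefly suppressed (one period) at each stimulus
        onset, emulating stimulus-locked vasomotion.
    """

    freq: float
    bandwidth: float = 0.0
    amplitude: float = 2.0
    phase_locking: StimulusParadigm | None = None

    def __post_init__(self) -> None:
        if self.freq <= 0:
            raise ValueError(f"freq must be positive, got {self.freq}")
        if self.bandwidth < 0:
            raise ValueError(f"bandwidth must be >= 0, got {self.bandwidth}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class BoldSpec:
    """BOLD responses to a block paradigm; amplitude in % of baseline."""

    paradigm: StimulusParadigm
    amplitude: float = 2.0
    hrf_params: HRFParams = field(default_factory=HRFParams)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class SignalRecipe:
    """Full description of one synthetic time course."""

    duration: float = 600.0
    dt: float = 1.0
    baseline: float = 100.0
    drift_order: int = 1
    drift_sd: float = 1.0
    noise_sd: float = 1.0
    hdo: OscillationSpec | None = None
    respiration: OscillationSpec | None = None
    bold: BoldSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.drift_order < 0:
            raise ValueError(f"drift_order must be >= 0, got {self.drift_order}")
        if round(self.duration / self.dt) < 64:
            raise ValueError("duration/dt must give at least 64 samples "
                             f"(got {self.duration / self.dt:.1f})")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt))


def _ou_path(rng: np.random.Generator, n: int, dt: float, tau: float,
             std: float) -> np.ndarray:
    """Stationary Ornstein--Uhlenbeck path, mean 0, stationary std ``std``."""
    a = np.exp(-dt / tau)
    innov_sd = std * np.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = rng.normal(0.0, std)
    eps = rng.normal(0.0, innov_sd, n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + eps[i - 1]
    return x


def _oscillation(spec: OscillationSpec, n: int, dt: float, baseline: float,
                 rng: np.random.Generator) -> np.ndarray:
    amp = spec.amplitude / 100.0 * baseline
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    if spec.bandwidth > 0:
        # the amplitude spectrum is the square root of the power spectrum,
        # which widens the fitted Gaussian by sqrt(2); compensate here
        delta = _ou_path(rng, n, dt, _FREQ_DRIFT_TAU,
                         spec.bandwidth / np.sqrt(2.0))
        env = 1.0 + _ou_path(rng, n, dt, _AMP_DRIFT_TAU, _AMP_DRIFT_STD)
        env = np.clip(env, 0.0, None)
    else:
        delta = np.zeros(n)
        env = np.ones(n)
    inst_freq = spec.freq + delta
    phase = phi0 + 2.0 * np.pi * np.concatenate(
        [[0.0], np.cumsum(inst_freq[:-1]) * dt])
    if spec.phase_locking is not None:
        t = np.arange(n) * dt
        period = 1.0 / spec.freq
        for onset in spec.phase_locking.onsets:
            after = t >= onset
            if not after.any():
                continue
            i0 = int(np.argmax(after))
            # phase reset at onset ...
            phase[after] -= phase[i0]
            # ... and brief interruption for one period
            env = env * np.where((t >= onset) & (t < onset + period), 0.0, 1.0)
    return amp * env * np.cos(phase)


def _legendre_drift(order: int, sd: float, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n)
    drift = np.zeros(n)
    for k in range(1, order + 1):
        coeff = rng.normal(0.0, sd)
        drift += coeff * np.polynomial.legendre.Legendre.basis(k)(x)
    return drift


def _bold_component(spec: BoldSpec, n: int, dt: float,
                    baseline: float) -> np.ndarray:
    box = spec.paradigm.boxcar(n, dt)
    basis = hrf_basis(dt, params=spec.hrf_params)
    resp = np.convolve(box, basis[:, 0])[:n]
    peak = np.max(np.abs(resp))
    if peak > 0:
        resp = resp / peak
    return spec.amplitude / 100.0 * baseline * resp


def simulate_time_course(recipe: SignalRecipe) -> TimeCourse:
    """Generate one synthetic time course.

    Deterministic given ``recipe.seed``.  Each component (drift, HDO,
    respiration, BOLD, noise) draws from its own child stream of the seed,
    so the output is the exact sample-wise sum of the components generated
    separately with the same seed (linearity).
    """
    n = recipe.n_samples
    streams = [np.random.default_rng(s) for s in
               np.random.SeedSequence(recipe.seed).spawn(5)]
    rng_drift, rng_hdo, rng_resp, _rng_bold, rng_noise = streams

    signal = np.full(n, float(recipe.baseline))
    if recipe.drift_order > 0 and recipe.drift_sd > 0:
        signal = signal + _legendre_drift(recipe.drift_order, recipe.drift_sd,
                                          n, rng_drift)
    if recipe.hdo is not None:
        signal = signal + _oscillation(recipe.hdo, n, recipe.dt,
                                       recipe.baseline, rng_hdo)
    if recipe.respiration is not None:
        signal = signal + _oscillation(recipe.respiration, n, recipe.dt,
                                       recipe.baseline, rng_resp)
    if recipe.bold is not None:
        signal = signal + _bold_component(recipe.bold, n, recipe.dt,
                                          recipe.baseline)
    if recipe.noise_sd > 0:
        signal = signal + rng_noise.normal(0.0, recipe.noise_sd, n)
    return TimeCourse(signal, dt=recipe.dt, t0=0.0, label=f"synthetic-{recipe.seed}")


# ---------------------------------------------------------------------------
# multi-region datasets and volumes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticDataset:
    """A set of region time courses with known HDO ground truth."""

    region_names: list
    time_courses: list
    oscillatory_nodes: list
    truth_labels: dict

    def __post_init__(self) -> None:
        if not set(self.oscillatory_nodes) <= set(self.region_names):
            raise ValueError("oscillatory_nodes must be a subset of region_names")
        for name in self.region_names:
            expected = name in self.oscillatory_nodes
            if self.truth_labels[name] != expected:
                raise ValueError(f"truth label inconsistent for region {name}")

    def course(self, name: str) -> TimeCourse:
        return self.time_courses[self.region_names.index(name)]


def simulate_dataset(n_regions: int, n_oscillatory: int,
                     recipe_defaults: SignalRecipe | None = None,
                     seed: int = 0) -> SyntheticDataset:
    """Simulate ``n_regions`` region courses, ``n_oscillatory`` of them with HDO.

    The oscillatory node subset is drawn from ``seed``; per-region component
    seeds derive from ``seed`` as well.
    """
    if not 0 <= n_oscillatory <= n_regions:
        raise ValueError(
            f"n_oscillatory must be in [0, n_regions], got {n_oscillatory}")
    base = recipe_defaults or SignalRecipe()
    hdo_spec = base.hdo or OscillationSpec(freq=0.20, bandwidth=0.025,
                                           amplitude=3.0)
    rng = np.random.default_rng(seed)
    names = [f"R{i + 1:02d}" for i in range(n_regions)]
    osc = sorted(rng.choice(names, size=n_oscillatory, replace=False).tolist())
    region_seeds = rng.integers(0, 2**31 - 1, size=n_regions)
    courses = []
    for name, rseed in zip(names, region_seeds):
        recipe = replace(base, hdo=hdo_spec if name in osc else None,
                         seed=int(rseed))
        courses.append(replace(simulate_time_course(recipe), label=name))
    labels = {name: name in osc for name in names}
    return SyntheticDataset(names, courses, osc, labels)


def make_block_labels(shape: tuple, n_regions: int) -> np.ndarray:
    """Partition a 3-D grid into ``n_regions`` contiguous slabs (labels 1..n).

    Slabs run along the first axis; any leftover voxels keep label 0
    (background).  Convenience for building synthetic label volumes.
    """
    labels = np.zeros(shape, dtype=int)
    nx = shape[0]
    if n_regions > nx:
        raise ValueError("need at least one x-plane per region")
    edges = np.linspace(0, nx, n_regions + 1).astype(int)
    for r in range(n_regions):
        labels[edges[r]:edges[r + 1]] = r + 1
    return labels


def simulate_volume(labels: np.ndarray, dataset: SyntheticDataset,
                    voxel_noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Expand region courses into a 4-D volume (x, y, z, t).

    Each voxel with label ``k`` carries the course of region ``k`` plus
    independent Gaussian voxel noise; label-0 (background) voxels are pure
    noise and belong to no region.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("labels must be a 3-D integer volume")
    present = set(int(v) for v in np.unique(labels)) - {0}
    if len(present) > len(dataset.region_names):
        raise ValueError("label volume references more regions than dataset has")
    max_label = max(present) if present else 0
    if max_label > len(dataset.region_names):
        raise ValueError(
            f"label {max_label} has no matching region in the dataset")
    n_t = len(dataset.time_courses[0])
    rng = np.random.default_rng(seed)
    vol = rng.normal(0.0, voxel_noise_sd if voxel_noise_sd > 0 else 1.0,
                     labels.shape + (n_t,))
    if voxel_noise_sd == 0:
        vol[:] = 0.0
    for k in present:
        vol[labels == k] += dataset.time_courses[k - 1].values
    return vol


# ---------------------------------------------------------------------------
# standard benchmark for detector training / evaluation
# ---------------------------------------------------------------------------

def benchmark_courses(n_positive: int, n_negative: int, seed: int,
                      duration: float = 600.0, dt: float = 1.0,
                      respiration_fraction: float = 0.7):
    """Labelled synthetic benchmark for the HDO detector.

    Negatives: Gaussian noise (1% of baseline), low-order polynomial drift
    and, for ``respiration_fraction`` of courses, a narrowband ~0.9 Hz
    respiration component (which aliases into the low-frequency band at
    TR = 1 s, the confound the detector must reject).  Positives add an HDO
    component with center frequency N(0.20, 0.02) Hz, peak width
    |N(0.025, 0.015)| Hz and amplitude uniform in 2--6% of baseline.

    Returns ``(courses, labels)`` with ``labels[i]`` True for HDO present.
    """
    rng = np.random.default_rng(seed)
    courses, labels = [], []
    for i in range(n_positive + n_negative):
        positive = i < n_positive
        resp = None
        if rng.uniform() < respiration_fraction:
            resp = OscillationSpec(freq=rng.normal(0.9, 0.05),
                                   bandwidth=0.02,
                                   amplitude=rng.uniform(0.5, 2.0))
        hdo = None
        if positive:
            freq = float(np.clip(rng.normal(0.20, 0.02), 0.12, 0.30))
            bw = float(np.clip(abs(rng.normal(0.025, 0.015)), 0.004, 0.06))
            hdo = OscillationSpec(freq=freq, bandwidth=bw,
                                  amplitude=rng.uniform(2.0, 6.0))
        recipe = SignalRecipe(duration=duration, dt=dt,
                              drift_order=int(rng.integers(0, 3)),
                              hdo=hdo, respiration=resp,
                              seed=int(rng.integers(0, 2**31 - 1)))
        courses.append(simulate_time_course(recipe))
        labels.append(positive)
    return courses, np.array(labels, dtype=bool)


def connectivity_benchmark(seed: int = 0, n_nodes: int = 28, n_pairs: int = 9,
                           clique_nodes: int = 4, effect_d: float = 2.0,
                           shift: float = 0.1, planted: bool = True):
    """Paired connectivity matrices with a known altered component.

    Emulates the suppressed-vs-unsuppressed contrast: a group-level
    connectivity backbone (Fisher-z strengths uniform in [0.1, 0.5], the
    planted clique elevated to 0.7 so its edges rank among the strongest),
    per-subject z-noise shared between the two conditions, and independent
    per-edge paired differences of standard deviation ``shift / effect_d``.
    With ``planted`` the ``clique_nodes``-node clique's edges additionally
    shift by ``shift`` (suppressed minus unsuppressed), i.e. a per-edge
    paired effect size of exactly ``effect_d``; without it the two
    conditions share the same generator (global null).

    Returns ``(unsuppressed, suppressed, clique_edges)``.
    """
    from .network import ConnectivityMatrix  # local import: avoid cycle

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_nodes, k=1)
    base = np.zeros((n_nodes, n_nodes))
    base[iu] = rng.uniform(0.1, 0.5, iu[0].size)
    base = base + base.T
    nodes = rng.choice(n_nodes, clique_nodes, replace=False)
    clique = [(min(a, b), max(a, b)) for ai, a in enumerate(nodes)
              for b in nodes[ai + 1:]]
    if planted:
        for i, j in clique:
            base[i, j] = base[j, i] = 0.7
    sd = shift / effect_d
    regions = [f"R{k + 1:02d}" for k in range(n_nodes)]
    unsup, sup = [], []
    for k in range(n_pairs):
        rk = np.random.default_rng(seed * 1000 + k)
        zb = np.zeros((n_nodes, n_nodes))
        zb[iu] = base[iu] + rk.normal(0.0, 0.05, iu[0].size)
        zb = zb + zb.T
        dn = np.zeros((n_nodes, n_nodes))
        dn[iu] = rk.normal(0.0, sd, iu[0].size)
        dn = dn + dn.T
        if planted:
            for i, j in clique:
                dn[i, j] += shift
                dn[j, i] += shift
        r1, r2 = np.tanh(zb), np.tanh(zb + dn)
        for r in (r1, r2):
            np.fill_diagonal(r, 1.0)
        unsup.append(ConnectivityMatrix(regions, np.clip(r1, 0.0, None)))
        sup.append(ConnectivityMatrix(regions, np.clip(r2, 0.0, None)))
    return unsup, sup, clique


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, out_dir, seed: int | None = None,
                  recipe: SignalRecipe | None = None) -> None:
    """Write one CSV per region plus a JSON manifest with the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, tc in zip(dataset.region_names, dataset.time_courses):
        tc.to_csv(out / f"{name}.csv")
    manifest = {
        "region_names": dataset.region_names,
        "oscillatory_nodes": dataset.oscillatory_nodes,
        "truth_labels": {k: bool(v) for k, v in dataset.truth_labels.items()},
        "seed": seed,
        "recipe": None if recipe is None else {
            "duration": recipe.duration, "dt": recipe.dt,
            "baseline": recipe.baseline, "noise_sd": recipe.noise_sd,
            "drift_order": recipe.drift_order,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
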