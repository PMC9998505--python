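"""GLM activation mapping and the impact of HDO suppression on it.

Voxelwise general linear model with a 3rd-order canonical basis set (rat
HRF convolved with the stimulation boxcar, plus its temporal and dispersion
derivatives), an omnibus F-test over the three task regressors, Bonferroni
family-wise error correction across voxels, and face-connected cluster
extraction.  Impact is summarized as the ratio of cluster size and maximum
F between suppressed and original data, compared between oscillatory and
non-oscillatory cohorts with a Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .hrf import HRFParams, hrf_basis
from .timecourse import StimulusParadigm

__all__ = [
    "DesignMatrix",
    "ActivationResult",
    "ImpactSummary",
    "build_design",
    "fit_glm_f",
    "threshold_and_cluster",
    "impact_summary",
    "compare_groups",
    "passes_activation_criteria",
]

_OVERSAMPLE = 16  # boxcar/HRF convolution grid refinement


@dataclass(frozen=True)
class DesignMatrix:
    """Task + nuisance regressors; the first three columns are the task set."""

    X: np.ndarray
    dt: float
    names: list

    def __post_init__(self) -> None:
        if self.X.shape[1] < 4:
            raise ValueError("design needs >= 4 columns (3 task + intercept)")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_scans(self) -> int:
        return self.X.shape[0]

    @property
    def task(self) -> np.ndarray:
        return self.X[:, :3]

    @property
    def nuisance(self) -> np.ndarray:
        return self.X[:, 3:]


def build_design(paradigm: StimulusParadigm, n_scans: int, dt: float,
                 hrf_params: HRFParams | None = None,
                 drift_order: int = 1) -> DesignMatrix:
    """Build the design matrix for a block paradigm.

    The three task regressors are the boxcar convolved with the HRF, its
    temporal derivative and its dispersion derivative, computed on an
    oversampled grid, resampled to the scan grid and mean-centered.
    Nuisance columns are a Legendre drift basis up to ``drift_order``
    (order 0 = intercept).
    """
    if len(paradigm) == 0:
        raise ValueError("paradigm has no stimulation blocks")
    if paradigm.onsets[0] >= n_scans * dt:
        raise ValueError("paradigm starts after the end of the scan")
    fine_dt = dt / _OVERSAMPLE
    n_fine = n_scans * _OVERSAMPLE
    box = paradigm.boxcar(n_fine, fine_dt)
    basis = hrf_basis(fine_dt, params=hrf_params)
    cols = []
    for k in range(3):
        conv = np.convolve(box, basis[:, k])[:n_fine] * fine_dt
        coarse = conv.reshape(n_scans, _OVERSAMPLE).mean(axis=1)
        col = coarse - coarse.mean()
        # orthogonalize each derivative against the preceding task columns
        for prev in cols:
            col = col - prev * (prev @ col) / (prev @ prev)
        cols.append(col)
    x = np.linspace(-1.0, 1.0, n_scans)
    names = ["hrf", "hrf_dt", "hrf_disp"]
    for k in range(drift_order + 1):
        cols.append(np.polynomial.legendre.Legendre.basis(k)(x))
        names.append(f"drift{k}")
    return DesignMatrix(X=np.column_stack(cols), dt=dt, names=names)


def fit_glm_f(data: np.ndarray, design: DesignMatrix):
    """Omnibus F statistic for the three task regressors.

    ``data`` is (n_scans,) for one series or (n_scans, n_series).  Returns
    ``(F, dof)`` with ``dof = (3, n - p)``; F has the shape of the series
    axis.
    """
    X = design.X
    n, p = X.shape
    if n <= p + 10:
        raise ValueError(f"need n_scans > n_regressors + 10 ({n} vs {p})")
    Y = np.asarray(data, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    if Y.shape[0] != n:
        raise ValueError("data length does not match the design")

    def rss(M):
        beta, *_ = np.linalg.lstsq(M, Y, rcond=None)
        r = Y - M @ beta
        return np.einsum("ij,ij->j", r, r)

    rss_full = rss(X)
    rss_red = rss(design.nuisance)
    dof = (3, n - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / dof[0]) / (rss_full / dof[1])
    F = np.where(rss_full <= 0, np.inf, F)
    return (float(F[0]) if squeeze else F), dof


@dataclass(frozen=True)
class ActivationResult:
    """Thresholded F map with its face-connected suprathreshold clusters."""

    F_map: np.ndarray
    threshold: float
    clusters: list  # list of {"voxels": ndarray of indices, "size": int}
    max_F: float | None

    @property
    def n_activated(self) -> int:
        return int(sum(c["size"] for c in self.clusters))


def threshold_and_cluster(F_map: np.ndarray, dof: tuple, alpha: float = 0.05,
                          n_voxels: int | None = None) -> ActivationResult:
    """Bonferroni-FWE threshold and face-connected components.

    ``n_voxels`` is the correction count (defaults to the map size, i.e.
    an all-brain mask).
    """
    F_map = np.asarray(F_map, dtype=float)
    if n_voxels is None:
        n_voxels = F_map.size
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    thr = float(stats.f.isf(alpha / n_voxels, *dof))
    mask = F_map > thr
    structure = ndimage.generate_binary_structure(F_map.ndim, 1)
    labelled, n_comp = ndimage.label(mask, structure=structure)
    clusters = []
    for k in range(1, n_comp + 1):
        vox = np.argwhere(labelled == k)
        clusters.append({"voxels": vox, "size": int(vox.shape[0])})
    clusters.sort(key=lambda c: c["size"], reverse=True)
    max_F = float(F_map[mask].max()) if mask.any() else None
    return ActivationResult(F_map=F_map, threshold=thr, clusters=clusters,
                            max_F=max_F)


def passes_activation_criteria(result: ActivationResult, min_voxels: int = 12,
                               max_voxels: int = 100) -> bool:
    """Dataset inclusion rule: more than 12 and at most 100 activated voxels."""
    return min_voxels < result.n_activated <= max_voxels


def _primary_cluster_size(result: ActivationResult,
                          target_mask: np.ndarray | None) -> int:
    if not result.clusters:
        return 0
    if target_mask is None:
        return result.clusters[0]["size"]
    best = 0
    for c in result.clusters:
        idx = tuple(c["voxels"].T)
        if target_mask[idx].any():
            best = max(best, c["size"])
    return best


@dataclass(frozen=True)
class ImpactSummary:
    """Suppressed/original ratios for one dataset."""

    rel_cluster_size: float
    rel_max_F: float
    group: str  # "oscillatory" | "non-oscillatory"


def impact_summary(orig: ActivationResult, supp: ActivationResult, group: str,
                   target_mask: np.ndarray | None = None) -> ImpactSummary:
    """Ratios of primary-cluster size and maximum F, suppressed / original."""
    if not orig.clusters or orig.max_F is None:
        raise ValueError("original map has no activation; dataset excluded")
    size_o = _primary_cluster_size(orig, target_mask)
    size_s = _primary_cluster_size(supp, target_mask)
    if size_o == 0:
        raise ValueError("no original cluster intersects the target region")
    max_s = supp.max_F if supp.max_F is not None else 0.0
    return ImpactSummary(rel_cluster_size=size_s / size_o,
                         rel_max_F=max_s / orig.max_F, group=group)


def compare_groups(oscillatory: list[ImpactSummary],
                   non_oscillatory: list[ImpactSummary]) -> dict:
    """Two-sided Mann-Whitney U tests on both ratios, Bonferroni-corrected.

    The Bonferroni factor is 2 (the two comparisons: relative max F and
    relative cluster size).
    """
    if len(oscillatory) < 2 or len(non_oscillatory) < 2:
        raise ValueError("each group needs at least 2 datasets")
    out = {}
    for key, get in (("rel_max_F", lambda s: s.rel_max_F),
                     ("rel_cluster_size", lambda s: s.rel_cluster_size)):
        a = [get(s) for s in oscillatory]
        b = [get(s) for s in non_oscillatory]
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        out[key] = {"U": float(res.statistic), "p": float(res.pvalue),
                    "p_bonferroni": float(min(1.0, 2.0 * res.pvalue))}
    return out
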