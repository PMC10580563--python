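"""Incremental per-voxel GLM and network activation z-scores for feedback.

Each time a volume arrives, every voxel in the DMN and FPN masks gets its
nuisance GLM (intercept, six relative-displacement motion regressors, one
linear drift regressor) refit over all volumes so far via Gentleman's
square-root-free Givens updating — O(p²) per volume per voxel instead of a
from-scratch solve.  The fitted nuisance prediction is subtracted from the
measured signal; the residual is z-scored against the mean and SD of the
residuals over the 25-volume (30 s) baseline window, and network
activation is the inverse-baseline-variance ("efficiency") weighted mean
of voxel z-scores.  The feedback quantity is the Positive Diametric
Activity, PDA = z_FPN − z_DMN, and a volume is an outlier when either
network z exceeds 2 baseline SDs in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from scipy import ndimage

N_REGRESSORS = 8  # intercept + 6 motion relative displacements + drift

#: baseline residual SDs at or below this are treated as degenerate
#: (nuisance-spanned signal); such voxels get z = 0 and weight 0
SD_TOL = 1e-8


class SequencingError(RuntimeError):
    """A volume arrived out of order."""


@dataclass
class ActivationSample:
    t: int
    z_dmn: float
    z_fpn: float
    outlier: bool

    @property
    def pda(self) -> float:
        """Positive Diametric Activity: FPN minus DMN activation, in SD units."""
        return self.z_fpn - self.z_dmn


class GentlemanGLM:
    """Square-root-free Givens (Gentleman) updating for many shared-design GLMs.

    One triangular system (scale vector ``d`` and unit upper triangle
    ``rbar``) is shared across voxels because every voxel sees the same
    design row; the projected responses ``theta`` and residual sums of
    squares are carried per voxel, so a volume update costs O(p²) scalar
    work plus O(p) vector operations over voxels.
    """

    def __init__(self, n_regressors: int, n_series: int):
        self.p = n_regressors
        self.n_series = n_series
        self.d = np.zeros(n_regressors)
        self.rbar = np.zeros((n_regressors, n_regressors))
        self.theta = np.zeros((n_regressors, n_series))
        self.sserr = np.zeros(n_series)
        self.n_obs = 0

    def include(self, x: np.ndarray, y: np.ndarray) -> None:
        """Fold one observation row (design ``x``, responses ``y``) into the fit."""
        x = np.array(x, dtype=float)
        y = np.array(y, dtype=float)
        w = 1.0
        for i in range(self.p):
            if w == 0.0:
                break
            xi = x[i]
            if xi == 0.0:
                continue
            di = self.d[i]
            dpi = di + w * xi * xi
            cbar = di / dpi
            sbar = w * xi / dpi
            w = cbar * w
            self.d[i] = dpi
            if i + 1 < self.p:
                xk = x[i + 1:].copy()
                x[i + 1:] = xk - xi * self.rbar[i, i + 1:]
                self.rbar[i, i + 1:] = cbar * self.rbar[i, i + 1:] + sbar * xk
            told = self.theta[i].copy()
            self.theta[i] = cbar * told + sbar * y
            y = y - xi * told
        self.sserr += w * y * y
        self.n_obs += 1

    def coefficients(self, tol: float = 1e-10) -> np.ndarray:
        """Back-substitute for the coefficient matrix (p, n_series).

        Columns whose accumulated scale is (numerically) zero are linearly
        dependent on earlier ones for the data seen so far; their
        coefficients are set to zero (the dropped-column convention).
        """
        beta = np.zeros((self.p, self.n_series))
        scale = max(self.d.max(), 1.0)
        for i in range(self.p - 1, -1, -1):
            if self.d[i] <= tol * scale:
                continue
            beta[i] = self.theta[i]
            if i + 1 < self.p:
                beta[i] -= self.rbar[i, i + 1:] @ beta[i + 1:]
        return beta


def erode_whole_brain(whole_brain: np.ndarray) -> np.ndarray:
    """Erode the whole-brain mask by one voxel with 6-connectivity."""
    structure = ndimage.generate_binary_structure(3, 1)
    return ndimage.binary_erosion(whole_brain, structure=structure)


def network_activation(z_voxels: np.ndarray, weights: np.ndarray) -> float:
    """Efficiency-weighted network activation: Σ w_v z_v with Σ w_v = 1."""
    if weights.size == 0 or weights.sum() <= 0:
        raise ValueError("no weighted voxels for network activation")
    return float(np.dot(weights, z_voxels))


def efficiency_weights(baseline_sd: np.ndarray) -> np.ndarray:
    """Weights inversely proportional to baseline residual variance.

    Voxels with zero baseline residual variance are excluded (weight 0)
    rather than producing non-finite weights; the remainder renormalizes
    to sum 1.
    """
    ok = baseline_sd > SD_TOL
    w = np.zeros_like(baseline_sd)
    w[ok] = 1.0 / baseline_sd[ok] ** 2
    total = w.sum()
    if total <= 0:
        raise ValueError("every voxel has zero baseline residual variance")
    return w / total


@dataclass
class EngineConfig:
    baseline_volumes: int = 25
    outlier_sd: float = 2.0
    n_volumes_expected: int = 150  # scales the drift regressor


class RealtimeEngine:
    """Streams volumes through the incremental GLM and emits PDA samples."""

    def __init__(self, dmn: np.ndarray, fpn: np.ndarray, whole_brain: np.ndarray,
                 config: Optional[EngineConfig] = None):
        self.config = config or EngineConfig()
        eroded = erode_whole_brain(whole_brain)
        dmn_e = dmn & eroded
        fpn_e = fpn & eroded
        if not dmn_e.any() or not fpn_e.any():
            raise ValueError("a network mask is empty after whole-brain erosion")
        self.grid_shape = dmn.shape
        union = dmn_e | fpn_e
        self.vox_idx = np.flatnonzero(union.ravel())
        flat_to_local = {v: i for i, v in enumerate(self.vox_idx)}
        self.dmn_local = np.array([flat_to_local[v]
                                   for v in np.flatnonzero(dmn_e.ravel())])
        self.fpn_local = np.array([flat_to_local[v]
                                   for v in np.flatnonzero(fpn_e.ravel())])
        self.masks = {"DMN": dmn_e, "FPN": fpn_e}

        self.glm = GentlemanGLM(N_REGRESSORS, self.vox_idx.size)
        self.t = 0
        self.prev_motion: Optional[np.ndarray] = None
        nb = self.config.baseline_volumes
        self._baseline_x = np.zeros((nb, N_REGRESSORS))
        self._baseline_y = np.zeros((nb, self.vox_idx.size))
        self.baseline_mean: Optional[np.ndarray] = None
        self.baseline_sd: Optional[np.ndarray] = None
        self.weights: Dict[str, np.ndarray] = {}
        self.excluded_voxels: Dict[str, int] = {}
        self.log: List[str] = []

    # -- design -------------------------------------------------------------
    def _design_row(self, t: int, motion: np.ndarray) -> np.ndarray:
        rel = (np.zeros(6) if self.prev_motion is None
               else np.asarray(motion, float) - self.prev_motion)
        n = max(self.config.n_volumes_expected, 2)
        drift = (t - 1) / (n - 1) - 0.5
        return np.concatenate([[1.0], rel, [drift]])

    # -- baseline freeze ----------------------------------------------------
    def _freeze_baseline(self) -> None:
        beta = self.glm.coefficients()
        resid = self._baseline_y - self._baseline_x @ beta
        self.baseline_mean = resid.mean(axis=0)
        self.baseline_sd = resid.std(axis=0, ddof=1)
        for net, local in (("DMN", self.dmn_local), ("FPN", self.fpn_local)):
            sd = self.baseline_sd[local]
            try:
                self.weights[net] = efficiency_weights(sd)
            except ValueError:
                # fully nuisance-spanned mask: activation is identically 0
                self.weights[net] = np.zeros_like(sd)
                self.log.append(f"{net}: all voxels degenerate; activation fixed at 0")
            n_excl = int((sd <= SD_TOL).sum())
            self.excluded_voxels[net] = n_excl
            if n_excl and self.weights[net].sum() > 0:
                self.log.append(
                    f"{net}: {n_excl} zero-baseline-variance voxels excluded "
                    "from efficiency weighting"
                )

    # -- streaming ----------------------------------------------------------
    def ingest(self, volume: np.ndarray, motion: np.ndarray,
               t: Optional[int] = None) -> Optional[ActivationSample]:
        """Fold one volume into the GLM; return a sample after the baseline.

        Returns None during the baseline window (a baseline-phase marker).
        Volumes containing non-finite values are rejected: the GLM is not
        updated and, post-baseline, the emitted sample is flagged outlier
        with undefined z-scores.
        """
        expected = self.t + 1
        if t is not None and t != expected:
            raise SequencingError(f"expected volume {expected}, got {t}")
        y = volume.ravel()[self.vox_idx]
        if not np.all(np.isfinite(y)):
            self.t = expected
            self.log.append(f"volume {expected}: non-finite values, rejected")
            if expected > self.config.baseline_volumes:
                return ActivationSample(expected, float("nan"), float("nan"), True)
            return None

        x = self._design_row(expected, motion)
        self.glm.include(x, y)
        self.prev_motion = np.asarray(motion, dtype=float)
        self.t = expected

        nb = self.config.baseline_volumes
        if expected <= nb:
            self._baseline_x[expected - 1] = x
            self._baseline_y[expected - 1] = y
            if expected == nb:
                self._freeze_baseline()
            return None

        beta = self.glm.coefficients()
        resid = y - x @ beta
        z_vox = (resid - self.baseline_mean) / np.where(
            self.baseline_sd > SD_TOL, self.baseline_sd, np.inf)
        z_dmn = (float(np.dot(self.weights["DMN"], z_vox[self.dmn_local]))
                 if self.weights["DMN"].sum() > 0 else 0.0)
        z_fpn = (float(np.dot(self.weights["FPN"], z_vox[self.fpn_local]))
                 if self.weights["FPN"].sum() > 0 else 0.0)
        outlier = (abs(z_dmn) > self.config.outlier_sd
                   or abs(z_fpn) > self.config.outlier_sd)
        return ActivationSample(expected, z_dmn, z_fpn, outlier)

    def config_dict(self) -> Dict:
        return {
            "baseline_volumes": self.config.baseline_volumes,
            "outlier_sd": self.config.outlier_sd,
            "n_volumes_expected": self.config.n_volumes_expected,
            "n_dmn_voxels": int(self.dmn_local.size),
            "n_fpn_voxels": int(self.fpn_local.size),
            "excluded_voxels": dict(self.excluded_voxels),
        }


def init_engine(dmn: np.ndarray, fpn: np.ndarray, whole_brain: np.ndarray,
                baseline_volumes: int = 25, **kwargs) -> RealtimeEngine:
    """Convenience constructor mirroring the session configuration."""
    cfg = EngineConfig(baseline_volumes=baseline_volumes, **kwargs)
    return RealtimeEngine(dmn, fpn, whole_brain, cfg)
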