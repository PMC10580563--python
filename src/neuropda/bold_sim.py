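"""Synthetic BOLD phantoms, runs, and motion traces with known ground truth.

The simulator emulates the statistical structure a closed-loop DMN/FPN
neurofeedback pipeline assumes: a voxel grid partitioned into labeled
regions (DMN hubs mPFC and PCC, remaining DMN, FPN, white matter, CSF,
other brain tissue), region-level AR(1) latent timecourses with a
user-specified cross-correlation structure (anticorrelated DMN/FPN,
correlated mPFC-PCC), linear scanner drift, additive Gaussian noise, and
rigid-motion traces with occasional spikes.  Motion couples into the image
only as an additive nuisance signal proportional to relative displacement;
no resampling is performed, so the real-time GLM's nuisance-regression
premise holds exactly at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

REGION_NAMES = ("DMN_mPFC", "DMN_PCC", "DMN_other", "FPN", "WM", "CSF", "other_brain")

#: rotations are converted to displacements on a sphere of this radius (mm),
#: the standard head-size convention for framewise-displacement scalars
HEAD_RADIUS_MM = 50.0


@dataclass
class PhantomSpec:
    """Geometry of the synthetic head: grid, voxel size, and region sizes.

    ``region_sizes`` requests a voxel count per region; :func:`make_phantom`
    turns the request into concrete disjoint voxel index sets stored in
    ``region_voxels`` (maps region name -> (3, n) integer index arrays).
    """

    grid_shape: Tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 2.0
    region_sizes: Dict[str, int] = field(default_factory=lambda: {
        "DMN_mPFC": 200,
        "DMN_PCC": 200,
        "DMN_other": 2200,
        "FPN": 2600,
        "WM": 800,
        "CSF": 400,
        "other_brain": 600,
    })
    region_voxels: Optional[Dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3 positive integers")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        unknown = set(self.region_sizes) - set(REGION_NAMES)
        if unknown:
            raise ValueError(f"unknown regions: {sorted(unknown)}")

    @property
    def affine(self) -> np.ndarray:
        """RAS affine with isotropic voxels centered at the origin."""
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size_mm
        aff[:3, 3] = -np.asarray(self.grid_shape) * self.voxel_size_mm / 2.0
        return aff

    def mask(self, *regions: str) -> np.ndarray:
        """Binary 3D array covering the union of the named regions."""
        if self.region_voxels is None:
            raise ValueError("phantom is abstract; call make_phantom first")
        out = np.zeros(self.grid_shape, dtype=bool)
        for r in regions:
            ix = self.region_voxels[r]
            out[ix[0], ix[1], ix[2]] = True
        return out

    def template_masks(self) -> Dict[str, np.ndarray]:
        """Template network/ROI masks derived from the ground-truth regions."""
        return {
            "DMN": self.mask("DMN_mPFC", "DMN_PCC", "DMN_other"),
            "FPN": self.mask("FPN"),
            "mPFC": self.mask("DMN_mPFC"),
            "PCC": self.mask("DMN_PCC"),
            "WM": self.mask("WM"),
            "CSF": self.mask("CSF"),
            "whole_brain": self.mask(*REGION_NAMES),
        }


@dataclass
class AcquisitionParams:
    tr_ms: float = 1200.0
    n_volumes: int = 150
    baseline_volumes: int = 25

    def __post_init__(self) -> None:
        if self.tr_ms <= 0 or self.n_volumes <= 0:
            raise ValueError("tr_ms and n_volumes must be positive")
        if not (0 <= self.baseline_volumes < self.n_volumes):
            raise ValueError("baseline_volumes must be < n_volumes")

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_ms / 1000.0


@dataclass
class SignalSpec:
    """Latent-signal parameters for one simulated run.

    Amplitudes are in units of the noise-free signal SD; ``network_corr``
    is the target stationary correlation between the DMN and FPN latents,
    ``mpfc_pcc_corr`` the target correlation between the two DMN hub
    latents.  ``fpn_shift`` adds a constant offset (in amplitude units) to
    FPN voxels after ``fpn_shift_onset`` volumes, used to emulate
    successful up-regulation during feedback.
    """

    dmn_amplitude: float = 1.0
    fpn_amplitude: float = 1.0
    network_corr: float = -0.3
    mpfc_pcc_corr: float = 0.7
    drift_slope: float = 0.0
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    outlier_volumes: frozenset = frozenset()
    seed: int = 0
    motion_coupling: float = 0.0
    motion_spike_mm: float = 2.0
    fpn_shift: float = 0.0
    fpn_shift_onset: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.network_corr <= 1.0):
            raise ValueError("network_corr must lie in [-1, 1]")
        if not (0.0 <= self.mpfc_pcc_corr <= 1.0):
            raise ValueError("mpfc_pcc_corr must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.ar1_coef < 1.0):
            raise ValueError("ar1_coef must lie in [0, 1)")
        # fail fast if the implied latent correlation matrix is not PSD
        latent_correlation_matrix(self.network_corr, self.mpfc_pcc_corr)


def latent_correlation_matrix(network_corr: float, mpfc_pcc_corr: float) -> np.ndarray:
    """Correlation matrix over latents (mPFC, PCC, DMN_other, FPN).

    Within-DMN latents share ``mpfc_pcc_corr``; every DMN latent correlates
    ``network_corr`` with the FPN latent.  Raises if the matrix is not
    positive semi-definite.
    """
    ch, cn = mpfc_pcc_corr, network_corr
    c = np.array([
        [1.0, ch, ch, cn],
        [ch, 1.0, ch, cn],
        [ch, ch, 1.0, cn],
        [cn, cn, cn, 1.0],
    ])
    eigmin = np.linalg.eigvalsh(c)[0]
    if eigmin < -1e-10:
        raise ValueError(
            f"(network_corr={cn}, mpfc_pcc_corr={ch}) implies a non-PSD "
            f"latent correlation matrix (min eigenvalue {eigmin:.3g})"
        )
    return c


@dataclass
class MotionTrace:
    """Per-volume rigid-motion 6-vectors and derived displacement scalars."""

    params: np.ndarray  # (n_volumes, 6): 3 translations mm, 3 rotations rad

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must be (n_volumes, 6)")

    @property
    def relative_displacement(self) -> np.ndarray:
        """Difference from the previous volume; zero vector at volume 1."""
        rel = np.diff(self.params, axis=0, prepend=self.params[:1])
        return rel

    @property
    def framewise_displacement(self) -> np.ndarray:
        """Scalar FD per volume: |Δtranslation| + 50 mm · |Δrotation|."""
        rel = np.abs(self.relative_displacement)
        return rel[:, :3].sum(axis=1) + HEAD_RADIUS_MM * rel[:, 3:].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        return pd.DataFrame(self.params, columns=cols)


@dataclass
class Run4D:
    """One 4D BOLD run: voxel grid x time plus acquisition/motion metadata."""

    data: np.ndarray  # (nx, ny, nz, n_volumes)
    params: AcquisitionParams
    motion: MotionTrace
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    ground_truth: Optional[pd.DataFrame] = None  # latent timecourses

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("run data must be 4-dimensional")
        if self.data.shape[3] != self.params.n_volumes:
            raise ValueError("time axis length must equal params.n_volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("run contains non-finite values")
        if self.motion.params.shape[0] != self.params.n_volumes:
            raise ValueError("motion trace length must equal n_volumes")

    @property
    def n_volumes(self) -> int:
        return self.params.n_volumes

    def copy_with(self, data: np.ndarray) -> "Run4D":
        return replace(self, data=data)


def make_phantom(spec: PhantomSpec, seed: int = 0) -> PhantomSpec:
    """Place the requested regions as disjoint compact blobs inside a brain.

    Brain voxels are the interior of a superellipsoid spanning ~90% of the grid.
    Each region grows outward from a seed anchor (anchors jittered by
    ``seed``), claiming its nearest unassigned brain voxels, so counts are
    exact and placements differ across seeds.
    """
    rng = np.random.default_rng(seed)
    shape = np.asarray(spec.grid_shape)
    total = int(sum(spec.region_sizes.values()))

    ix = np.indices(spec.grid_shape).reshape(3, -1).T.astype(float)
    center = (shape - 1) / 2.0
    # superellipsoid (exponent 4): rounder than a box, roomier than a sphere,
    # so the default 24^3 grid holds all requested regions with margin
    semi = shape * 0.46
    inside = (((np.abs(ix - center)) / semi) ** 4).sum(axis=1) <= 1.0
    brain = ix[inside]
    if total > brain.shape[0]:
        raise ValueError(
            f"requested {total} region voxels but the brain ellipsoid holds "
            f"only {brain.shape[0]} on grid {tuple(spec.grid_shape)}"
        )

    # anchors: fixed directions from center, jittered per seed
    base_dirs = np.array([
        [0.9, 0.0, 0.6],    # mPFC (anterior-superior)
        [-0.9, 0.0, 0.6],   # PCC (posterior-superior)
        [0.0, 0.8, 0.3],    # DMN_other
        [0.0, -0.8, 0.3],   # FPN
        [0.3, 0.3, -0.7],   # WM
        [0.0, 0.0, 0.0],    # CSF (ventricles, central)
        [-0.3, -0.3, -0.7], # other_brain
    ])
    anchors = center + base_dirs * semi * 0.7 + rng.normal(0, 0.8, base_dirs.shape)

    assigned = np.zeros(brain.shape[0], dtype=bool)
    region_voxels: Dict[str, np.ndarray] = {}
    for name, anchor in zip(REGION_NAMES, anchors):
        want = int(spec.region_sizes.get(name, 0))
        if want == 0:
            region_voxels[name] = np.zeros((3, 0), dtype=int)
            continue
        free = np.flatnonzero(~assigned)
        d = np.linalg.norm(brain[free] - anchor, axis=1)
        take = free[np.argsort(d, kind="stable")[:want]]
        assigned[take] = True
        region_voxels[name] = brain[take].T.astype(int)

    out = replace(spec, region_voxels=region_voxels)
    return out


def _ar1_latents(n_volumes: int, corr: np.ndarray, phi: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance AR(1) latents with cross-correlated innovations.

    With a common AR coefficient, the stationary cross-correlation equals the
    innovation cross-correlation, so ``corr`` is hit exactly in expectation.
    """
    k = corr.shape[0]
    # sqrt factor via eigen-decomposition (tolerates semi-definite corr)
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    chol = v * np.sqrt(w)
    eta = rng.standard_normal((n_volumes, k)) @ chol.T
    lat = np.empty((n_volumes, k))
    lat[0] = eta[0]
    scale = math.sqrt(1.0 - phi * phi)
    for t in range(1, n_volumes):
        lat[t] = phi * lat[t - 1] + scale * eta[t]
    return lat


def _region_profile(vox: np.ndarray) -> np.ndarray:
    """Gaussian taper of signal loading with distance from the region core.

    Normalized to mean 1 so region amplitude keeps its stated scale; the
    strict ordering of loadings makes "voxels loading most strongly"
    well-defined on the ground-truth side as well.
    """
    pts = vox.T.astype(float)
    center = pts.mean(axis=0)
    d = np.linalg.norm(pts - center, axis=1)
    sigma = max(d.max(), 1.0) / 1.5
    w = np.exp(-0.5 * (d / sigma) ** 2)
    return w / w.mean()


def _motion_trace(n_volumes: int, outlier_volumes, spike_mm: float,
                  rng: np.random.Generator) -> MotionTrace:
    """Slow random-walk motion with translation spikes at outlier volumes."""
    step_t = rng.normal(0.0, 0.02, (n_volumes, 3))   # mm per volume
    step_r = rng.normal(0.0, 0.0004, (n_volumes, 3))  # rad per volume
    steps = np.hstack([step_t, step_r])
    steps[0] = 0.0
    for t in outlier_volumes:
        if 0 < t < n_volumes:
            steps[t, 0] += spike_mm
    params = np.cumsum(steps, axis=0)
    return MotionTrace(params=params)


def simulate_run(phantom: PhantomSpec, acq: AcquisitionParams,
                 sig: SignalSpec) -> Run4D:
    """Generate one BOLD run on the phantom under the given signal spec."""
    if phantom.region_voxels is None:
        raise ValueError("phantom is abstract; call make_phantom first")
    rng = np.random.default_rng(sig.seed)
    n = acq.n_volumes

    corr = latent_correlation_matrix(sig.network_corr, sig.mpfc_pcc_corr)
    lat = _ar1_latents(n, corr, sig.ar1_coef, rng)  # columns: mPFC,PCC,other,FPN
    motion = _motion_trace(n, sig.outlier_volumes, sig.motion_spike_mm, rng)

    amp = {
        "DMN_mPFC": (0, sig.dmn_amplitude),
        "DMN_PCC": (1, sig.dmn_amplitude),
        "DMN_other": (2, sig.dmn_amplitude),
        "FPN": (3, sig.fpn_amplitude),
    }
    data = np.zeros(phantom.grid_shape + (n,))
    drift = sig.drift_slope * np.arange(n, dtype=float)
    nuis = sig.motion_coupling * np.abs(motion.relative_displacement).sum(axis=1)

    brain = phantom.mask(*REGION_NAMES)
    for name in REGION_NAMES:
        vox = phantom.region_voxels[name]
        if vox.shape[1] == 0:
            continue
        base = 100.0  # nominal mean intensity so brain extraction is nontrivial
        background = base + drift + nuis
        if name in amp:
            col, a = amp[name]
            series = a * lat[:, col]
            if name == "FPN" and sig.fpn_shift != 0.0:
                shifted = np.zeros(n)
                shifted[sig.fpn_shift_onset:] = sig.fpn_shift
                series = series + shifted
            # graded loading profile: strongest at the region core, tapering
            # outward, as in real network maps (mean loading 1 over the region)
            profile = _region_profile(vox)
            data[vox[0], vox[1], vox[2], :] = (background[None, :]
                                               + profile[:, None] * series[None, :])
        else:
            data[vox[0], vox[1], vox[2], :] = background[None, :]
    if sig.noise_sd > 0:
        noise = rng.normal(0.0, sig.noise_sd, data.shape)
        noise[~brain] = 0.0
        data += noise

    gt = pd.DataFrame(lat, columns=["mPFC", "PCC", "DMN_other", "FPN"])
    counts = np.array([phantom.region_voxels[r].shape[1]
                       for r in ("DMN_mPFC", "DMN_PCC", "DMN_other")], dtype=float)
    gt["DMN"] = lat[:, :3] @ (counts / counts.sum())
    return Run4D(data=data, params=acq, motion=motion,
                 affine=phantom.affine, ground_truth=gt)


def stream_volumes(run: Run4D) -> Iterator[Tuple[int, np.ndarray, np.ndarray]]:
    """Yield (1-based volume index, 3D volume, absolute motion 6-vector).

    Emulates real-time export: volumes arrive strictly in time order,
    exactly once each.  The iterator is a generator; calling this function
    again replays the identical sequence.
    """
    for t in range(run.n_volumes):
        yield t + 1, run.data[..., t], run.motion.params[t]


# ---------------------------------------------------------------------------
# NIfTI / TSV persistence

def save_run(run: Run4D, path: str) -> None:
    nib.save(nib.Nifti1Image(run.data.astype(np.float32), run.affine), path)


def load_run(path: str, acq: AcquisitionParams, motion: MotionTrace) -> Run4D:
    img = nib.load(path)
    return Run4D(data=np.asanyarray(img.dataobj, dtype=float), params=acq,
                 motion=motion, affine=np.asarray(img.affine))


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), path)


def load_mask(path: str) -> np.ndarray:
    return np.asanyarray(nib.load(path).dataobj) > 0


def save_motion(motion: MotionTrace, path: str) -> None:
    motion.to_frame().to_csv(path, sep="\t", index=False)


def load_motion(path: str) -> MotionTrace:
    return MotionTrace(params=pd.read_csv(path, sep="\t").to_numpy())
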