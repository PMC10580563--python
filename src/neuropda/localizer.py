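"""Personalized DMN/FPN network masks from resting-state runs.

Pipeline: per-run preprocessing (brain extraction by robust intensity
threshold, Gaussian spatial smoothing, temporal high-pass), trimming and
temporal concatenation of the two localizer runs, spatial ICA (PCA
reduction then fixed-point ICA), selection of the component most spatially
correlated with each network template, and thresholding the selected
component to the 2000 template-supported voxels with the strongest
positive weights.  If insufficient resting-state data are available the
template masks themselves are returned (``template_fallback`` provenance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage, signal
from sklearn.decomposition import FastICA

from .bold_sim import Run4D

FWHM_TO_SIGMA = 1.0 / (8.0 * np.log(2.0)) ** 0.5


class LocalizerError(RuntimeError):
    """Raised when personalized mask generation is not possible."""


@dataclass
class PreprocParams:
    smoothing_fwhm_mm: float = 5.0
    highpass_hz: float = 0.01
    brain_threshold: float = 0.1  # fraction of robust intensity range

    def validate(self, tr_ms: float) -> None:
        nyquist = 1000.0 / (2.0 * tr_ms)
        if not (0 < self.highpass_hz < nyquist):
            raise ValueError("highpass_hz must lie below Nyquist")


@dataclass
class ComponentSet:
    maps: np.ndarray        # (n_components, nx, ny, nz), variance-normalized
    mixing: np.ndarray      # (n_volumes, n_components) timecourses
    template_corrs: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]


@dataclass
class NetworkMask:
    network: str
    voxels: np.ndarray      # binary 3D array
    provenance: str         # "personalized" | "template_fallback"
    source_component: Optional[int] = None
    selection_corr: Optional[float] = None
    warnings: List[str] = field(default_factory=list)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def _brain_mask(run: Run4D, threshold_frac: float) -> np.ndarray:
    mean = run.data.mean(axis=3)
    lo, hi = np.percentile(mean, [2, 98])
    return mean > lo + threshold_frac * (hi - lo)


def preprocess_localizer(run: Run4D, p: PreprocParams,
                         voxel_size_mm: float = 2.0) -> Run4D:
    """Brain-extract, smooth (FWHM in mm), and temporally high-pass a run.

    Realignment is the identity in synthetic space: motion is tabulated and
    never resamples the image.  High-passed series are demeaned exactly.
    """
    if run.n_volumes < 3:
        raise ValueError("run must have at least 3 volumes")
    p.validate(run.params.tr_ms)
    brain = _brain_mask(run, p.brain_threshold)
    data = np.where(brain[..., None], run.data, 0.0)

    sigma_vox = p.smoothing_fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    data = ndimage.gaussian_filter(data, sigma=(sigma_vox,) * 3 + (0.0,))

    fs = 1000.0 / run.params.tr_ms
    sos = signal.butter(2, p.highpass_hz, btype="highpass", fs=fs, output="sos")
    flat = data.reshape(-1, run.n_volumes)
    nz = flat.std(axis=1) > 0
    flat[nz] = signal.sosfiltfilt(sos, flat[nz], axis=1)
    flat[nz] -= flat[nz].mean(axis=1, keepdims=True)
    return run.copy_with(flat.reshape(run.data.shape))


def _centroid_shift(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Translation (voxels) aligning volume ``b`` onto volume ``a``."""
    def centroid(v):
        w = np.clip(v, 0, None)
        s = w.sum()
        if s == 0:
            return np.zeros(3)
        return np.array(ndimage.center_of_mass(w))
    return centroid(a) - centroid(b)


def concatenate_runs(run1: Run4D, run2: Optional[Run4D] = None,
                     min_volumes: int = 125) -> Run4D:
    """Trim both runs to the shorter length and concatenate in time.

    A second run shorter than ``min_volumes`` is dropped; a first run
    shorter than ``min_volumes`` makes the localizer unusable and triggers
    the template-fallback path.  The second run is aligned to the first
    run's median volume by translation before concatenation, and each run
    is demeaned voxelwise before joining (multi-session concatenation).
    """
    if run1.n_volumes < min_volumes:
        raise LocalizerError(
            f"first localizer run has {run1.n_volumes} < {min_volumes} volumes"
        )
    d1 = run1.data - run1.data.mean(axis=3, keepdims=True)
    if run2 is None or run2.n_volumes < min_volumes:
        return run1.copy_with(d1)

    n = min(run1.n_volumes, run2.n_volumes)
    d1 = d1[..., :n]
    median1 = np.median(run1.data, axis=3)
    median2 = np.median(run2.data, axis=3)
    shift = _centroid_shift(median1, median2)
    d2 = run2.data[..., :n]
    if np.any(np.abs(shift) > 0.25):
        d2 = ndimage.shift(d2, tuple(shift) + (0.0,), order=1, mode="nearest")
    d2 = d2 - d2.mean(axis=3, keepdims=True)

    from .bold_sim import AcquisitionParams, MotionTrace
    acq = AcquisitionParams(tr_ms=run1.params.tr_ms, n_volumes=2 * n,
                            baseline_volumes=run1.params.baseline_volumes)
    motion = MotionTrace(params=np.vstack([run1.motion.params[:n],
                                           run2.motion.params[:n]]))
    return Run4D(data=np.concatenate([d1, d2], axis=3), params=acq,
                 motion=motion, affine=run1.affine)


def estimate_signal_rank(eigenvalues: np.ndarray, n_components: int) -> int:
    """Signal dimensionality: eigenvalues clearly above the noise floor.

    The noise floor is taken as the median of the leading ``n_components``
    eigenvalues of the temporal covariance; dimensions more than twice the
    floor count as signal.  Clamped to [2, n_components].
    """
    lead = eigenvalues[:n_components]
    floor = np.median(lead)
    d = int((lead > 2.0 * floor).sum())
    return max(2, min(d, n_components))


def extract_components(run: Run4D, n_components: int = 35, seed: int = 0,
                       max_retries: int = 3) -> ComponentSet:
    """Spatial ICA: PCA to ``n_components``, fixed-point unmixing, maps out.

    Voxels are ICA samples and timepoints features, so estimated sources
    are spatial maps and the mixing matrix holds component timecourses.
    The fixed-point iteration runs on the estimated signal subspace only
    (fixed-point ICA over-learns when asked for far more components than
    the data's signal rank, shattering large networks into sparse
    fragments); the remaining principal-component maps are returned
    unrotated so the set always holds exactly ``n_components`` maps, as a
    probabilistic-ICA tool would.  Maps are variance-normalized.
    Non-convergence retries with deterministic sub-seeds before raising.
    """
    if run.n_volumes <= n_components:
        raise ValueError("run must have more volumes than components")
    shape = run.data.shape[:3]
    flat = run.data.reshape(-1, run.n_volumes)
    support = np.flatnonzero(flat.std(axis=1) > 1e-12)
    x = flat[support] - flat[support].mean(axis=1, keepdims=True)

    u, s, wt = np.linalg.svd(x, full_matrices=False)
    d = estimate_signal_rank(s ** 2, n_components)

    sources = None
    for attempt in range(max_retries):
        sub_seed = (seed + 104729 * attempt) % (2**31)
        ica = FastICA(n_components=d, random_state=sub_seed,
                      whiten="unit-variance", max_iter=1000, tol=1e-4)
        strict = attempt < max_retries - 1
        with warnings.catch_warnings():
            # on the final attempt accept a not-fully-converged unmixing:
            # the convergence flag is far stricter than what template
            # correlation component selection needs
            warnings.simplefilter("error" if strict else "ignore",
                                  category=UserWarning)
            try:
                sources = ica.fit_transform(x @ wt[:d].T)
                break
            except (UserWarning, ValueError):
                continue
    if sources is None:
        raise LocalizerError(f"ICA failed after {max_retries} attempts")

    sources = sources / (sources.std(axis=0, keepdims=True) + 1e-12)
    noise_maps = u[:, d:n_components]
    noise_maps = noise_maps / (noise_maps.std(axis=0, keepdims=True) + 1e-12)
    all_maps = np.concatenate([sources, noise_maps], axis=1)

    # timecourses: ICA mixing lifted back to volume space, then raw PCs
    mixing_ica = wt[:d].T @ ica.mixing_
    mixing_pc = wt[d:n_components].T * s[d:n_components]
    mixing = np.concatenate([mixing_ica, mixing_pc], axis=1)

    maps = np.zeros((n_components, flat.shape[0]))
    maps[:, support] = all_maps.T
    return ComponentSet(maps=maps.reshape((n_components,) + shape),
                        mixing=mixing)


def spatial_correlation(component_map: np.ndarray, template: np.ndarray) -> float:
    """Pearson correlation between a component map and a binary template."""
    a = component_map.ravel().astype(float)
    b = template.ravel().astype(float)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def select_network_component(components: ComponentSet,
                             template: np.ndarray) -> Tuple[int, float]:
    """Pick the component with the highest |spatial correlation| to template.

    Returns the (index, signed correlation); downstream code flips the
    component's sign when the winning correlation is negative so the
    template-supported weights are positive.
    """
    if template.shape != components.maps.shape[1:]:
        raise ValueError("template grid does not match component maps")
    corrs = np.array([spatial_correlation(m, template) for m in components.maps])
    if np.all(corrs == 0):
        raise LocalizerError("all component-template correlations are zero")
    k = int(np.argmax(np.abs(corrs)))
    return k, float(corrs[k])


def personalize_mask(component_map: np.ndarray, template: np.ndarray,
                     network: str, n_vox: int = 2000,
                     source_component: Optional[int] = None,
                     selection_corr: Optional[float] = None) -> NetworkMask:
    """Threshold a sign-corrected component to its strongest template voxels.

    Keeps the ``n_vox`` highest positive weights inside the template
    support; ties at the threshold break by ascending linear voxel index.
    """
    support = np.flatnonzero(template.ravel())
    if support.size == 0:
        raise LocalizerError("template support is empty")
    weights = component_map.ravel()[support]
    positive = support[weights > 0]
    wpos = weights[weights > 0]
    notes: List[str] = []
    if positive.size < n_vox:
        notes.append(
            f"only {positive.size} positive-weight voxels in template support "
            f"(< {n_vox}); keeping all of them"
        )
        chosen = positive
    else:
        order = np.lexsort((positive, -wpos))
        chosen = positive[order[:n_vox]]
    mask = np.zeros(component_map.size, dtype=bool)
    mask[chosen] = True
    return NetworkMask(network=network, voxels=mask.reshape(component_map.shape),
                       provenance="personalized", source_component=source_component,
                       selection_corr=selection_corr, warnings=notes)


def fallback_template_masks(templates: Dict[str, np.ndarray]
                            ) -> Tuple[NetworkMask, NetworkMask]:
    """Return the template DMN/FPN masks directly, flagged as fallback."""
    return (
        NetworkMask(network="DMN", voxels=templates["DMN"].copy(),
                    provenance="template_fallback"),
        NetworkMask(network="FPN", voxels=templates["FPN"].copy(),
                    provenance="template_fallback"),
    )


def localize(run1: Run4D, run2: Optional[Run4D],
             templates: Dict[str, np.ndarray],
             preproc: Optional[PreprocParams] = None,
             n_components: int = 35, n_vox: int = 2000, seed: int = 0,
             voxel_size_mm: float = 2.0) -> Tuple[NetworkMask, NetworkMask, Dict]:
    """Full localizer pipeline; falls back to templates when it cannot run.

    If one component wins both networks it is assigned to the network with
    the larger |correlation| and the runner-up serves the other network;
    the event is reported in the returned log.
    """
    preproc = preproc or PreprocParams()
    log: Dict = {"provenance": "personalized", "events": []}
    try:
        p1 = preprocess_localizer(run1, preproc, voxel_size_mm)
        p2 = preprocess_localizer(run2, preproc, voxel_size_mm) if run2 is not None else None
        cat = concatenate_runs(p1, p2)
        comps = extract_components(cat, n_components=n_components, seed=seed)
    except (LocalizerError, ValueError) as err:
        log["provenance"] = "template_fallback"
        log["events"].append(f"localizer failed ({err}); using template masks")
        dmn, fpn = fallback_template_masks(templates)
        return dmn, fpn, log

    corrs = {net: np.array([spatial_correlation(m, templates[net])
                            for m in comps.maps]) for net in ("DMN", "FPN")}
    comps.template_corrs = corrs
    pick = {net: int(np.argmax(np.abs(corrs[net]))) for net in ("DMN", "FPN")}
    if pick["DMN"] == pick["FPN"]:
        k = pick["DMN"]
        keep = "DMN" if abs(corrs["DMN"][k]) >= abs(corrs["FPN"][k]) else "FPN"
        other = "FPN" if keep == "DMN" else "DMN"
        runner = np.abs(corrs[other]).copy()
        runner[k] = -np.inf
        pick[other] = int(np.argmax(runner))
        log["events"].append(
            f"component {k} won both networks; kept for {keep}, "
            f"runner-up {pick[other]} used for {other}"
        )

    masks = []
    for net in ("DMN", "FPN"):
        k = pick[net]
        rho = float(corrs[net][k])
        cmap = comps.maps[k] if rho >= 0 else -comps.maps[k]
        m = personalize_mask(cmap, templates[net], net, n_vox=n_vox,
                             source_component=k, selection_corr=rho)
        log.setdefault("selection", {})[net] = {
            "component": k, "correlation": rho, "n_voxels": m.n_voxels,
        }
        log["events"].extend(m.warnings)
        masks.append(m)
    return masks[0], masks[1], log
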