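"""Closed-loop PDA feedback: ball dynamics, hits, adaptive calibration.

The ball's per-volume velocity is gain × PDA (positive PDA = FPN > DMN
moves it toward the top circle).  A hit — reaching the circle — flashes
that circle for one volume, returns the ball to center, and shrinks the
hit circle's radius by 10% (within-run difficulty adaptation).  Between
runs the gain is recalibrated from the previous run's hit count: ×1.25
below 3 hits, ×0.75 above 5, unchanged for 3–5.  Outlier volumes (either
network |z| > 2 baseline SDs) pause the ball.

Radius geometry: the protocol's 2-D display (a ball on a vertical track
between two circles) leaves the effect of a shrinking radius on a
"reaches the center" criterion ambiguous.  Two interpretations are
implemented behind ``radius_mode``:

* ``boundary`` (default): a smaller disc is harder to enter — the hit
  boundary moves from ±1 to ±(2 − radius), so each 10% shrink pushes the
  target 0.1 screen units farther and the shrink rule is consequential.
* ``cosmetic``: the radius is display-only; the hit boundary stays at ±1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import bold_sim, localizer, rtengine
from .bold_sim import AcquisitionParams, PhantomSpec, SignalSpec
from .rtengine import ActivationSample

SHRINK_FACTOR = 0.9
GAIN_UP = 1.25
GAIN_DOWN = 0.75
HIT_BAND = (3, 5)  # inclusive band of hits leaving the gain unchanged


@dataclass
class FeedbackState:
    ball_y: float = 0.0
    radius_top: float = 1.0
    radius_bottom: float = 1.0
    gain: float = 0.05
    hits_this_run: int = 0
    paused: bool = False
    flash: Optional[str] = None  # "top" | "bottom" during the flash volume
    radius_mode: str = "boundary"

    def __post_init__(self) -> None:
        if not (0.0 < self.radius_top <= 1.0 and 0.0 < self.radius_bottom <= 1.0):
            raise ValueError("radii must lie in (0, 1]")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.radius_mode not in ("boundary", "cosmetic"):
            raise ValueError("radius_mode must be 'boundary' or 'cosmetic'")

    def hit_boundary(self, side: str) -> float:
        radius = self.radius_top if side == "top" else self.radius_bottom
        if self.radius_mode == "cosmetic":
            return 1.0
        return 2.0 - radius


def step(state: FeedbackState, sample: ActivationSample) -> tuple:
    """Advance the controller by one feedback volume.

    Returns (new state, events) where events is a list of strings among
    ``hit_top``, ``hit_bottom``, ``paused``.  A flash from the previous
    volume's hit is cleared; during the flash volume itself no movement
    is integrated.
    """
    events: List[str] = []
    st = replace(state)
    if st.flash is not None:
        st.flash = None  # flash lasted exactly one volume; no integration
        return st, events
    if sample.outlier:
        st.paused = True
        events.append("paused")
        return st, events
    st.paused = False
    top_b = st.hit_boundary("top")
    bot_b = st.hit_boundary("bottom")
    y = st.ball_y + st.gain * sample.pda
    y = min(max(y, -bot_b), top_b)
    if y >= top_b:
        st.radius_top *= SHRINK_FACTOR
        st.hits_this_run += 1
        st.ball_y = 0.0
        st.flash = "top"
        events.append("hit_top")
    elif y <= -bot_b:
        st.radius_bottom *= SHRINK_FACTOR
        st.hits_this_run += 1
        st.ball_y = 0.0
        st.flash = "bottom"
        events.append("hit_bottom")
    else:
        st.ball_y = y
    return st, events


def recalibrate_between_runs(gain: float, hits_previous_run: int) -> float:
    """Adapt the gain from the previous run's hit count."""
    if hits_previous_run < 0:
        raise ValueError("hit count cannot be negative")
    if gain <= 0:
        raise ValueError("gain must be positive")
    lo, hi = HIT_BAND
    if hits_previous_run < lo:
        return gain * GAIN_UP
    if hits_previous_run > hi:
        return gain * GAIN_DOWN
    return gain


@dataclass
class RunPlan:
    kind: str          # "rest" | "no_neurofeedback" | "neurofeedback"
    n_volumes: int
    baseline_volumes: int = 25

    def __post_init__(self) -> None:
        if self.kind not in ("rest", "no_neurofeedback", "neurofeedback"):
            raise ValueError(f"unknown run kind {self.kind!r}")


def build_schedule(dose: str, rest_volumes: int = 250,
                   feedback_volumes: int = 150) -> List[RunPlan]:
    """Session-2 run schedule for the 15- or 30-minute dose condition.

    15-min: 2 pre rest, no-NF, 5 NF, no-NF, 2 post rest.
    30-min: 2 pre rest, no-NF, 5 NF, no-NF, 5 NF, no-NF, 2 post rest.
    """
    rest = RunPlan("rest", rest_volumes)
    nonf = RunPlan("no_neurofeedback", feedback_volumes)
    nf = RunPlan("neurofeedback", feedback_volumes)
    if dose == "min15":
        return [rest, rest, nonf] + [nf] * 5 + [nonf, rest, rest]
    if dose == "min30":
        return [rest, rest, nonf] + [nf] * 5 + [nonf] + [nf] * 5 + [nonf, rest, rest]
    raise ValueError(f"unknown dose {dose!r} (expected 'min15' or 'min30')")


@dataclass
class RunLog:
    plan: RunPlan
    gain: float
    samples: pd.DataFrame          # volume, pda, z_dmn, z_fpn, ball_y, paused, hit, flash
    hits: int = 0
    final_radius_top: float = 1.0
    final_radius_bottom: float = 1.0


@dataclass
class SessionLog:
    dose: str
    schedule: List[str] = field(default_factory=list)
    run_logs: List[RunLog] = field(default_factory=list)
    gains: List[float] = field(default_factory=list)
    mask_provenance: str = "personalized"
    localizer_events: List[str] = field(default_factory=list)
    rest_runs_pre: List[bold_sim.Run4D] = field(default_factory=list)
    rest_runs_post: List[bold_sim.Run4D] = field(default_factory=list)

    def summary(self) -> Dict:
        return {
            "dose": self.dose,
            "run_order": list(self.schedule),
            "gains": self.gains,
            "hits_per_run": [rl.hits for rl in self.run_logs
                             if rl.plan.kind == "neurofeedback"],
            "mask_provenance": self.mask_provenance,
        }


@dataclass
class ScenarioSpec:
    """Signal conditions across the session's runs.

    ``mpfc_pcc_corr_pre/post`` set the DMN-hub coupling of the pre vs post
    resting runs (the connectivity outcome the analyses test); ``fpn_shift``
    is a sustained FPN offset (amplitude units) during feedback runs,
    emulating successful up-regulation.
    """
    network_corr: float = -0.3
    mpfc_pcc_corr_pre: float = 0.7
    mpfc_pcc_corr_post: float = 0.55
    fpn_shift: float = 0.0
    noise_sd: float = 1.0
    amplitude: float = 1.0
    drift_slope: float = 0.01
    motion_coupling: float = 0.0


def _run_feedback_run(run: bold_sim.Run4D, plan: RunPlan, dmn: np.ndarray,
                      fpn: np.ndarray, whole_brain: np.ndarray,
                      state: FeedbackState) -> tuple:
    """Stream one feedback-type run through the engine and controller."""
    engine = rtengine.init_engine(
        dmn, fpn, whole_brain, baseline_volumes=plan.baseline_volumes,
        n_volumes_expected=plan.n_volumes)
    active = plan.kind == "neurofeedback"
    rows = []
    for t, vol, motion in bold_sim.stream_volumes(run):
        sample = engine.ingest(vol, motion, t=t)
        if sample is None:
            continue
        events: List[str] = []
        if active:
            state, events = step(state, sample)
        rows.append({
            "volume": t,
            "pda": sample.pda,
            "z_dmn": sample.z_dmn,
            "z_fpn": sample.z_fpn,
            "ball_y": state.ball_y,
            "paused": state.paused,
            "hit": any(e.startswith("hit") for e in events),
            "flash": state.flash or "",
        })
    log = RunLog(plan=plan, gain=state.gain, samples=pd.DataFrame(rows),
                 hits=state.hits_this_run,
                 final_radius_top=state.radius_top,
                 final_radius_bottom=state.radius_bottom)
    return state, log


def run_session(phantom: PhantomSpec, dose: str,
                scenario: Optional[ScenarioSpec] = None, seed: int = 0,
                initial_gain: float = 0.05, radius_mode: str = "boundary",
                reset_radii_between_runs: bool = True,
                localizer_volumes: int = 250) -> SessionLog:
    """Simulate the full two-session visit computationally.

    Session 1: two resting localizer runs → personalized DMN/FPN masks
    (template fallback when localization fails).  Session 2: the dose's
    run schedule with a fresh engine per run, the controller active only
    during neurofeedback runs, gain carried across runs through the
    between-run recalibration rule, and pre/post resting runs retained
    for the connectivity analyses.
    """
    scenario = scenario or ScenarioSpec()
    rng = np.random.default_rng(seed)
    templates = phantom.template_masks()

    def make_sig(mpfc_pcc, fpn_shift=0.0, onset=0):
        return SignalSpec(
            dmn_amplitude=scenario.amplitude, fpn_amplitude=scenario.amplitude,
            network_corr=scenario.network_corr, mpfc_pcc_corr=mpfc_pcc,
            drift_slope=scenario.drift_slope, noise_sd=scenario.noise_sd,
            motion_coupling=scenario.motion_coupling,
            fpn_shift=fpn_shift, fpn_shift_onset=onset,
            seed=int(rng.integers(2**31)))

    acq_rest = AcquisitionParams(n_volumes=localizer_volumes)
    loc1 = bold_sim.simulate_run(phantom, acq_rest, make_sig(scenario.mpfc_pcc_corr_pre))
    loc2 = bold_sim.simulate_run(phantom, acq_rest, make_sig(scenario.mpfc_pcc_corr_pre))
    dmn_mask, fpn_mask, loc_log = localizer.localize(
        loc1, loc2, templates, seed=seed)

    schedule = build_schedule(dose)
    log = SessionLog(dose=dose, schedule=[p.kind for p in schedule],
                     mask_provenance=loc_log["provenance"],
                     localizer_events=list(loc_log["events"]))
    gain = initial_gain
    state = FeedbackState(gain=gain, radius_mode=radius_mode)
    n_rest_seen = 0
    for plan in schedule:
        if plan.kind == "rest":
            pre = n_rest_seen < 2
            n_rest_seen += 1
            sig = make_sig(scenario.mpfc_pcc_corr_pre if pre
                           else scenario.mpfc_pcc_corr_post)
            run = bold_sim.simulate_run(
                phantom, AcquisitionParams(n_volumes=plan.n_volumes), sig)
            (log.rest_runs_pre if pre else log.rest_runs_post).append(run)
            continue
        sig = make_sig(scenario.mpfc_pcc_corr_pre,
                       fpn_shift=(scenario.fpn_shift
                                  if plan.kind == "neurofeedback" else 0.0),
                       onset=plan.baseline_volumes)
        run = bold_sim.simulate_run(
            phantom,
            AcquisitionParams(n_volumes=plan.n_volumes,
                              baseline_volumes=plan.baseline_volumes),
            sig)
        if reset_radii_between_runs:
            state = FeedbackState(gain=gain, radius_mode=radius_mode)
        else:
            state = replace(state, ball_y=0.0, hits_this_run=0,
                            paused=False, flash=None, gain=gain)
        state, run_log = _run_feedback_run(
            run, plan, dmn_mask.voxels, fpn_mask.voxels,
            templates["whole_brain"], state)
        log.run_logs.append(run_log)
        if plan.kind == "neurofeedback":
            log.gains.append(gain)
            gain = recalibrate_between_runs(gain, run_log.hits)
    return log


def write_session_log(log: SessionLog, out_dir) -> None:
    """Persist per-run TSVs and the session-level JSON summary."""
    import json
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, rl in enumerate(log.run_logs, start=1):
        rl.samples.to_csv(out / f"run{i:02d}_{rl.plan.kind}.tsv",
                          sep="\t", index=False)
    summary = log.summary()
    summary["localizer_events"] = log.localizer_events
    summary["final_radii"] = [
        {"run": i + 1, "top": rl.final_radius_top, "bottom": rl.final_radius_bottom}
        for i, rl in enumerate(log.run_logs)]
    (out / "session.json").write_text(json.dumps(summary, indent=2))
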