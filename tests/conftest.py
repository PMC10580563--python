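import numpy as np
import pandas as pd
import pytest

import neuropda as npd


@pytest.fixture(scope="session")
def phantom():
    """Default concrete phantom shared across tests (expensive pieces reuse it)."""
    return npd.make_phantom(npd.PhantomSpec(), seed=1)


@pytest.fixture(scope="session")
def templates(phantom):
    return phantom.template_masks()


@pytest.fixture(scope="session")
def localizer_runs(phantom):
    """Two preprocessable resting runs with planted network structure."""
    acq1 = npd.AcquisitionParams(n_volumes=250)
    acq2 = npd.AcquisitionParams(n_volumes=240)
    run1 = npd.simulate_run(phantom, acq1, npd.SignalSpec(seed=11))
    run2 = npd.simulate_run(phantom, acq2, npd.SignalSpec(seed=12))
    return run1, run2


@pytest.fixture(scope="session")
def personalized_masks(phantom, templates, localizer_runs):
    run1, run2 = localizer_runs
    return npd.localize(run1, run2, templates, seed=1)


def make_records(n=40, effect=-0.2, dose_extra=0.0, seed=0, sub_sd=0.2,
                 slope_sd=0.05, res_sd=0.15, baseline=0.5):
    """Connectivity records drawn from the mixed-model generative process."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        b0 = rng.normal(baseline, sub_sd)
        b1 = rng.normal(effect, slope_sd)
        dose = i % 2
        age = rng.uniform(13.0, 18.0)
        for t in (0, 0, 1, 1):
            fz = b0 + b1 * t + dose_extra * dose * t + rng.normal(0, res_sd)
            rows.append(dict(id=f"s{i:03d}", time=t, dose=dose, fisher_z=fz,
                             mean_fd=rng.uniform(0.05, 0.3), age=age))
    return pd.DataFrame(rows)
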