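"""Personalize DMN and FPN masks from two simulated resting runs.

Preprocessing (brain extraction, 5 mm smoothing, 0.01 Hz high-pass) is
followed by temporal concatenation, 35-component spatial ICA, selection of
the component most correlated with each network template, and
thresholding to the 2000 strongest template-supported voxels.
"""

import neuropda as npd

phantom = npd.make_phantom(npd.PhantomSpec(), seed=1)
templates = phantom.template_masks()

run1 = npd.simulate_run(phantom, npd.AcquisitionParams(n_volumes=250),
                        npd.SignalSpec(seed=11))
run2 = npd.simulate_run(phantom, npd.AcquisitionParams(n_volumes=240),
                        npd.SignalSpec(seed=12))

dmn, fpn, log = npd.localize(run1, run2, templates, seed=1)

print(f"provenance: {log['provenance']}")
for mask, name in ((dmn, "DMN"), (fpn, "FPN")):
    sel = log["selection"][name]
    tpl = templates[name]
    jaccard = (mask.voxels & tpl).sum() / (mask.voxels | tpl).sum()
    print(f"{name}: component {sel['component']:2d} "
          f"(|spatial r| = {abs(sel['correlation']):.2f}), "
          f"{mask.n_voxels} voxels, Jaccard vs ground truth {jaccard:.2f}")
print("\nEach mask keeps exactly the 2000 voxels loading most strongly on "
      "the selected component inside the network template; Jaccard near "
      "0.77 means the mask is essentially the planted network's core.")
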