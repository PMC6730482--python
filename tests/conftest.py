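import numpy as np
import pytest

import tractmargin as tm


def straight_bundle_spec(n_streamlines=3, jitter=0.0, seed=0):
    """20 mm straight bundle along +x with a small spherical GTV at its start."""
    return tm.PhantomSpec(
        dims=(28, 20, 20), voxel_sizes=(1.0, 1.0, 1.0),
        bundles=[tm.BundleSpec(kind="line", start=(3.5, 10.5, 10.5),
                               end=(23.5, 10.5, 10.5),
                               n_streamlines=n_streamlines, spacing=1.0,
                               jitter_sd=jitter)],
        rois={"gtv": tm.RoiSpec(shape="sphere", center=(4.5, 10.5, 10.5),
                                radius=1.2, role="GTV"),
              "brain": tm.RoiSpec(shape="box",
                                  bounds=((0.0, 28.0), (0.0, 20.0), (0.0, 20.0)),
                                  role="brain")},
        seed=seed)


@pytest.fixture
def straight_phantom():
    return tm.make_phantom(straight_bundle_spec())


def random_phantom_spec(rng):
    """Small randomized phantom: line or arc bundle, jitter on/off, anisotropic voxels."""
    vs = tuple(rng.choice([0.8, 1.0, 1.3], size=3))
    dims = (18, 18, 14)
    extent = np.array(dims) * np.array(vs)
    if rng.random() < 0.5:
        margin = 0.15 * extent
        start = margin + rng.random(3) * 0.2 * extent
        end = extent - margin - rng.random(3) * 0.2 * extent
        bundle = tm.BundleSpec(kind="line", start=tuple(start), end=tuple(end),
                               n_streamlines=int(rng.integers(1, 4)),
                               spacing=float(rng.choice([0.5, 1.0])),
                               jitter_sd=float(rng.choice([0.0, 0.2])))
        roi_center = tuple(start + 0.15 * (end - start))
    else:
        center = extent / 2
        radius = 0.25 * float(extent.min())
        bundle = tm.BundleSpec(kind="arc", center=tuple(center), radius=radius,
                               angles=(0.0, np.pi / 2), plane=(0, 1),
                               n_streamlines=int(rng.integers(1, 4)),
                               spacing=float(rng.choice([0.5, 1.0])),
                               jitter_sd=float(rng.choice([0.0, 0.2])))
        roi_center = (center[0] + radius, center[1], center[2])
    return tm.PhantomSpec(
        dims=dims, voxel_sizes=vs, bundles=[bundle],
        rois={"gtv": tm.RoiSpec(shape="sphere", center=roi_center,
                                radius=1.5 * min(vs), role="GTV")},
        seed=int(rng.integers(0, 2**31)))
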