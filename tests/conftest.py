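import numpy as np
import pytest

from avmflow.vessels import (
    SyntheticAVMConfig,
    VascularNetwork,
    VesselSegment,
    generate_synthetic_avm,
)


def straight_centerline(a, b, n=5):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) * np.asarray(a, float) + t * np.asarray(b, float)


def make_single_tube(radius=1e-3, length=20e-3):
    """One straight artery segment from inlet to outlet, along x."""
    cl = straight_centerline([0, 0, 0], [length, 0, 0])
    seg = VesselSegment(0, 0, 1, radius, cl, "artery")
    net = VascularNetwork(
        nodes={0: cl[0], 1: cl[-1]},
        segments=[seg],
        inlet_nodes=[0],
        outlet_nodes=[1],
    )
    net.validate()
    return net


def make_parallel_feeders(r1=0.5e-3, r2=0.5e-3, length=10e-3):
    """Inlet -> artery -> two parallel feeders -> drainer -> vein -> outlet.

    Both feeders connect the same two junctions, so with equal radii the
    flow split is exactly symmetric.  Feeder centerlines bow apart in y so
    the polylines differ while arc lengths stay equal.
    """
    a = np.array([0.0, 0.0, 0.0])
    b = np.array([10e-3, 0.0, 0.0])
    c = b + np.array([length, 0.0, 0.0])
    d = c + np.array([10e-3, 0.0, 0.0])
    def feeder_cl(sign):
        mid = (b + c) / 2 + np.array([0.0, sign * 2e-3, 0.0])
        # three-point polyline with identical length for either sign
        return np.array([b, mid, c])

    segs = [
        VesselSegment(0, 0, 1, 1.5e-3, straight_centerline(a, b), "artery"),
        VesselSegment(1, 1, 2, r1, feeder_cl(+1), "feeder"),
        VesselSegment(2, 1, 2, r2, feeder_cl(-1), "feeder"),
        VesselSegment(3, 2, 3, 1.2e-3, straight_centerline(c, d), "drainer"),
    ]
    net = VascularNetwork(
        nodes={0: a, 1: b, 2: c, 3: d},
        segments=segs,
        inlet_nodes=[0],
        outlet_nodes=[3],
    )
    return net


@pytest.fixture
def single_tube():
    return make_single_tube()


@pytest.fixture
def parallel_feeders():
    return make_parallel_feeders()


@pytest.fixture
def small_avm():
    return generate_synthetic_avm(SyntheticAVMConfig(n_feeders=3, seed=42))
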