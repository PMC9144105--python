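import numpy as np
import pytest

from coromorph.model import Segment, VascularNetwork


def make_segment(axis, outer=(200.0, 200.0, 200.0), inner=(160.0, 160.0, 160.0),
                 sid=1, parent=None):
    return Segment(id=sid, axis=np.asarray(axis, float), outer_diams=outer,
                   inner_diams=inner, parent=parent)


@pytest.fixture
def bent_345():
    """A 3-4-5 right-angle polyline: flow 700, chord 500, T = 28.57%."""
    return make_segment([(0.0, 0.0), (300.0, 0.0), (300.0, 400.0)])


@pytest.fixture
def straight_500():
    return make_segment([(0.0, 0.0), (500.0, 0.0)])


def make_y_network(trunk_len=1000.0, d_mother=200.0, d1=170.0, d2=120.0,
                   angle1=-20.0, angle2=40.0, daughter_len=600.0):
    """A mother along +X with two straight daughters at given angles."""
    def ray(start, deg, length):
        t = np.radians(deg)
        return np.array([start, start + length * np.array([np.cos(t), np.sin(t)])])

    end = np.array([trunk_len, 0.0])
    segs = {
        1: make_segment([(0.0, 0.0), tuple(end)], outer=(d_mother,) * 3,
                        inner=(0.8 * d_mother,) * 3, sid=1),
        2: make_segment(ray(end, angle1, daughter_len), outer=(d1,) * 3,
                        inner=(0.8 * d1,) * 3, sid=2, parent=1),
        3: make_segment(ray(end, angle2, daughter_len), outer=(d2,) * 3,
                        inner=(0.8 * d2,) * 3, sid=3, parent=1),
    }
    return VascularNetwork(segments=segs)


@pytest.fixture
def y_network():
    return make_y_network()


@pytest.fixture(scope="session")
def baseline_network():
    from coromorph.simulate import TreeGenParams, generate_network

    return generate_network(TreeGenParams(), seed=7)
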