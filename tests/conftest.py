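import numpy as np
import pytest
from hypothesis import settings

from csiscore import LesionMeasurement, Reach, Vessel

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def _m(vessel, reach="none", **kw):
    return LesionMeasurement(vessel=Vessel(vessel), reach=Reach(reach), **kw)


@pytest.fixture
def fig_a_measurements():
    """Worked example A: ostial 40% CA, proximal 73% SMA, healthy IMA."""
    return (
        _m("CA", "ostial", percent_override=40.0),
        _m("SMA", "proximal", percent_override=73.0),
        _m("IMA", "none"),
    )


@pytest.fixture
def fig_b_measurements():
    """Worked example B: ostial 56% CA, proximal 77% SMA, ostial 45% IMA."""
    return (
        _m("CA", "ostial", percent_override=56.0),
        _m("SMA", "proximal", percent_override=77.0),
        _m("IMA", "ostial", percent_override=45.0),
    )


@pytest.fixture
def fig_c_measurements():
    """Worked example C: extended occlusion of CA and SMA, ostial occlusion of IMA."""
    return (
        _m("CA", "extended", occluded=True),
        _m("SMA", "extended", occluded=True),
        _m("IMA", "ostial", occluded=True),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20220742)


def brute_force_auc(pos, neg):
    """Pairwise-counting oracle for the tie-aware AUC."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def random_labeled_instance(rng, max_n=30, integer=False):
    """A random two-class score sample with ties likely."""
    n_pos = int(rng.integers(1, max_n))
    n_neg = int(rng.integers(1, max_n))
    if integer or rng.random() < 0.5:
        pos = rng.integers(0, 10, n_pos).astype(float)
        neg = rng.integers(0, 10, n_neg).astype(float)
    else:
        pos = rng.normal(0.5, 1.0, n_pos)
        neg = rng.normal(0.0, 1.0, n_neg)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    return scores, labels, pos, neg
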