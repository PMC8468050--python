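import itertools

import numpy as np
import pytest

import zipfent as z


@pytest.fixture(scope="session")
def zml_calib():
    return z.default_calibration("zml")


@pytest.fixture(scope="session")
def equi_calib():
    return z.default_calibration("equiprobable")


@pytest.fixture()
def identity_calib():
    """A hand-built power calibration M = 1 * D^1 + 0 for rank 1."""
    return z.CalibrationModel(
        dist_family="equiprobable",
        form="power",
        params={1: (1.0, 1.0, 0.0)},
        valid_range={1: (1.0, 1000.0)},
    )


def exhaustive_first_collision_pmf(probs, n_max):
    """Exact first-collision law by enumerating all draw sequences.

    Brute-force oracle: every length-n_max tuple over the alphabet is
    weighted by its product probability and assigned the position of its
    first repeated symbol.
    """
    K = len(probs)
    f = np.zeros(n_max + 2)
    for tup in itertools.product(range(K), repeat=n_max):
        w = 1.0
        for s in tup:
            w *= probs[s]
        pos = 0
        seen = set()
        for i, s in enumerate(tup, start=1):
            if s in seen:
                pos = i
                break
            seen.add(s)
        f[pos] += w  # pos 0 collects "no collision within n_max"
    return f  # index n holds P(first collision at draw n)
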