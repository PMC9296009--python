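import logging

import numpy as np
import pytest

from loop4c.simulate import (
    SmfishSimSpec,
    build_locus,
    paper_locus_spec,
    simulate_smfish,
)

logging.getLogger("loop4c").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def paper_locus():
    """Deterministic paper-design locus (toy genome, maps, expected means)."""
    return build_locus(paper_locus_spec())


@pytest.fixture(scope="session")
def small_smfish_spec():
    """A compact field of view: 4 cells, study-like noise and PSF."""
    return SmfishSimSpec(shape=(17, 180, 180), n_cells=4, cyto_mrna_mean=12.0)


@pytest.fixture(scope="session")
def small_smfish(small_smfish_spec):
    return simulate_smfish(small_smfish_spec, 42)


def match_spots(detected, truth, radius=2.0):
    """One-to-one nearest matching of detected vs planted spots.

    Returns (recall, precision, detected_idx, truth_idx) using an optimal
    assignment within ``radius`` voxels.
    """
    from scipy.optimize import linear_sum_assignment

    P = detected[["z", "y", "x"]].to_numpy()
    T = truth[["z", "y", "x"]].to_numpy()
    if len(P) == 0 or len(T) == 0:
        return 0.0, 0.0, np.array([], int), np.array([], int)
    D = np.linalg.norm(P[:, None, :] - T[None, :, :], axis=2)
    ri, ci = linear_sum_assignment(np.where(D < radius, D, 1e6))
    ok = D[ri, ci] < radius
    return ok.sum() / len(T), ok.sum() / len(P), ri[ok], ci[ok]
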