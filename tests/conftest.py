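"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from msbind import simulate
from msbind.chem import PROTON_MASS


def bisect_free_ligand(kds, p_tot, l_tot, n_iter=200):
    """Independent bisection oracle for the equilibrium mass balance.

    Deliberately written from the definition (stepwise mass-action products)
    rather than reusing any package code, so it can cross-check the solver.
    """
    kds = list(kds)

    def excess(free_l):
        weights = [1.0]
        for kd in kds:
            weights.append(weights[-1] * free_l / kd)
        total = sum(weights)
        bound = sum(i * w for i, w in enumerate(weights)) / total
        return free_l + p_tot * bound - l_tot

    lo, hi = 0.0, l_tot
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def exact_series_peaks(mass, charges, intensities=None):
    """Peak list constructed directly from the m/z formula (no generator)."""
    from msbind.nativems import PeakList

    charges = list(charges)
    mz = np.array([(mass + z * PROTON_MASS) / z for z in charges])
    inten = np.ones(len(charges)) if intensities is None else np.asarray(intensities, float)
    return PeakList(mz, inten)


@pytest.fixture(scope="session")
def hdx_noiseless():
    return simulate.gen_hdx(simulate.HDX_PRESETS["hdx-noiseless"], seed=1)


@pytest.fixture(scope="session")
def hdx_noisy():
    return simulate.gen_hdx(simulate.HDX_PRESETS["hdx-synergy"], seed=5)


@pytest.fixture(scope="session")
def hdx_additive():
    return simulate.gen_hdx(simulate.HDX_PRESETS["hdx-additive"], seed=11)


@pytest.fixture(scope="session")
def segments_by_name():
    return {seg.name: seg for seg in simulate.SEGMENTS}
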