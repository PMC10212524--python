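"""Shared fixtures and independent brute-force oracles.

The oracles enumerate outcomes directly (itertools + exact combinatorics)
and never call the package's convolution/pmf code paths, so they serve as
independent references for the forward model and the thinning formulas.
"""

from __future__ import annotations

from collections import defaultdict
from itertools import product
from math import comb

import numpy as np
import pytest

import prenotrace as pt


@pytest.fixture(scope="session")
def dol16() -> pt.CompoundSpec:
    return pt.get_compound("Dol-16")


@pytest.fixture(scope="session")
def pren11() -> pt.CompoundSpec:
    return pt.get_compound("Pren-11")


@pytest.fixture(scope="session")
def mvl() -> pt.PrecursorSpec:
    return pt.get_precursor("MVL")


@pytest.fixture(scope="session")
def dx() -> pt.PrecursorSpec:
    return pt.get_precursor("DX")


def brute_force_envelope(
    n_units: int,
    n_carbons: int,
    d: int,
    q: float,
    p13C: float,
    z: np.ndarray,
    mode: str = "unit",
) -> np.ndarray:
    """Exhaustive enumeration of every (13C count, per-unit labeling outcome).

    Feasible for N <= 4. Returns the envelope over Δm = 0..n_carbons + d*N.
    """
    acc: dict[int, float] = defaultdict(float)
    c13 = [
        comb(n_carbons, k) * p13C**k * (1.0 - p13C) ** (n_carbons - k)
        for k in range(n_carbons + 1)
    ]
    for i, zi in enumerate(np.asarray(z, dtype=float)):
        if zi == 0.0:
            continue
        if mode == "unit":
            # each labeled unit independently keeps its d deuteriums (prob 1-q)
            outcomes = product([0, 1], repeat=i)
            for keep in outcomes:
                p_keep = 1.0
                for o in keep:
                    p_keep *= (1.0 - q) if o else q
                k_d = d * sum(keep)
                for k13, p13 in enumerate(c13):
                    acc[k_d + k13] += zi * p_keep * p13
        else:
            # each of the d*i sites independently deuterated (prob 1-q)
            for keep in product([0, 1], repeat=d * i):
                p_keep = 1.0
                for o in keep:
                    p_keep *= (1.0 - q) if o else q
                k_d = sum(keep)
                for k13, p13 in enumerate(c13):
                    acc[k_d + k13] += zi * p_keep * p13
    out = np.zeros(n_carbons + d * n_units + 1)
    for k, v in acc.items():
        out[k] = v
    return out


def brute_force_thinned_pattern(z: np.ndarray, q: float) -> np.ndarray:
    """Exhaustive per-unit enumeration of the deuteriation pattern under
    unit-level impurity (how many labeled units actually carry deuterium)."""
    n = len(z) - 1
    out = np.zeros(n + 1)
    for i, zi in enumerate(np.asarray(z, dtype=float)):
        if zi == 0.0:
            continue
        for keep in product([0, 1], repeat=i):
            p_keep = 1.0
            for o in keep:
                p_keep *= (1.0 - q) if o else q
            out[sum(keep)] += zi * p_keep
    return out


@pytest.fixture(scope="session")
def tiny_compound() -> pt.CompoundSpec:
    """A 4-unit polyprenol, small enough for exhaustive oracles."""
    return pt.CompoundSpec(
        name="Pren-4", family="polyprenol", n_units=4,
        formula={"C": 20, "H": 34, "O": 1},
    )
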