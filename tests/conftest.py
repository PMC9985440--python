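"""Shared fixtures: analytically generated structures and small libraries."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from threadfold.structio import CaTrace
from threadfold.synthgen import SynthSpec, make_structure


def ideal_helix(n: int, trace_id: str = "helix") -> CaTrace:
    """Analytic α-helix: 1.5 Å rise, 100°/residue on a 2.3 Å radius."""
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    coords = np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i], axis=1)
    return CaTrace(
        id=trace_id, res_names=["ALA"] * n, seq_pos=np.arange(1, n + 1), coords=coords
    )


def ideal_strand(n: int, offset=(0.0, 0.0, 0.0), trace_id: str = "strand") -> CaTrace:
    """Extended zigzag strand: 3.4 Å rise, 3.8 Å virtual bonds."""
    i = np.arange(n)
    lateral = np.sqrt(3.8**2 - 3.4**2) / 2.0
    coords = np.stack([3.4 * i, lateral * (-1.0) ** i, np.zeros(n)], axis=1) + np.asarray(offset)
    return CaTrace(
        id=trace_id, res_names=["VAL"] * n, seq_pos=np.arange(1, n + 1), coords=coords
    )


def random_coil(n: int, seed: int, trace_id: str = "coil") -> CaTrace:
    """Self-avoiding 3.8 Å random walk."""
    spec = SynthSpec(seed=seed, topology=(("C", n),))
    t = make_structure(spec, trace_id=trace_id)
    return dataclasses.replace(t, ss=None)


def rigid_copy(trace: CaTrace, seed: int) -> CaTrace:
    """Rotated + translated copy of a trace."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(size=3) * 15.0
    return dataclasses.replace(trace, id=trace.id + "_rigid", coords=trace.coords @ Q.T + t)


@pytest.fixture(scope="session")
def mixed_trace() -> CaTrace:
    """An 80-residue mixed-topology structure used across modules."""
    spec = SynthSpec(
        seed=42,
        topology=(("H", 20), ("C", 5), ("E", 10), ("C", 5), ("E", 10), ("C", 5), ("H", 25)),
    )
    return make_structure(spec, trace_id="mixed80")


@pytest.fixture(scope="session")
def small_trace() -> CaTrace:
    """A 40-residue structure for cheaper per-test work."""
    spec = SynthSpec(seed=7, topology=(("H", 12), ("C", 4), ("E", 8), ("C", 4), ("H", 12)))
    return make_structure(spec, trace_id="mixed40")
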