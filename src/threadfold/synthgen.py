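"""Seeded generator of synthetic Cα structures, families and profiles.

Emulates the statistical structure the threading method assumes —
conserved cores, divergent peripheries, flexible regions with two
alternate conformations (the source of multi-peak distance
histograms) — so every stage is testable without external databases.
Geometry is idealized Cα-only: helices with 1.5 Å rise and 100°/residue
on a 2.3 Å radius, extended strands as a 3.4 Å-rise zigzag, loops as
self-avoiding 3.8 Å random walks; segments are chained with random
placements under a 2.5 Å clash limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .profiles import BINS, BinScheme, DistanceProfile, profile_from_structure
from .structio import CaTrace

logger = logging.getLogger(__name__)

CA_STEP = 3.8
CLASH = 2.5

_SEG_RESIDUE = {"H": "ALA", "E": "VAL", "C": "GLY"}

_AA_POOL = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()


class GenerationError(RuntimeError):
    """Self-avoidance could not be satisfied after retries."""


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic structure or family.

    ``topology`` lists (ss_type, length) segments; ``coordinate_noise``
    is the per-member Gaussian jitter in Å; ``flexible_regions`` are
    1-based residue ranges given a second conformation (hinge-rotated)
    so their pair distances become bimodal; ``peripheral_divergence``
    is the fraction of residues (taken from the C-terminal side, whole
    segments) re-sampled independently per family member.
    """

    seed: int = 0
    topology: tuple[tuple[str, int], ...] = (("H", 12), ("C", 5), ("E", 8))
    coordinate_noise: float = 0.0
    n_members: int = 1
    flexible_regions: tuple[tuple[int, int], ...] = ()
    peripheral_divergence: float = 0.0
    smear_sigma: float = 0.5

    def __post_init__(self) -> None:
        if any(length < 1 for _, length in self.topology):
            raise ValueError("segment lengths must be ≥ 1")
        if self.coordinate_noise < 0 or self.smear_sigma < 0:
            raise ValueError("noise levels must be ≥ 0")
        if not 0.0 <= self.peripheral_divergence <= 1.0:
            raise ValueError("peripheral_divergence must be in [0, 1]")

    @property
    def L(self) -> int:
        return sum(length for _, length in self.topology)

    @property
    def ss(self) -> str:
        return "".join(t * length for t, length in self.topology)


def _helix(n: int) -> np.ndarray:
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    return np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i], axis=1)


def _strand(n: int) -> np.ndarray:
    i = np.arange(n)
    lateral = np.sqrt(CA_STEP**2 - 3.4**2) / 2.0
    return np.stack([3.4 * i, lateral * (-1.0) ** i, np.zeros(n)], axis=1)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix, sign-fixed to a proper rotation
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _clashes(new: np.ndarray, placed: np.ndarray, skip_last: int = 1) -> bool:
    """Any pair closer than the clash limit, ignoring the chain junction."""
    if len(placed) == 0:
        return False
    ref = placed[:-skip_last] if skip_last else placed
    if len(ref) == 0:
        return False
    d = np.linalg.norm(new[:, None, :] - ref[None, :, :], axis=2)
    return bool(np.any(d < CLASH))


def _loop(n: int, anchor: np.ndarray, placed: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    coords = np.empty((n, 3))
    prev = anchor
    for k in range(n):
        for _ in range(200):
            cand = prev + CA_STEP * _random_unit(rng)
            body = np.vstack([placed, coords[:k]]) if k else placed
            if not _clashes(cand[None, :], body, skip_last=1):
                coords[k] = cand
                break
        else:
            raise GenerationError("loop self-avoidance failed")
        prev = coords[k]
    return coords


def make_structure(spec: SynthSpec, trace_id: str | None = None) -> CaTrace:
    """Build one idealized Cα structure from a topology recipe.

    Deterministic per (seed, spec).  Helix/strand segments are rigid
    ideal fragments placed with random orientation 3.8 Å beyond the
    previous residue; loops are grown residue by residue.  Placement
    retries until the 2.5 Å self-avoidance limit holds.
    """
    rng = np.random.default_rng(spec.seed)
    return _assemble(spec, rng, trace_id or f"synth{spec.seed}")


def _assemble(
    spec: SynthSpec,
    rng: np.random.Generator,
    trace_id: str,
    keep_segments: dict[int, np.ndarray] | None = None,
) -> CaTrace:
    """Assemble segments; ``keep_segments`` pins given segment coordinates.

    Pinned segments (by index in the topology) are reused verbatim so
    family members share an identical core frame.
    """
    placed = np.empty((0, 3))
    parts: list[np.ndarray] = []
    names: list[str] = []
    for si, (ss_type, length) in enumerate(spec.topology):
        names.extend([_SEG_RESIDUE[ss_type]] * length)
        if keep_segments is not None and si in keep_segments:
            seg = keep_segments[si]
            parts.append(seg)
            placed = np.vstack([placed, seg])
            continue
        anchor = placed[-1] if len(placed) else np.zeros(3)
        if ss_type == "C":
            seg = _loop(length, anchor, placed, rng)
            parts.append(seg)
            placed = np.vstack([placed, seg])
            continue
        local = _helix(length) if ss_type == "H" else _strand(length)
        local = local - local[0]
        ok = False
        for _ in range(200):
            Q = _random_rotation(rng)
            start = anchor + CA_STEP * _random_unit(rng) if len(placed) else np.zeros(3)
            seg = local @ Q.T + start
            # also require the segment not to clash with itself at >|i-j|>2 — ideal
            # fragments are self-consistent, so only check against placed atoms
            if not _clashes(seg, placed, skip_last=1):
                ok = True
                break
        if not ok:
            raise GenerationError(f"cannot place segment {si} ({ss_type}{length})")
        parts.append(seg)
        placed = np.vstack([placed, seg])
    coords = np.vstack(parts)
    return CaTrace(
        id=trace_id,
        res_names=names,
        seq_pos=np.arange(1, spec.L + 1),
        coords=coords,
        ss=spec.ss,
    )


def _segment_bounds(spec: SynthSpec) -> list[tuple[int, int]]:
    """0-based [start, end) bounds of each topology segment."""
    bounds = []
    pos = 0
    for _, length in spec.topology:
        bounds.append((pos, pos + length))
        pos += length
    return bounds


def peripheral_segments(spec: SynthSpec) -> list[int]:
    """Indices of the trailing segments covered by peripheral_divergence."""
    if spec.peripheral_divergence == 0.0:
        return []
    target = spec.peripheral_divergence * spec.L
    chosen: list[int] = []
    covered = 0
    for si in range(len(spec.topology) - 1, -1, -1):
        if covered >= target:
            break
        chosen.append(si)
        covered += spec.topology[si][1]
    return sorted(chosen)


def make_family(spec: SynthSpec, base_id: str | None = None) -> tuple[list[CaTrace], np.ndarray]:
    """Generate a structural family and its ground-truth core mask.

    Members share the base structure's core segments (plus Gaussian
    coordinate noise); the peripheral segments are re-sampled per
    member.  Returns (members, core_mask) where core_mask is a boolean
    length-L array, True on conserved-core residues.
    """
    if spec.n_members < 1:
        raise ValueError("n_members must be ≥ 1")
    base = make_structure(spec, trace_id=base_id or f"fam{spec.seed}")
    bounds = _segment_bounds(spec)
    periph = set(peripheral_segments(spec))
    core_mask = np.ones(spec.L, dtype=bool)
    for si in periph:
        s, e = bounds[si]
        core_mask[s:e] = False
    members: list[CaTrace] = []
    for k in range(spec.n_members):
        rng = np.random.default_rng((spec.seed, 7919, k))
        if periph:
            keep = {
                si: base.coords[bounds[si][0] : bounds[si][1]]
                for si in range(len(spec.topology))
                if si not in periph
            }
            member = _assemble(spec, rng, f"{base.id}_m{k}", keep_segments=keep)
        else:
            member = replace(base, id=f"{base.id}_m{k}", coords=base.coords.copy())
        if spec.coordinate_noise > 0:
            member.coords = member.coords + rng.normal(
                scale=spec.coordinate_noise, size=member.coords.shape
            )
        # homologous members diverge in sequence, not just coordinates
        member.res_names = [
            _AA_POOL[i] for i in rng.integers(0, len(_AA_POOL), size=spec.L)
        ]
        members.append(member)
    return members, core_mask


def _hinge_alternate(trace: CaTrace, region: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Second conformation: rotate the region rigidly about its first residue."""
    lo, hi = region  # 1-based inclusive
    coords = trace.coords.copy()
    pivot = coords[lo - 1]
    axis = _random_unit(rng)
    angle = np.deg2rad(50.0)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    seg = coords[lo - 1 : hi]
    coords[lo - 1 : hi] = (seg - pivot) @ R.T + pivot
    return coords


def make_profile(
    trace: CaTrace, spec: SynthSpec, scheme: BinScheme = BINS
) -> DistanceProfile:
    """Emulated predicted distance profile for a structure.

    Pair histograms are Gaussian-smeared around the true distances; for
    pairs with at least one residue inside a flexible region, an equal-
    mass mixture with the hinge-rotated alternate conformation makes
    the histogram bimodal (the multi-peak case).
    """
    main = profile_from_structure(trace, smear_sigma=spec.smear_sigma, scheme=scheme)
    if not spec.flexible_regions:
        return main
    rng = np.random.default_rng((spec.seed, 104729))
    flexible = np.zeros(trace.L, dtype=bool)
    alt_coords = trace.coords
    for region in spec.flexible_regions:
        flexible[region[0] - 1 : region[1]] = True
        alt_coords_trace = replace(trace, coords=alt_coords)
        alt_coords = _hinge_alternate(alt_coords_trace, region, rng)
    alt = profile_from_structure(
        replace(trace, coords=alt_coords), smear_sigma=spec.smear_sigma, scheme=scheme
    )
    P = main.P.copy()
    mask = flexible[:, None] | flexible[None, :]
    P[mask] = 0.5 * main.P[mask] + 0.5 * alt.P[mask]
    return DistanceProfile(L=trace.L, P=P, scheme=scheme)


# ---------------------------------------------------------------------------
# fold archetypes for multi-fold benchmark libraries

def _archetype_topologies(L: int) -> list[tuple[tuple[str, int], ...]]:
    """Structurally distinct topology archetypes of total length ≈ L.

    Different segment-type patterns and counts keep between-fold
    TM-scores far below clustering thresholds by construction.
    """
    u = max(L // 8, 4)

    def pad(topo: list[tuple[str, int]]) -> tuple[tuple[str, int], ...]:
        total = sum(n for _, n in topo)
        if total < L:
            topo[-1] = (topo[-1][0], topo[-1][1] + L - total)
        return tuple(topo)

    return [
        pad([("H", 2 * u), ("C", u // 2), ("H", 2 * u), ("C", u // 2), ("H", 2 * u)]),
        pad([("E", u), ("C", u // 2), ("E", u), ("C", u // 2), ("E", u), ("C", u // 2), ("E", u)]),
        pad([("H", 3 * u), ("C", u), ("E", u), ("C", u // 2), ("E", u)]),
        pad([("E", u), ("C", u // 2), ("H", 2 * u), ("C", u // 2), ("E", u), ("C", u), ("H", u)]),
        pad([("C", u), ("H", 4 * u), ("C", u), ("H", u)]),
        pad([("E", 2 * u), ("C", u), ("H", u), ("C", u), ("E", 2 * u)]),
        pad([("H", u), ("C", u // 2), ("E", u), ("C", u // 2), ("H", u), ("C", u // 2), ("E", u)]),
        pad([("C", 2 * u), ("E", 2 * u), ("C", 2 * u), ("H", 2 * u)]),
    ]


def make_fold_library(
    seed: int,
    n_folds: int = 6,
    members_per_fold: int = 5,
    length: int = 80,
    coordinate_noise: float = 0.5,
) -> tuple[list[CaTrace], dict[str, int], dict[str, SynthSpec]]:
    """Synthetic multi-fold benchmark set with ground-truth labels.

    Returns (traces, truth labels id→fold index, spec per member id).
    Each fold uses a distinct topology archetype; members carry
    Gaussian coordinate noise around the fold's base structure.
    """
    archetypes = _archetype_topologies(length)
    if n_folds > len(archetypes):
        raise ValueError(f"at most {len(archetypes)} distinct folds supported")
    traces: list[CaTrace] = []
    labels: dict[str, int] = {}
    specs: dict[str, SynthSpec] = {}
    for f in range(n_folds):
        spec = SynthSpec(
            seed=seed * 1000 + f,
            topology=archetypes[f],
            coordinate_noise=coordinate_noise,
            n_members=members_per_fold,
        )
        members, _ = make_family(spec, base_id=f"fold{f}")
        for m in members:
            traces.append(m)
            labels[m.id] = f
            specs[m.id] = spec
    return traces, labels, specs
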