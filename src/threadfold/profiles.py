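"""Distance and structure profiles over a 37-bin Cα distance histogram.

Residue-pair distances are discretized into 36 bins of 0.5 Å spanning
2–20 Å plus one overflow bin for ≥20 Å.  A *distance profile* is the
predicted per-pair probability histogram for a query sequence (here
emulated from a structure plus Gaussian smear); a *structure profile*
aggregates the observed distances of a structural cluster's members
after alignment to the cluster centroid, excluding gapped pairs from
the counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.special import ndtr

from .structio import CaTrace
from .superpose import AlignmentFailure, structural_align

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinScheme:
    """Distance binning: 36 interior bins of 0.5 Å over [2, 20) Å + overflow."""

    lo: float = 2.0
    hi: float = 20.0
    width: float = 0.5
    n_bins: int = 37

    @property
    def overflow(self) -> int:
        return self.n_bins - 1

    @property
    def edges(self) -> np.ndarray:
        """Interior bin edges: lo, lo+width, ..., hi (length 37)."""
        return self.lo + self.width * np.arange(self.n_bins)

    def bin(self, d: float) -> int:
        """Bin index for distance d (Å); d < lo clamps to bin 0."""
        if d < 0:
            raise ValueError(f"negative distance {d}")
        if d >= self.hi:
            return self.overflow
        if d < self.lo:
            return 0
        return int((d - self.lo) // self.width)

    def bin_array(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d)
        if np.any(d < 0):
            raise ValueError("negative distance")
        t = np.floor((d - self.lo) / self.width).astype(np.int64)
        t = np.clip(t, 0, None)
        t[d >= self.hi] = self.overflow
        return t

    def center(self, t) -> np.ndarray | float:
        """Bin center for interior bins (undefined for the overflow bin)."""
        return self.lo + self.width * np.asarray(t) + self.width / 2.0


BINS = BinScheme()


def bin_distance(d: float, scheme: BinScheme = BINS) -> int:
    """Bin index for a Cα–Cα distance in Å (overflow bin for ≥20 Å)."""
    return scheme.bin(d)


@dataclass
class PeakSet:
    """Per-pair local maxima of a profile, for the alignment kernels.

    Arrays are (L, L, k_max) / (L, L); ``npk`` counts valid peaks per
    pair, ``dist``/``prob`` hold peak distances (bin centers, Å) and
    probabilities sorted by probability descending, ``D`` is the largest
    peak distance among the selected peaks (the cut-off distance of the
    profile cut weight) and ``pmax`` the highest histogram probability
    over the interior bins.
    """

    dist: np.ndarray
    prob: np.ndarray
    npk: np.ndarray
    D: np.ndarray
    pmax: np.ndarray

    @property
    def L(self) -> int:
        return self.npk.shape[0]

    def peaks(self, n: int, m: int) -> list[tuple[float, float]]:
        """(distance, prob) peaks of pair (n, m), 1-based indices."""
        k = int(self.npk[n - 1, m - 1])
        return [
            (float(self.dist[n - 1, m - 1, i]), float(self.prob[n - 1, m - 1, i]))
            for i in range(k)
        ]


@dataclass
class DistanceProfile:
    """Predicted multi-peak distance distribution of a query, (L, L, 37)."""

    L: int
    P: np.ndarray
    scheme: BinScheme = field(default_factory=BinScheme)

    def validate(self) -> None:
        if self.P.shape != (self.L, self.L, self.scheme.n_bins):
            raise ValueError("P shape mismatch")
        if np.any(self.P < -1e-12):
            raise ValueError("negative probabilities")
        sums = self.P.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("histograms must sum to 1")
        if not np.allclose(self.P, self.P.transpose(1, 0, 2), atol=1e-9):
            raise ValueError("profile not symmetric")


@dataclass
class StructureProfile:
    """Cluster-derived distance histogram of a centroid, with observation counts."""

    L: int
    Q: np.ndarray
    counts: np.ndarray
    scheme: BinScheme = field(default_factory=BinScheme)

    def validate(self) -> None:
        if self.Q.shape != (self.L, self.L, self.scheme.n_bins):
            raise ValueError("Q shape mismatch")
        observed = self.counts > 0
        sums = self.Q.sum(axis=2)
        if not np.allclose(sums[observed], 1.0, atol=1e-6):
            raise ValueError("observed histograms must sum to 1")
        if np.any(np.abs(sums[~observed]) > 1e-9):
            raise ValueError("unobserved pairs must have empty histograms")


def extract_peaks(
    P: np.ndarray,
    k: int = 3,
    p_min: float = 0.05,
    scheme: BinScheme = BINS,
) -> PeakSet:
    """Find up to k local maxima per pair histogram.

    A peak is a bin (or leftmost bin of a plateau) strictly greater than
    its neighbours; the overflow bin never yields a peak and absent
    neighbours count as −∞ (so a histogram that is flat across its whole
    support has no peaks).  Peaks with probability < p_min are dropped;
    survivors are sorted by probability descending (tie: shorter
    distance) and reported at the bin center.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    L = P.shape[0]
    nb = scheme.n_bins
    dist = np.zeros((L, L, k))
    prob = np.zeros((L, L, k))
    npk = np.zeros((L, L), dtype=np.int64)
    D = np.zeros((L, L))
    pmax = P[:, :, : nb - 1].max(axis=2)

    # vectorized plateau-aware local-maximum detection over interior bins
    interior = P[:, :, : nb - 1]
    for n in range(L):
        for m in range(L):
            h = interior[n, m]
            cand: list[tuple[float, float]] = []  # (-prob, distance)
            t = 0
            while t < nb - 1:
                e = t
                while e + 1 < nb - 1 and h[e + 1] == h[t]:
                    e += 1
                left = h[t - 1] if t > 0 else -np.inf
                right = h[e + 1] if e + 1 < nb - 1 else P[n, m, nb - 1]
                if e + 1 == nb - 1 and t == 0:
                    right = np.inf  # flat across entire interior: no peak
                if h[t] > left and h[t] > right and h[t] >= p_min:
                    cand.append((-h[t], float(scheme.center(t))))
                t = e + 1
            cand.sort()
            kk = min(k, len(cand))
            for i in range(kk):
                prob[n, m, i] = -cand[i][0]
                dist[n, m, i] = cand[i][1]
            npk[n, m] = kk
            if kk:
                D[n, m] = dist[n, m, :kk].max()
    return PeakSet(dist=dist, prob=prob, npk=npk, D=D, pmax=pmax)


def profile_from_structure(
    trace: CaTrace, smear_sigma: float = 0.0, scheme: BinScheme = BINS
) -> DistanceProfile:
    """Emulate a predicted distance profile from a known structure.

    Each pair's true Cα distance becomes a discretized Gaussian over the
    interior bins (point mass for σ=0); probability mass beyond 20 Å
    accumulates in the overflow bin.  Pairs separated by a flagged chain
    break (e.g. complex linkers) get overflow-only histograms so they
    are excluded from scoring by the distance cut.
    """
    if smear_sigma < 0:
        raise ValueError("smear_sigma must be ≥ 0")
    X = trace.coords
    L = trace.L
    diff = X[:, None, :] - X[None, :, :]
    dmat = np.sqrt(np.sum(diff * diff, axis=2))
    nb = scheme.n_bins
    P = np.zeros((L, L, nb))
    if smear_sigma == 0.0:
        t = scheme.bin_array(dmat)
        idx = np.indices((L, L))
        P[idx[0], idx[1], t] = 1.0
    else:
        edges = scheme.edges  # (37,) interior edges 2..20
        z = (edges[None, None, :] - dmat[:, :, None]) / smear_sigma
        cdf = ndtr(z)  # (L, L, 37)
        P[:, :, 0] = cdf[:, :, 1]  # mass below first interior edge folds to bin 0
        P[:, :, 1 : nb - 1] = cdf[:, :, 2:] - cdf[:, :, 1 : nb - 1]
        P[:, :, nb - 1] = 1.0 - cdf[:, :, nb - 1]
    if trace.chain_breaks.any():
        broken = np.flatnonzero(trace.chain_breaks)
        P[broken, :, :] = 0.0
        P[:, broken, :] = 0.0
        P[broken, :, nb - 1] = 1.0
        P[:, broken, nb - 1] = 1.0
    return DistanceProfile(L=L, P=P, scheme=scheme)


def build_structure_profile(
    centroid: CaTrace,
    members: list[CaTrace],
    scheme: BinScheme = BINS,
) -> StructureProfile:
    """Aggregate member distances into the centroid's structure profile.

    Each member is structurally aligned to the centroid; for every
    centroid residue pair with both positions covered by the alignment,
    the member's own Cα distance between its aligned residues is binned.
    Gapped pairs do not count toward the totals.  Members whose
    alignment fails are skipped with a log message.
    """
    L = centroid.L
    nb = scheme.n_bins
    hist = np.zeros((L, L, nb))
    counts = np.zeros((L, L), dtype=np.int64)
    for member in members:
        if member is centroid or member.id == centroid.id:
            corr = [(i, i) for i in range(1, L + 1)]
        else:
            try:
                corr = structural_align(centroid, member).correspondence
            except AlignmentFailure:
                logger.warning(
                    "member %s failed to align to centroid %s; skipped",
                    member.id, centroid.id,
                )
                continue
        ci = np.array([p[0] for p in corr]) - 1
        mi = np.array([p[1] for p in corr]) - 1
        Xm = member.coords[mi]
        diff = Xm[:, None, :] - Xm[None, :, :]
        dmat = np.sqrt(np.sum(diff * diff, axis=2))
        t = scheme.bin_array(dmat)
        n_al = len(ci)
        rows = np.repeat(ci, n_al)
        cols = np.tile(ci, n_al)
        np.add.at(hist, (rows, cols, t.ravel()), 1.0)
        np.add.at(counts, (rows, cols), 1)
    observed = counts > 0
    Q = np.zeros_like(hist)
    Q[observed] = hist[observed] / counts[observed][:, None]
    return StructureProfile(L=L, Q=Q, counts=counts, scheme=scheme)


# ---------------------------------------------------------------------------
# serialization: HDF5 tensor container + plain-text exchange format

def save_profile(path, profile: DistanceProfile | StructureProfile) -> None:
    """Write a profile to an HDF5 container (datasets P[, counts])."""
    with h5py.File(path, "w") as f:
        if isinstance(profile, StructureProfile):
            f.create_dataset("P", data=profile.Q.astype(np.float32), compression="gzip")
            f.create_dataset("counts", data=profile.counts)
            f.attrs["kind"] = "structure"
        else:
            f.create_dataset("P", data=profile.P.astype(np.float32), compression="gzip")
            f.attrs["kind"] = "distance"
        f.attrs["L"] = profile.L
        f.attrs["bin_lo"] = profile.scheme.lo
        f.attrs["bin_hi"] = profile.scheme.hi
        f.attrs["bin_width"] = profile.scheme.width
        f.attrs["n_bins"] = profile.scheme.n_bins


def load_profile(path) -> DistanceProfile | StructureProfile:
    """Read a profile written by :func:`save_profile`."""
    with h5py.File(path, "r") as f:
        scheme = BinScheme(
            lo=float(f.attrs["bin_lo"]),
            hi=float(f.attrs["bin_hi"]),
            width=float(f.attrs["bin_width"]),
            n_bins=int(f.attrs["n_bins"]),
        )
        P = np.asarray(f["P"], dtype=np.float64)
        L = int(f.attrs["L"])
        if f.attrs["kind"] == "structure":
            counts = np.asarray(f["counts"])
            return StructureProfile(L=L, Q=P, counts=counts, scheme=scheme)
        return DistanceProfile(L=L, P=P, scheme=scheme)


def write_profile_text(path, profile: DistanceProfile | StructureProfile) -> None:
    """Plain-text exchange format: one `n m bin prob` row per nonzero entry."""
    P = profile.Q if isinstance(profile, StructureProfile) else profile.P
    with open(path, "w") as f:
        f.write(f"# L={profile.L} n_bins={profile.scheme.n_bins}\n")
        nz = np.argwhere(P > 0)
        for n, m, t in nz:
            f.write(f"{n + 1}\t{m + 1}\t{t}\t{P[n, m, t]:.6g}\n")


def read_profile_text(path) -> DistanceProfile:
    """Read the plain-text exchange format back into a distance profile."""
    with open(path) as f:
        header = f.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        L = int(meta["L"])
        nb = int(meta["n_bins"])
        P = np.zeros((L, L, nb))
        for line in f:
            n, m, t, p = line.split()
            P[int(n) - 1, int(m) - 1, int(t)] = float(p)
    return DistanceProfile(L=L, P=P, scheme=BinScheme(n_bins=nb))


def peakset_from_profile(
    profile: DistanceProfile | StructureProfile,
    k: int,
    p_min: float = 0.05,
) -> PeakSet:
    """Extract peaks from either profile flavour."""
    P = profile.Q if isinstance(profile, StructureProfile) else profile.P
    return extract_peaks(P, k=k, p_min=p_min, scheme=profile.scheme)
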