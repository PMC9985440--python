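"""Master structure library: pLDDT filtering, greedy structural clustering.

Mirrors how large template libraries are compacted in practice: filter
low-confidence models, then single-pass greedy incremental clustering
(CD-HIT style) at a TM-score threshold — the first unassigned structure
in length order seeds a cluster, later structures join the first seed
they match.  Each cluster carries a structure profile of its seed for
the first search stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import StructureProfile, build_structure_profile, load_profile, save_profile
from .structio import CaTrace, read_structure, write_structure
from .superpose import AlignmentFailure, structural_align

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.8
DEFAULT_PLDDT_MIN = 90.0


@dataclass
class Cluster:
    seed_id: str
    member_ids: list[str]
    tm_to_seed: dict[str, float]


@dataclass
class ClusterLibrary:
    """Greedy clusters of structures with per-cluster structure profiles."""

    clusters: list[Cluster] = field(default_factory=list)
    traces: dict[str, CaTrace] = field(default_factory=dict)
    profiles: dict[str, StructureProfile] = field(default_factory=dict)
    threshold: float = DEFAULT_THRESHOLD
    plddt_min: float = DEFAULT_PLDDT_MIN

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_structures(self) -> int:
        return sum(len(c.member_ids) for c in self.clusters)

    def cluster_of(self, structure_id: str) -> int:
        for k, c in enumerate(self.clusters):
            if structure_id in c.member_ids:
                return k
        raise KeyError(structure_id)

    def labels(self) -> dict[str, int]:
        """structure id → cluster index."""
        return {sid: k for k, c in enumerate(self.clusters) for sid in c.member_ids}


def filter_by_plddt(traces: list[CaTrace], plddt_min: float = DEFAULT_PLDDT_MIN) -> list[CaTrace]:
    """Keep traces whose mean per-residue score is ≥ plddt_min (inclusive).

    Traces without a per-residue score pass with a warning (experimental
    structures carry no pLDDT).
    """
    kept = []
    for t in traces:
        if t.per_residue_score is None:
            warnings.warn(f"{t.id}: no per-residue score; passing pLDDT filter by default")
            kept.append(t)
        elif float(np.mean(t.per_residue_score)) >= plddt_min:
            kept.append(t)
    return kept


def dedup_by_sequence(traces: list[CaTrace]) -> list[CaTrace]:
    """Drop later traces whose residue sequence is identical to an earlier one."""
    seen: set[tuple[str, ...]] = set()
    kept = []
    for t in traces:
        key = tuple(t.res_names)
        if key in seen:
            logger.info("dropping %s: identical sequence to an earlier structure", t.id)
            continue
        seen.add(key)
        kept.append(t)
    return kept


def membership_tm(seed: CaTrace, candidate: CaTrace) -> float:
    """Symmetric, conservative membership score: min of both TM normalizations."""
    try:
        sup = structural_align(seed, candidate)
    except AlignmentFailure:
        return 0.0
    return min(sup.tm_score_by_a, sup.tm_score_by_b)


def _scan_order(traces: list[CaTrace]) -> list[CaTrace]:
    return sorted(traces, key=lambda t: (-t.L, t.id))


def greedy_cluster(
    traces: list[CaTrace],
    threshold: float = DEFAULT_THRESHOLD,
    best_fit: bool = False,
    build_profiles: bool = True,
) -> ClusterLibrary:
    """Greedy incremental clustering at a TM-score threshold.

    Structures are scanned by length descending (ties broken by id); a
    structure joins the first existing seed with membership TM ≥
    threshold (or, with ``best_fit``, the highest-scoring seed above
    threshold), else it seeds a new cluster.
    """
    if not traces:
        raise ValueError("no structures to cluster")
    lib = ClusterLibrary(threshold=threshold)
    for t in _scan_order(traces):
        lib.traces[t.id] = t
        placed = False
        best_k, best_score = -1, -1.0
        for k, cluster in enumerate(lib.clusters):
            score = membership_tm(lib.traces[cluster.seed_id], t)
            if score >= threshold:
                if not best_fit:
                    cluster.member_ids.append(t.id)
                    cluster.tm_to_seed[t.id] = score
                    placed = True
                    break
                if score > best_score:
                    best_k, best_score = k, score
        if best_fit and best_k >= 0:
            lib.clusters[best_k].member_ids.append(t.id)
            lib.clusters[best_k].tm_to_seed[t.id] = best_score
            placed = True
        if not placed:
            lib.clusters.append(Cluster(seed_id=t.id, member_ids=[t.id], tm_to_seed={t.id: 1.0}))
    if build_profiles:
        attach_profiles(lib)
    return lib


def extend_library(
    library: ClusterLibrary,
    new_traces: list[CaTrace],
    build_profiles: bool = True,
) -> ClusterLibrary:
    """Add structures to an existing library without moving its seeds.

    Each new structure joins an existing cluster if it matches that
    cluster's seed at the library threshold, else it seeds a new cluster
    (greedily, in length order over the new structures).
    """
    if not new_traces:
        return library
    changed: set[str] = set()
    for t in _scan_order(new_traces):
        library.traces[t.id] = t
        placed = False
        for cluster in library.clusters:
            score = membership_tm(library.traces[cluster.seed_id], t)
            if score >= library.threshold:
                cluster.member_ids.append(t.id)
                cluster.tm_to_seed[t.id] = score
                changed.add(cluster.seed_id)
                placed = True
                break
        if not placed:
            library.clusters.append(
                Cluster(seed_id=t.id, member_ids=[t.id], tm_to_seed={t.id: 1.0})
            )
            changed.add(t.id)
    if build_profiles:
        attach_profiles(library, only_seeds=changed)
    return library


def attach_profiles(library: ClusterLibrary, only_seeds: set[str] | None = None) -> None:
    """(Re)build the per-cluster structure profiles from current members."""
    for cluster in library.clusters:
        if only_seeds is not None and cluster.seed_id not in only_seeds:
            continue
        centroid = library.traces[cluster.seed_id]
        members = [library.traces[mid] for mid in cluster.member_ids]
        library.profiles[cluster.seed_id] = build_structure_profile(centroid, members)


# ---------------------------------------------------------------------------
# on-disk layout: manifest.tsv + structures/*.pdb + profiles/*.h5

def save_library(library: ClusterLibrary, out_dir) -> None:
    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    (out / "profiles").mkdir(exist_ok=True)
    rows = []
    for k, cluster in enumerate(library.clusters):
        for mid in cluster.member_ids:
            rows.append(
                {
                    "cluster_id": k,
                    "seed_id": cluster.seed_id,
                    "member_id": mid,
                    "tm_to_seed": round(cluster.tm_to_seed.get(mid, float("nan")), 4),
                }
            )
        if cluster.seed_id in library.profiles:
            save_profile(
                out / "profiles" / f"{cluster.seed_id}.h5", library.profiles[cluster.seed_id]
            )
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    for sid, trace in library.traces.items():
        write_structure(trace, out / "structures" / f"{sid}.pdb", bfactor_from_score=True)
    with open(out / "params.tsv", "w") as f:
        f.write(f"threshold\t{library.threshold}\nplddt_min\t{library.plddt_min}\n")


def load_library(in_dir) -> ClusterLibrary:
    src = Path(in_dir)
    manifest = src / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"no library manifest at {manifest}")
    df = pd.read_csv(manifest, sep="\t")
    lib = ClusterLibrary()
    params_path = src / "params.tsv"
    if params_path.exists():
        params = dict(
            line.split("\t") for line in params_path.read_text().strip().splitlines()
        )
        lib.threshold = float(params.get("threshold", DEFAULT_THRESHOLD))
        lib.plddt_min = float(params.get("plddt_min", DEFAULT_PLDDT_MIN))
    for cid, group in df.groupby("cluster_id", sort=True):
        seed_id = group["seed_id"].iloc[0]
        cluster = Cluster(seed_id=seed_id, member_ids=[], tm_to_seed={})
        for _, row in group.iterrows():
            cluster.member_ids.append(row["member_id"])
            cluster.tm_to_seed[row["member_id"]] = float(row["tm_to_seed"])
        lib.clusters.append(cluster)
        prof_path = src / "profiles" / f"{seed_id}.h5"
        if prof_path.exists():
            prof = load_profile(prof_path)
            assert isinstance(prof, StructureProfile)
            lib.profiles[seed_id] = prof
    for _, row in df.iterrows():
        mid = row["member_id"]
        if mid not in lib.traces:
            lib.traces[mid] = read_structure(
                src / "structures" / f"{mid}.pdb", trace_id=mid
            )
    return lib
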