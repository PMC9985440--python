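"""Structure I/O: Cα traces, secondary structure, chain linking.

The universal structural currency of the package is the :class:`CaTrace`:
an ordered list of Cα coordinates with residue identities, an optional
three-state secondary-structure string and an optional per-residue score
(pLDDT on input from AlphaFold-style files, or a residue-frequency score
on output for visualisation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: residues inserted between chains when linking a complex into one trace:
#: seven Gly-Gly-Ser repeats (21 residues)
LINKER_RESIDUES = ("GLY", "GLY", "SER") * 7

# 8-state DSSP classes collapsed to 3 states
_DSSP_TO_3 = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structural input."""


@dataclass
class CaTrace:
    """Ordered Cα trace of one protein chain.

    Attributes
    ----------
    id:
        Text identifier (file stem + chain by default).
    res_names:
        Three-letter residue codes, one per residue.
    seq_pos:
        1-based author/sequence numbering, strictly increasing for
        traces produced by this package.
    coords:
        (L, 3) float array of Cα positions in Å.
    ss:
        Optional secondary-structure string over {H, E, C}, length L.
    per_residue_score:
        Optional per-residue real score (pLDDT or ResFscore).
    chain_breaks:
        Boolean mask, True where a chain break precedes the residue
        (linker residues in linked complexes are flagged this way).
    """

    id: str
    res_names: list[str]
    seq_pos: np.ndarray
    coords: np.ndarray
    ss: str | None = None
    per_residue_score: np.ndarray | None = None
    chain_breaks: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.seq_pos = np.asarray(self.seq_pos, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coords must be an (L, 3) array")
        if len(self.res_names) != len(self.coords) or len(self.seq_pos) != len(self.coords):
            raise StructureError("res_names, seq_pos and coords must have equal length")
        if self.per_residue_score is not None:
            self.per_residue_score = np.asarray(self.per_residue_score, dtype=np.float64)
            if len(self.per_residue_score) != len(self.coords):
                raise StructureError("per_residue_score length mismatch")
        if self.chain_breaks is None:
            self.chain_breaks = np.zeros(len(self.coords), dtype=bool)
        else:
            self.chain_breaks = np.asarray(self.chain_breaks, dtype=bool)
        if self.ss is not None and len(self.ss) != len(self.coords):
            raise StructureError("ss length mismatch")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def L(self) -> int:
        return len(self.coords)

    def validate(self, check_geometry: bool = True) -> None:
        """Check trace invariants; raise :class:`StructureError` on violation.

        Consecutive Cα–Cα distances must lie in (2.0, 4.5) Å unless the
        following residue is flagged as a chain break.
        """
        if self.L == 0:
            raise StructureError("empty trace")
        if np.any(np.diff(self.seq_pos) <= 0):
            raise StructureError("seq_pos not strictly increasing")
        if check_geometry and self.L > 1:
            d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
            ok = (d > 2.0) & (d < 4.5)
            ok |= self.chain_breaks[1:]
            # a break flagged on residue i also relaxes the bond leaving it
            ok |= self.chain_breaks[:-1]
            if not np.all(ok):
                bad = int(np.flatnonzero(~ok)[0])
                raise StructureError(
                    f"unphysical Cα–Cα distance {d[bad]:.2f} Å between residues "
                    f"{self.seq_pos[bad]} and {self.seq_pos[bad + 1]}"
                )

    def with_ss(self, ss: str | None = None) -> "CaTrace":
        """Return a copy with secondary structure assigned (or overridden)."""
        return replace(self, ss=ss if ss is not None else assign_secondary_structure(self))


def _pick_altloc(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Return the CA atom, resolving altlocs to highest occupancy (tie: first)."""
    best = None
    for atom in residue:
        if atom.name != "CA":
            continue
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def read_structure(path, chain: str | None = None, trace_id: str | None = None) -> CaTrace:
    """Read a PDB or mmCIF file into a :class:`CaTrace`.

    Parameters
    ----------
    path:
        PDB or mmCIF file (format auto-detected by gemmi).
    chain:
        Chain identifier; default is the first chain in the file.

    The B-factor column fills ``per_residue_score`` (AlphaFold DB models
    carry pLDDT there).  Altlocs resolve to the highest-occupancy CA;
    residues without a CA atom are dropped with a warning.  Insertion
    codes are preserved through file order; where they make author
    numbering non-monotone the trace is renumbered sequentially.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0 or len(st[0]) == 0:
        raise StructureError(f"no chains in {path}")
    model = st[0]
    if chain is None:
        ch = model[0]
    else:
        ch = model.find_chain(chain)
        if ch is None:
            raise KeyError(f"chain {chain!r} not found in {path}")

    names: list[str] = []
    pos: list[int] = []
    xyz: list[tuple[float, float, float]] = []
    scores: list[float] = []
    for residue in ch:
        ca = _pick_altloc(residue)
        if ca is None:
            if residue.name not in ("HOH", "WAT"):
                logger.warning("residue %s %s has no CA atom; dropped", residue.name, residue.seqid)
            continue
        names.append(residue.name)
        pos.append(residue.seqid.num)
        xyz.append((ca.pos.x, ca.pos.y, ca.pos.z))
        scores.append(ca.b_iso)
    if not names:
        raise StructureError(f"zero Cα atoms in {path} (chain {ch.name})")
    pos_arr = np.asarray(pos, dtype=np.int64)
    if np.any(np.diff(pos_arr) <= 0):
        # insertion codes / repeated author numbering: keep file order, renumber
        pos_arr = np.arange(1, len(pos) + 1, dtype=np.int64)
    from pathlib import Path as _Path

    tid = trace_id if trace_id is not None else f"{_Path(str(path)).stem}_{ch.name}"
    score_arr = np.asarray(scores)
    if np.all(score_arr == 0.0):
        score_arr = None  # an all-zero B-factor column carries no confidence
    return CaTrace(
        id=tid,
        res_names=names,
        seq_pos=pos_arr,
        coords=np.asarray(xyz),
        per_residue_score=score_arr,
    )


def write_structure(trace: CaTrace, path, bfactor_from_score: bool = False) -> None:
    """Write a Cα-only PDB file.

    With ``bfactor_from_score`` the B-factor column carries
    ``per_residue_score`` clipped to [0, 100]; scores already on a [0, 1]
    scale are multiplied by 100.  Without a score the column is 0.00.
    """
    if bfactor_from_score and trace.per_residue_score is not None:
        s = trace.per_residue_score
        b = s * 100.0 if np.nanmax(s, initial=0.0) <= 1.0 else s
        b = np.clip(b, 0.0, 100.0)
    else:
        b = np.zeros(trace.L)

    st = gemmi.Structure()
    st.name = trace.id
    model = gemmi.Model("1")
    ch = gemmi.Chain("A")
    for i in range(trace.L):
        res = gemmi.Residue()
        res.name = trace.res_names[i]
        res.seqid = gemmi.SeqId(int(trace.seq_pos[i]), " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*trace.coords[i])
        atom.occ = 1.0
        atom.b_iso = float(b[i])
        res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def map_dssp_to_3state(dssp: str) -> str:
    """Collapse an 8-state DSSP string to {H, E, C}."""
    return "".join(_DSSP_TO_3.get(c.upper(), "C") for c in dssp)


def assign_secondary_structure(trace: CaTrace, dssp: str | None = None) -> str:
    """Assign three-state secondary structure from Cα geometry.

    An externally supplied DSSP string (8-state) overrides the
    computation and is collapsed to {H, E, C}.  The geometric rules are
    P-SEA-style windows on the i→i+2 and i→i+3 Cα distances:

    * helix:  d(i,i+2) in [4.9, 6.1] Å and d(i,i+3) in [4.4, 6.2] Å
    * strand: d(i,i+2) ≥ 6.2 Å and d(i,i+3) ≥ 9.0 Å

    Both tests use distances only, so the assignment is invariant under
    rigid transforms.  Traces shorter than 5 residues are all-coil.
    """
    if dssp is not None:
        if len(dssp) != trace.L:
            raise StructureError("DSSP string length mismatch")
        return map_dssp_to_3state(dssp)
    L = trace.L
    if L < 5:
        return "C" * L
    X = trace.coords
    d2 = np.linalg.norm(X[2:] - X[:-2], axis=1)  # d(i, i+2), length L-2
    d3 = np.linalg.norm(X[3:] - X[:-3], axis=1)  # d(i, i+3), length L-3

    ss = np.full(L, "C", dtype="<U1")
    helix_start = (d2[: L - 3] >= 4.9) & (d2[: L - 3] <= 6.1) & (d3 >= 4.4) & (d3 <= 6.2)
    strand_start = (d2[: L - 3] >= 6.2) & (d3 >= 9.0)
    # a window starting at i supports residues i..i+3
    for i in np.flatnonzero(helix_start):
        ss[i : i + 4] = "H"
    for i in np.flatnonzero(strand_start):
        if not np.any(ss[i : i + 4] == "H"):
            ss[i : i + 4] = "E"
    return "".join(ss)


def link_chains(traces: list[CaTrace], linker_id: str | None = None) -> CaTrace:
    """Concatenate chains of a complex into one trace.

    Chains are joined by a 21-residue Gly-Gly-Ser repeat linker (7×GGS)
    whose residues carry placeholder coordinates (evenly spaced on the
    straight segment between the flanking termini) and are flagged as
    chain breaks so downstream scoring can exclude them.  Residue
    numbering is rebuilt 1..total.
    """
    if len(traces) == 0:
        raise ValueError("no traces to link")
    if len(traces) == 1:
        warnings.warn("link_chains called with a single chain; returned unchanged")
        return traces[0]

    names: list[str] = []
    coords: list[np.ndarray] = []
    breaks: list[np.ndarray] = []
    ss_parts: list[str] = []
    have_ss = all(t.ss is not None for t in traces)
    n_link = len(LINKER_RESIDUES)
    for k, t in enumerate(traces):
        if k > 0:
            prev_end = coords[-1][-1]
            nxt_start = t.coords[0]
            frac = (np.arange(1, n_link + 1) / (n_link + 1))[:, None]
            names.extend(LINKER_RESIDUES)
            coords.append(prev_end + frac * (nxt_start - prev_end))
            breaks.append(np.ones(n_link, dtype=bool))
            if have_ss:
                ss_parts.append("C" * n_link)
        names.extend(t.res_names)
        coords.append(t.coords)
        b = t.chain_breaks.copy()
        if k > 0:
            b[0] = True
        breaks.append(b)
        if have_ss:
            ss_parts.append(t.ss)  # type: ignore[arg-type]
    total = sum(map(len, coords))
    return CaTrace(
        id=linker_id or "+".join(t.id for t in traces),
        res_names=names,
        seq_pos=np.arange(1, total + 1),
        coords=np.vstack(coords),
        ss="".join(ss_parts) if have_ss else None,
        chain_breaks=np.concatenate(breaks),
    )
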