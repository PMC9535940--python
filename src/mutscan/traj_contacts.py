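"""Trajectory observables for two-helix dimers.

Distances are in nm end to end; the PDB reader converts from Angstrom on
ingest.  "Contact distance" between two residues means the minimum
heavy-atom distance (a CA-CA alternative is available by flag), matching
common practice for membrane-helix contact maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

NM_PER_ANGSTROM = 0.1


@dataclass
class HelixDimerTrajectory:
    """Frames of two-chain heavy-atom coordinates with residue mapping.

    ``atoms`` has one row per atom (columns ``chain``, ``resid``,
    ``resname``, ``name``); ``coords`` has shape ``(n_frames, n_atoms, 3)``
    in nm.  The atom topology is identical across frames.
    """

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords second axis must match the atom table")
        chains = set(self.atoms["chain"])
        if not {"A", "B"} <= chains:
            raise ValueError(f"expected chains A and B, found {sorted(chains)}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def atom_indices(
        self,
        chain: str,
        resid_lo: int | None = None,
        resid_hi: int | None = None,
        names: list[str] | None = None,
    ) -> np.ndarray:
        m = (self.atoms["chain"] == chain).to_numpy()
        resid = self.atoms["resid"].to_numpy()
        if resid_lo is not None:
            m &= resid >= resid_lo
        if resid_hi is not None:
            m &= resid <= resid_hi
        if names is not None:
            m &= self.atoms["name"].isin(names).to_numpy()
        return np.flatnonzero(m)

    def residues(self, chain: str) -> list[int]:
        sel = self.atoms.loc[self.atoms["chain"] == chain, "resid"]
        return sorted(sel.unique())


# ---------------------------------------------------------------------------
# PDB IO
# ---------------------------------------------------------------------------


def write_pdb(traj: HelixDimerTrajectory, path: str | Path) -> None:
    """Write one MODEL per frame (coordinates converted nm -> Angstrom)."""
    lines = []
    atoms = traj.atoms
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        serial = 1
        for i, row in enumerate(atoms.itertuples()):
            x, y, z = traj.coords[f, i] / NM_PER_ANGSTROM
            name = row.name if len(row.name) >= 4 else f" {row.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {row.resname:<3s} "
                f"{row.chain}{row.resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {row.name[0]:>2s}"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def load_pdb(path: str | Path) -> HelixDimerTrajectory:
    """Read a multi-MODEL PDB into a trajectory (Angstrom -> nm)."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        atoms = pd.DataFrame(
            {
                "chain": u.atoms.chainIDs
                if hasattr(u.atoms, "chainIDs")
                else u.atoms.segids,
                "resid": u.atoms.resids,
                "resname": u.atoms.resnames,
                "name": u.atoms.names,
            }
        )
        coords = np.array(
            [u.atoms.positions.copy() for _ in u.trajectory], dtype=float
        )
    return HelixDimerTrajectory(atoms, coords * NM_PER_ANGSTROM)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------


def _pair_min(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum Euclidean distance between two coordinate sets (one frame)."""
    d = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((d * d).sum(axis=2)).min())


def min_motif_distance(
    traj: HelixDimerTrajectory,
    motif_a_span: tuple[int, int],
    motif_b_span: tuple[int, int],
) -> np.ndarray:
    """Per-frame minimum heavy-atom distance between the two motifs.

    ``motif_a_span`` selects residues (inclusive) on chain A,
    ``motif_b_span`` on chain B.
    """
    ia = traj.atom_indices("A", *motif_a_span)
    ib = traj.atom_indices("B", *motif_b_span)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("empty motif span")
    return np.array(
        [
            _pair_min(traj.coords[f, ia], traj.coords[f, ib])
            for f in range(traj.n_frames)
        ]
    )


def contact_distance_map(
    traj: HelixDimerTrajectory, mode: str = "heavy"
) -> pd.DataFrame:
    """Mean over frames of per-frame minimum residue-residue distances.

    Rows are chain A residues, columns chain B residues.  ``mode`` selects
    all heavy atoms (default) or ``ca`` for CA-CA distances.
    """
    if traj.n_frames < 1:
        raise ValueError("need at least one frame")
    if mode not in ("heavy", "ca"):
        raise ValueError("mode must be 'heavy' or 'ca'")
    names = ["CA"] if mode == "ca" else None
    res_a = traj.residues("A")
    res_b = traj.residues("B")
    idx_a = {r: traj.atom_indices("A", r, r, names) for r in res_a}
    idx_b = {r: traj.atom_indices("B", r, r, names) for r in res_b}
    out = np.zeros((len(res_a), len(res_b)))
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        for i, ra in enumerate(res_a):
            a = xyz[idx_a[ra]]
            for j, rb in enumerate(res_b):
                out[i, j] += _pair_min(a, xyz[idx_b[rb]])
    out /= traj.n_frames
    return pd.DataFrame(out, index=res_a, columns=res_b)


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion.

    Without explicit hydrogens (the default here): donor-acceptor distance
    <= ``distance_cutoff_nm`` and the acceptor must lie within
    ``cone_angle_deg`` of the antecedent->donor direction.  With hydrogens,
    a donor-hydrogen-acceptor angle >= ``dha_angle_deg`` is required
    instead of the cone.
    """

    distance_cutoff_nm: float = 0.35
    cone_angle_deg: float = 30.0
    dha_angle_deg: float = 150.0

    def __post_init__(self) -> None:
        if self.distance_cutoff_nm <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.cone_angle_deg < 180:
            raise ValueError("cone angle must be in (0, 180)")


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


_GLN_ATOMS = {"donor": "NE2", "acceptor": "OE1", "antecedent": "CD"}


def hbond_occupancy(
    traj: HelixDimerTrajectory,
    donor_residue: int,
    acceptor_residue: int,
    criterion: HBondCriterion | None = None,
) -> float:
    """Fraction of frames with an inter-chain side-chain hydrogen bond.

    Both directions (chain A donates to chain B and vice versa) are
    evaluated; a frame counts once if either satisfies the criterion.
    Residues must carry Gln-like side-chain atoms (NE2 donor, OE1
    acceptor, CD antecedent); missing atoms raise an error listing them.
    """
    crit = criterion or HBondCriterion()

    def single_atom(chain: str, resid: int, name: str) -> int | None:
        idx = traj.atom_indices(chain, resid, resid, [name])
        return int(idx[0]) if idx.size else None

    needed: dict[tuple[str, int, str], int | None] = {}
    required = [
        ("A", donor_residue, "NE2"), ("A", donor_residue, "CD"),
        ("B", acceptor_residue, "OE1"),
        ("B", donor_residue, "NE2"), ("B", donor_residue, "CD"),
        ("A", acceptor_residue, "OE1"),
    ]
    missing = []
    for chain, resid, name in required:
        idx = single_atom(chain, resid, name)
        needed[(chain, resid, name)] = idx
        if idx is None:
            missing.append(f"{chain}:{resid}:{name}")
    if missing:
        raise ValueError(f"missing hydrogen-bond atoms: {missing}")

    def satisfied(f: int, dchain: str, achain: str) -> bool:
        d = traj.coords[f, needed[(dchain, donor_residue, "NE2")]]
        ante = traj.coords[f, needed[(dchain, donor_residue, "CD")]]
        a = traj.coords[f, needed[(achain, acceptor_residue, "OE1")]]
        if np.linalg.norm(a - d) > crit.distance_cutoff_nm:
            return False
        return _angle_deg(a - d, d - ante) <= crit.cone_angle_deg

    hits = sum(
        1
        for f in range(traj.n_frames)
        if satisfied(f, "A", "B") or satisfied(f, "B", "A")
    )
    return hits / traj.n_frames
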