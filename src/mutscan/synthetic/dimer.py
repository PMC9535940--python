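"""Idealized two-helix transmembrane dimer trajectories.

Two 30-residue ideal alpha-helices (rise 0.15 nm/residue, 100 deg/residue,
heavy atoms only, coordinates in nm) are crossed so that either the
N-terminal TGMVGA motifs (N-pose) or the C-terminal ALGIG motifs (C-pose)
are in contact.  Chain B is the 180-degree rotation of chain A about the
dimer axis, so all pair observables are exactly chain-swap symmetric
(before per-frame jitter).  An optional fraction of frames places the
Gln side-chain donor/acceptor atoms of an L->Q mutant in hydrogen-bond
geometry; that placement is deterministic per frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_letters_1to3

from ..traj_contacts import HelixDimerTrajectory

#: Default transmembrane fixture: 30 residues in precursor numbering,
#: with Met at 650 and 668 (the catalogue/UniProt sequence).
TM_SEGMENT_SEQ = "KIPSIATGMVGALLLLLVVALGIGLFMRRR"
TM_SEGMENT_OFFSET = 642

#: Inclusive residue spans of the two dimerization motifs.
N_MOTIF_SPAN = (648, 653)  # TGMVGA
C_MOTIF_SPAN = (661, 665)  # ALGIG

_RISE = 0.15  # nm per residue
_TWIST = math.radians(100.0)  # per residue
_D_CLOSE = 0.85  # inter-axis distance at the contact motif (nm)
_D_FAR = 2.40  # inter-axis distance at the other motif (nm)

_HBOND_ATOMS = ("NE2", "OE1", "CD")


def _cyl(radius: float, theta: float, z: float) -> np.ndarray:
    return np.array([radius * math.cos(theta), radius * math.sin(theta), z])


def _base_helix(sequence: str, offset: int) -> tuple[pd.DataFrame, np.ndarray]:
    """One ideal helix along +z; returns (atom table, coords)."""
    rows, coords = [], []

    def add(resid: int, resname: str, name: str, xyz: np.ndarray) -> None:
        rows.append(
            {"chain": "A", "resid": resid, "resname": resname, "name": name}
        )
        coords.append(xyz)

    for i, aa in enumerate(sequence):
        resid = offset + i
        resname = protein_letters_1to3[aa].upper()
        th = _TWIST * i
        z = _RISE * i
        add(resid, resname, "N", _cyl(0.23, th - 0.44, z - 0.05))
        add(resid, resname, "CA", _cyl(0.23, th, z))
        add(resid, resname, "C", _cyl(0.23, th + 0.44, z + 0.05))
        add(resid, resname, "O", _cyl(0.20, th + 0.44, z + 0.10))
        if aa != "G":
            add(resid, resname, "CB", _cyl(0.33, th, z))
        if aa == "Q":
            add(resid, resname, "CG", _cyl(0.45, th, z + 0.02))
            add(resid, resname, "CD", _cyl(0.57, th, z + 0.04))
            add(resid, resname, "OE1", _cyl(0.65, th + 0.14, z + 0.04))
            add(resid, resname, "NE2", _cyl(0.65, th - 0.14, z + 0.08))
    return pd.DataFrame(rows), np.array(coords)


def _span_center_z(span: tuple[int, int], offset: int) -> float:
    return _RISE * ((span[0] + span[1]) / 2.0 - offset)


@dataclass(frozen=True)
class _Placement:
    beta: float  # crossing half-angle (rotation of chain A about y)
    zc: float  # z of the crossing point
    half_sep: float  # half inter-axis distance at the crossing point


def _placement(pose: str, offset: int) -> _Placement:
    z_n = _span_center_z(N_MOTIF_SPAN, offset)
    z_c = _span_center_z(C_MOTIF_SPAN, offset)
    zc = 0.5 * (z_n + z_c)
    z_contact = z_n if pose == "N" else z_c
    d_mid = 0.5 * (_D_CLOSE + _D_FAR)
    sin_beta = (d_mid - _D_CLOSE) / (2.0 * (z_contact - zc))
    return _Placement(
        beta=math.asin(sin_beta), zc=zc, half_sep=d_mid / 2.0
    )


def _chain_a_coords(base: np.ndarray, pl: _Placement) -> np.ndarray:
    cb, sb = math.cos(pl.beta), math.sin(pl.beta)
    p = base.copy()
    p[:, 2] -= pl.zc
    x, z = p[:, 0].copy(), p[:, 2].copy()
    p[:, 0] = cb * x + sb * z
    p[:, 2] = -sb * x + cb * z
    p[:, 2] += pl.zc
    p[:, 0] -= pl.half_sep
    return p


def _rz_pi(coords: np.ndarray) -> np.ndarray:
    out = coords.copy()
    out[:, 0] *= -1.0
    out[:, 1] *= -1.0
    return out


def simulate_helix_dimer(
    pose: str,
    n_frames: int,
    hbond_fraction: float = 0.0,
    seed: int = 0,
    mutations: dict[int, str] | None = None,
    jitter_nm: float = 0.01,
    sequence: str = TM_SEGMENT_SEQ,
    numbering_offset: int = TM_SEGMENT_OFFSET,
    hbond_residue: int = 658,
) -> HelixDimerTrajectory:
    """Generate a two-chain dimer trajectory in N- or C-pose.

    ``mutations`` maps residue numbers to single-letter substitutions
    (e.g. ``{658: "Q"}``); hydrogen-bond placement requires a Gln at
    ``hbond_residue``.  In the first ``round(hbond_fraction * n_frames)``
    frames the Gln side-chain donor/acceptor atoms of both chains are
    placed (without jitter) to satisfy the default geometric criterion;
    in the remaining frames they point away from the dimer interface.
    """
    if pose not in ("N", "C"):
        raise ValueError("pose must be 'N' or 'C'")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0.0 <= hbond_fraction <= 1.0:
        raise ValueError("hbond_fraction must be in [0, 1]")

    seq = list(sequence)
    for resid, aa in (mutations or {}).items():
        idx = resid - numbering_offset
        if not 0 <= idx < len(seq):
            raise ValueError(f"mutation position {resid} outside the segment")
        seq[idx] = aa.upper()
    seq = "".join(seq)
    if hbond_fraction > 0 and seq[hbond_residue - numbering_offset] != "Q":
        raise ValueError(
            f"hydrogen-bond placement requires Gln at residue {hbond_residue}"
        )

    atoms_a, base = _base_helix(seq, numbering_offset)
    pl = _placement(pose, numbering_offset)
    chain_a = _chain_a_coords(base, pl)
    chain_b = _rz_pi(chain_a)
    atoms_b = atoms_a.assign(chain="B")
    atoms = pd.concat([atoms_a, atoms_b], ignore_index=True)
    static = np.vstack([chain_a, chain_b])
    n_atoms = static.shape[0]

    # indices of the Gln hydrogen-bonding atoms (never jittered, so that
    # per-frame hydrogen-bond placement stays deterministic)
    protected = np.zeros(n_atoms, dtype=bool)
    overrides: dict[int, np.ndarray] = {}
    if hbond_fraction > 0:
        ca_idx = np.flatnonzero(
            (atoms_a["resid"] == hbond_residue) & (atoms_a["name"] == "CA")
        )[0]
        zg = float(chain_a[ca_idx, 2])
        placed_a = {
            "NE2": np.array([-0.15, 0.05, zg]),
            "CD": np.array([-0.30, 0.05, zg]),
            "OE1": np.array([-0.15, -0.05, zg]),
        }
        for chain, flip in (("A", False), ("B", True)):
            for name, xyz in placed_a.items():
                sel = np.flatnonzero(
                    (atoms["chain"] == chain)
                    & (atoms["resid"] == hbond_residue)
                    & (atoms["name"] == name)
                )
                idx = int(sel[0])
                protected[idx] = True
                overrides[idx] = _rz_pi(xyz[None, :])[0] if flip else xyz

    n_hbond = int(round(hbond_fraction * n_frames))
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        xyz = static + rng.normal(0.0, jitter_nm, (n_atoms, 3))
        xyz[protected] = static[protected]
        if f < n_hbond:
            for idx, pos in overrides.items():
                xyz[idx] = pos
        frames[f] = xyz
    return HelixDimerTrajectory(atoms, frames)
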