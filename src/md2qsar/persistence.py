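"""Persistence of sidechain contacts and hydrogen bonds over a trajectory.

Persistence is the percentage of frames in which an interaction's
geometric criteria hold.  Two interaction kinds are supported:

* **hydrophobic** — two apolar residues whose sidechain centres of mass
  lie within a distance cutoff (default 5.0 Å over the residue set
  ALA/VAL/LEU/ILE/PHE/MET/PRO/TRP, the convention of sidechain
  interaction-network analysis);
* **hydrogen bond** — donor–acceptor distance within a cutoff (default
  3.5 Å) *and* donor–hydrogen–acceptor angle at least a minimum
  (default 120°), both satisfied in the same frame.

A mutation that swaps an apolar sidechain for a polar one dismantles a
hydrophobic cluster (its contacts lose persistence) while enabling new,
typically less persistent hydrogen bonds — the signature this module
quantifies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import BACKBONE_NAMES, Trajectory

#: Residues treated as hydrophobic for sidechain contact analysis.
DEFAULT_HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PHE", "MET", "PRO", "TRP"}
)


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric thresholds defining the two interaction kinds."""

    hydrophobic_cutoff: float = 5.0          # sidechain COM distance, Å
    hydrophobic_residues: frozenset = DEFAULT_HYDROPHOBIC_RESIDUES
    hbond_da_cutoff: float = 3.5             # donor–acceptor distance, Å
    hbond_angle_min: float = 120.0           # donor–H–acceptor angle, degrees

    def __post_init__(self) -> None:
        if self.hydrophobic_cutoff <= 0 or self.hbond_da_cutoff <= 0:
            raise ValueError("distance cutoffs must be positive")
        if not (0.0 < self.hbond_angle_min <= 180.0):
            raise ValueError("hbond_angle_min must lie in (0, 180]")


def sidechain_atoms(traj: Trajectory, resid: int) -> np.ndarray:
    """Indices of the sidechain atoms of one residue (may be empty)."""
    a = traj.atoms
    mask = (a["resid"] == resid).to_numpy() & ~a["name"].str.strip().isin(
        BACKBONE_NAMES
    ).to_numpy()
    return np.flatnonzero(mask)


def _sidechain_com(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    """Mass-weighted sidechain centroid per frame, shape (n_frames, 3)."""
    m = traj.atoms["mass"].to_numpy()[idx]
    return np.einsum("fij,i->fj", traj.coords[:, idx, :], m) / m.sum()


def hydrophobic_persistence(
    traj: Trajectory,
    criteria: InteractionCriteria = InteractionCriteria(),
    pairs: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Contact persistence between hydrophobic sidechain centres of mass.

    For every candidate residue pair (all hydrophobic-vs-hydrophobic
    pairs when ``pairs`` is omitted) the persistence is the percentage
    of frames whose sidechain centre-of-mass distance is within the
    cutoff.  Residues without sidechain atoms (glycine) are skipped with
    a warning.

    Returns a DataFrame with columns ``resid_a, resid_b, kind,
    persistence, n_frames``.
    """
    a = traj.atoms
    if pairs is None:
        hydro = sorted(
            a.loc[a["resname"].isin(criteria.hydrophobic_residues), "resid"].unique()
        )
        pairs = list(combinations(hydro, 2))

    records = []
    com_cache: dict[int, np.ndarray | None] = {}

    def com_of(resid: int) -> np.ndarray | None:
        if resid not in com_cache:
            idx = sidechain_atoms(traj, resid)
            if idx.size == 0:
                warnings.warn(f"residue {resid} has no sidechain atoms; skipped")
                com_cache[resid] = None
            else:
                com_cache[resid] = _sidechain_com(traj, idx)
        return com_cache[resid]

    for ra, rb in pairs:
        if not (a["resid"] == ra).any() or not (a["resid"] == rb).any():
            raise ValueError(f"residue pair ({ra}, {rb}) not found in trajectory")
        ca, cb = com_of(ra), com_of(rb)
        if ca is None or cb is None:
            continue
        d = np.linalg.norm(ca - cb, axis=1)
        frac = float((d <= criteria.hydrophobic_cutoff).mean())
        records.append(
            {"resid_a": ra, "resid_b": rb, "kind": "hydrophobic",
             "persistence": 100.0 * frac, "n_frames": traj.n_frames}
        )
    return pd.DataFrame(
        records, columns=["resid_a", "resid_b", "kind", "persistence", "n_frames"]
    )


def hbond_persistence(
    traj: Trajectory,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    criteria: InteractionCriteria = InteractionCriteria(),
) -> pd.DataFrame:
    """Hydrogen-bond persistence for donor/acceptor atom selections.

    Parameters
    ----------
    donors:
        List of ``(donor_atom_index, hydrogen_atom_index)`` pairs; a
        donor listed without an attached hydrogen is a hard error.
    acceptors:
        Acceptor atom indices.
    criteria:
        Distance and angle thresholds; a frame counts only when the
        donor–acceptor distance is within ``hbond_da_cutoff`` *and* the
        donor–H–acceptor angle is at least ``hbond_angle_min``.

    Returns a DataFrame with columns ``donor, hydrogen, acceptor, kind,
    persistence, n_frames``.
    """
    names = traj.atoms["name"].to_numpy()
    records = []
    for d_idx, h_idx in donors:
        if h_idx is None:
            raise ValueError(f"donor atom {names[d_idx]!r} (index {d_idx}) has no hydrogen")
        for acc in acceptors:
            if acc == d_idx or acc == h_idx:
                continue
            dpos = traj.coords[:, d_idx, :]
            hpos = traj.coords[:, h_idx, :]
            apos = traj.coords[:, acc, :]
            da = np.linalg.norm(apos - dpos, axis=1)
            # angle at the hydrogen between donor and acceptor
            v1 = dpos - hpos
            v2 = apos - hpos
            cosang = np.einsum("ij,ij->i", v1, v2) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            ok = (da <= criteria.hbond_da_cutoff) & (ang >= criteria.hbond_angle_min)
            records.append(
                {"donor": int(d_idx), "hydrogen": int(h_idx), "acceptor": int(acc),
                 "kind": "hbond", "persistence": 100.0 * float(ok.mean()),
                 "n_frames": traj.n_frames}
            )
    return pd.DataFrame(
        records,
        columns=["donor", "hydrogen", "acceptor", "kind", "persistence", "n_frames"],
    )
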