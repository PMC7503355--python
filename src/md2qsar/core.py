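"""Core in-memory containers shared across the pipeline.

The central object is :class:`Trajectory`: a static atom table (identity,
group membership and nonbonded parameters per atom) plus a stack of
per-frame Cartesian coordinates in Ångström.  All descriptor and
persistence operations consume this container; the synthetic generator
and the PDB/TSV readers produce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every atom table must carry.
ATOM_COLUMNS = [
    "serial",       # integer atom serial, unique
    "name",         # atom name, e.g. "CA", "CB", "O1"
    "resid",        # residue sequence number
    "resname",      # residue name, e.g. "LEU"
    "group",        # group tag: "protein", "NADP", "hPGS", "other"
    "radius",       # van der Waals radius, Å
    "charge",       # partial charge, e
    "lj_epsilon",   # Lennard-Jones well depth, kJ/mol
    "lj_sigma",     # Lennard-Jones size parameter, nm
]

#: Atomic masses (u) for the elements that occur in protein/ligand systems.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "SE": 78.971, "K": 39.098, "NA": 22.990, "MG": 24.305, "CA": 40.078,
    "ZN": 65.38, "FE": 55.845,
}

#: Backbone atom names; everything else in a residue counts as sidechain.
BACKBONE_NAMES = {"N", "CA", "C", "O", "H", "HA", "H1", "H2", "H3", "OXT"}


def element_of(atom_name: str) -> str:
    """Infer the element symbol from a PDB-style atom name.

    Two-letter elements common in biomolecules (CL, BR, SE, ...) are
    recognised; otherwise the first alphabetic character wins, so "CA"
    inside a residue is carbon, "1HB" is hydrogen.
    """
    stripped = atom_name.strip().upper().lstrip("0123456789")
    if stripped[:2] in ATOMIC_MASSES and stripped[:2] not in ("CA", "NA"):
        return stripped[:2]
    return stripped[0]


@dataclass
class Trajectory:
    """Static atom table plus per-frame coordinates (Å).

    Parameters
    ----------
    atoms:
        DataFrame with at least :data:`ATOM_COLUMNS`.  An ``element``
        column is added on construction when absent (inferred from the
        atom name) together with a ``mass`` column in unified atomic
        mass units.
    coords:
        Array of shape ``(n_frames, n_atoms, 3)`` in Å.
    """

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coords carry {self.coords.shape[1]} atoms per frame, "
                f"atom table has {len(self.atoms)}"
            )
        if (self.atoms["radius"] <= 0).any():
            raise ValueError("atom radii must be positive")
        if "element" not in self.atoms.columns:
            self.atoms = self.atoms.assign(
                element=[element_of(n) for n in self.atoms["name"]]
            )
        if "mass" not in self.atoms.columns:
            self.atoms = self.atoms.assign(
                mass=[ATOMIC_MASSES[e.upper()] for e in self.atoms["element"]]
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def group_indices(self, group: str) -> np.ndarray:
        """Positional indices of the atoms carrying ``group`` as tag."""
        return np.flatnonzero((self.atoms["group"] == group).to_numpy())


@dataclass
class DescriptorRow:
    """Per-variant trajectory descriptors, mean ± SD over frames.

    Surface areas are in nm², interaction energies in kJ/mol, matching
    how the quantities are conventionally tabulated for enzyme variants.
    """

    variant: str
    sas_nadp: float
    sas_nadp_sd: float
    sas_hpgs: float
    sas_hpgs_sd: float
    ie_p_hp: float
    ie_p_hp_sd: float
    ie_n_hp: float
    ie_n_hp_sd: float
    n_frames: int

    def __post_init__(self) -> None:
        for sd in (self.sas_nadp_sd, self.sas_hpgs_sd, self.ie_p_hp_sd, self.ie_n_hp_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if self.sas_nadp < 0 or self.sas_hpgs < 0:
            raise ValueError("surface areas must be non-negative")


@dataclass
class KineticsRow:
    """Michaelis–Menten parameters for one enzyme variant.

    Km in µM, kcat in min⁻¹, kcat/Km in min⁻¹µM⁻¹.  ``measured`` is False
    for rows whose values are model predictions rather than experiments.
    """

    variant: str
    km: float | None
    kcat: float | None
    kcat_over_km: float | None
    measured: bool = True
    km_sd: float | None = None

    def __post_init__(self) -> None:
        for v in (self.km, self.kcat, self.kcat_over_km):
            if v is not None and v <= 0:
                raise ValueError("kinetic parameters must be positive")


def descriptor_frame(rows: list[DescriptorRow]) -> pd.DataFrame:
    """Tabulate descriptor rows (one row per variant)."""
    return pd.DataFrame(
        {
            "variant": [r.variant for r in rows],
            "SAS_NADP": [r.sas_nadp for r in rows],
            "SAS_NADP_sd": [r.sas_nadp_sd for r in rows],
            "SAS_hPGS": [r.sas_hpgs for r in rows],
            "SAS_hPGS_sd": [r.sas_hpgs_sd for r in rows],
            "IE_P_hP": [r.ie_p_hp for r in rows],
            "IE_P_hP_sd": [r.ie_p_hp_sd for r in rows],
            "IE_N_hP": [r.ie_n_hp for r in rows],
            "IE_N_hP_sd": [r.ie_n_hp_sd for r in rows],
            "n_frames": [r.n_frames for r in rows],
        }
    )


def kinetics_frame(rows: list[KineticsRow]) -> pd.DataFrame:
    """Tabulate kinetics rows (one row per variant)."""
    return pd.DataFrame(
        {
            "variant": [r.variant for r in rows],
            "Km": [r.km for r in rows],
            "Km_sd": [r.km_sd for r in rows],
            "kcat": [r.kcat for r in rows],
            "kcat_over_Km": [r.kcat_over_km for r in rows],
            "measured": [r.measured for r in rows],
        }
    )
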