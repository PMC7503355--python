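"""Structural and energetic descriptors of an MD trajectory.

Four observables summarise how a ligand sits in its binding site over a
trajectory of an enzyme–cofactor–ligand ternary complex:

* the solvent-accessible surface area (SASA) of the cofactor and the
  ligand within the full complex, via the Shrake–Rupley rolling-probe
  construction;
* the pairwise molecular-mechanics interaction energy (Coulomb plus
  Lennard-Jones 12-6) between atom groups, e.g. protein↔ligand and
  cofactor↔ligand;
* the per-residue root mean square fluctuation (RMSF) of Cα atoms about
  the trajectory-average structure, optionally after least-squares
  superposition;
* a one-tailed Welch t-test comparing descriptor samples between two
  variants.

A ligand buried deeper in the site exposes less surface to solvent and
binds with a more negative interaction energy; both respond to variant-
induced rearrangements of the binding-site loops and are therefore the
raw material for kinetics-predicting regression models.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .core import DescriptorRow, Trajectory

#: Coulomb constant 1/(4πε₀) in kJ·mol⁻¹·nm·e⁻².
COULOMB_KE = 138.935485

#: Water-probe radius, Å.
DEFAULT_PROBE_RADIUS = 1.4

#: Quadrature points per atom sphere for Shrake–Rupley.
DEFAULT_SPHERE_POINTS = 960


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors via the golden-spiral lattice."""
    k = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k      # golden angle increments
    z = 1.0 - (2.0 * k + 1.0) / n                   # uniform in z
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def compute_sasa(
    coords: np.ndarray,
    atoms: pd.DataFrame,
    group: str,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> float:
    """Shrake–Rupley solvent-accessible area of a group, in nm².

    Each atom of the target group is inflated by the probe radius and
    sampled with a quasi-uniform point lattice; a point is accessible
    when it lies outside the probe-extended sphere of every *other* atom
    of the whole system, so the group's area is computed in the context
    of all atoms, not in isolation.

    Parameters
    ----------
    coords:
        Single-frame coordinates, shape ``(n_atoms, 3)``, Å.
    atoms:
        Atom table aligned with ``coords`` (needs ``group`` and
        ``radius`` columns).
    group:
        Group tag whose accessible area is wanted.
    probe_radius:
        Solvent probe radius in Å (water ≈ 1.4 Å).
    n_sphere_points:
        Quadrature points per atom; the relative quadrature error scales
        as ~1/√n.

    Returns
    -------
    float
        Accessible area in nm² (1 nm² = 100 Å²).
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_sphere_points < 12:
        raise ValueError("n_sphere_points must be at least 12")
    coords = np.asarray(coords, dtype=float)
    mask = (atoms["group"] == group).to_numpy()
    target = np.flatnonzero(mask)
    if target.size == 0:
        raise ValueError(f"group {group!r} has no atoms")

    radii = atoms["radius"].to_numpy(dtype=float) + probe_radius
    unit = sphere_points(n_sphere_points)
    area_a2 = 0.0
    for i in target:
        pts = coords[i] + radii[i] * unit
        # neighbours whose extended sphere can reach atom i's surface
        d = np.linalg.norm(coords - coords[i], axis=1)
        neigh = np.flatnonzero((d < radii + radii[i]) & (np.arange(len(d)) != i))
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neigh:
            accessible &= (
                np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
                >= radii[j] * radii[j]
            )
        area_a2 += 4.0 * math.pi * radii[i] ** 2 * accessible.mean()
    return area_a2 / 100.0


def compute_interaction_energy(
    coords: np.ndarray,
    atoms: pd.DataFrame,
    group_a: str,
    group_b: str,
    cutoff: float | None = None,
) -> float:
    """Nonbonded inter-group energy for one frame, in kJ/mol.

    Sums, over all pairs with one atom in each group, the Coulomb term
    ``ke·qi·qj/r`` and the Lennard-Jones 12-6 term
    ``4ε[(σ/r)¹² − (σ/r)⁶]`` with Lorentz–Berthelot combination rules
    (arithmetic mean σ, geometric mean ε).  Distances beyond ``cutoff``
    (Å) are excluded when a cutoff is given; by default every pair
    contributes.
    """
    coords = np.asarray(coords, dtype=float)
    ia = np.flatnonzero((atoms["group"] == group_a).to_numpy())
    ib = np.flatnonzero((atoms["group"] == group_b).to_numpy())
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(ia, ib).size:
        raise ValueError("groups overlap")

    # pair distances in nm
    diff = coords[ia][:, None, :] - coords[ib][None, :, :]
    r_nm = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff)) / 10.0
    if np.any(r_nm == 0.0):
        raise ValueError("coincident atoms across groups (r = 0)")
    included = np.ones_like(r_nm, dtype=bool)
    if cutoff is not None:
        included = r_nm <= cutoff / 10.0

    q = atoms["charge"].to_numpy(dtype=float)
    eps = atoms["lj_epsilon"].to_numpy(dtype=float)
    sig = atoms["lj_sigma"].to_numpy(dtype=float)

    coulomb = COULOMB_KE * np.outer(q[ia], q[ib]) / r_nm
    sig_ij = 0.5 * (sig[ia][:, None] + sig[ib][None, :])
    eps_ij = np.sqrt(np.outer(eps[ia], eps[ib]))
    sr6 = (sig_ij / r_nm) ** 6
    lj = 4.0 * eps_ij * (sr6 * sr6 - sr6)
    return float(((coulomb + lj) * included).sum())


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centred ``mobile`` onto ``reference``."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, 1.0, d])
    return u @ correction @ vt


def compute_rmsf(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    superpose: bool = True,
) -> pd.DataFrame:
    """Per-atom RMSF (Å) about the trajectory-average structure.

    With ``superpose`` each frame is first least-squares fitted (Kabsch)
    onto the mean structure of the selection; the mean is then recomputed
    from the fitted frames and the fluctuation measured against it.  The
    default selection is all Cα atoms.

    Returns a DataFrame with columns ``resid`` and ``rmsf``.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if selection is None:
        selection = np.flatnonzero((traj.atoms["name"] == "CA").to_numpy())
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty atom selection")

    frames = traj.coords[:, selection, :].astype(float)
    if superpose:
        mean = frames.mean(axis=0)
        mean_c = mean - mean.mean(axis=0)
        fitted = np.empty_like(frames)
        for t in range(frames.shape[0]):
            x = frames[t] - frames[t].mean(axis=0)
            fitted[t] = x @ kabsch_rotation(x, mean_c)
        frames = fitted
    mean = frames.mean(axis=0)
    disp2 = ((frames - mean) ** 2).sum(axis=2)  # (n_frames, n_sel)
    rmsf = np.sqrt(disp2.mean(axis=0))
    return pd.DataFrame(
        {"resid": traj.atoms["resid"].to_numpy()[selection], "rmsf": rmsf}
    )


def summarize_descriptors(
    traj: Trajectory,
    variant: str,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
    cutoff: float | None = None,
) -> DescriptorRow:
    """Reduce a trajectory to mean ± SD of the four binding descriptors.

    Per frame, the cofactor (group ``NADP``) and ligand (group ``hPGS``)
    accessible areas and the protein↔ligand / cofactor↔ligand interaction
    energies are evaluated; each series is then summarised as mean and
    population standard deviation over frames (frames are the complete
    sampled population of the trajectory).
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    for g in ("protein", "NADP", "hPGS"):
        if traj.group_indices(g).size == 0:
            raise ValueError(f"trajectory has no {g!r} atoms")

    sas_n, sas_h, ie_p, ie_n = [], [], [], []
    for frame in traj.coords:
        sas_n.append(compute_sasa(frame, traj.atoms, "NADP", probe_radius, n_sphere_points))
        sas_h.append(compute_sasa(frame, traj.atoms, "hPGS", probe_radius, n_sphere_points))
        ie_p.append(compute_interaction_energy(frame, traj.atoms, "protein", "hPGS", cutoff))
        ie_n.append(compute_interaction_energy(frame, traj.atoms, "NADP", "hPGS", cutoff))

    def mean_sd(x: list[float]) -> tuple[float, float]:
        a = np.asarray(x)
        return float(a.mean()), float(a.std())  # population SD

    mn, sn = mean_sd(sas_n)
    mh, sh = mean_sd(sas_h)
    mp, sp = mean_sd(ie_p)
    mi, si = mean_sd(ie_n)
    return DescriptorRow(
        variant=variant,
        sas_nadp=mn, sas_nadp_sd=sn,
        sas_hpgs=mh, sas_hpgs_sd=sh,
        ie_p_hp=mp, ie_p_hp_sd=sp,
        ie_n_hp=mi, ie_n_hp_sd=si,
        n_frames=traj.n_frames,
    )


def compare_descriptors(
    samples_a: np.ndarray,
    samples_b: np.ndarray,
    alternative: str = "less",
) -> float:
    """One-tailed Welch t-test p-value comparing two descriptor samples.

    ``alternative`` states the tested direction for B relative to A:
    ``"greater"`` tests mean(B) > mean(A), ``"less"`` tests
    mean(B) < mean(A).  Two samples with zero variance and equal means
    sit exactly on the null boundary and return p = 0.5.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if a.std() == 0.0 and b.std() == 0.0 and a.mean() == b.mean():
        return 0.5
    res = stats.ttest_ind(b, a, equal_var=False, alternative=alternative)
    return float(res.pvalue)
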