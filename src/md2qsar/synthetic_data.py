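"""Synthetic inputs with machine-readable ground truth.

Every stage of the pipeline gets a generator here, so the whole chain is
testable without any external download:

* :func:`make_trajectory` — a toy multi-frame coordinate set in which
  selected atom pairs are in contact for an exactly scheduled fraction
  of frames, plus bounded Gaussian positional jitter;
* :func:`make_qsar_table` — a descriptor/kinetics panel with a planted
  log-linear law relating interaction-energy descriptors to enzymatic
  parameters;
* :func:`make_family_variants` — a family genotype matrix with one
  planted causal variant that alone satisfies the full segregation
  filtering cascade.

Contact scheduling is deterministic: frames are assigned to the
"in-contact" state by index before jitter is applied, and the jitter is
clipped so that it can never flip a frame's contact state — scheduled
fractions are therefore exact, which downstream persistence tests rely
on.  Coordinates are generated in Å throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DescriptorRow, KineticsRow, Trajectory
from .variant_filter import Pedigree

# ---------------------------------------------------------------- trajectory


@dataclass
class SyntheticTrajectorySpec:
    """Recipe for a toy trajectory with scheduled contacts.

    ``contact_schedule`` maps atom-index pairs to the fraction of frames
    the pair must spend within ``contact_cutoff`` Å of each other.
    ``displacement_sigma`` is the per-axis SD of the Gaussian jitter
    applied around each atom's mean position (clipped at 3σ so contact
    states cannot flip).
    """

    n_atoms: int = 10
    n_frames: int = 100
    displacement_sigma: float = 0.1
    contact_schedule: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    seed: int = 0
    contact_cutoff: float = 5.0
    group_of: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.displacement_sigma < 0:
            raise ValueError("displacement_sigma must be non-negative")
        seen: set[int] = set()
        for (i, j), frac in self.contact_schedule:
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"contact fraction {frac} outside [0, 1]")
            if i == j or not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValueError(f"invalid atom pair ({i}, {j})")
            if i in seen or j in seen:
                raise ValueError("an atom may appear in at most one scheduled pair")
            seen.update((i, j))


def make_trajectory(spec: SyntheticTrajectorySpec) -> Trajectory:
    """Build the trajectory; the achieved schedule is in ``.ground_truth``.

    Atoms are one-atom residues (name CB, hydrophobic residue names) on
    a 20 Å grid, so only scheduled pairs can ever be in contact.  For a
    scheduled pair, the first ``round(fraction · n_frames)`` frames place
    the pair just inside the cutoff and the rest just outside, with a
    separation margin exceeding the maximum possible jitter excursion.
    ``ground_truth`` records, per pair, the exact achieved fraction and
    the in-contact frame indices.
    """
    rng = np.random.default_rng(spec.seed)
    bound = 3.0 * spec.displacement_sigma          # per-axis jitter clip
    margin = 2.0 * np.sqrt(3.0) * bound + 0.1      # max pair-distance excursion
    d_in = spec.contact_cutoff - margin
    d_out = spec.contact_cutoff + margin
    if d_in <= 0.5:
        raise ValueError(
            "displacement_sigma too large relative to contact_cutoff: "
            "jitter could flip contact states"
        )

    # grid of mean positions, spacing 20 Å (>> cutoff + jitter)
    side = int(np.ceil(spec.n_atoms ** (1.0 / 3.0)))
    grid = np.array(
        [(x, y, z) for x in range(side) for y in range(side) for z in range(side)],
        dtype=float,
    )[: spec.n_atoms] * 20.0

    base = np.tile(grid, (spec.n_frames, 1, 1))
    truth: dict[tuple[int, int], dict] = {}
    for (i, j), frac in spec.contact_schedule:
        k = int(round(frac * spec.n_frames))
        # partner j sits along +x from i at the scheduled distance
        base[:, j, :] = base[:, i, :]
        base[:k, j, 0] += d_in
        base[k:, j, 0] += d_out
        truth[(i, j)] = {
            "fraction": k / spec.n_frames,
            "in_contact_frames": list(range(k)),
        }

    if spec.displacement_sigma > 0:
        jitter = rng.normal(0.0, spec.displacement_sigma, size=base.shape)
        jitter = np.clip(jitter, -bound, bound)
        base = base + jitter

    resnames = ["LEU", "VAL", "ILE", "PHE", "MET", "ALA", "TRP", "PRO"]
    atoms = pd.DataFrame(
        {
            "serial": np.arange(1, spec.n_atoms + 1),
            "name": ["CB"] * spec.n_atoms,
            "resid": np.arange(1, spec.n_atoms + 1),
            "resname": [resnames[i % len(resnames)] for i in range(spec.n_atoms)],
            "group": [spec.group_of.get(i, "protein") for i in range(spec.n_atoms)],
            "radius": 1.9,
            "charge": 0.0,
            "lj_epsilon": 0.5,
            "lj_sigma": 0.35,
        }
    )
    traj = Trajectory(atoms=atoms, coords=base)
    traj.ground_truth = truth  # type: ignore[attr-defined]
    return traj


# ------------------------------------------------------------------- QSAR


def _default_true_models() -> dict:
    # planted laws shaped like the fitted study models: kcat driven by the
    # protein-ligand energy, efficiency by both energies, Km the quotient
    return {
        "kcat": (-3.521, {"IE_P_hP": -0.0444}),
        "kcat_over_Km": (-7.581, {"IE_P_hP": -0.0769, "IE_N_hP": 0.0426}),
    }


def _default_ranges() -> dict:
    return {
        "IE_P_hP": (-130.0, -95.0),
        "IE_N_hP": (-35.0, -5.0),
        "SAS_NADP": (0.9, 1.6),   # distractor descriptors, nm²
        "SAS_hPGS": (0.8, 1.5),
    }


@dataclass
class SyntheticQSARSpec:
    """Recipe for a descriptor/kinetics panel with a planted linear law.

    ``true_models`` maps a response name to ``(intercept, {descriptor:
    slope})`` on the log10 scale; Km is always derived as
    kcat ÷ (kcat/Km) so the three kinetic columns stay consistent.
    ``noise_sigma`` is the residual SD added to each modelled log10
    response.  Descriptors are drawn uniformly from
    ``predictor_ranges`` (kJ/mol for energies, nm² for areas).
    """

    n_variants: int = 8
    true_models: dict = field(default_factory=_default_true_models)
    noise_sigma: float = 0.0
    predictor_ranges: dict = field(default_factory=_default_ranges)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        max_pred = max(len(slopes) for _, slopes in self.true_models.values())
        minimum = 3 if max_pred == 1 else 4
        if self.n_variants < minimum:
            raise ValueError(
                f"n_variants must be at least {minimum} for "
                f"{max_pred}-predictor models"
            )
        for resp, (_, slopes) in self.true_models.items():
            for name in slopes:
                if name not in self.predictor_ranges:
                    raise ValueError(f"{resp} uses unknown predictor {name}")


def make_qsar_table(
    spec: SyntheticQSARSpec,
) -> tuple[list[DescriptorRow], list[KineticsRow]]:
    """Draw descriptors, apply the planted laws, return the panel.

    The spec itself is the ground truth (it holds the planted
    coefficients); refitting the returned table at zero noise recovers
    them to machine precision.
    """
    rng = np.random.default_rng(spec.seed)
    values = {
        name: rng.uniform(lo, hi, size=spec.n_variants)
        for name, (lo, hi) in spec.predictor_ranges.items()
    }

    def log_response(resp: str) -> np.ndarray:
        intercept, slopes = spec.true_models[resp]
        y = np.full(spec.n_variants, intercept, dtype=float)
        for name, slope in slopes.items():
            y += slope * values[name]
        if spec.noise_sigma > 0:
            y += rng.normal(0.0, spec.noise_sigma, size=spec.n_variants)
        return y

    log_kcat = log_response("kcat")
    log_eff = log_response("kcat_over_Km")
    kcat = 10.0 ** log_kcat
    eff = 10.0 ** log_eff
    km = kcat / eff

    descriptors, kinetics = [], []
    for i in range(spec.n_variants):
        vid = f"V{i:02d}"
        descriptors.append(
            DescriptorRow(
                variant=vid,
                sas_nadp=float(values.get("SAS_NADP", np.full(spec.n_variants, 1.1))[i]),
                sas_nadp_sd=0.05,
                sas_hpgs=float(values.get("SAS_hPGS", np.full(spec.n_variants, 1.0))[i]),
                sas_hpgs_sd=0.05,
                ie_p_hp=float(values["IE_P_hP"][i]),
                ie_p_hp_sd=abs(0.05 * values["IE_P_hP"][i]),
                ie_n_hp=float(values["IE_N_hP"][i]),
                ie_n_hp_sd=abs(0.05 * values["IE_N_hP"][i]),
                n_frames=1000,
            )
        )
        kinetics.append(
            KineticsRow(
                variant=vid,
                km=float(km[i]),
                kcat=float(kcat[i]),
                kcat_over_km=float(eff[i]),
                measured=True,
            )
        )
    return descriptors, kinetics


# ------------------------------------------------------------------ family


def default_family() -> pd.DataFrame:
    """A three-generation family of 12 with 3 affected females.

    Mirrors the study design: two affected sisters and an affected
    daughter, everyone else unaffected; all members genotyped.
    """
    rows = [
        # id, sex, affected, father, mother
        ("I:1", "M", False, "0", "0"),
        ("I:2", "F", False, "0", "0"),
        ("II:1", "M", False, "I:1", "I:2"),
        ("II:2", "F", False, "0", "0"),
        ("II:3", "F", False, "I:1", "I:2"),
        ("III:1", "M", False, "0", "0"),
        ("III:2", "F", True, "II:1", "II:2"),
        ("III:5", "M", False, "0", "0"),
        ("III:6", "F", True, "II:1", "II:2"),
        ("IV:1", "M", False, "III:1", "III:2"),
        ("IV:4", "F", True, "III:5", "III:6"),
        ("IV:5", "F", False, "III:5", "III:6"),
    ]
    return pd.DataFrame(rows, columns=["id", "sex", "affected", "father", "mother"])


@dataclass
class SyntheticFamilySpec:
    """Recipe for a family variant table with one planted causal variant.

    The causal variant is heterozygous in every affected member and
    absent everywhere else; each background variant is built to violate
    exactly one cascade criterion, and the generator keeps a per-stage
    tally in the table's ``attrs``.  ``causal_af`` above the filtering
    threshold makes even the causal variant removable (frequency stage).
    """

    pedigree: pd.DataFrame = field(default_factory=default_family)
    n_background_variants: int = 100
    causal_af: float = 0.0
    n_cohort: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        aff = self.pedigree["affected"].astype(bool)
        if not aff.any() or aff.all():
            raise ValueError("pedigree needs both affected and unaffected members")
        if not (0.0 <= self.causal_af <= 1.0):
            raise ValueError("causal_af must be a fraction in [0, 1]")


BASES = np.array(["A", "C", "G", "T"])

_BACKGROUND_STAGES = [
    "not_het_in_all_affected",
    "present_in_unaffected_family",
    "present_in_unrelated_cohort",
    "common_in_population",
    "synonymous",
]


def make_family_variants(
    spec: SyntheticFamilySpec,
) -> tuple[pd.DataFrame, Pedigree]:
    """Generate the genotype matrix and pedigree for the filtering cascade.

    Returns ``(variants, pedigree)``; ``variants.attrs`` carries
    ``causal_index`` (row of the planted causal variant) and
    ``stage_tally`` (how many background variants were planted to fail
    at each stage).
    """
    rng = np.random.default_rng(spec.seed)
    cohort_ids = [f"C{i + 1:02d}" for i in range(spec.n_cohort)]
    ped = Pedigree(individuals=spec.pedigree.copy(), cohort_ids=cohort_ids)
    family_ids = list(spec.pedigree["id"])
    affected = ped.affected_ids
    unaffected = ped.unaffected_ids
    all_samples = family_ids + cohort_ids

    n_total = spec.n_background_variants + 1
    causal_row = int(rng.integers(0, n_total))
    positions = np.sort(rng.choice(np.arange(1, 10_000_000), size=n_total, replace=False))

    tally = {s: 0 for s in _BACKGROUND_STAGES}
    records = []
    for v in range(n_total):
        ref, alt = rng.choice(BASES, size=2, replace=False)
        row = {
            "chrom": str(rng.integers(1, 23)),
            "pos": int(positions[v]),
            "ref": str(ref),
            "alt": str(alt),
            "af": float(rng.uniform(0.0, 0.009)),
            "consequence": "missense",
        }
        gt = {s: 0 for s in all_samples}
        if v == causal_row:
            for s in affected:
                gt[s] = 1
            row["af"] = spec.causal_af
        else:
            stage = _BACKGROUND_STAGES[int(rng.integers(0, len(_BACKGROUND_STAGES)))]
            tally[stage] += 1
            for s in affected:
                gt[s] = 1
            if stage == "not_het_in_all_affected":
                spoiled = affected[int(rng.integers(0, len(affected)))]
                gt[spoiled] = int(rng.choice([0, 2]))
            elif stage == "present_in_unaffected_family":
                carrier = unaffected[int(rng.integers(0, len(unaffected)))]
                gt[carrier] = 1
            elif stage == "present_in_unrelated_cohort":
                carrier = cohort_ids[int(rng.integers(0, len(cohort_ids)))]
                gt[carrier] = 1
            elif stage == "common_in_population":
                row["af"] = float(rng.uniform(0.011, 0.5))
            elif stage == "synonymous":
                row["consequence"] = "synonymous"
        for s in all_samples:
            row[f"gt_{s}"] = gt[s]
        records.append(row)

    variants = pd.DataFrame(records)
    variants.attrs["causal_index"] = causal_row
    variants.attrs["stage_tally"] = tally
    return variants, ped
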