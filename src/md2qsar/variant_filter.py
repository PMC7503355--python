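"""Pedigree-based candidate-variant filtering for a dominant trait.

Given a family genotype matrix, an affected/unaffected annotation and an
unrelated sequenced cohort, a variant survives the cascade iff it

1. is heterozygous in every affected family member,
2. is absent in every unaffected family member,
3. is absent in every unrelated-cohort individual,
4. has population allele frequency at or below a threshold
   (default 1%; variants *more* frequent are removed),
5. is not synonymous.

The stages are independent predicates, so the surviving set does not
depend on the order of application; the per-stage removal counts do,
and are reported in the order above (each variant is charged to the
first stage that removes it).

Genotypes are encoded as 0 (hom-ref), 1 (het), 2 (hom-alt), -1
(missing).  "Absent" in controls means hom-ref; by default a missing
genotype in a control is treated leniently as absent (configurable to
strict, where missing fails the absence requirement).  A missing
genotype in an affected individual is always a hard error: segregation
cannot be asserted without it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

KNOWN_CONSEQUENCES = {
    "synonymous", "missense", "stop_gained", "stop_lost", "splice",
    "frameshift", "inframe_indel", "intronic", "utr",
}

STAGES = [
    "not_het_in_all_affected",
    "present_in_unaffected_family",
    "present_in_unrelated_cohort",
    "common_in_population",
    "synonymous",
]


@dataclass
class Pedigree:
    """Family members with affected status plus the unrelated cohort IDs."""

    individuals: pd.DataFrame  # id, sex, affected, father, mother
    cohort_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        req = {"id", "sex", "affected", "father", "mother"}
        missing = req - set(self.individuals.columns)
        if missing:
            raise ValueError(f"pedigree missing columns: {sorted(missing)}")
        ids = set(self.individuals["id"])
        for col in ("father", "mother"):
            parents = set(self.individuals[col]) - {"0", 0, None}
            if not parents <= ids:
                raise ValueError(f"unresolved {col} references: {parents - ids}")
        if not self.individuals["affected"].any():
            raise ValueError("pedigree has no affected individual")

    @property
    def affected_ids(self) -> list[str]:
        m = self.individuals
        return list(m.loc[m["affected"].astype(bool), "id"])

    @property
    def unaffected_ids(self) -> list[str]:
        m = self.individuals
        return list(m.loc[~m["affected"].astype(bool), "id"])


@dataclass
class FilterReport:
    """Survivors plus how many variants each stage removed."""

    survivors: pd.DataFrame
    stage_counts: dict[str, int]
    n_input: int

    def __post_init__(self) -> None:
        if sum(self.stage_counts.values()) + len(self.survivors) != self.n_input:
            raise ValueError("stage counts and survivors do not add up to input size")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": s, "removed": c} for s, c in self.stage_counts.items()]
        rows.append({"stage": "survivors", "removed": len(self.survivors)})
        return pd.DataFrame(rows)


def _genotype(row: pd.Series, sample: str) -> int:
    gt = row[f"gt_{sample}"]
    if pd.isna(gt):
        return -1
    return int(gt)


def failing_stage(
    row: pd.Series,
    ped: Pedigree,
    af_threshold: float,
    missing_policy: str,
) -> str | None:
    """First cascade stage that removes this variant, or None if it survives."""
    for s in ped.affected_ids:
        gt = _genotype(row, s)
        if gt == -1:
            raise ValueError(f"missing genotype for affected individual {s}")
        if gt != 1:
            return "not_het_in_all_affected"

    def present(gt: int) -> bool:
        if gt == -1:
            return missing_policy == "strict"
        return gt != 0

    for s in ped.unaffected_ids:
        if f"gt_{s}" in row.index and present(_genotype(row, s)):
            return "present_in_unaffected_family"
    for s in ped.cohort_ids:
        if f"gt_{s}" in row.index and present(_genotype(row, s)):
            return "present_in_unrelated_cohort"
    if row["af"] > af_threshold:
        return "common_in_population"
    if row["consequence"] == "synonymous":
        return "synonymous"
    return None


def filter_candidates(
    variants: pd.DataFrame,
    ped: Pedigree,
    af_threshold: float = 0.01,
    missing_policy: str = "lenient",
) -> FilterReport:
    """Apply the five-stage segregation cascade to a variant table.

    ``variants`` needs columns ``chrom, pos, ref, alt, af, consequence``
    plus one ``gt_<sample>`` column per genotyped individual.  Unknown
    consequence strings pass the synonymous stage with a warning.
    """
    if missing_policy not in ("lenient", "strict"):
        raise ValueError("missing_policy must be 'lenient' or 'strict'")
    if not (0 <= af_threshold <= 1):
        raise ValueError("af_threshold must be a fraction in [0, 1]")
    if ((variants["af"] < 0) | (variants["af"] > 1)).any():
        raise ValueError("population allele frequencies must lie in [0, 1]")
    unknown = set(variants["consequence"]) - KNOWN_CONSEQUENCES
    if unknown:
        warnings.warn(f"unknown consequence strings pass through: {sorted(unknown)}")

    counts = {s: 0 for s in STAGES}
    keep = []
    for idx, row in variants.iterrows():
        stage = failing_stage(row, ped, af_threshold, missing_policy)
        if stage is None:
            keep.append(idx)
        else:
            counts[stage] += 1
    return FilterReport(
        survivors=variants.loc[keep].reset_index(drop=True),
        stage_counts=counts,
        n_input=len(variants),
    )
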