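"""File-format boundary: trajectories, variant tables, pedigrees, tables.

Trajectories travel as multi-MODEL PDB files with a sidecar TSV keyed by
atom serial carrying the nonbonded parameters (radius Å, charge e, LJ ε
kJ/mol, LJ σ nm) and the group tag.  Variant tables travel as minimal
VCF 4.2 (per-sample GT, AF and CSQ in INFO) plus a PED pedigree file.
Reading PDB goes through Biopython; reading VCF goes through pysam.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ATOM_COLUMNS, Trajectory
from .variant_filter import Pedigree

# ------------------------------------------------------------- trajectories

_PARAM_COLUMNS = ["serial", "group", "radius", "charge", "lj_epsilon", "lj_sigma"]


def write_trajectory(traj: Trajectory, pdb_path: str | Path, params_path: str | Path) -> None:
    """Write frames as MODEL/ENDMDL blocks plus the parameter sidecar."""
    pdb_path, params_path = Path(pdb_path), Path(params_path)
    a = traj.atoms
    with open(pdb_path, "w") as fh:
        for m, frame in enumerate(traj.coords, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i in range(traj.n_atoms):
                name = str(a["name"].iloc[i])
                pad = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    "ATOM  {serial:5d} {name:<4s}{res:>4s} A{resid:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                    "{elem:>2s}\n".format(
                        serial=int(a["serial"].iloc[i]),
                        name=pad,
                        res=str(a["resname"].iloc[i]),
                        resid=int(a["resid"].iloc[i]),
                        x=frame[i, 0], y=frame[i, 1], z=frame[i, 2],
                        occ=1.0, b=0.0,
                        elem=str(a["element"].iloc[i]),
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
    a[_PARAM_COLUMNS].to_csv(params_path, sep="\t", index=False)


def read_trajectory(pdb_path: str | Path, params_path: str | Path) -> Trajectory:
    """Read a multi-MODEL PDB plus its parameter sidecar back in."""
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # toy files trigger benign PDB warnings
        structure = PDBParser(QUIET=True).get_structure("traj", str(pdb_path))
    frames, meta = [], None
    for model in structure:
        coords, rows = [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    coords.append(atom.coord)
                    rows.append(
                        {
                            "serial": atom.serial_number,
                            "name": atom.get_name(),
                            "resid": residue.id[1],
                            "resname": residue.get_resname(),
                            "element": atom.element,
                        }
                    )
        frames.append(np.asarray(coords, dtype=float))
        if meta is None:
            meta = pd.DataFrame(rows)
    params = pd.read_csv(params_path, sep="\t")
    atoms = meta.merge(params, on="serial", validate="one_to_one")
    return Trajectory(atoms=atoms[ATOM_COLUMNS + ["element"]], coords=np.stack(frames))


# ------------------------------------------------------------ variants, PED

_GT_CODE_TO_VCF = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
_VCF_TO_GT_CODE = {v: k for k, v in _GT_CODE_TO_VCF.items()}


def write_vcf(variants: pd.DataFrame, path: str | Path) -> None:
    """Write the genotype matrix as a minimal uncompressed VCF 4.2."""
    samples = [c[3:] for c in variants.columns if c.startswith("gt_")]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(variants["chrom"].unique(), key=str):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        ordered = variants.sort_values(["chrom", "pos"], key=lambda s: s.astype(str))
        for _, row in ordered.iterrows():
            gts = "\t".join(_GT_CODE_TO_VCF[int(row[f"gt_{s}"])] for s in samples)
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t.\t.\t"
                f"AF={row['af']:.6g};CSQ={row['consequence']}\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF back into the genotype-matrix layout (via pysam)."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    records = []
    for rec in vf:
        row = {
            "chrom": rec.chrom,
            "pos": rec.pos,
            "ref": rec.ref,
            "alt": rec.alts[0] if rec.alts else ".",
            "af": float(np.atleast_1d(rec.info.get("AF", 0.0))[0]),
            "consequence": str(rec.info.get("CSQ", "missense")),
        }
        for s in samples:
            alleles = rec.samples[s]["GT"]
            if alleles is None or any(a is None for a in alleles):
                row[f"gt_{s}"] = -1
            else:
                row[f"gt_{s}"] = int(sum(alleles))
        records.append(row)
    return pd.DataFrame(records)


def write_ped(ped: Pedigree, path: str | Path, family_id: str = "FAM1") -> None:
    """Write the family as a six-column PED file (phenotype 2=affected)."""
    with open(path, "w") as fh:
        for _, r in ped.individuals.iterrows():
            sex = {"M": 1, "F": 2}.get(r["sex"], 0)
            pheno = 2 if r["affected"] else 1
            fh.write(
                f"{family_id}\t{r['id']}\t{r['father']}\t{r['mother']}\t{sex}\t{pheno}\n"
            )


def read_ped(path: str | Path, cohort_ids: list[str] | None = None) -> Pedigree:
    """Parse a six-column PED file."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            _, iid, father, mother, sex, pheno = line.split()[:6]
            rows.append(
                {
                    "id": iid,
                    "sex": {"1": "M", "2": "F"}.get(sex, "U"),
                    "affected": pheno == "2",
                    "father": father,
                    "mother": mother,
                }
            )
    return Pedigree(individuals=pd.DataFrame(rows), cohort_ids=cohort_ids or [])
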