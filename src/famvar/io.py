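"""File formats, run configuration and manifests.

Pedigrees use LINKAGE-style whitespace/tab columns ``FID IID FATHER MOTHER
SEX`` (1 = male, 2 = female) with optional ``HOUSEHOLD`` and ``PROBAND``
columns; ``0`` or ``NA`` mark a missing parent or household.  Phenotype and
covariate tables are plain CSV/TSV with a header and an ``id`` column.
Genotype matrices are TSV with SNPs as rows and individuals as columns
(values 0/1/2 or dosages), plus optional ``info`` and position columns.

Every CLI output directory receives a JSON manifest recording the seed, the
configuration and its hash, and package versions, so runs are reproducible
and attributable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from famvar.pedigree import KinshipMatrix, Pedigree, PedigreeError, build_pedigree

__all__ = [
    "read_pedigree_file",
    "write_pedigree_file",
    "read_table",
    "write_table",
    "read_genotype_file",
    "write_genotype_file",
    "write_kinship",
    "RunConfig",
    "write_manifest",
]

_PED_COLS = ["FID", "IID", "FATHER", "MOTHER", "SEX", "HOUSEHOLD", "PROBAND"]


def read_pedigree_file(path) -> Pedigree:
    """Read and validate a LINKAGE-style pedigree file.

    A header line is optional (detected by a first field of ``FID``).
    Malformed rows raise :class:`PedigreeError` naming the line number.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines and lines[0].split()[:1] == ["FID"]:
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise PedigreeError(
                f"{path.name}:{lineno}: expected at least 5 columns "
                f"(FID IID FATHER MOTHER SEX), got {len(parts)}"
            )
        if parts[4].lower() not in ("1", "2", "m", "f", "male", "female"):
            raise PedigreeError(
                f"{path.name}:{lineno}: unknown sex code {parts[4]!r}"
            )
        rec = {
            "family_id": parts[0],
            "id": parts[1],
            "father_id": parts[2],
            "mother_id": parts[3],
            "sex": parts[4],
        }
        if len(parts) > 5:
            rec["household_id"] = parts[5]
        if len(parts) > 6:
            rec["proband"] = parts[6]
        rows.append(rec)
    try:
        return build_pedigree(rows)
    except PedigreeError as e:
        raise PedigreeError(f"{path.name}: {e}") from None


def write_pedigree_file(ped: Pedigree, path) -> None:
    sex_code = {"male": "1", "female": "2"}
    with open(path, "w") as fh:
        fh.write("\t".join(_PED_COLS) + "\n")
        for ind in ped.individuals:
            fh.write(
                "\t".join(
                    [
                        ind.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        sex_code[ind.sex],
                        ind.household_id or "NA",
                        "1" if ind.proband else "0",
                    ]
                )
                + "\n"
            )


def read_table(path, index_col: Optional[str] = "id") -> pd.DataFrame:
    """CSV/TSV table with a header; separator chosen by extension."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if index_col and index_col in df.columns:
        df = df.set_index(index_col)
        df.index = df.index.astype(str)
    return df


def write_table(df: pd.DataFrame, path, index: bool = True,
                index_label: str = "id") -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=index,
              index_label=index_label if index else None, float_format="%.10g")


def read_genotype_file(path) -> tuple[pd.DataFrame, Optional[pd.Series]]:
    """Genotype TSV (rows = SNPs, columns = individuals) -> (ind x snp, info).

    A column named ``info`` (imputation quality) is split off when present.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    info = None
    if "info" in df.columns:
        info = df.pop("info").astype(float)
    geno = df.T
    geno.index = geno.index.astype(str)
    return geno.astype(float), info


def write_genotype_file(geno: pd.DataFrame, path,
                        info: Optional[pd.Series] = None) -> None:
    out = geno.T.copy()
    if info is not None:
        out.insert(0, "info", info.reindex(out.index))
    out.to_csv(path, sep="\t", index_label="snp", float_format="%.10g")


def write_kinship(kin: KinshipMatrix, path) -> None:
    """Nonzero 2*Phi entries in long format (id1, id2, 2phi)."""
    kin.to_long_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class RunConfig:
    """Configuration of a CLI run, hashed into the output manifest."""

    command: str
    inputs: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(out_dir, config: RunConfig, extra: Optional[dict] = None) -> Path:
    import famvar

    manifest = {
        "command": config.command,
        "seed": config.seed,
        "inputs": config.inputs,
        "options": config.options,
        "config_hash": config.config_hash(),
        "famvar_version": famvar.__version__,
        "numpy_version": np.__version__,
    }
    if extra:
        manifest.update(extra)
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return path
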