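"""TSV/PED readers and writers for the pipeline's file dialects.

All tables are UTF-8, tab-separated, with a header row and ``#`` comment
lines.  TSV rather than CSV avoids decimal-comma ambiguity, and fraction
columns carry explicit allele names (f_GT, f_A, f_GTGT, f_G) so the assay
orientation is fixed by the header, not by convention.

Dialects:

* sample sheet — ``sample_id  [population]  f_GT  f_A`` (fractions), or the
  peak variant ``sample_id  h_GT  h_GTGT  h_A  h_G`` (raw heights);
* trios — ``sample_id  b  n  c``;
* PED — the usual 6 columns ``family  id  father  mother  sex  phenotype``
  with ``0`` for an absent parent;
* qPCR — ``sample_id  condition  gene  ct  replicate``;
* standards — ``gene  quantity  ct``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import DomainError, InputError
from .psv_model import (
    AlleleFractionProfile,
    CopyNumberTrio,
    PeakPair,
    PsvAssay,
    EXON2_INDEL,
    EXON9_SNV,
    peaks_to_fractions,
)
from .pedigree import Individual, Pedigree

__all__ = [
    "read_tsv",
    "write_tsv",
    "read_sample_sheet",
    "read_peak_table",
    "read_trios",
    "read_ped",
    "write_ped",
    "read_qpcr",
    "read_standards",
]


def read_tsv(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def _check_unique_samples(df: pd.DataFrame, path: str | Path) -> None:
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise InputError(f"{path}: duplicate sample id(s) {sorted(set(dup))}")


def read_sample_sheet(path: str | Path) -> list[AlleleFractionProfile]:
    """Fraction-dialect sample sheet -> validated profiles (row-addressed errors)."""
    df = read_tsv(path, required=("sample_id", "f_GT", "f_A"))
    _check_unique_samples(df, path)
    profiles = []
    for i, row in df.iterrows():
        try:
            profiles.append(
                AlleleFractionProfile(
                    f_gt=float(row["f_GT"]), f_a=float(row["f_A"]),
                    sample_id=str(row["sample_id"]),
                )
            )
        except (InputError, ValueError) as exc:
            raise InputError(f"{path} row {i + 2}: {exc}") from exc
    return profiles


def read_peak_table(
    path: str | Path,
    assay_exon2: PsvAssay = EXON2_INDEL,
    assay_exon9: PsvAssay = EXON9_SNV,
) -> list[AlleleFractionProfile]:
    """Peak-height dialect sample sheet -> fraction profiles via calibration."""
    df = read_tsv(path, required=("sample_id", "h_GT", "h_GTGT", "h_A", "h_G"))
    _check_unique_samples(df, path)
    profiles = []
    for i, row in df.iterrows():
        try:
            profiles.append(
                peaks_to_fractions(
                    PeakPair(float(row["h_GT"]), float(row["h_GTGT"])),
                    PeakPair(float(row["h_A"]), float(row["h_G"])),
                    assay_exon2, assay_exon9,
                    sample_id=str(row["sample_id"]),
                )
            )
        except (InputError, ValueError) as exc:
            raise InputError(f"{path} row {i + 2}: {exc}") from exc
    return profiles


def read_trios(path: str | Path) -> dict[str, CopyNumberTrio]:
    df = read_tsv(path, required=("sample_id", "b", "n", "c"))
    _check_unique_samples(df, path)
    out: dict[str, CopyNumberTrio] = {}
    for i, row in df.iterrows():
        try:
            out[str(row["sample_id"])] = CopyNumberTrio(
                int(row["b"]), int(row["n"]), int(row["c"])
            )
        except (InputError, ValueError, DomainError) as exc:
            raise InputError(f"{path} row {i + 2}: {exc}") from exc
    return out


def read_ped(path: str | Path) -> Pedigree:
    """6-column whitespace-separated PED file -> Pedigree (``0`` = no parent)."""
    inds: list[Individual] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise InputError(f"{path} line {lineno}: expected 6 PED columns, got {len(parts)}")
            fam, iid, fa, mo, sex, _pheno = parts[:6]
            inds.append(
                Individual(
                    iid=iid,
                    father=None if fa == "0" else fa,
                    mother=None if mo == "0" else mo,
                    sex=sex,
                    family=fam,
                )
            )
    return Pedigree(inds)


def write_ped(ped: Pedigree, path: str | Path, phenotype: str = "0") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for iid in ped.order:
            ind = ped.members[iid]
            fh.write(
                f"{ind.family}\t{ind.iid}\t{ind.father or 0}\t{ind.mother or 0}"
                f"\t{ind.sex}\t{phenotype}\n"
            )


def read_qpcr(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, required=("sample_id", "condition", "gene", "ct", "replicate"))
    bad = df.index[~df["ct"].map(lambda v: math.isfinite(v) and v > 0)]
    if len(bad):
        raise InputError(f"{path} row {bad[0] + 2}: Ct must be finite and positive")
    return df


def read_standards(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, required=("gene", "quantity", "ct"))
    bad = df.index[df["quantity"] <= 0]
    if len(bad):
        raise InputError(f"{path} row {bad[0] + 2}: standard quantity must be > 0")
    return df
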