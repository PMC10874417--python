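"""PLINK-1 binary trio and TSV readers/writers.

The .bed codec implements the SNP-major PLINK-1 layout: a 3-byte header
(``0x6C 0x1B`` magic, mode ``0x01``), then ``ceil(m/4)`` bytes per SNP with
two bits per sample, least-significant pair first::

    00  homozygous allele1  -> count 2
    01  missing             -> MISSING
    10  heterozygous        -> count 1
    11  homozygous allele2  -> count 0

Genotypes therefore count copies of the .bim A1 allele; no re-polarisation
by frequency happens at read time, so write -> read is bit-exact.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    AlignmentError,
    CovariateMatrix,
    FormatError,
    GenotypeDataset,
    PhenotypeVector,
    SampleInfo,
    SNPInfo,
    TruncatedFileError,
    UnsupportedOrientationError,
)

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

# 2-bit code -> allele1 count; index by code value.
_DECODE_LUT = np.array([2, MISSING, 1, 0], dtype=np.int8)
# allele1 count (+1 so MISSING maps to slot 0) -> 2-bit code.
_ENCODE_LUT = np.array([0b01, 0b11, 0b10, 0b00], dtype=np.uint8)

_CHROM_ALIASES = {"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26}
_SEX_FROM_FAM = {1: "male", 2: "female"}
_SEX_TO_FAM = {"male": 1, "female": 2, "unknown": 0}


def _parse_chrom(token: str) -> int:
    token = token.strip().upper()
    if token in _CHROM_ALIASES:
        return _CHROM_ALIASES[token]
    return int(token)


def read_plink_binary(bed_path, bim_path=None, fam_path=None) -> GenotypeDataset:
    """Read a PLINK-1 .bed/.bim/.fam trio into a :class:`GenotypeDataset`.

    ``bed_path`` may be a prefix (``.bim``/``.fam`` are inferred) or the
    ``.bed`` file itself with the companions given explicitly.
    """
    bed_path = Path(bed_path)
    if bed_path.suffix != ".bed" and bim_path is None:
        prefix = bed_path
        bed_path = prefix.with_suffix(".bed") if prefix.suffix == "" else Path(str(prefix) + ".bed")
    if bim_path is None:
        bim_path = bed_path.with_suffix(".bim")
    if fam_path is None:
        fam_path = bed_path.with_suffix(".fam")

    snps = _read_bim(bim_path)
    samples = _read_fam(fam_path)
    m, n = len(samples), len(snps)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise FormatError(f"{bed_path}: missing PLINK .bed magic bytes 0x6C 0x1B")
    mode = int(raw[2])
    if mode == 0x00:
        raise UnsupportedOrientationError(
            f"{bed_path}: individual-major .bed (mode 0x00) is not supported"
        )
    if mode != _BED_SNP_MAJOR:
        raise FormatError(f"{bed_path}: unknown mode byte 0x{mode:02X}")

    bytes_per_snp = (m + 3) // 4
    expected = 3 + bytes_per_snp * n
    if raw.size != expected:
        raise TruncatedFileError(
            f"{bed_path}: {raw.size} bytes, expected {expected} for "
            f"{m} samples x {n} SNPs"
        )

    body = raw[3:].reshape(n, bytes_per_snp)
    codes = np.empty((n, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    genotypes = _DECODE_LUT[codes[:, :m]].T  # -> (m, n)
    return GenotypeDataset(np.ascontiguousarray(genotypes), snps, samples)


def write_plink_binary(dataset: GenotypeDataset, prefix) -> tuple[Path, Path, Path]:
    """Write ``dataset`` as a SNP-major PLINK-1 trio; returns the three paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path = Path(str(prefix) + ".bed")
    bim_path = Path(str(prefix) + ".bim")
    fam_path = Path(str(prefix) + ".fam")

    m, n = dataset.n_samples, dataset.n_snps
    bytes_per_snp = (m + 3) // 4
    codes = _ENCODE_LUT[dataset.genotypes.T.astype(np.int16) + 1]  # (n, m)
    padded = np.zeros((n, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :m] = codes
    body = np.zeros((n, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        body |= padded[:, k::4] << (2 * k)

    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
        body.tofile(fh)

    with open(bim_path, "w") as fh:
        for s in dataset.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos_bp}\t{s.allele1}\t{s.allele2}\n")

    with open(fam_path, "w") as fh:
        for s in dataset.samples:
            fh.write(f"{s.sample_id}\t{s.sample_id}\t0\t0\t{_SEX_TO_FAM[s.sex]}\t-9\n")

    return bed_path, bim_path, fam_path


def _read_bim(path) -> list[SNPInfo]:
    snps: list[SNPInfo] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6:
                raise FormatError(f"{path}: expected 6 .bim columns, got {len(fields)}")
            chrom, snp_id, _cm, pos, a1, a2 = fields
            snps.append(SNPInfo(snp_id, _parse_chrom(chrom), int(pos), a1, a2))
    return snps


def _read_fam(path) -> list[SampleInfo]:
    samples: list[SampleInfo] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6:
                raise FormatError(f"{path}: expected 6 .fam columns, got {len(fields)}")
            _fid, iid, _pid, _mid, sex, _pheno = fields
            samples.append(
                SampleInfo(iid, sex=_SEX_FROM_FAM.get(int(float(sex)), "unknown"))
            )
    return samples


# ---------------------------------------------------------------------------
# Phenotype / covariate tables
# ---------------------------------------------------------------------------

def read_trait_table(
    path, dataset: GenotypeDataset, id_column: str = "sample_id", value_column: str = "trait"
) -> PhenotypeVector:
    """Read a TSV trait table and align it to ``dataset`` sample order.

    The join is keyed on sample ID, so any row order in the file yields the
    same vector.  Samples absent from the table are marked missing.
    """
    table = pd.read_csv(path, sep="\t", dtype={id_column: str})
    return align_trait_table(table, dataset, id_column, value_column)


def align_trait_table(
    table: pd.DataFrame,
    dataset: GenotypeDataset,
    id_column: str = "sample_id",
    value_column: str = "trait",
) -> PhenotypeVector:
    for col in (id_column, value_column):
        if col not in table.columns:
            raise FormatError(f"trait table lacks column {col!r}")
    mapping: dict[str, float] = {}
    for sid, raw in zip(table[id_column].astype(str), table[value_column]):
        try:
            mapping[sid] = float(raw)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric trait value {raw!r} for sample {sid}") from exc
    ids = dataset.sample_ids
    if not set(ids) & set(mapping):
        raise AlignmentError("no overlapping sample IDs between trait table and dataset")
    values = np.array([mapping.get(s, np.nan) for s in ids], dtype=np.float64)
    return PhenotypeVector.from_values(values)


def encode_covariates(
    table: pd.DataFrame,
    dataset: GenotypeDataset,
    diag_reference: str = "NC",
    id_column: str = "sample_id",
) -> CovariateMatrix:
    """Build the age / sex / diagnosis design matrix aligned to ``dataset``.

    Diagnosis is expanded to k-1 dummy indicators against ``diag_reference``;
    sex is coded 1 = male, 0 = female.  Samples absent from the table, or
    with unparseable fields, get NaN rows (covariate-missing).  A column that
    is constant over the complete rows sets ``rank_warning``.
    """
    required = {id_column, "age", "sex", "diagnosis"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise FormatError(f"covariate table lacks columns {sorted(missing_cols)}")

    levels = [lvl for lvl in ("NC", "MCI", "AD") if lvl != diag_reference]
    if diag_reference not in ("NC", "MCI", "AD"):
        raise ValueError(f"unknown diagnosis reference {diag_reference!r}")

    rows: dict[str, np.ndarray] = {}
    for _, rec in table.iterrows():
        sid = str(rec[id_column])
        row = np.full(2 + len(levels), np.nan)
        try:
            row[0] = float(rec["age"])
        except (TypeError, ValueError):
            pass
        sex = str(rec["sex"]).strip().lower()
        if sex in ("male", "m", "1"):
            row[1] = 1.0
        elif sex in ("female", "f", "2", "0"):
            row[1] = 0.0
        dx = str(rec["diagnosis"]).strip()
        if dx in ("NC", "MCI", "AD"):
            for j, lvl in enumerate(levels):
                row[2 + j] = 1.0 if dx == lvl else 0.0
        elif dx not in ("", "missing", "nan", "NaN"):
            raise ValueError(f"unknown diagnosis level {dx!r} for sample {sid}")
        rows[sid] = row

    ids = dataset.sample_ids
    values = np.vstack(
        [rows.get(s, np.full(2 + len(levels), np.nan)) for s in ids]
    )
    names = ["age", "sex"] + [f"dx_{lvl}" for lvl in levels]

    complete = np.all(np.isfinite(values), axis=1)
    rank_warning = False
    if complete.sum() >= 2:
        sub = values[complete]
        rank_warning = bool(np.any(np.ptp(sub, axis=0) == 0))
    return CovariateMatrix(values=values, names=names, rank_warning=rank_warning)


def write_covariate_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Results table
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "snp1", "snp2", "chrom1", "chrom2", "gene1", "gene2",
    "beta_int", "F", "df2", "p", "n_used",
    "r2_cov", "dr2_add", "dr2_int",
]


def write_results_table(
    results: Iterable,
    path,
    dataset: GenotypeDataset | None = None,
    partitions: Mapping[tuple[int, int], object] | None = None,
    gene_map: Mapping[int, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Write interaction results as a TSV with a stable column order.

    Rows are sorted by ascending p (invalid/NaN last), ties broken by the
    SNP index pair.  Numeric fields are rendered with 12 significant digits
    so a parse-back round trip is lossless at that precision.  The frame
    actually written is returned for convenience.
    """
    records = []
    for res in results:
        i, j = res.snp1_index, res.snp2_index
        rec = {
            "snp1": dataset.snps[i].snp_id if dataset else str(i),
            "snp2": dataset.snps[j].snp_id if dataset else str(j),
            "chrom1": dataset.snps[i].chrom if dataset else np.nan,
            "chrom2": dataset.snps[j].chrom if dataset else np.nan,
            "gene1": ";".join(gene_map.get(i, [])) if gene_map else "",
            "gene2": ";".join(gene_map.get(j, [])) if gene_map else "",
            "beta_int": res.beta_int,
            "F": res.F,
            "df2": res.df2,
            "p": res.p,
            "n_used": res.n_used,
            "r2_cov": np.nan,
            "dr2_add": np.nan,
            "dr2_int": np.nan,
            "_i": i,
            "_j": j,
        }
        if partitions and (i, j) in partitions:
            part = partitions[(i, j)]
            rec["r2_cov"] = part.r2_cov
            rec["dr2_add"] = part.dr2_add
            rec["dr2_int"] = part.dr2_int
        records.append(rec)

    frame = pd.DataFrame.from_records(records, columns=RESULT_COLUMNS + ["_i", "_j"])
    if len(frame):
        frame = frame.sort_values(
            by=["p", "_i", "_j"], ascending=True, na_position="last", kind="mergesort"
        )
    frame = frame.drop(columns=["_i", "_j"]).reset_index(drop=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return frame


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
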