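"""Readers and writers for the package's file dialects.

Read counts travel as long-format TSV (sample, marker, major_reads,
minor_reads) or VCF with AD fields; coded genotype matrices as wide TSV
(samples x markers, NA for missing) or VCF with GT; phenotypes as long
CSV (progeny, condition, replicate, trait, value); run settings as TOML
manifests.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import MISSING, DiploidCodedMatrix, ReadCountMatrix


# ---------------------------------------------------------------- read counts

def write_read_counts_tsv(rc: ReadCountMatrix, path) -> None:
    n, p = rc.major.shape
    df = pd.DataFrame(
        {
            "sample": np.repeat(rc.sample_ids, p),
            "marker": np.tile(rc.marker_ids, n),
            "major_reads": rc.major.ravel(),
            "minor_reads": rc.minor.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_read_counts_tsv(path) -> ReadCountMatrix:
    df = pd.read_csv(path, sep="\t")
    wide_major = df.pivot(index="sample", columns="marker", values="major_reads")
    wide_minor = df.pivot(index="sample", columns="marker", values="minor_reads")
    # preserve first-appearance order of ids
    samples = list(dict.fromkeys(df["sample"]))
    markers = list(dict.fromkeys(df["marker"]))
    wide_major = wide_major.loc[samples, markers]
    wide_minor = wide_minor.loc[samples, markers]
    return ReadCountMatrix(
        wide_major.to_numpy(dtype=np.int64),
        wide_minor.to_numpy(dtype=np.int64),
        [str(s) for s in samples],
        [str(m) for m in markers],
    )


# ------------------------------------------------------------- coded matrices

def write_codes_tsv(m: DiploidCodedMatrix, path) -> None:
    frame = pd.DataFrame(m.codes, index=m.sample_ids, columns=m.marker_ids)
    frame = frame.astype("Int64").where(frame != MISSING)
    frame.to_csv(path, sep="\t", index_label="sample", na_rep="NA")


def read_codes_tsv(path) -> DiploidCodedMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="sample")
    codes = frame.to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    return DiploidCodedMatrix(
        codes, [str(s) for s in frame.index], [str(c) for c in frame.columns]
    )


# ------------------------------------------------------------------------ VCF

_GT_BY_CODE = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}
_CODE_BY_GT = {(0, 0): 2, (0, 1): 1, (1, 0): 1, (1, 1): 0}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=tetrags
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (major, minor tag allele)">
"""


def write_vcf(
    m: DiploidCodedMatrix,
    path,
    read_counts: ReadCountMatrix | None = None,
    positions: pd.DataFrame | None = None,
) -> None:
    """Write genotypes (and optionally AD read counts) as uncompressed VCF.

    The major tag allele is REF.  Markers without coordinates get
    sequential positions on chromosome '1'.
    """
    pos_map = {}
    if positions is not None:
        pos_map = {
            r["marker"]: (r["chromosome"], int(r["position"]))
            for _, r in positions.iterrows()
        }
    fmt = "GT:AD" if read_counts is not None else "GT"
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.sample_ids)
            + "\n"
        )
        for j, mid in enumerate(m.marker_ids):
            chrom, pos = pos_map.get(mid, ("1", j + 1))
            cells = []
            for i in range(m.n_samples):
                gt = _GT_BY_CODE[int(m.codes[i, j])]
                if read_counts is not None:
                    cells.append(f"{gt}:{read_counts.major[i, j]},{read_counts.minor[i, j]}")
                else:
                    cells.append(gt)
            fh.write(
                f"{chrom}\t{pos}\t{mid}\tA\tC\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path, with_read_counts: bool = False):
    """Read a VCF into a coded matrix (and read counts when AD present)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    codes_rows, major_rows, minor_rows, marker_ids = [], [], [], []
    for variant in vcf:
        marker_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                row[i] = _CODE_BY_GT[(a, b)]
        codes_rows.append(row)
        if with_read_counts:
            ad = variant.format("AD")
            major_rows.append(ad[:, 0].astype(np.int64))
            minor_rows.append(ad[:, 1].astype(np.int64))
    codes = np.array(codes_rows, dtype=np.int8).T if codes_rows else np.zeros((len(samples), 0), np.int8)
    m = DiploidCodedMatrix(codes, samples, marker_ids)
    if not with_read_counts:
        return m
    rc = ReadCountMatrix(
        np.array(major_rows).T if major_rows else np.zeros((len(samples), 0), np.int64),
        np.array(minor_rows).T if minor_rows else np.zeros((len(samples), 0), np.int64),
        samples,
        marker_ids,
    )
    return m, rc


# ------------------------------------------------------------ phenotypes etc.

def write_phenotypes_csv(p: pd.DataFrame, path) -> None:
    p.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth_csv(truth, path) -> None:
    pd.DataFrame(
        {"marker_index": np.arange(len(truth.beta)), "beta": truth.beta}
    ).to_csv(path, index=False)


# ----------------------------------------------------------------------- TOML

def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_toml(data: dict, path) -> None:
    """Write a (possibly nested, one level) dict as TOML."""
    lines: list[str] = []
    tables = {k: v for k, v in data.items() if isinstance(v, dict)}
    for k, v in data.items():
        if not isinstance(v, dict) and v is not None:
            lines.append(f"{k} = {_toml_value(v)}")
    for name, table in tables.items():
        lines.append(f"\n[{name}]")
        for k, v in table.items():
            if v is not None:
                lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_toml(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)
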