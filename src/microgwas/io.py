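"""Readers and writers for the plain-text formats the pipeline exchanges.

Genotypes travel either as VCF v4.2 (GT field only; read via cyvcf2) or as a
simple TSV dialect (rows = SNPs with id/chrom/pos/ref/alt metadata columns,
one column per individual, values 0/1/2/NA).  Abundance, covariate, trait,
distance-matrix, F_ST and association tables are TSV; gene annotations are
BED (0-based half-open); ground truth is JSON.  Writers prepend ``#``
provenance comment lines (tool version, seed, config hash when known) which
every reader here skips.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import MISSING, DistanceMatrix, GenotypeMatrix

__all__ = [
    "read_genotype_tsv", "write_genotype_tsv",
    "read_vcf", "write_vcf",
    "read_table", "write_table",
    "read_distance_matrix", "write_distance_matrix",
    "read_bed", "write_bed",
    "write_json", "read_json",
]

_META_COLS = ["id", "chrom", "pos", "ref", "alt"]


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


# ---------------------------------------------------------------------------
# generic TSV


def write_table(df: pd.DataFrame, path, provenance: dict | None = None,
                index: bool = False):
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# genotype TSV dialect


def write_genotype_tsv(matrix: GenotypeMatrix, path, provenance: dict | None = None):
    """Rows = SNPs: id, chrom, pos, ref, alt, then one 0/1/2/NA column per
    individual."""
    g = matrix.values.T.astype(object)
    g[g == MISSING] = "NA"
    df = pd.concat(
        [matrix.snp_meta[_META_COLS].reset_index(drop=True),
         pd.DataFrame(g, columns=list(matrix.individual_ids))],
        axis=1,
    )
    write_table(df, path, provenance)


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    individuals = [c for c in df.columns if c not in _META_COLS]
    g = df[individuals].to_numpy(dtype=object)
    vals = np.where(pd.isna(g) | (g == "NA"), MISSING, g).astype(np.int8).T
    return GenotypeMatrix(vals, df[_META_COLS].copy(), individuals)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(matrix: GenotypeMatrix, path, provenance: dict | None = None):
    """Minimal VCF v4.2 with GT-only genotype records."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if provenance:
            for k, v in provenance.items():
                fh.write(f"##{k}={v}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.individual_ids) + "\n")
        for j, row in matrix.snp_meta.iterrows():
            gts = "\t".join(code[int(v)] for v in matrix.values[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    meta_rows, cols = [], []
    for i, var in enumerate(vcf):
        alt = var.ALT[0] if var.ALT else "."
        vid = var.ID if var.ID else f"{var.CHROM}:{var.POS}"
        meta_rows.append((vid, str(var.CHROM), int(var.POS), var.REF, alt))
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt (cyvcf2 coding)
        gt = np.asarray(var.gt_types)
        col = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        cols.append(col.astype(np.int8))
    vcf.close()
    meta = pd.DataFrame(meta_rows, columns=_META_COLS)
    values = (
        np.column_stack(cols) if cols
        else np.zeros((len(individuals), 0), dtype=np.int8)
    )
    return GenotypeMatrix(values, meta, individuals)


# ---------------------------------------------------------------------------
# distance matrices


def write_distance_matrix(dm: DistanceMatrix, path, provenance: dict | None = None):
    prov = dict(provenance or {})
    prov["kind"] = dm.kind
    write_table(dm.to_frame(), path, prov, index=True)


def read_distance_matrix(path, kind: str | None = None) -> DistanceMatrix:
    if kind is None:
        kind = "distance"
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if line.startswith("# kind:"):
                    kind = line.split(":", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float), kind)


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> pd.DataFrame:
    """BED3+ -> DataFrame(chrom, start, end, name); 0-based half-open kept."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
        dtype={"chrom": str},
    )
    return df


def write_bed(df: pd.DataFrame, path, provenance: dict | None = None):
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        df[["chrom", "start", "end", "name"]].to_csv(
            fh, sep="\t", header=False, index=False
        )


# ---------------------------------------------------------------------------
# JSON


def write_json(obj, path, provenance: dict | None = None):
    payload = {"provenance": provenance or {}, **({"data": obj})}
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def read_json(path):
    return json.loads(Path(path).read_text())["data"]


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, set):
        return sorted(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")
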