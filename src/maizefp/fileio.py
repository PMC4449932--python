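"""Readers and writers for the package's text formats.

Everything is UTF-8, tab-delimited with a mandatory header row. "NC" is
the single missing-genotype token. Cluster files serialize to a
versioned JSON schema; a minimal VCF 4.2 export is provided for
interchange with standard variant tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import GENOTYPE_CODES, GENOTYPES
from .signalmodel import ClusterFile, ClusterRegion, LocusClusters

__all__ = [
    "read_genotype_matrix", "write_genotype_matrix",
    "read_locus_map", "write_locus_map",
    "read_sample_meta", "write_sample_meta",
    "read_intensities", "write_intensities",
    "read_cluster_file", "write_cluster_file",
    "write_panel_list", "read_panel_list",
    "write_panel_vcf",
]

CLUSTER_FILE_SCHEMA_VERSION = 1

_VCF_GT = {"AA": "0/0", "AB": "0/1", "BB": "1/1", "NC": "./."}


def read_genotype_matrix(path) -> pd.DataFrame:
    """Load a samples x loci call table (first column ``sample_id``).

    Cells must be one of AA/AB/BB/NC; a malformed cell is reported with
    its sample and locus coordinates. Duplicate sample or locus ids are
    rejected.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id', got {header[:1]!r}")
    loci = header[1:]
    if len(set(loci)) != len(loci):  # pandas would silently mangle these
        raise ValueError(f"{path}: duplicate locus ids in header")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df["sample_id"].duplicated().any():
        dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes[:5]}")
    matrix = df.set_index("sample_id")
    arr = matrix.to_numpy()
    bad = ~np.isin(arr, list(GENOTYPE_CODES))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{path}: invalid genotype {arr[i, j]!r} at sample "
            f"{matrix.index[i]!r}, locus {matrix.columns[j]!r}"
        )
    matrix.index.name = None
    return matrix


def write_genotype_matrix(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_locus_map(path) -> pd.DataFrame:
    """Locus map TSV -> DataFrame indexed by locus_id."""
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "chromosome": int,
                                            "position": int})
    required = {"locus_id", "chromosome", "position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: locus map missing columns {sorted(missing)}")
    if df["locus_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate locus ids")
    return df.set_index("locus_id", drop=False)


def write_locus_map(locus_map: pd.DataFrame, path) -> None:
    locus_map.to_csv(path, sep="\t", index=False)


def read_sample_meta(path) -> pd.DataFrame:
    """Sample metadata TSV -> DataFrame indexed by sample_id (missing
    link fields normalized to empty strings)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns or "role" not in df.columns:
        raise ValueError(f"{path}: sample metadata needs sample_id and role columns")
    if "purity" in df.columns:
        df["purity"] = df["purity"].astype(float)
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df.set_index("sample_id", drop=False)


def write_sample_meta(sample_meta: pd.DataFrame, path) -> None:
    sample_meta.to_csv(path, sep="\t", index=False)


def read_intensities(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str,
                                            "x": float, "y": float})
    required = {"sample_id", "locus_id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: intensity table missing columns {sorted(missing)}")
    return df


def write_intensities(intensities: pd.DataFrame, path) -> None:
    intensities.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_cluster_file(cluster_file: ClusterFile, path) -> None:
    """Serialize a cluster file to versioned JSON."""
    doc = {
        "schema_version": CLUSTER_FILE_SCHEMA_VERSION,
        "provenance": cluster_file.provenance,
        "loci": {
            lid: {
                "r_floor": lc.r_floor,
                "weak": lc.weak,
                "regions": [
                    {
                        "genotype": reg.genotype,
                        "theta_center": reg.theta_center,
                        "theta_halfwidth": reg.theta_halfwidth,
                        "r_floor": reg.r_floor,
                        "occupied": reg.occupied,
                    }
                    for reg in lc.regions
                ],
            }
            for lid, lc in cluster_file.loci.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8")


def read_cluster_file(path) -> ClusterFile:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    version = doc.get("schema_version")
    if version != CLUSTER_FILE_SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported cluster-file schema version {version!r}")
    loci = {}
    for lid, entry in doc["loci"].items():
        regions = tuple(
            ClusterRegion(
                genotype=reg["genotype"],
                theta_center=reg["theta_center"],
                theta_halfwidth=reg["theta_halfwidth"],
                r_floor=reg["r_floor"],
                occupied=reg["occupied"],
            )
            for reg in entry["regions"]
        )
        loci[lid] = LocusClusters(lid, regions, entry["r_floor"], weak=entry["weak"])
    return ClusterFile(loci=loci, provenance=doc.get("provenance", {}))


def write_panel_list(panel: list[str], path) -> None:
    Path(path).write_text("".join(f"{lid}\n" for lid in panel), encoding="utf-8")


def read_panel_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text(encoding="utf-8").splitlines()
            if line.strip()]


def write_panel_vcf(panel: list[str], locus_map: pd.DataFrame, matrix: pd.DataFrame,
                    path) -> None:
    """Minimal VCF 4.2 export of a panel's calls.

    Alleles are the abstract array alleles (REF=A, ALT=B); genotypes map
    AA/AB/BB/NC -> 0/0, 0/1, 1/1, ./. . Records are sorted by chromosome
    then position.
    """
    unmapped = [l for l in panel if l not in locus_map.index]
    if unmapped:
        raise KeyError(f"unmapped panel loci: {unmapped[:10]}")
    sub = locus_map.loc[panel].sort_values(["chromosome", "position"])
    samples = list(matrix.index)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in sorted(sub["chromosome"].unique()):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for lid, row in sub.iterrows():
        calls = matrix[lid] if lid in matrix.columns else pd.Series("NC", index=samples)
        gts = "\t".join(_VCF_GT[calls[s]] for s in samples)
        lines.append(f"{row['chromosome']}\t{row['position']}\t{lid}\tA\tB\t.\t.\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
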