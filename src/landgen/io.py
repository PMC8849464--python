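"""File I/O: VCF and CSV genotypes, metadata tables, ESRI ASCII rasters,
labelled distance matrices, JSON summaries.

All on-disk formats are plain text. Rasters use the ESRI ASCII grid format
(``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`` header followed by
rows top-to-bottom). VCF output is a minimal GT-only biallelic file; VCF input
goes through cyvcf2 when available, with a plain-text fallback parser.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    ConfigurationError,
    DistanceMatrix,
    GenotypeMatrix,
    RasterSurface,
)

# ---------------------------------------------------------------- rasters


def write_ascii_grid(raster: RasterSurface, path: str | Path, nodata: float = -9999.0) -> None:
    nrows, ncols = raster.shape
    vals = np.where(raster.nodata_mask, nodata, raster.values)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {nodata}\n"
    )
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in vals)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path, kind: str = "continuous") -> RasterSurface:
    lines = Path(path).read_text().splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            hdr[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for req in ("ncols", "nrows", "cellsize"):
        if req not in hdr:
            raise ConfigurationError(f"ASCII grid missing header field {req}")
    data = np.loadtxt(lines[i:], dtype=float)
    data = data.reshape(int(hdr["nrows"]), int(hdr["ncols"]))
    nodata = hdr.get("nodata_value")
    mask = (data == nodata) if nodata is not None else None
    return RasterSurface(
        data,
        cell_size=hdr["cellsize"],
        origin=(hdr.get("xllcorner", 0.0), hdr.get("yllcorner", 0.0)),
        nodata_mask=mask,
        kind=kind,
    )


# ---------------------------------------------------------------- genotypes


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Minimal biallelic VCF with GT-only genotype fields; missing = ``./.``."""
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=landgen\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, locus in enumerate(gm.locus_ids):
            gts = "\t".join(gt_codes[int(g)] for g in gm.genotypes[:, j])
            fh.write(f"1\t{j + 1}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def _read_vcf_text(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    samples: list[str] = []
    loci: list[str] = []
    rows: list[list[int]] = []
    code = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
            "1/1": 2, "1|1": 2, "./.": MISSING, ".|.": MISSING, ".": MISSING}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            loci.append(fields[2] if fields[2] != "." else f"{fields[0]}:{fields[1]}")
            gt_index = fields[8].split(":").index("GT")
            rows.append([code.get(f.split(":")[gt_index], MISSING) for f in fields[9:]])
    return np.asarray(rows, dtype=np.int8).T, samples, loci


def _read_vcf_cyvcf2(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        loci.append(var.ID or f"{var.CHROM}:{var.POS}")
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        g = var.gt_types.astype(np.int8)
        g = np.select([g == 0, g == 1, g == 3], [0, 1, 2], default=MISSING)
        rows.append(g.astype(np.int8))
    return np.asarray(rows, dtype=np.int8).T, samples, loci


def read_vcf(path: str | Path, meta: pd.DataFrame) -> GenotypeMatrix:
    """Read biallelic genotypes from VCF; `meta` indexed by sample id."""
    try:
        genotypes, samples, loci = _read_vcf_cyvcf2(path)
    except ImportError:
        genotypes, samples, loci = _read_vcf_text(path)
    return GenotypeMatrix(genotypes, samples, loci, meta)


def write_genotype_csv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        gm.genotypes.astype(float), index=gm.sample_ids, columns=gm.locus_ids
    ).replace(float(MISSING), np.nan)
    df.to_csv(path, index_label="sample_id", na_rep="NA")


def read_genotype_csv(path: str | Path, meta: pd.DataFrame) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    genotypes = df.to_numpy(dtype=float)
    genotypes = np.where(np.isnan(genotypes), MISSING, genotypes).astype(np.int8)
    return GenotypeMatrix(genotypes, list(df.index), list(df.columns), meta)


def write_metadata(gm: GenotypeMatrix, path: str | Path) -> None:
    gm.meta[["site_id", "ecotope", "year", "x", "y"]].to_csv(
        path, index_label="sample_id"
    )


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


# ---------------------------------------------------------------- matrices


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_frame().to_csv(path, index_label=f"kind:{dm.kind}")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    kind = "generic"
    if isinstance(df.index.name, str) and df.index.name.startswith("kind:"):
        kind = df.index.name.split(":", 1)[1]
    return DistanceMatrix(list(df.columns), df.to_numpy(dtype=float), kind)


# ---------------------------------------------------------------- json


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")
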