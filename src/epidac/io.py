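"""Readers and writers for the plain-text interchange formats.

Everything is TSV/CSV with explicit headers: beta and detection-p matrices
(probe x sample), the probe annotation manifest (BED-style 0-based half-open
coordinates, gene links encoded as ``gene:region`` pairs joined with ``;``),
gene coordinates, count matrices (gene x sample), per-sample compartment
tracks, gene-set collections in GMT, and the survival / flow CSVs.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import pandas as pd

from .annotation import ProbeAnnotation
from .methylation import BetaMatrix

FLOAT_FORMAT = "%.6g"


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_beta(bm: BetaMatrix, beta_path: str | Path,
               detection_path: str | Path | None = None) -> None:
    write_matrix(bm.beta, beta_path)
    if detection_path is not None:
        write_matrix(bm.detection_p, detection_path)


def read_beta(beta_path: str | Path,
              detection_path: str | Path | None = None) -> BetaMatrix:
    beta = read_matrix(beta_path)
    detp = read_matrix(detection_path) if detection_path else None
    return BetaMatrix(beta, detp)


def write_annotation(ann: ProbeAnnotation, probes_path: str | Path,
                     genes_path: str | Path | None = None) -> None:
    links = (ann.links.assign(pair=lambda d: d["gene_id"] + ":" + d["region_class"])
             .groupby("probe_id")["pair"].apply(";".join))
    table = ann.probes.copy()
    table["gene_links"] = links.reindex(table.index).fillna(".")
    table[["in_cimp_panel", "in_epitoc_panel"]] = (
        table[["in_cimp_panel", "in_epitoc_panel"]].astype(int))
    table.to_csv(probes_path, sep="\t")
    if genes_path is not None and ann.genes is not None:
        ann.genes.to_csv(genes_path, sep="\t")


def read_annotation(probes_path: str | Path,
                    genes_path: str | Path | None = None) -> ProbeAnnotation:
    table = pd.read_csv(probes_path, sep="\t", index_col=0)
    rows = []
    for probe_id, enc in table["gene_links"].items():
        if enc == "." or pd.isna(enc):
            continue
        for pair in str(enc).split(";"):
            gene_id, region = pair.rsplit(":", 1)
            rows.append((probe_id, gene_id, region))
    links = pd.DataFrame(rows, columns=["probe_id", "gene_id", "region_class"])
    probes = table.drop(columns=["gene_links"])
    probes[["in_cimp_panel", "in_epitoc_panel"]] = (
        probes[["in_cimp_panel", "in_epitoc_panel"]].astype(bool))
    genes = pd.read_csv(genes_path, sep="\t", index_col=0) if genes_path else None
    return ProbeAnnotation(probes=probes, links=links, genes=genes)


def write_track(track: pd.DataFrame, path: str | Path) -> None:
    track.to_csv(path, sep="\t", index=False)


def read_track(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gmt(gene_sets: Mapping[str, list], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(gene_sets[name])
            fh.write(f"{name}\tna\t{genes}\n")


def read_gmt(path: str | Path) -> dict[str, list]:
    sets: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
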