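"""Reading and writing the flat-text formats used between analysis stages.

Marker matrices are stored as two tab-separated files: a call table
(entries x markers, codes A/H/B/N for recurrent-parent homozygous,
heterozygous, donor homozygous, missing) and a marker annotation table
(marker, chromosome, bp; positions 1-based).  Candidate genes travel as
BED (0-based half-open) with a pathway column and are converted to
1-based inclusive coordinates on load.  Phenotype and hormone-assay
tables are long-format CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .genotype_core import MarkerMatrix

__all__ = [
    "read_marker_matrix",
    "write_marker_matrix",
    "read_genes_bed",
    "write_genes_bed",
    "read_phenotypes",
    "write_phenotypes",
    "read_hormone_assay",
    "write_hormone_assay",
    "write_json",
]


def write_marker_matrix(matrix: MarkerMatrix, calls_path, markers_path) -> None:
    matrix.calls.to_csv(calls_path, sep="\t", index_label="entry")
    matrix.markers.to_csv(markers_path, sep="\t", index_label="marker")


def read_marker_matrix(calls_path, markers_path) -> MarkerMatrix:
    calls = pd.read_csv(calls_path, sep="\t", index_col="entry")
    markers = pd.read_csv(markers_path, sep="\t", index_col="marker")
    return MarkerMatrix(calls=calls, markers=markers)


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    """Write genes (1-based inclusive start/end) as BED with a pathway column."""
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"] - 1,  # BED is 0-based half-open
            "end": genes["end"],
            "name": genes["gene"],
            "pathway": genes["pathway"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name", "pathway"]
    )
    return pd.DataFrame(
        {
            "gene": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"] + 1,
            "end": bed["end"],
            "pathway": bed["pathway"],
        }
    )


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_hormone_assay(assay: pd.DataFrame, path) -> None:
    assay.to_csv(path, index=False)


def read_hormone_assay(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    try:
        return o.item()  # numpy scalars
    except AttributeError:
        raise TypeError(f"not JSON serializable: {type(o)}")
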