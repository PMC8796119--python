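"""Readers and writers for the toolkit's file formats.

piRNAs: FASTA (abundance optionally as ``abundance=X`` in the description)
or headered 2-column TSV (sequence, abundance). Transcripts: FASTA with a
sidecar gene-class TSV. Small-RNA alignments: BED-like TSV or SAM/BAM in
transcript coordinates. Sites: BED6-like TSV with extended pairing-count
columns. Spots and axes: CSV. Comment lines starting with '#' are ignored
in all tabular formats.
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .spatial import GermlineAxis
from .targeting import PiRNA, Transcript

_ABUNDANCE_RE = re.compile(r"abundance=([0-9.eE+-]+)")


def read_pirnas(path: str | Path) -> list[PiRNA]:
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
        out = []
        for rec in SeqIO.parse(str(path), "fasta"):
            m = _ABUNDANCE_RE.search(rec.description)
            out.append(PiRNA(rec.id, str(rec.seq), float(m.group(1)) if m else 1.0))
        return out
    table = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in table.columns}
    seq_col = cols.get("sequence", table.columns[0] if "id" not in cols else None)
    out = []
    for i, row in table.iterrows():
        pid = str(row[cols["pirna_id"]]) if "pirna_id" in cols else (
            str(row[cols["id"]]) if "id" in cols else f"pirna-{i:05d}"
        )
        out.append(
            PiRNA(
                pid,
                str(row[cols.get("sequence", seq_col)]),
                float(row[cols["abundance"]]) if "abundance" in cols else 1.0,
            )
        )
    return out


def read_gene_classes(path: str | Path) -> pd.DataFrame:
    """TSV with transcript_id (optional), gene_id and gene_class columns."""
    table = pd.read_csv(path, sep="\t", comment="#")
    if "gene_class" not in table.columns or "gene_id" not in table.columns:
        raise ValueError("gene class table needs gene_id and gene_class columns")
    if "transcript_id" not in table.columns:
        table["transcript_id"] = table["gene_id"]
    return table


def read_transcripts(
    fasta: str | Path, classes: str | Path | pd.DataFrame | None = None
) -> list[Transcript]:
    if classes is not None and not isinstance(classes, pd.DataFrame):
        classes = read_gene_classes(classes)
    lookup = (
        classes.set_index("transcript_id")[["gene_id", "gene_class"]]
        if classes is not None
        else None
    )
    out = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        gene_id, gene_class = rec.id, "other"
        if lookup is not None and rec.id in lookup.index:
            gene_id = str(lookup.at[rec.id, "gene_id"])
            gene_class = str(lookup.at[rec.id, "gene_class"])
        out.append(Transcript(rec.id, str(rec.seq), gene_id, gene_class))
    return out


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_alignments(path: str | Path) -> pd.DataFrame:
    """BED-like alignment TSV or SAM/BAM (by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".sam", ".bam"}:
        return read_alignments_sam(path)
    table = pd.read_csv(path, sep="\t", comment="#")
    if "length" not in table.columns and "end" in table.columns:
        table["length"] = table["end"] - table["start"]
    if "count" not in table.columns:
        table["count"] = 1
    if "strand" in table.columns:
        table["strand"] = table["strand"].replace({"+": "sense", "-": "antisense"})
    needed = {"transcript_id", "start", "length", "strand", "first_base", "count"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"alignment table missing columns: {sorted(missing)}")
    if "read_id" not in table.columns:
        table["read_id"] = [f"r{i}" for i in range(len(table))]
    return table[
        ["read_id", "transcript_id", "start", "length", "strand", "first_base", "count"]
    ]


def read_alignments_sam(path: str | Path) -> pd.DataFrame:
    """SAM/BAM records in transcript space; 5' base and length from the read."""
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    rows = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            seq = rec.get_forward_sequence() or ""
            rows.append(
                {
                    "read_id": rec.query_name,
                    "transcript_id": rec.reference_name,
                    "start": rec.reference_start,
                    "length": rec.query_length,
                    "strand": "antisense" if rec.is_reverse else "sense",
                    "first_base": (seq[:1] or "N").replace("T", "U"),
                    "count": 1,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["read_id", "transcript_id", "start", "length", "strand",
                 "first_base", "count"],
    )


def write_sites(sites: pd.DataFrame, path: str | Path) -> None:
    """BED6-like site table (strand '-': sites lie antisense to the guide)."""
    out = sites.copy()
    out["strand"] = "-"
    cols = [
        "transcript_id", "start", "end", "pirna_id", "pirna_abundance", "strand",
        "center", "seed_mm", "seed_gu", "nonseed_mm", "nonseed_gu",
    ]
    out[cols].to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_spots(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, comment="#")
    missing = {"x", "y", "z"} - set(table.columns)
    if missing:
        raise ValueError(f"spot table missing columns: {sorted(missing)}")
    return table


def read_axis(path: str | Path, loop_index: int | None = None) -> GermlineAxis:
    """Axis CSV with x,y,z columns; the loop is the ``is_loop`` row or given."""
    table = pd.read_csv(path, comment="#")
    points = table[["x", "y", "z"]].to_numpy(float)
    if loop_index is None:
        if "is_loop" not in table.columns:
            raise ValueError("axis CSV needs an is_loop column or explicit loop_index")
        loop_index = int(np.flatnonzero(table["is_loop"].to_numpy(bool))[0])
    return GermlineAxis(points, loop_index)
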