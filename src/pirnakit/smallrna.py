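"""22G-RNA classification, RPM normalization and IP enrichment.

22G-RNAs are RdRP-made secondary small RNAs, ~22 nt with a 5' G, antisense
to the mRNAs they silence. Alignments are kept as a plain DataFrame with one
row per distinct read placement and a ``count`` multiplicity:

    read_id, transcript_id, start, length, strand, first_base, count

``start`` is the leftmost (BED-like) 0-based transcript coordinate of the
covered interval; for an antisense read the biological 5' end sits at
``start + length - 1``.
"""
from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

ALN_COLUMNS = (
    "read_id", "transcript_id", "start", "length", "strand", "first_base", "count"
)


def filter_22g(
    alignments: pd.DataFrame,
    min_length: int = 21,
    max_length: int = 23,
    first_base: str = "G",
) -> pd.DataFrame:
    """Keep antisense reads with the configured 5' base and length bounds.

    The strict-22 convention is ``min_length=max_length=22``.
    """
    keep = (
        (alignments["strand"] == "antisense")
        & (alignments["first_base"] == first_base)
        & alignments["length"].between(min_length, max_length)
    )
    return alignments.loc[keep].reset_index(drop=True)


def rpm(count, library_total: float):
    """Reads-per-million normalization; works on scalars and arrays."""
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    return count * (1e6 / library_total)


def library_size(alignments: pd.DataFrame) -> int:
    return int(alignments["count"].sum())


def gene_antisense_rpm(
    alignments: pd.DataFrame,
    gene_map: Mapping[str, str] | pd.Series,
    library_total: float,
    genes: Sequence[str] | None = None,
) -> pd.Series:
    """Per-gene RPM of (pre-filtered) antisense reads.

    gene_map maps transcript_id -> gene_id; reads on different isoforms of
    one gene are summed. Every gene in ``genes`` (default: all genes in the
    map) gets a row, zero if unread.
    """
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    gene_map = pd.Series(dict(gene_map) if not isinstance(gene_map, pd.Series) else gene_map)
    unknown = set(alignments["transcript_id"]) - set(gene_map.index)
    if unknown:
        raise KeyError(f"alignments reference unknown transcripts: {sorted(unknown)[:10]}")
    if genes is None:
        genes = pd.unique(gene_map.values)
    counts = (
        alignments.assign(gene_id=alignments["transcript_id"].map(gene_map))
        .groupby("gene_id")["count"].sum()
    )
    counts = counts.reindex(genes, fill_value=0).astype(float)
    out = counts * 1e6 / library_total
    out.name = "rpm"
    return out


def average_replicates(tables: Sequence[pd.Series]) -> pd.Series:
    """Elementwise mean of per-gene RPM tables (replicates on the RPM scale)."""
    if not tables:
        raise ValueError("no replicate tables given")
    frame = pd.concat(list(tables), axis=1)
    if frame.isna().any().any():
        raise ValueError("replicate tables must share one gene universe")
    out = frame.mean(axis=1)
    out.name = "rpm"
    return out


def ip_enrichment(
    ip_rpm: pd.Series,
    input_rpm: pd.Series,
    min_ip_rpm: float = 1.0,
    pseudocount: float = 1.0,
    fold_threshold: float = 2.0,
) -> tuple[pd.DataFrame, set[str]]:
    """IP-vs-input log2 fold change and the enriched target set.

    Genes at or below ``min_ip_rpm`` in the IP are excluded (log2fc NaN),
    matching the strict >1 RPM filter applied to Argonaute IPs. Targets are
    genes with log2fc >= log2(fold_threshold).
    """
    if not ip_rpm.index.equals(input_rpm.index):
        input_rpm = input_rpm.reindex(ip_rpm.index)
        if input_rpm.isna().any():
            raise ValueError("ip and input tables must share one gene universe")
    log2fc = np.log2((ip_rpm + pseudocount) / (input_rpm + pseudocount))
    log2fc = log2fc.where(ip_rpm > min_ip_rpm)
    table = pd.DataFrame(
        {"ip_rpm": ip_rpm, "input_rpm": input_rpm, "log2fc": log2fc}
    )
    targets = set(table.index[table["log2fc"] >= np.log2(fold_threshold)])
    return table, targets


def dependence_fold_change(
    rpm_condition_a: pd.Series,
    rpm_condition_b: pd.Series,
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2((a+pc)/(b+pc)) per gene, e.g. piwi-mutant IP over wild-type IP."""
    if not rpm_condition_a.index.equals(rpm_condition_b.index):
        rpm_condition_b = rpm_condition_b.reindex(rpm_condition_a.index)
        if rpm_condition_b.isna().any():
            raise ValueError("condition tables must share one gene universe")
    out = np.log2((rpm_condition_a + pseudocount) / (rpm_condition_b + pseudocount))
    out.name = "log2fc"
    return out
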