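"""smFISH oligonucleotide probe-candidate filtering.

Candidates are all 30-mers of a target (typically intronic) DNA sequence.
The filter chain keeps candidates with GC content between 35 and 85%
(inclusive), then removes from that pool any candidate containing a
homopolymer run of 7 or more, any candidate with at least one genomic
off-target within 5 mismatches (both strands, windows overlapping the
intended locus exempt), and any candidate whose melting temperature deviates
from the GC-passing pool's mean by more than 10 °C. Final probe-set
optimization is out of scope; the output is the filtered pool with all
metrics and per-filter flags.

Melting temperatures model the DNA probe : RNA target hybrid with a
nearest-neighbor table (Sugimoto et al.-style RNA/DNA parameters, pinned in
``NN_DNA_RNA``), duplex initiation, the two-state formula
``Tm = ΔH / (ΔS + R ln(C/4))``, a 16.6*log10([monovalent]) salt correction
and a linear formamide correction (default 0.72 °C per % v/v).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .sequences import encode_dna, normalize_dna, revcomp_dna

logger = logging.getLogger(__name__)

PROBE_LENGTH = 30

# Nearest-neighbor ΔH (kcal/mol) and ΔS (cal/mol/K) for RNA/DNA hybrids,
# indexed by the RNA-strand dinucleotide read 5'->3'. Pinned constants of
# this implementation; the duplicate-formula oracle in the tests re-codes
# them independently.
NN_DNA_RNA: dict[str, tuple[float, float]] = {
    "AA": (-7.8, -21.9),
    "AC": (-5.9, -12.3),
    "AG": (-9.1, -23.5),
    "AU": (-8.3, -23.9),
    "CA": (-9.0, -26.1),
    "CC": (-9.3, -23.2),
    "CG": (-16.3, -47.1),
    "CU": (-7.0, -19.7),
    "GA": (-5.5, -13.5),
    "GC": (-8.0, -17.1),
    "GG": (-12.8, -31.9),
    "GU": (-7.8, -21.6),
    "UA": (-7.8, -23.2),
    "UC": (-8.6, -22.9),
    "UG": (-10.4, -28.4),
    "UU": (-11.5, -36.4),
}
NN_INITIATION = (1.9, -3.9)  # ΔH, ΔS duplex initiation
GAS_CONSTANT = 1.987  # cal/(mol*K)


@dataclass(frozen=True)
class ProbeConfig:
    gc_lo: float = 0.35
    gc_hi: float = 0.85
    max_homopolymer: int = 6  # runs of 7+ are discarded
    max_offtarget_mm: int = 5
    tm_max_deviation: float = 10.0  # °C from the pool mean
    oligo_conc: float = 0.05e-6  # M
    monovalent: float = 1.04  # M
    formamide: float = 25.0  # % v/v
    formamide_coeff: float = 0.72  # °C per %


DEFAULT_PROBE_CONFIG = ProbeConfig()


def gc_content(seq: str) -> float:
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s) if s else 0.0


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best if seq else 0


def enumerate_30mers(target_seq: str, k: int = PROBE_LENGTH) -> pd.DataFrame:
    """All k-mers of the target sequence, ordered by start coordinate."""
    seq = normalize_dna(target_seq, "target")
    if len(seq) < k:
        warnings.warn(f"target shorter than {k} nt; no candidates", stacklevel=2)
        return pd.DataFrame(columns=["start", "sequence"])
    rows = [(i, seq[i : i + k]) for i in range(len(seq) - k + 1)]
    return pd.DataFrame(rows, columns=["start", "sequence"])


def gc_filter(
    candidates: pd.DataFrame, lo: float = 0.35, hi: float = 0.85
) -> pd.DataFrame:
    """Keep candidates with lo <= GC fraction <= hi (bounds inclusive)."""
    gc = candidates["sequence"].map(gc_content)
    return candidates.loc[(gc >= lo) & (gc <= hi)].reset_index(drop=True)


def homopolymer_filter(candidates: pd.DataFrame, max_run: int = 6) -> pd.DataFrame:
    """Drop candidates containing any single-base run longer than max_run."""
    runs = candidates["sequence"].map(max_homopolymer_run)
    return candidates.loc[runs <= max_run].reset_index(drop=True)


def offtarget_hits(
    candidate: str,
    genome: dict[str, str],
    max_mm: int = 5,
    target_locus: tuple[str, int, int] | None = None,
) -> int:
    """Count genomic windows within ``max_mm`` mismatches of the candidate.

    Both strands are scanned (a minus-strand hit at window w is a plus-strand
    hit of the candidate's reverse complement). Windows overlapping
    ``target_locus = (seq_id, start, end)`` are exempt on both strands: a
    probe's own locus is not an off-target.
    """
    cand = encode_dna(normalize_dna(candidate))
    rc = encode_dna(revcomp_dna(normalize_dna(candidate)))
    k = cand.size
    total = 0
    for seq_id, seq in genome.items():
        enc = encode_dna(normalize_dna(seq, seq_id))
        if enc.size < k:
            continue
        win = sliding_window_view(enc, k)
        hit = np.zeros(len(win), dtype=bool)
        for probe in (cand, rc):
            hit |= (win != probe[None, :]).sum(axis=1) <= max_mm
        if target_locus is not None and target_locus[0] == seq_id:
            _, lo, hi = target_locus
            starts = np.arange(len(win))
            overlap = (starts < hi) & (starts + k > lo)
            hit &= ~overlap
        total += int(hit.sum())
    return total


def offtarget_filter(
    candidates: pd.DataFrame,
    genome: dict[str, str],
    max_mm: int = 5,
    target_locus: tuple[str, int, int] | None = None,
) -> pd.DataFrame:
    """Drop candidates with >= 1 off-target within ``max_mm`` mismatches."""
    hits = candidates["sequence"].map(
        lambda s: offtarget_hits(s, genome, max_mm, target_locus)
    )
    return candidates.loc[hits == 0].reset_index(drop=True)


def melting_temperature(
    candidate: str,
    oligo_conc: float = 0.05e-6,
    monovalent: float = 1.04,
    formamide: float = 25.0,
    formamide_coeff: float = 0.72,
) -> float:
    """Nearest-neighbor Tm (°C) of the DNA probe : RNA target hybrid.

    The candidate is the DNA-space sequence of the targeted region; the
    duplex pairs it with its complementary RNA strand, whose 5'->3'
    dinucleotides index ``NN_DNA_RNA``. Salt correction is
    16.6*log10([monovalent]); formamide lowers Tm linearly.
    """
    dna = normalize_dna(candidate, "candidate")
    if len(dna) < 2:
        raise ValueError("candidate too short for nearest-neighbor Tm")
    rna = revcomp_dna(dna).replace("T", "U")
    dh, ds = NN_INITIATION
    for i in range(len(rna) - 1):
        h, s = NN_DNA_RNA[rna[i : i + 2]]
        dh += h
        ds += s
    tm_k = dh * 1000.0 / (ds + GAS_CONSTANT * np.log(oligo_conc / 4.0))
    tm = tm_k - 273.15
    tm += 16.6 * np.log10(monovalent)
    tm -= formamide_coeff * formamide
    return float(tm)


def tm_pool_filter(
    candidates: pd.DataFrame,
    tm_column: str = "tm",
    max_deviation: float = 10.0,
    pool_mean: float | None = None,
) -> pd.DataFrame:
    """Drop candidates whose Tm deviates from the pool mean by > max_deviation.

    The pool mean is computed over the incoming candidates (the GC-passing
    pool) unless given explicitly; a deviation of exactly max_deviation is
    kept.
    """
    if pool_mean is None:
        pool_mean = float(candidates[tm_column].mean())
    dev = (candidates[tm_column] - pool_mean).abs()
    return candidates.loc[dev <= max_deviation].reset_index(drop=True)


def design_probes(
    target_seq: str,
    genome: dict[str, str],
    target_locus: tuple[str, int, int] | None = None,
    config: ProbeConfig = DEFAULT_PROBE_CONFIG,
) -> pd.DataFrame:
    """Run the full candidate filter chain; returns all metrics and flags.

    Chain: enumerate 30-mers -> GC filter; the surviving pool is then
    filtered by the three independent predicates (homopolymer, off-target,
    Tm deviation from the pool's mean). ``pass_all`` marks the final
    survivors.
    """
    table = enumerate_30mers(target_seq)
    if table.empty:
        return table.assign(
            gc=[], max_homopolymer=[], tm=[], offtarget_hits=[],
            pass_gc=[], pass_homopolymer=[], pass_offtarget=[], pass_tm=[],
            pass_all=[],
        )
    table["gc"] = table["sequence"].map(gc_content)
    table["max_homopolymer"] = table["sequence"].map(max_homopolymer_run)
    table["tm"] = table["sequence"].map(
        lambda s: melting_temperature(
            s, config.oligo_conc, config.monovalent,
            config.formamide, config.formamide_coeff,
        )
    )
    table["offtarget_hits"] = table["sequence"].map(
        lambda s: offtarget_hits(s, genome, config.max_offtarget_mm, target_locus)
    )
    table["pass_gc"] = (table["gc"] >= config.gc_lo) & (table["gc"] <= config.gc_hi)
    pool_mean = float(table.loc[table["pass_gc"], "tm"].mean())
    table["pass_homopolymer"] = table["max_homopolymer"] <= config.max_homopolymer
    table["pass_offtarget"] = table["offtarget_hits"] == 0
    table["pass_tm"] = (table["tm"] - pool_mean).abs() <= config.tm_max_deviation
    table["pass_all"] = (
        table["pass_gc"] & table["pass_homopolymer"]
        & table["pass_offtarget"] & table["pass_tm"]
    )
    logger.info(
        "probe chain: %d candidates, %d GC-pass, %d survivors",
        len(table), int(table["pass_gc"].sum()), int(table["pass_all"].sum()),
    )
    return table
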