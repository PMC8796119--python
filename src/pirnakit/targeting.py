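"""Prediction of piRNA (21U-RNA) target sites on transcripts.

C. elegans piRNAs are 21-nt, 5'-U guides that recognize mRNAs by imperfect
antiparallel base pairing. A 21-nt transcript window is accepted as a target
site under stringent criteria: the seed region of the guide (positions 2-8 by
default) must pair perfectly apart from at most one G:U wobble, the remainder
of the guide tolerates at most two mismatches plus at most one additional G:U
wobble, and whatever faces guide position 1 is never counted (the 5' U is
anchored in the PIWI protein and does not read the target).

Coordinates are 0-based half-open on the transcript; a site's ``center`` is
the transcript base pairing guide position 11 (``start + 10``).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .sequences import encode_rna, normalize_rna

logger = logging.getLogger(__name__)

PIRNA_LENGTH = 21

# pair classes
WC, GU, MM, NA1, AMBIG = 0, 1, 2, 3, 4
PAIR_CLASS_NAMES = {WC: "WC", GU: "GU", MM: "MM", NA1: "NA1", AMBIG: "AMBIG"}

GENE_CLASSES = ("spermatogenic", "oogenic", "other")

# lookup: guide base code x target base code -> pair class
_PAIR_LUT = np.full((5, 5), MM, dtype=np.uint8)
for _g, _t in ((0, 3), (3, 0), (2, 1), (1, 2)):  # A:U, U:A, G:C, C:G
    _PAIR_LUT[_g, _t] = WC
for _g, _t in ((2, 3), (3, 2)):  # G:U, U:G wobbles
    _PAIR_LUT[_g, _t] = GU
_PAIR_LUT[4, :] = AMBIG
_PAIR_LUT[:, 4] = AMBIG

SITE_COLUMNS = [
    "transcript_id", "start", "end", "center", "pirna_id", "pirna_abundance",
    "seed_mm", "seed_gu", "nonseed_mm", "nonseed_gu",
]


def classify_base_pair(pirna_base: str, target_base: str) -> str:
    """Classify a guide:target base pair as 'WC', 'GU' or 'MM'."""
    for b, role in ((pirna_base, "piRNA"), (target_base, "target")):
        if b not in "ACGU":
            raise ValueError(f"non-RNA {role} base {b!r}")
    cls = _PAIR_LUT[encode_rna(pirna_base)[0], encode_rna(target_base)[0]]
    return PAIR_CLASS_NAMES[int(cls)]


@dataclass(frozen=True)
class TargetingConfig:
    """Pairing-rule parameters.

    seed_start/seed_end are 1-based inclusive guide positions; position 1 is
    always exempt even if included in the seed bounds. With
    ``global_mm_budget`` the mismatch budget applies to all counted positions
    (2-21) jointly instead of the non-seed region alone; the seed G:U cap is
    retained in both readings.
    """

    seed_start: int = 2
    seed_end: int = 8
    max_seed_mm: int = 0
    max_seed_gu: int = 1
    max_nonseed_mm: int = 2
    max_nonseed_gu: int = 1
    global_mm_budget: bool = False
    center_offset: int = 10  # base pairing guide position 11

    def __post_init__(self) -> None:
        if not (1 <= self.seed_start <= self.seed_end <= PIRNA_LENGTH):
            raise ValueError("invalid seed bounds")

    @property
    def seed_positions(self) -> tuple[int, ...]:
        return tuple(
            p for p in range(self.seed_start, self.seed_end + 1) if p != 1
        )

    @property
    def nonseed_positions(self) -> tuple[int, ...]:
        seed = set(self.seed_positions)
        return tuple(
            p for p in range(2, PIRNA_LENGTH + 1) if p not in seed
        )


DEFAULT_CONFIG = TargetingConfig()


@dataclass(frozen=True)
class PiRNA:
    """A 21U-RNA guide: 21-nt RNA, 5'->3', abundance in RPM."""

    id: str
    sequence: str
    abundance: float = 0.0
    strict: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence, self.id))
        if len(self.sequence) != PIRNA_LENGTH:
            raise ValueError(
                f"piRNA {self.id!r} is {len(self.sequence)} nt; expected {PIRNA_LENGTH}"
            )
        if "N" in self.sequence:
            raise ValueError(f"piRNA {self.id!r} contains N")
        if self.abundance < 0:
            raise ValueError(f"piRNA {self.id!r} has negative abundance")
        if self.sequence[0] != "U":
            if self.strict:
                raise ValueError(f"piRNA {self.id!r} does not start with U")
            logger.warning("piRNA %s does not start with U", self.id)


@dataclass(frozen=True)
class Transcript:
    """A transcript sequence with its gene id and expression class."""

    id: str
    sequence: str
    gene_id: str = ""
    gene_class: str = "other"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence, self.id))
        if not self.gene_id:
            object.__setattr__(self, "gene_id", self.id)
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(
                f"gene_class {self.gene_class!r} not in {GENE_CLASSES}"
            )


@dataclass(frozen=True)
class PairingProfile:
    """Per-position pair classes (guide positions 1-21) and budget tallies."""

    pair_classes: tuple[str, ...]
    seed_mm: int
    seed_gu: int
    nonseed_mm: int
    nonseed_gu: int

    def __post_init__(self) -> None:
        if len(self.pair_classes) != PIRNA_LENGTH:
            raise ValueError("pairing profile must cover 21 positions")
        if self.pair_classes[0] != "NA1":
            raise ValueError("guide position 1 must be NA1")


@dataclass(frozen=True)
class TargetSite:
    pirna_id: str
    transcript_id: str
    start: int
    profile: PairingProfile
    pirna_abundance: float = 0.0

    @property
    def end(self) -> int:
        return self.start + PIRNA_LENGTH

    @property
    def center(self) -> int:
        return self.start + 10


def _class_matrix(guide: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Pair classes for each window; column j is guide position j+1.

    Guide position i (1-based) pairs antiparallel with window position
    22-i, i.e. guide index gi with window index 20-gi.
    """
    return _PAIR_LUT[guide[None, :], windows[:, ::-1]]


def _counts(classes: np.ndarray, cfg: TargetingConfig):
    """Seed/non-seed MM and GU counts. Position 1 (column 0) never counted."""
    seed_cols = [p - 1 for p in cfg.seed_positions]
    nonseed_cols = [p - 1 for p in cfg.nonseed_positions]
    cs = classes[:, seed_cols]
    cn = classes[:, nonseed_cols]
    return (
        (cs == MM).sum(axis=1),
        (cs == GU).sum(axis=1),
        (cn == MM).sum(axis=1),
        (cn == GU).sum(axis=1),
    )


def _accepted(seed_mm, seed_gu, nonseed_mm, nonseed_gu, cfg: TargetingConfig):
    if cfg.global_mm_budget:
        mm_ok = (seed_mm + nonseed_mm) <= cfg.max_nonseed_mm
    else:
        mm_ok = (seed_mm <= cfg.max_seed_mm) & (nonseed_mm <= cfg.max_nonseed_mm)
    return (
        mm_ok
        & (seed_gu <= cfg.max_seed_gu)
        & (nonseed_gu <= cfg.max_nonseed_gu)
    )


def evaluate_duplex(
    pirna: PiRNA, window: str, config: TargetingConfig = DEFAULT_CONFIG
) -> tuple[PairingProfile, bool]:
    """Evaluate one guide against one 21-nt window (transcript 5'->3')."""
    w = normalize_rna(window, "window")
    if len(w) != PIRNA_LENGTH:
        raise ValueError(f"window is {len(w)} nt; expected {PIRNA_LENGTH}")
    if "N" in w:
        raise ValueError("window contains N; ambiguous windows are skipped in scans")
    classes = _class_matrix(encode_rna(pirna.sequence), encode_rna(w)[None, :])
    seed_mm, seed_gu, nonseed_mm, nonseed_gu = (
        int(x[0]) for x in _counts(classes, config)
    )
    ok = bool(
        _accepted(
            np.array([seed_mm]), np.array([seed_gu]),
            np.array([nonseed_mm]), np.array([nonseed_gu]), config
        )[0]
    )
    names = [PAIR_CLASS_NAMES[int(c)] for c in classes[0]]
    names[0] = "NA1"
    profile = PairingProfile(tuple(names), seed_mm, seed_gu, nonseed_mm, nonseed_gu)
    return profile, ok


def scan_transcript(
    pirna: PiRNA, transcript: Transcript, config: TargetingConfig = DEFAULT_CONFIG
) -> list[TargetSite]:
    """All accepted 21-nt windows of one transcript, sorted by start.

    Windows containing N are skipped (counted in the module log). A transcript
    shorter than 21 nt yields an empty list.
    """
    enc = encode_rna(transcript.sequence)
    if enc.size < PIRNA_LENGTH:
        return []
    windows = sliding_window_view(enc, PIRNA_LENGTH)
    classes = _class_matrix(encode_rna(pirna.sequence), windows)
    ambiguous = (classes == AMBIG).any(axis=1)
    n_skipped = int(ambiguous.sum())
    if n_skipped:
        logger.debug(
            "%s x %s: skipped %d windows containing N",
            pirna.id, transcript.id, n_skipped,
        )
    seed_mm, seed_gu, nonseed_mm, nonseed_gu = _counts(classes, config)
    ok = _accepted(seed_mm, seed_gu, nonseed_mm, nonseed_gu, config) & ~ambiguous
    sites = []
    for k in np.flatnonzero(ok):
        names = [PAIR_CLASS_NAMES[int(c)] for c in classes[k]]
        names[0] = "NA1"
        profile = PairingProfile(
            tuple(names), int(seed_mm[k]), int(seed_gu[k]),
            int(nonseed_mm[k]), int(nonseed_gu[k]),
        )
        sites.append(
            TargetSite(pirna.id, transcript.id, int(k), profile, pirna.abundance)
        )
    return sites


def scan_transcriptome(
    pirnas: list[PiRNA],
    transcripts: list[Transcript],
    config: TargetingConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Scan every piRNA against every transcript; one row per accepted window.

    Uses a concatenated transcriptome with a seed-region prefilter so the
    per-window work is vectorized across the whole transcriptome; results are
    identical to running :func:`scan_transcript` per pair. Rows are ordered by
    (transcript_id, start, pirna_id).
    """
    if not pirnas:
        raise ValueError("empty piRNA list")
    if not transcripts:
        raise ValueError("empty transcript list")
    ids = [t.id for t in transcripts]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate transcript ids: {dupes}")

    # concatenate with N spacers so no window spans two transcripts
    spacer = np.full(PIRNA_LENGTH - 1, 4, dtype=np.uint8)
    chunks, offsets = [], []
    pos = 0
    for t in transcripts:
        enc = encode_rna(t.sequence)
        offsets.append(pos)
        chunks.append(enc)
        chunks.append(spacer)
        pos += enc.size + spacer.size
    genome = np.concatenate(chunks)
    offsets_arr = np.asarray(offsets)
    lengths = np.asarray([len(t.sequence) for t in transcripts])
    windows = sliding_window_view(genome, PIRNA_LENGTH)

    # seed prefilter columns (window index 20 - (guide pos - 1))
    seed_pos = np.asarray(config.seed_positions)
    seed_widx = PIRNA_LENGTH - seed_pos  # window indices pairing the seed
    seed_mm_cap = (
        config.max_nonseed_mm if config.global_mm_budget else config.max_seed_mm
    )

    rows = []
    for p in pirnas:
        g = encode_rna(p.sequence)
        g_seed = g[seed_pos - 1]
        cseed = _PAIR_LUT[g_seed[None, :], windows[:, seed_widx]]
        cand = np.flatnonzero(
            ((cseed == MM) | (cseed == AMBIG)).sum(axis=1) <= seed_mm_cap
        )
        if cand.size == 0:
            continue
        classes = _class_matrix(g, windows[cand])
        ambiguous = (classes == AMBIG).any(axis=1)
        seed_mm, seed_gu, nonseed_mm, nonseed_gu = _counts(classes, config)
        ok = _accepted(seed_mm, seed_gu, nonseed_mm, nonseed_gu, config) & ~ambiguous
        hits = cand[ok]
        if hits.size == 0:
            continue
        tidx = np.searchsorted(offsets_arr, hits, side="right") - 1
        starts = hits - offsets_arr[tidx]
        inside = starts + PIRNA_LENGTH <= lengths[tidx]
        sel = np.flatnonzero(ok)[inside]
        for j, ti, st in zip(sel, tidx[inside], starts[inside]):
            rows.append((
                ids[ti], int(st), int(st) + PIRNA_LENGTH, int(st) + 10,
                p.id, p.abundance,
                int(seed_mm[j]), int(seed_gu[j]),
                int(nonseed_mm[j]), int(nonseed_gu[j]),
            ))
    table = pd.DataFrame(rows, columns=SITE_COLUMNS)
    table = table.sort_values(
        ["transcript_id", "start", "pirna_id"], kind="mergesort"
    ).reset_index(drop=True)
    logger.info(
        "scanned %d piRNAs x %d transcripts: %d sites",
        len(pirnas), len(transcripts), len(table),
    )
    return table


def sites_to_frame(sites: list[TargetSite]) -> pd.DataFrame:
    rows = [
        (
            s.transcript_id, s.start, s.end, s.center, s.pirna_id,
            s.pirna_abundance, s.profile.seed_mm, s.profile.seed_gu,
            s.profile.nonseed_mm, s.profile.nonseed_gu,
        )
        for s in sites
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)
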