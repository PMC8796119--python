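"""Site-centered 22G-RNA density metaprofiles.

Reimplements the bigwig/deeptools-style computation natively: per-transcript
RPM coverage tracks (full-read coverage by default, optional 5'-end counting),
a site x offset matrix sampled in a window centered on each predicted target
site, and group/quartile mean profiles. Offsets run 5'->3' along the
transcript, so negative offsets are the 5'/upstream side of the site center.
Window cells falling outside the transcript are masked and excluded from
means.
"""
from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def coverage_track(
    alignments: pd.DataFrame,
    transcript_length: int,
    library_total: float,
    mode: str = "coverage",
) -> np.ndarray:
    """Per-position RPM density on one transcript.

    'coverage': every position covered by a read accumulates the read's RPM
    (bigwig semantics). 'five_prime': only the read's biological 5'-end
    position accumulates (start+length-1 for antisense reads).
    """
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    scale = 1e6 / library_total
    values = np.zeros(transcript_length)
    if alignments.empty:
        return values
    starts = alignments["start"].to_numpy(int)
    lengths = alignments["length"].to_numpy(int)
    weights = alignments["count"].to_numpy(float) * scale
    if (starts < 0).any() or (starts + lengths > transcript_length).any():
        raise ValueError("alignment outside transcript bounds")
    if mode == "coverage":
        diff = np.zeros(transcript_length + 1)
        np.add.at(diff, starts, weights)
        np.add.at(diff, starts + lengths, -weights)
        values = np.cumsum(diff[:-1])
    elif mode == "five_prime":
        anti = alignments["strand"].to_numpy() == "antisense"
        pos = np.where(anti, starts + lengths - 1, starts)
        np.add.at(values, pos, weights)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return values


def coverage_tracks(
    alignments: pd.DataFrame,
    transcript_lengths: Mapping[str, int],
    library_total: float,
    mode: str = "coverage",
) -> dict[str, np.ndarray]:
    """Tracks for every transcript in ``transcript_lengths`` (zeros if unread)."""
    tracks = {}
    grouped = dict(tuple(alignments.groupby("transcript_id", sort=False)))
    for tid, length in transcript_lengths.items():
        sub = grouped.get(tid)
        if sub is None:
            tracks[tid] = np.zeros(int(length))
        else:
            tracks[tid] = coverage_track(sub, int(length), library_total, mode)
    return tracks


def average_tracks(
    replicate_tracks: Sequence[Mapping[str, np.ndarray]],
) -> dict[str, np.ndarray]:
    """Elementwise mean across replicate track sets (same transcript universe)."""
    if not replicate_tracks:
        raise ValueError("no replicate track sets given")
    keys = set(replicate_tracks[0])
    for rep in replicate_tracks[1:]:
        if set(rep) != keys:
            raise ValueError("replicate track sets must cover the same transcripts")
    return {
        tid: np.mean([rep[tid] for rep in replicate_tracks], axis=0)
        for tid in replicate_tracks[0]
    }


@dataclass
class ProfileMatrix:
    """Rows = sites, columns = offsets -halfwidth..+halfwidth around centers."""

    matrix: np.ma.MaskedArray
    offsets: np.ndarray
    sites: pd.DataFrame
    n_skipped: int = 0

    @property
    def halfwidth(self) -> int:
        return int(self.offsets.max())

    def mean_profile(self, rows=None) -> np.ndarray:
        sub = self.matrix if rows is None else self.matrix[rows]
        return np.ma.mean(sub, axis=0).filled(np.nan)


def site_window_matrix(
    tracks: Mapping[str, np.ndarray],
    sites: pd.DataFrame,
    halfwidth: int = 100,
) -> ProfileMatrix:
    """Sample each track in a (2*halfwidth+1)-nt window around site centers.

    Sites on transcripts without a track are skipped (counted in
    ``n_skipped``); overlapping sites contribute independent rows.
    """
    offsets = np.arange(-halfwidth, halfwidth + 1)
    rows, kept = [], []
    n_skipped = 0
    for idx, site in sites.iterrows():
        track = tracks.get(site["transcript_id"])
        if track is None:
            n_skipped += 1
            continue
        center = int(site["center"])
        pos = center + offsets
        inside = (pos >= 0) & (pos < track.size)
        row = np.ma.masked_all(offsets.size)
        row[inside] = track[pos[inside]]
        rows.append(row)
        kept.append(idx)
    if n_skipped:
        logger.warning("site_window_matrix: skipped %d sites without tracks", n_skipped)
    matrix = (
        np.ma.stack(rows) if rows else np.ma.masked_all((0, offsets.size))
    )
    return ProfileMatrix(matrix, offsets, sites.loc[kept].reset_index(drop=True), n_skipped)


def group_mean_profiles(
    profile: ProfileMatrix, groups: Sequence[str]
) -> pd.DataFrame:
    """Mean profile per group label (offset x group table).

    ``groups`` is aligned with the matrix rows; typical labels are
    'target' (spermatogenic HRDE-1 targets) vs 'non-target'.
    """
    groups = np.asarray(groups)
    if groups.size != profile.matrix.shape[0]:
        raise ValueError("group labels must align with matrix rows")
    data = {}
    for label in pd.unique(groups):
        data[label] = profile.mean_profile(groups == label)
    return pd.DataFrame(data, index=pd.Index(profile.offsets, name="offset"))


def quartile_stratified_profiles(
    profile: ProfileMatrix, abundances: Sequence[float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Mean profiles for piRNA-abundance quartiles Q1 (least) .. Q4 (most).

    Sites are ranked by abundance with a deterministic
    (transcript_id, start) tie-break and split into 4 equal-as-possible
    groups. Returns (4 x n_offsets profile array, per-site quartile labels
    1-4 in matrix row order).
    """
    sites = profile.sites
    if abundances is None:
        abundances = sites["pirna_abundance"].to_numpy(float)
    abundances = np.asarray(abundances, dtype=float)
    n = abundances.size
    if n < 4:
        raise ValueError("need at least 4 sites for quartile stratification")
    if n != profile.matrix.shape[0]:
        raise ValueError("abundances must align with matrix rows")
    order = np.lexsort(
        (sites["start"].to_numpy(), sites["transcript_id"].to_numpy(), abundances)
    )
    quartiles = np.array_split(order, 4)
    labels = np.empty(n, dtype=int)
    profiles = np.empty((4, profile.offsets.size))
    for q, rows in enumerate(quartiles, start=1):
        labels[rows] = q
        profiles[q - 1] = profile.mean_profile(rows)
    return profiles, labels


def window_mass(mean_profile: np.ndarray, offsets: np.ndarray, lo: int, hi: int) -> float:
    """Sum of a mean profile over offsets in [lo, hi] (NaN columns ignored)."""
    sel = (offsets >= lo) & (offsets <= hi)
    return float(np.nansum(mean_profile[sel]))
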