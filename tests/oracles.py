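"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written naively (character loops, exhaustive search,
re-coded constants) and deliberately shares no code with the package paths
it checks.
"""
from itertools import permutations

import numpy as np

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def naive_pair_class(guide_base: str, target_base: str) -> str:
    if (guide_base, target_base) in _WC:
        return "WC"
    if (guide_base, target_base) in _GU:
        return "GU"
    return "MM"


def naive_duplex_counts(pirna: str, window: str) -> dict:
    """Counts for guide positions 2-21; position 1 pairs window[20] and is skipped."""
    counts = {"seed_mm": 0, "seed_gu": 0, "nonseed_mm": 0, "nonseed_gu": 0}
    for pos in range(2, 22):
        cls = naive_pair_class(pirna[pos - 1], window[21 - pos])
        region = "seed" if 2 <= pos <= 8 else "nonseed"
        if cls == "MM":
            counts[f"{region}_mm"] += 1
        elif cls == "GU":
            counts[f"{region}_gu"] += 1
    return counts


def naive_accept(counts: dict, global_mm_budget: bool = False) -> bool:
    if global_mm_budget:
        mm_ok = counts["seed_mm"] + counts["nonseed_mm"] <= 2
    else:
        mm_ok = counts["seed_mm"] == 0 and counts["nonseed_mm"] <= 2
    return mm_ok and counts["seed_gu"] <= 1 and counts["nonseed_gu"] <= 1


def naive_scan(pirna: str, transcript: str, global_mm_budget: bool = False):
    """All accepted windows as (start, counts), skipping windows with N."""
    hits = []
    for start in range(len(transcript) - 20):
        window = transcript[start : start + 21]
        if "N" in window:
            continue
        counts = naive_duplex_counts(pirna, window)
        if naive_accept(counts, global_mm_budget):
            hits.append((start, counts))
    return hits


def brute_force_matching(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal total distance over all one-to-one pairings (|a| == |b| <= 8)."""
    assert len(a) == len(b) <= 8
    cost = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    best = np.inf
    for perm in permutations(range(len(b))):
        best = min(best, sum(cost[i, j] for i, j in enumerate(perm)))
    return float(best)


def shifted_hamming_hits(candidate: str, genome: dict, max_mm: int, exempt=None) -> int:
    """Off-target count via per-shift equality accumulation (both strands)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(candidate))
    k = len(candidate)
    total = 0
    for seq_id, seq in genome.items():
        n = len(seq) - k + 1
        if n <= 0:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        hit = np.zeros(n, dtype=bool)
        for probe in (candidate, rc):
            penc = np.frombuffer(probe.encode(), dtype=np.uint8)
            mism = np.zeros(n, dtype=np.int32)
            for j in range(k):
                mism += arr[j : j + n] != penc[j]
            hit |= mism <= max_mm
        if exempt is not None and exempt[0] == seq_id:
            _, lo, hi = exempt
            pos = np.arange(n)
            hit &= ~((pos < hi) & (pos + k > lo))
        total += int(hit.sum())
    return total


def exact_hamming_hits(candidate: str, genome: dict, max_mm: int, exempt=None) -> int:
    """Pure-Python exact scan; only for very small genomes."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(candidate))
    k = len(candidate)
    total = 0
    for seq_id, seq in genome.items():
        for start in range(len(seq) - k + 1):
            if exempt is not None and exempt[0] == seq_id:
                _, lo, hi = exempt
                if start < hi and start + k > lo:
                    continue
            window = seq[start : start + k]
            if (
                sum(x != y for x, y in zip(window, candidate)) <= max_mm
                or sum(x != y for x, y in zip(window, rc)) <= max_mm
            ):
                total += 1
    return total


# Re-coded pinned melting-temperature constants (duplicate-formula oracle).
_NN = {
    "AA": (-7.8, -21.9), "AC": (-5.9, -12.3), "AG": (-9.1, -23.5),
    "AU": (-8.3, -23.9), "CA": (-9.0, -26.1), "CC": (-9.3, -23.2),
    "CG": (-16.3, -47.1), "CU": (-7.0, -19.7), "GA": (-5.5, -13.5),
    "GC": (-8.0, -17.1), "GG": (-12.8, -31.9), "GU": (-7.8, -21.6),
    "UA": (-7.8, -23.2), "UC": (-8.6, -22.9), "UG": (-10.4, -28.4),
    "UU": (-11.5, -36.4),
}


def naive_tm(candidate_dna: str, oligo_conc=0.05e-6, monovalent=1.04, formamide=25.0):
    comp = {"A": "U", "C": "G", "G": "C", "T": "A"}
    rna = "".join(comp[b] for b in reversed(candidate_dna))
    dh, ds = 1.9, -3.9
    for i in range(len(rna) - 1):
        h, s = _NN[rna[i : i + 2]]
        dh += h
        ds += s
    tm = dh * 1000.0 / (ds + 1.987 * np.log(oligo_conc / 4.0)) - 273.15
    return tm + 16.6 * np.log10(monovalent) - 0.72 * formamide
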