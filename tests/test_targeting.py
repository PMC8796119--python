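"""Pairing rules, duplex evaluation and transcript scanning."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pirnakit.sequences import revcomp_rna
from pirnakit.targeting import (
    PiRNA,
    TargetingConfig,
    Transcript,
    classify_base_pair,
    evaluate_duplex,
    scan_transcript,
    scan_transcriptome,
)

from .oracles import naive_accept, naive_duplex_counts, naive_scan

GUIDE = "UGAGGUAGUAGGUUGUAUAGU"  # fixed 21U guide used by the curated cases
BASES = "ACGU"

rna_strategy = st.text(alphabet=BASES, min_size=21, max_size=80)
guide_strategy = st.builds(
    lambda s: "U" + s, st.text(alphabet=BASES, min_size=20, max_size=20)
)


def mutate(window: str, guide: str, guide_pos: int, kind: str) -> str:
    """Introduce a MM or GU pair opposite a 1-based guide position."""
    wi = 21 - guide_pos
    g = guide[guide_pos - 1]
    if kind == "MM":
        new = g  # same-base pairs are always plain mismatches
    elif kind == "GU":
        new = {"G": "U", "U": "G"}[g]  # wobble partner of the guide base
    else:
        raise ValueError(kind)
    return window[:wi] + new + window[wi + 1 :]


def test_classify_base_pair_definitions():
    assert classify_base_pair("A", "U") == "WC"
    assert classify_base_pair("U", "A") == "WC"
    assert classify_base_pair("G", "C") == "WC"
    assert classify_base_pair("G", "U") == "GU"
    assert classify_base_pair("U", "G") == "GU"
    assert classify_base_pair("C", "U") == "MM"
    assert classify_base_pair("A", "A") == "MM"
    with pytest.raises(ValueError, match="X"):
        classify_base_pair("X", "A")


# (description, [(guide_pos, kind), ...], accepted under default rules)
CURATED_DUPLEXES = [
    ("perfect complement", [], True),
    ("position-1 mismatch exempt", [(1, "MM")], True),
    ("position-1 wobble exempt", [(1, "GU")], True),
    ("seed MM at 2", [(2, "MM")], False),
    ("seed MM at 3", [(3, "MM")], False),
    ("seed MM at 4", [(4, "MM")], False),
    ("seed MM at 5", [(5, "MM")], False),
    ("seed MM at 6", [(6, "MM")], False),
    ("seed MM at 7", [(7, "MM")], False),
    ("seed MM at 8", [(8, "MM")], False),
    ("one seed GU at 2", [(2, "GU")], True),
    ("one seed GU at 6", [(6, "GU")], True),
    ("one seed GU at 8", [(8, "GU")], True),
    ("two seed GU", [(2, "GU"), (6, "GU")], False),
    ("seed GU plus position-1 MM", [(6, "GU"), (1, "MM")], True),
    ("one non-seed MM", [(12, "MM")], True),
    ("two non-seed MM", [(12, "MM"), (15, "MM")], True),
    ("three non-seed MM", [(12, "MM"), (15, "MM"), (18, "MM")], False),
    ("two non-seed MM + one GU", [(12, "MM"), (15, "MM"), (9, "GU")], True),
    ("two non-seed MM + two GU", [(12, "MM"), (15, "MM"), (9, "GU"), (13, "GU")], False),
    ("one non-seed GU", [(13, "GU")], True),
    ("two non-seed GU", [(9, "GU"), (13, "GU")], False),
    ("GU not counted as MM: 2 MM + 1 GU + seed GU", [(12, "MM"), (15, "MM"), (9, "GU"), (6, "GU")], True),
    ("seed MM with clean non-seed", [(5, "MM")], False),
    ("everything at budget", [(1, "MM"), (6, "GU"), (12, "MM"), (15, "MM"), (9, "GU")], True),
    ("budget + one extra non-seed MM", [(1, "MM"), (6, "GU"), (12, "MM"), (15, "MM"), (18, "MM")], False),
    ("non-seed MM at boundary position 9", [(9, "MM")], True),
    ("non-seed MM at 21", [(21, "MM")], True),
    ("seed MM at boundary position 8 rejected", [(8, "MM"), (21, "MM")], False),
    ("three MM where one is at position 1", [(1, "MM"), (12, "MM"), (15, "MM")], True),
]


@pytest.mark.parametrize(
    "description,mutations,accepted",
    CURATED_DUPLEXES,
    ids=[c[0] for c in CURATED_DUPLEXES],
)
def test_pairing_rule_edge_cases(description, mutations, accepted):
    """Seed stringency, GU budgets and the position-1 exemption."""
    pirna = PiRNA("curated", GUIDE)
    window = revcomp_rna(GUIDE)
    for pos, kind in mutations:
        window = mutate(window, GUIDE, pos, kind)
    profile, ok = evaluate_duplex(pirna, window)
    assert ok is accepted, description
    # tallies agree with the naive per-position counter
    expected = naive_duplex_counts(GUIDE, window)
    assert profile.seed_mm == expected["seed_mm"]
    assert profile.seed_gu == expected["seed_gu"]
    assert profile.nonseed_mm == expected["nonseed_mm"]
    assert profile.nonseed_gu == expected["nonseed_gu"]
    assert profile.pair_classes[0] == "NA1"


def test_perfect_duplex_counts_zero():
    profile, ok = evaluate_duplex(PiRNA("p", GUIDE), revcomp_rna(GUIDE))
    assert ok
    assert (profile.seed_mm, profile.seed_gu, profile.nonseed_mm, profile.nonseed_gu) == (0, 0, 0, 0)


def test_global_mm_budget_reading():
    """Alternative rule: <=2 MM anywhere outside position 1."""
    cfg = TargetingConfig(global_mm_budget=True)
    pirna = PiRNA("p", GUIDE)
    w = mutate(mutate(revcomp_rna(GUIDE), GUIDE, 5, "MM"), GUIDE, 12, "MM")
    assert evaluate_duplex(pirna, w)[1] is False  # default: seed MM kills it
    assert evaluate_duplex(pirna, w, cfg)[1] is True  # global: 2 MM total
    w3 = mutate(w, GUIDE, 15, "MM")
    assert evaluate_duplex(pirna, w3, cfg)[1] is False  # 3 MM total


def test_wrong_window_length_rejected():
    with pytest.raises(ValueError, match="20"):
        evaluate_duplex(PiRNA("p", GUIDE), "A" * 20)


def test_scan_exact_complement_at_origin():
    tr = Transcript("t", revcomp_rna(GUIDE))
    sites = scan_transcript(PiRNA("p", GUIDE), tr)
    assert len(sites) == 1
    assert sites[0].start == 0 and sites[0].center == 10 and sites[0].end == 21


def test_scan_short_transcript_is_empty():
    assert scan_transcript(PiRNA("p", GUIDE), Transcript("t", "ACGU" * 5)) == []


def test_scan_skips_ambiguous_windows():
    seq = revcomp_rna(GUIDE) + "N" + revcomp_rna(GUIDE)
    sites = scan_transcript(PiRNA("p", GUIDE), Transcript("t", seq))
    assert [s.start for s in sites] == [0, 22]


@given(guide=guide_strategy, transcript=rna_strategy)
def test_scanner_agrees_with_bruteforce(guide, transcript):
    """Site sets and all per-site counts match naive window enumeration."""
    sites = scan_transcript(PiRNA("p", guide), Transcript("t", transcript))
    expected = naive_scan(guide, transcript)
    assert [s.start for s in sites] == [start for start, _ in expected]
    for site, (_, counts) in zip(sites, expected):
        assert site.profile.seed_mm == counts["seed_mm"]
        assert site.profile.seed_gu == counts["seed_gu"]
        assert site.profile.nonseed_mm == counts["nonseed_mm"]
        assert site.profile.nonseed_gu == counts["nonseed_gu"]


@given(
    guide=guide_strategy,
    prefix=st.text(alphabet=BASES, min_size=0, max_size=40),
    suffix=st.text(alphabet=BASES, min_size=0, max_size=40),
)
def test_embedded_reverse_complement_always_found(guide, prefix, suffix):
    """Embedding a guide's exact reverse complement at offset k yields start=k."""
    transcript = prefix + revcomp_rna(guide) + suffix
    sites = scan_transcript(PiRNA("p", guide), Transcript("t", transcript))
    assert len(prefix) in [s.start for s in sites]
    hit = next(s for s in sites if s.start == len(prefix))
    assert hit.center == len(prefix) + 10


@given(guide=guide_strategy, data=st.data())
def test_adding_nonseed_mismatch_never_creates_acceptance(guide, data):
    """Acceptance is monotone in the non-seed mismatch count."""
    window = revcomp_rna(guide)
    n_pre = data.draw(st.integers(0, 3))
    positions = data.draw(
        st.lists(st.integers(9, 21), min_size=n_pre + 1, max_size=n_pre + 1, unique=True)
    )
    for pos in positions[:-1]:
        window = mutate(window, guide, pos, "MM")
    _, before = evaluate_duplex(PiRNA("p", guide), window)
    worse = mutate(window, guide, positions[-1], "MM")
    _, after = evaluate_duplex(PiRNA("p", guide), worse)
    assert not (after and not before)


def test_sense_orientation_matches_oracle():
    """A transcript equal to the guide itself follows the oracle's verdict."""
    for seed in range(25):
        rng = np.random.default_rng(seed)
        guide = "U" + "".join(np.array(list(BASES))[rng.integers(0, 4, 20)])
        sites = scan_transcript(PiRNA("p", guide), Transcript("t", guide))
        assert [s.start for s in sites] == [s for s, _ in naive_scan(guide, guide)]


def test_scan_transcriptome_batch_and_ordering(rng):
    guides = []
    transcripts = []
    for i in range(2):
        g = "U" + "".join(np.array(list(BASES))[rng.integers(0, 4, 20)])
        guides.append(PiRNA(f"p{i}", g, abundance=float(i + 1)))
    for j in range(2):
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, 300)])
        # embed one perfect site per guide, far apart
        seq = (
            seq[:50] + revcomp_rna(guides[0].sequence)
            + seq[71:150] + revcomp_rna(guides[1].sequence) + seq[171:]
        )
        transcripts.append(Transcript(f"t{j}", seq))
    table = scan_transcriptome(guides, transcripts)
    embedded = table.merge(
        pd.DataFrame(
            [(t.id, 50, "p0") for t in transcripts]
            + [(t.id, 150, "p1") for t in transcripts],
            columns=["transcript_id", "start", "pirna_id"],
        ),
        on=["transcript_id", "start", "pirna_id"],
    )
    assert len(embedded) == 4
    assert list(table.columns[:4]) == ["transcript_id", "start", "end", "center"]
    ordered = table[["transcript_id", "start", "pirna_id"]].apply(tuple, axis=1)
    assert list(ordered) == sorted(ordered)


def test_scan_transcriptome_matches_bruteforce(rng):
    guides = [
        PiRNA(f"p{i}", "U" + "".join(np.array(list(BASES))[rng.integers(0, 4, 20)]))
        for i in range(50)
    ]
    transcripts = [
        Transcript(f"t{j}", "".join(np.array(list(BASES))[rng.integers(0, 4, 120)]))
        for j in range(20)
    ]
    table = scan_transcriptome(guides, transcripts)
    got = set(zip(table.pirna_id, table.transcript_id, table.start))
    expected = {
        (p.id, t.id, start)
        for p in guides
        for t in transcripts
        for start, _ in naive_scan(p.sequence, t.sequence)
    }
    assert got == expected


def test_scan_transcriptome_input_errors():
    t = Transcript("t", "ACGU" * 20)
    with pytest.raises(ValueError, match="empty piRNA"):
        scan_transcriptome([], [t])
    p = PiRNA("p", GUIDE)
    with pytest.raises(ValueError, match="duplicate"):
        scan_transcriptome([p], [t, t])


def test_pirna_validation():
    with pytest.raises(ValueError, match="22"):
        PiRNA("p", "U" + "A" * 21)
    with pytest.raises(ValueError):
        PiRNA("p", "A" * 21, strict=True)  # no 5' U in strict mode
    assert PiRNA("p", "A" * 21).sequence[0] == "A"  # warn-and-accept default
    assert PiRNA("p", "t" * 21).sequence == "U" * 21  # T/U normalization
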