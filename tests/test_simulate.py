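"""Synthetic-data generator: determinism, structure and parameter recovery."""
import hashlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from pirnakit import metaprofile, smallrna
from pirnakit.simulate import (
    SimConfig,
    as_pirna_objects,
    as_transcript_objects,
    make_pirnas_and_sites,
    make_transcriptome,
    simulate_22g_libraries,
    simulate_germline,
    simulate_spot_image,
    write_outputs,
)
from pirnakit.targeting import evaluate_duplex, scan_transcriptome


@pytest.fixture(scope="module")
def small_sim(small_config):
    tx = make_transcriptome(small_config)
    pirnas, tx, truth = make_pirnas_and_sites(small_config, tx)
    return small_config, tx, pirnas, truth


def test_transcriptome_counts_and_partition():
    cfg = SimConfig(
        seed=3, n_target=50, n_spermatogenic_nontarget=50, n_oogenic=100, n_other=300
    )
    tx = make_transcriptome(cfg)
    assert len(tx) == 500  # 100 spermatogenic + 100 oogenic + 300 other
    assert tx["gene_class"].value_counts().to_dict() == {
        "other": 300, "oogenic": 100, "spermatogenic": 100
    }
    assert tx["gene_id"].is_unique and tx["transcript_id"].is_unique
    lo, hi = cfg.transcript_length
    assert tx["length"].between(lo, hi).all()
    assert (tx["sequence"].str.len() == tx["length"]).all()


def test_generators_are_deterministic_under_seed(small_config):
    a = make_transcriptome(small_config)
    b = make_transcriptome(small_config)
    pd.testing.assert_frame_equal(a, b)
    other = make_transcriptome(replace(small_config, seed=small_config.seed + 1))
    assert not a["sequence"].equals(other["sequence"])


def test_written_outputs_are_byte_identical(tmp_path):
    cfg = SimConfig(
        seed=5, n_target=4, n_spermatogenic_nontarget=4, n_oogenic=2, n_other=10,
        transcript_length=(600, 700), n_violating_sites=2,
        library_depth=20_000, n_replicates=1, n_spots_per_channel=30,
    )
    write_outputs(cfg, tmp_path / "a")
    write_outputs(cfg, tmp_path / "b")
    for path_a in sorted((tmp_path / "a").iterdir()):
        path_b = tmp_path / "b" / path_a.name
        ha = hashlib.sha256(path_a.read_bytes()).hexdigest()
        hb = hashlib.sha256(path_b.read_bytes()).hexdigest()
        assert ha == hb, path_a.name
    assert f"seed={cfg.seed}" in (tmp_path / "a" / "pirnas.tsv").read_text()


def test_embedded_sites_satisfy_the_pairing_rule(small_sim):
    cfg, tx, pirnas, truth = small_sim
    seq = tx.set_index("transcript_id")["sequence"]
    guides = {p.id: p for p in as_pirna_objects(pirnas)}
    for row in truth.itertuples():
        window = seq[row.transcript_id][row.start : row.start + 21]
        _, ok = evaluate_duplex(guides[row.pirna_id], window)
        assert ok == (row.kind != "violating")


def test_scanner_recovers_embedded_truth(small_sim):
    cfg, tx, pirnas, truth = small_sim
    table = scan_transcriptome(as_pirna_objects(pirnas), as_transcript_objects(tx))
    found = set(zip(table.pirna_id, table.transcript_id, table.start))
    embedded = truth[truth.kind.isin(["target", "nontarget"])]
    assert all(
        (r.pirna_id, r.transcript_id, r.start) in found for r in embedded.itertuples()
    )
    violating = truth[truth.kind == "violating"]
    assert not any(
        (r.pirna_id, r.transcript_id, r.start) in found for r in violating.itertuples()
    )


def test_pirna_pool_structure(small_sim):
    cfg, tx, pirnas, truth = small_sim
    assert (pirnas["sequence"].str.len() == 21).all()
    assert (pirnas["sequence"].str[0] == "U").all()
    assert (pirnas["abundance"] > 0).all()
    # long tail: mean well above median
    assert pirnas["abundance"].mean() > 1.5 * pirnas["abundance"].median()


@pytest.fixture(scope="module")
def small_libraries(small_sim):
    cfg, tx, pirnas, truth = small_sim
    return simulate_22g_libraries(cfg, tx, pirnas, truth)


def test_library_depth_and_read_structure(small_sim, small_libraries):
    cfg, tx, _, _ = small_sim
    sim = small_libraries
    assert set(sim.totals.values()) == {cfg.library_depth}
    table = sim.libraries[("wt", "ip", 0)]
    assert (table["length"] == cfg.read_length).all()
    assert (table["strand"] == "antisense").all()
    assert (table["first_base"] == "G").all()
    lengths = tx.set_index("transcript_id")["length"]
    ends = table["start"] + table["length"]
    assert (table["start"] >= 0).all()
    assert (ends <= lengths[table["transcript_id"]].to_numpy()).all()


def _gene_rpm(sim, tx, key):
    gene_map = tx.set_index("transcript_id")["gene_id"]
    aln = smallrna.filter_22g(sim.libraries[key])
    return smallrna.gene_antisense_rpm(
        aln, gene_map, sim.totals[key], tx["gene_id"].to_numpy()
    )


def test_per_gene_counts_match_expected_shares(small_sim, small_libraries):
    """Realized per-gene RPM tracks the exact sampling probabilities."""
    cfg, tx, _, _ = small_sim
    sim = small_libraries
    got = _gene_rpm(sim, tx, ("wt", "input", 0))
    expected = sim.gene_probs["wt_input"] * 1e6
    resid = (got - expected) / np.sqrt(np.maximum(expected, 1.0))
    # multinomial: per-gene z-scores should look standard normal
    assert np.abs(resid).mean() < 2.0
    assert (np.abs(resid) < 6).all()


def test_ip_enrichment_fold_recovery(small_sim, small_libraries):
    cfg, tx, _, _ = small_sim
    sim = small_libraries
    ip = _gene_rpm(sim, tx, ("wt", "ip", 0))
    inp = _gene_rpm(sim, tx, ("wt", "input", 0))
    table, targets = smallrna.ip_enrichment(ip, inp)
    is_target = tx.set_index("gene_id")["is_target"]
    med = table["log2fc"][is_target.reindex(table.index).astype(bool)].median()
    assert med == pytest.approx(np.log2(cfg.ip_enrichment_fold), abs=0.1)
    true_targets = set(tx.loc[tx.is_target, "gene_id"])
    assert len(targets & true_targets) / len(true_targets) >= 0.95


def test_mutant_depletion_recovery(small_config, small_sim):
    """8-fold target depletion in the mutant IP: median log2fc near -3."""
    cfg8 = replace(small_config, mutant_depletion_fold=8.0)
    tx = make_transcriptome(cfg8)
    pirnas, tx, truth = make_pirnas_and_sites(cfg8, tx)
    sim = simulate_22g_libraries(cfg8, tx, pirnas, truth)
    mut = _gene_rpm(sim, tx, ("piwi", "ip", 0))
    wt = _gene_rpm(sim, tx, ("wt", "ip", 0))
    fc = smallrna.dependence_fold_change(mut, wt)
    is_target = tx.set_index("gene_id")["is_target"]
    med = fc[is_target.reindex(fc.index).astype(bool)].median()
    assert med == pytest.approx(-3.0, abs=0.15)


def test_site_reads_are_upstream_biased(small_sim, small_libraries):
    """In the wt IP, coverage near target sites sits at negative offsets."""
    cfg, tx, _, truth = small_sim
    sim = small_libraries
    key = ("wt", "ip", 0)
    aln = smallrna.filter_22g(sim.libraries[key])
    lengths = dict(zip(tx["transcript_id"], tx["length"]))
    tracks = metaprofile.coverage_tracks(aln, lengths, sim.totals[key])
    sites = truth[truth.kind == "target"].reset_index(drop=True)
    pm = metaprofile.site_window_matrix(tracks, sites)
    prof = pm.mean_profile()
    up = prof[pm.offsets <= 0].sum()
    down = prof[pm.offsets > 21].sum()  # past the paired window
    assert up > 5 * down


def test_germline_truth_and_channels(small_config):
    axis, spots, truth = simulate_germline(small_config)
    lo, hi = small_config.sperm_domain_um
    sperm = truth[truth.channel == "spermatogenic"]
    assert sperm["axial_position"].between(lo - 2, hi + 2).all()
    oog = truth[truth.channel == "oogenic"]
    assert (oog["axial_position"] < 0).all()
    assert len(spots) == 2 * small_config.n_spots_per_channel
    # loop point is the leftmost axis point and the arc-length origin
    assert axis.points[axis.loop_index, 0] == axis.points[:, 0].min()
    assert axis.signed_positions[axis.loop_index] == 0.0


def test_spot_image_truth_is_deterministic(small_config):
    img1, t1 = simulate_spot_image(small_config, n_spots=10)
    img2, t2 = simulate_spot_image(small_config, n_spots=10)
    assert np.array_equal(img1, img2)
    pd.testing.assert_frame_equal(t1, t2)
    assert img1.shape == small_config.image_shape
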