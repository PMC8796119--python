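"""Synthetic data with the statistical structure the analyses assume.

The generator emulates, at desk scale, the inputs of the analysis modules
together with machine-readable ground truth:

* a transcriptome with spermatogenic / oogenic / other gene classes, where a
  subset of spermatogenic genes are designated piRNA targets;
* a 21U piRNA pool with a long-tailed (lognormal) abundance distribution and
  exact-complement target sites embedded in target and non-target
  spermatogenic transcripts (plus deliberately rule-violating embeddings used
  as negative controls for the scanner);
* 22G-RNA libraries for {input, IP} x {wild-type, piwi-mutant} with
  replicates: read 5' ends of site-derived reads are drawn from a truncated
  geometric on the upstream side of the site center, background reads are
  uniform, IP libraries carry an exact fold-enrichment of target genes (the
  non-target share absorbs the complement, as in a real IP), and the
  piwi-mutant loses target-gene 22Gs by a configurable depletion factor;
* U-shaped germlines with a proximal spermatogenic expression domain and a
  distal oogenic domain, plus rendered 3D spot images with Gaussian PSF and
  Poisson noise.

Every generator is deterministic given ``SimConfig.seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .sequences import revcomp_rna
from .spatial import GermlineAxis
from .targeting import PIRNA_LENGTH, PiRNA, Transcript

RNA = np.array(list("ACGU"))

# per-generator stream tags so the functions are independently reproducible
_TAGS = {
    "transcriptome": 1,
    "pirnas": 2,
    "libraries": 3,
    "germline": 4,
    "image": 5,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic pipeline (see docs/methods.md)."""

    seed: int = 0
    # transcriptome
    n_target: int = 200
    n_spermatogenic_nontarget: int = 200
    n_oogenic: int = 200
    n_other: int = 400
    transcript_length: tuple[int, int] = (1000, 1800)
    # piRNA pool and sites
    sites_per_target: int = 2
    sites_per_nontarget: int = 2
    n_violating_sites: int = 50
    pirna_abundance_scale: float = 20.0  # median RPM
    pirna_abundance_sigma: float = 1.2  # lognormal shape (long-tailed)
    # 22G libraries
    library_depth: int = 1_000_000
    n_replicates: int = 2
    target_input_share: float = 0.15  # input library mass on target genes
    site_fraction: float = 0.8  # target-gene mass placed at sites
    ip_enrichment_fold: float = 4.0
    mutant_depletion_fold: float = 50.0
    upstream_geom_p: float = 0.05  # 5'-offset ~ -Geometric(p), truncated
    upstream_max_offset: int = 100
    read_length: int = 22
    # germline geometry (µm)
    arm_length_um: float = 100.0
    loop_radius_um: float = 15.0
    axis_step_um: float = 2.0
    sperm_domain_um: tuple[float, float] = (20.0, 60.0)
    oogenic_domain_um: tuple[float, float] = (-60.0, -5.0)
    n_spots_per_channel: int = 300
    spot_jitter_um: float = 3.0
    axis_max_dist_um: float = 10.0
    # imaging
    image_shape: tuple[int, int, int] = (24, 128, 128)
    voxel_size_um: tuple[float, float, float] = (0.3, 0.13, 0.13)
    psf_sigma_um: tuple[float, float, float] = (0.35, 0.15, 0.15)
    snr: float = 10.0
    background: float = 100.0


def _rng(config: SimConfig, tag: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, _TAGS[tag], extra])


# ---------------------------------------------------------------------------
# transcriptome and piRNA pool


def make_transcriptome(config: SimConfig) -> pd.DataFrame:
    """Random transcripts with gene classes and target designations."""
    rng = _rng(config, "transcriptome")
    rows = []
    classes = (
        ["spermatogenic"] * (config.n_target + config.n_spermatogenic_nontarget)
        + ["oogenic"] * config.n_oogenic
        + ["other"] * config.n_other
    )
    lo, hi = config.transcript_length
    for i, cls in enumerate(classes):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(RNA[rng.integers(0, 4, length)])
        gene = f"g{i:05d}"
        rows.append(
            {
                "transcript_id": f"{gene}.t1",
                "gene_id": gene,
                "gene_class": cls,
                "is_target": i < config.n_target,
                "length": length,
                "sequence": seq,
            }
        )
    return pd.DataFrame(rows)


def _site_positions(rng, length: int, n_sites: int, margin: int = 160) -> list[int]:
    """Non-overlapping embedding starts, away from transcript ends."""
    span = length - 2 * margin - PIRNA_LENGTH
    lanes = np.array_split(np.arange(span), n_sites)
    return [
        margin + int(rng.integers(lane[0], lane[-1] - PIRNA_LENGTH + 1))
        if len(lane) > PIRNA_LENGTH else margin + int(lane[0])
        for lane in lanes
    ]


def make_pirnas_and_sites(
    config: SimConfig, transcriptome: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """piRNA pool + embedded true sites.

    Returns (pirnas, transcriptome with embedded sites, truth table). Truth
    rows are kind 'target' (exact complements on designated target genes,
    one distinct piRNA each), 'nontarget' (exact complements on
    non-target spermatogenic genes, piRNAs drawn from the pool) or
    'violating' (three non-seed same-base mismatches; must be rejected by
    the scanner).
    """
    rng = _rng(config, "pirnas")
    n_pirnas = config.n_target * config.sites_per_target
    seqs = ["U" + "".join(RNA[rng.integers(0, 4, PIRNA_LENGTH - 1)]) for _ in range(n_pirnas)]
    abundance = config.pirna_abundance_scale * np.exp(
        config.pirna_abundance_sigma * rng.standard_normal(n_pirnas)
    )
    pirnas = pd.DataFrame(
        {
            "pirna_id": [f"21ur-{i:04d}" for i in range(n_pirnas)],
            "sequence": seqs,
            "abundance": abundance,
        }
    )

    transcriptome = transcriptome.copy()
    seq_by_row = transcriptome["sequence"].tolist()
    truth_rows = []

    def embed(row_idx: int, start: int, window: str, pirna_idx: int, kind: str):
        s = seq_by_row[row_idx]
        seq_by_row[row_idx] = s[:start] + window + s[start + PIRNA_LENGTH:]
        truth_rows.append(
            {
                "pirna_id": pirnas.at[pirna_idx, "pirna_id"],
                "transcript_id": transcriptome.at[row_idx, "transcript_id"],
                "gene_id": transcriptome.at[row_idx, "gene_id"],
                "start": start,
                "center": start + 10,
                "kind": kind,
                "pirna_abundance": float(pirnas.at[pirna_idx, "abundance"]),
            }
        )

    target_rows = transcriptome.index[transcriptome["is_target"]].tolist()
    k = 0
    for row_idx in target_rows:
        length = int(transcriptome.at[row_idx, "length"])
        for start in _site_positions(rng, length, config.sites_per_target):
            embed(row_idx, start, revcomp_rna(seqs[k]), k, "target")
            k += 1

    nontarget_rows = transcriptome.index[
        (transcriptome["gene_class"] == "spermatogenic") & ~transcriptome["is_target"]
    ].tolist()
    for row_idx in nontarget_rows:
        length = int(transcriptome.at[row_idx, "length"])
        for start in _site_positions(rng, length, config.sites_per_nontarget):
            j = int(rng.integers(0, n_pirnas))
            embed(row_idx, start, revcomp_rna(seqs[j]), j, "nontarget")

    other_rows = transcriptome.index[transcriptome["gene_class"] == "other"].tolist()
    for v in range(min(config.n_violating_sites, len(other_rows))):
        row_idx = other_rows[v]
        length = int(transcriptome.at[row_idx, "length"])
        start = _site_positions(rng, length, 1)[0]
        j = int(rng.integers(0, n_pirnas))
        window = list(revcomp_rna(seqs[j]))
        # same-base substitution is always a plain mismatch (never GU);
        # guide position i pairs window index 21-i
        for guide_pos in (12, 15, 18):
            window[PIRNA_LENGTH - guide_pos] = seqs[j][guide_pos - 1]
        embed(row_idx, start, "".join(window), j, "violating")

    transcriptome["sequence"] = seq_by_row
    truth = pd.DataFrame(truth_rows)
    return pirnas, transcriptome, truth


def as_pirna_objects(pirnas: pd.DataFrame) -> list[PiRNA]:
    return [
        PiRNA(r.pirna_id, r.sequence, r.abundance) for r in pirnas.itertuples()
    ]


def as_transcript_objects(transcriptome: pd.DataFrame) -> list[Transcript]:
    return [
        Transcript(r.transcript_id, r.sequence, r.gene_id, r.gene_class)
        for r in transcriptome.itertuples()
    ]


# ---------------------------------------------------------------------------
# 22G-RNA libraries


@dataclass
class LibrarySim:
    """Simulated alignment tables plus the exact sampling probabilities."""

    libraries: dict[tuple[str, str, int], pd.DataFrame]
    totals: dict[tuple[str, str, int], int]
    gene_probs: pd.DataFrame  # genes x (genotype, fraction) expected share
    config: SimConfig


def _library_probs(config, bg_nontarget, bg_target, site_mass, genotype, fraction):
    """Exact composition of one library.

    Input: target genes hold ``target_input_share`` of the library. IP:
    target genes hold exactly fold x their input share; non-targets absorb
    the complement. piwi mutant: target share divided by the depletion fold,
    again absorbed by non-targets. All vectors returned sum to 1.
    """
    fold = config.ip_enrichment_fold if fraction == "ip" else 1.0
    t_share = config.target_input_share * fold
    if t_share >= 1.0:
        raise ValueError("ip_enrichment_fold x target_input_share must be < 1")
    if genotype == "piwi":
        t_share = t_share / config.mutant_depletion_fold
    scale_t = t_share / config.target_input_share
    scale_n = (1.0 - t_share) / (1.0 - config.target_input_share)
    return bg_nontarget * scale_n, bg_target * scale_t, site_mass * scale_t


def simulate_22g_libraries(
    config: SimConfig,
    transcriptome: pd.DataFrame,
    pirnas: pd.DataFrame,
    truth_sites: pd.DataFrame,
) -> LibrarySim:
    """Multinomial 22G-RNA libraries for {wt, piwi} x {input, ip} x replicates.

    Within target genes a ``site_fraction`` of the input mass sits at the
    embedded 'target' truth sites, allocated across sites proportionally to
    piRNA abundance; site reads are antisense 22-mers whose 5' ends fall
    upstream of the site center (truncated geometric offsets). All other
    reads are placed uniformly.
    """
    rng = _rng(config, "libraries")
    genes = transcriptome.set_index("gene_id")
    target_mask = genes["is_target"].to_numpy()
    lengths = genes["length"].to_numpy()
    tids = genes["transcript_id"].to_numpy()
    gene_ids = genes.index.to_numpy()

    w = rng.gamma(2.0, 1.0, len(genes)) + 0.05
    T = config.target_input_share
    bg_nontarget = np.where(~target_mask, w, 0.0)
    bg_nontarget *= (1.0 - T) / bg_nontarget.sum()
    bg_target = np.where(target_mask, w, 0.0)
    bg_target *= (1.0 - config.site_fraction) * T / bg_target.sum()

    sites = truth_sites[truth_sites["kind"] == "target"].reset_index(drop=True)
    site_mass = sites["pirna_abundance"].to_numpy(float).copy()
    site_mass *= config.site_fraction * T / site_mass.sum()
    site_gene_idx = pd.Index(gene_ids).get_indexer(sites["gene_id"])
    site_tid = sites["transcript_id"].to_numpy()
    site_center = sites["center"].to_numpy(int)
    site_len = lengths[site_gene_idx]

    rl = config.read_length
    libraries, totals = {}, {}
    prob_cols = {}
    for genotype in ("wt", "piwi"):
        for fraction in ("input", "ip"):
            p_nt, p_tbg, p_site = _library_probs(
                config, bg_nontarget, bg_target, site_mass, genotype, fraction
            )
            gene_p = p_nt + p_tbg
            np.add.at(gene_p, site_gene_idx, p_site)
            prob_cols[f"{genotype}_{fraction}"] = gene_p
            probs = np.concatenate([p_nt + p_tbg, p_site])
            for rep in range(config.n_replicates):
                counts = rng.multinomial(config.library_depth, probs)
                gene_counts = counts[: len(genes)]
                site_counts = counts[len(genes):]
                frames = []
                for gi in np.flatnonzero(gene_counts):
                    n = gene_counts[gi]
                    starts = rng.integers(0, lengths[gi] - rl + 1, n)
                    uniq, cnt = np.unique(starts, return_counts=True)
                    frames.append(
                        pd.DataFrame(
                            {
                                "transcript_id": tids[gi],
                                "start": uniq,
                                "count": cnt,
                            }
                        )
                    )
                for sj in np.flatnonzero(site_counts):
                    n = site_counts[sj]
                    offset = -np.minimum(
                        rng.geometric(config.upstream_geom_p, n),
                        config.upstream_max_offset,
                    )
                    five_prime = site_center[sj] + offset
                    starts = np.clip(five_prime - (rl - 1), 0, site_len[sj] - rl)
                    uniq, cnt = np.unique(starts, return_counts=True)
                    frames.append(
                        pd.DataFrame(
                            {
                                "transcript_id": site_tid[sj],
                                "start": uniq,
                                "count": cnt,
                            }
                        )
                    )
                table = pd.concat(frames, ignore_index=True)
                table = (
                    table.groupby(["transcript_id", "start"], as_index=False)["count"]
                    .sum()
                )
                table["read_id"] = [
                    f"{genotype}.{fraction}.r{rep}.{i}" for i in range(len(table))
                ]
                table["length"] = rl
                table["strand"] = "antisense"
                table["first_base"] = "G"
                key = (genotype, fraction, rep)
                libraries[key] = table[
                    ["read_id", "transcript_id", "start", "length",
                     "strand", "first_base", "count"]
                ]
                totals[key] = int(table["count"].sum())
    gene_probs = pd.DataFrame(prob_cols, index=pd.Index(gene_ids, name="gene_id"))
    return LibrarySim(libraries, totals, gene_probs, config)


# ---------------------------------------------------------------------------
# germline geometry, spots and images


def make_axis(config: SimConfig) -> GermlineAxis:
    """U-shaped centerline: distal arm -> loop (leftmost point) -> proximal arm."""
    r = config.loop_radius_um
    step = config.axis_step_um
    xs = np.arange(config.arm_length_um, 0.0, -step)
    distal = np.column_stack([xs, np.full_like(xs, r), np.zeros_like(xs)])
    n_arc = max(int(np.pi * r / step), 4)
    theta = np.linspace(np.pi / 2, 3 * np.pi / 2, n_arc + 1)
    bend = np.column_stack([r * np.cos(theta) - 0.0, r * np.sin(theta), np.zeros_like(theta)])
    xs2 = np.arange(step, config.arm_length_um + step / 2, step)
    proximal = np.column_stack([xs2, np.full_like(xs2, -r), np.zeros_like(xs2)])
    points = np.vstack([distal, bend, proximal])
    loop_index = int(np.argmin(points[:, 0]))
    return GermlineAxis(points, loop_index)


def simulate_germline(
    config: SimConfig, index: int = 0
) -> tuple[GermlineAxis, pd.DataFrame, pd.DataFrame]:
    """One germline: axis, per-channel spots near it, and a truth table.

    The spermatogenic channel occupies a proximal domain (positive axial
    positions, held away from the loop); the oogenic channel sits on the
    distal side of the loop.
    """
    rng = _rng(config, "germline", index)
    axis = make_axis(config)
    signed = axis.signed_positions
    spots_rows, truth_rows = [], []
    domains = {
        "spermatogenic": config.sperm_domain_um,
        "oogenic": config.oogenic_domain_um,
    }
    for channel, (lo, hi) in domains.items():
        s = rng.uniform(lo, hi, config.n_spots_per_channel)
        vidx = np.clip(
            np.searchsorted(signed, s), 1, len(signed) - 1
        )
        vidx -= np.abs(signed[vidx - 1] - s) < np.abs(signed[vidx] - s)
        base = axis.points[vidx]
        direction = rng.standard_normal((len(s), 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        radius = rng.uniform(0, config.spot_jitter_um, len(s))
        xyz = base + direction * radius[:, None]
        for i in range(len(s)):
            spots_rows.append(
                {"channel": channel, "x": xyz[i, 0], "y": xyz[i, 1], "z": xyz[i, 2]}
            )
            truth_rows.append(
                {
                    "channel": channel,
                    "axial_position": float(signed[vidx[i]]),
                    "domain_lo": lo,
                    "domain_hi": hi,
                }
            )
    return axis, pd.DataFrame(spots_rows), pd.DataFrame(truth_rows)


def simulate_spot_image(
    config: SimConfig, n_spots: int = 20, index: int = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Poisson-noised 3D stack of Gaussian spots at the configured SNR.

    Spots sit at voxel centers with pairwise separation enforced; the truth
    table carries voxel indices and physical coordinates. Spot amplitude is
    ``snr * sqrt(background)`` (the shot-noise SD of the background).
    """
    rng = _rng(config, "image", index)
    shape = np.asarray(config.image_shape)
    voxel = np.asarray(config.voxel_size_um)
    sigma_vox = np.asarray(config.psf_sigma_um) / voxel
    margin = np.ceil(4 * sigma_vox).astype(int) + 1
    min_sep_vox = 8.0

    coords = []
    while len(coords) < n_spots:
        c = np.array(
            [rng.integers(margin[d], shape[d] - margin[d]) for d in range(3)]
        )
        if all(np.linalg.norm((c - p) * voxel / voxel[1]) >= min_sep_vox for p in coords):
            coords.append(c)
    coords = np.asarray(coords)

    amplitude = config.snr * np.sqrt(config.background)
    clean = np.full(tuple(shape), config.background, dtype=float)
    half = np.ceil(4 * sigma_vox).astype(int)
    grids = [np.arange(-h, h + 1) for h in half]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    kernel = amplitude * np.exp(
        -0.5 * (
            (zz / sigma_vox[0]) ** 2
            + (yy / sigma_vox[1]) ** 2
            + (xx / sigma_vox[2]) ** 2
        )
    )
    for c in coords:
        sl = tuple(
            slice(c[d] - half[d], c[d] + half[d] + 1) for d in range(3)
        )
        clean[sl] += kernel
    image = rng.poisson(clean).astype(float)
    truth = pd.DataFrame(
        {
            "zi": coords[:, 0], "yi": coords[:, 1], "xi": coords[:, 2],
            "z": coords[:, 0] * voxel[0],
            "y": coords[:, 1] * voxel[1],
            "x": coords[:, 2] * voxel[2],
        }
    )
    return image, truth


# ---------------------------------------------------------------------------
# file output (used by the CLI)


def write_outputs(config: SimConfig, outdir: str | Path, render_image: bool = False) -> None:
    """Write the full synthetic dataset as FASTA/TSV/CSV (seed in headers)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# pirnakit synthetic data; seed={config.seed}\n"

    transcriptome = make_transcriptome(config)
    pirnas, transcriptome, truth = make_pirnas_and_sites(config, transcriptome)

    with open(outdir / "transcripts.fasta", "w") as fh:
        for r in transcriptome.itertuples():
            fh.write(
                f">{r.transcript_id} gene={r.gene_id} class={r.gene_class} seed={config.seed}\n"
            )
            for i in range(0, len(r.sequence), 80):
                fh.write(r.sequence[i : i + 80] + "\n")
    with open(outdir / "gene_classes.tsv", "w") as fh:
        fh.write(header)
        transcriptome[["transcript_id", "gene_id", "gene_class"]].to_csv(
            fh, sep="\t", index=False
        )
    with open(outdir / "pirnas.tsv", "w") as fh:
        fh.write(header)
        pirnas.to_csv(fh, sep="\t", index=False)
    with open(outdir / "true_sites.tsv", "w") as fh:
        fh.write(header)
        truth.to_csv(fh, sep="\t", index=False)

    sim = simulate_22g_libraries(config, transcriptome, pirnas, truth)
    for (genotype, fraction, rep), table in sim.libraries.items():
        path = outdir / f"alignments_{genotype}_{fraction}_rep{rep}.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            table.to_csv(fh, sep="\t", index=False)

    axis, spots, spot_truth = simulate_germline(config)
    axis_df = pd.DataFrame(axis.points, columns=["x", "y", "z"])
    axis_df["is_loop"] = [i == axis.loop_index for i in range(len(axis_df))]
    for name, df in (
        ("axis.csv", axis_df), ("spots.csv", spots), ("spot_truth.csv", spot_truth),
    ):
        with open(outdir / name, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    if render_image:
        import tifffile

        image, img_truth = simulate_spot_image(config)
        tifffile.imwrite(outdir / "spots.tif", image.astype(np.float32))
        with open(outdir / "image_truth.csv", "w") as fh:
            fh.write(header)
            img_truth.to_csv(fh, index=False)
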