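"""Deterministic synthetic fixtures: toy genomes, feature tracks, planted
motifs, scored tracks, gene annotations, and foreground definitions.

Everything the pipeline consumes can be generated here from a single seed,
so every stage is testable end to end without downloads. Background
sequence is i.i.d. (no Markov structure) and the PWM-scoring background is
set to the generator's base composition, keeping log-odds calibration
exact. Fixture CRRs are produced by running the real CRR builder on the
synthetic feature tracks, so the builder participates in every end-to-end
test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .crr import CrrBuildConfig, build_crr_database
from .pwm import ALPHABET, PWM, write_pwms_cb
from .regions import GeneAnnotation, GeneEntry, GenomicRegion, RegionCollection, write_bed
from .scoring import GenomeSequences

__all__ = [
    "FixtureBundle",
    "make_genome",
    "make_pwm",
    "plant_motif",
    "make_track",
    "make_case",
    "write_bundle",
]

_BASES = np.array(list(ALPHABET))


def make_genome(
    seed: int, chrom_sizes: dict[str, int], gc: float = 0.5, tag: str = "toy"
) -> GenomeSequences:
    """i.i.d. random genome with P(G) + P(C) = gc; deterministic per seed."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    rng = np.random.default_rng(seed)
    seqs = {
        chrom: "".join(_BASES[rng.choice(4, size=size, p=probs)])
        for chrom, size in chrom_sizes.items()
    }
    return GenomeSequences(tag, seqs)


def make_pwm(
    rng: np.random.Generator,
    motif_id: str,
    length: int = 8,
    info: float = 8.0,
    background: np.ndarray | None = None,
) -> PWM:
    """Random informative PWM: per column, a Dirichlet draw sharpened
    toward a random consensus base (*info* = concentration on it)."""
    alpha = np.ones((length, 4))
    consensus = rng.integers(0, 4, size=length)
    alpha[np.arange(length), consensus] = info
    mat = np.vstack([rng.dirichlet(alpha[i]) for i in range(length)])
    mat = np.clip(mat, 1e-4, None)
    mat /= mat.sum(axis=1, keepdims=True)
    bg = background if background is not None else np.full(4, 0.25)
    return PWM(motif_id, mat, bg)


def plant_motif(
    genome: GenomeSequences,
    crrs: RegionCollection,
    pwm: PWM,
    target_region_ids: list[str],
    sites_per_region: int = 1,
    strength: float = 0.0,
    seed: int = 0,
) -> tuple[GenomeSequences, list[dict]]:
    """Write sampled motif instances into target regions; return the new
    genome and a truth record of every insertion.

    *strength* is a consensus-sampling temperature: column probabilities
    are sharpened as p^(1/t) before sampling, and t -> 0 inserts the
    consensus exactly. Sites within one region occupy disjoint equal
    slots. Regions too short for the requested sites are an error.
    """
    rng = np.random.default_rng(seed)
    L = len(pwm)
    sequences = {c: list(s) for c, s in genome.sequences.items()}
    truth: list[dict] = []
    for rid in target_region_ids:
        region = crrs[rid]
        if sites_per_region <= 0:
            continue
        slot = len(region) // sites_per_region
        if slot < L:
            raise ValueError(
                f"region {rid} too short for {sites_per_region} site(s) of length {L}"
            )
        ortho = genome.orthologs
        if ortho is not None:
            if rid not in ortho:
                continue
            chrom, rstart, rend = ortho[rid]
        else:
            chrom, rstart, rend = region.chrom, region.start, region.end
        for k in range(sites_per_region):
            if strength <= 0:
                site = pwm.consensus()
            else:
                site = "".join(
                    ALPHABET[_sample_sharpened(rng, col, strength)]
                    for col in pwm.matrix
                )
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                site = _revcomp(site)
            offset = int(rng.integers(0, slot - L + 1))
            pos = rstart + k * slot + offset
            sequences[chrom][pos : pos + L] = list(site)
            truth.append(
                {
                    "region_id": rid,
                    "chrom": chrom,
                    "pos": pos,
                    "strand": strand,
                    "site": site,
                    "strength": strength,
                }
            )
    new_genome = GenomeSequences(
        genome.tag, {c: "".join(s) for c, s in sequences.items()}, genome.orthologs
    )
    return new_genome, truth


def _sample_sharpened(rng: np.random.Generator, col: np.ndarray, t: float) -> int:
    p = col ** (1.0 / t)
    p /= p.sum()
    return int(rng.choice(4, p=p))


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def make_track(
    crrs: RegionCollection,
    enriched_region_ids: list[str],
    signal_high: float = 10.0,
    signal_low: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    track_id: str = "track",
) -> RegionCollection:
    """One scored peak per CRR: Gaussian-noised signal, high mean on the
    enriched regions."""
    if not signal_high > signal_low >= 0:
        raise ValueError("need signal_high > signal_low >= 0")
    rng = np.random.default_rng(seed)
    enriched = set(enriched_region_ids)
    peaks: list[GenomicRegion] = []
    scores: dict[str, float] = {}
    for i, r in enumerate(crrs):
        pid = f"{track_id}_p{i}"
        peaks.append(GenomicRegion(r.chrom, r.start, r.end, pid))
        mean = signal_high if r.region_id in enriched else signal_low
        scores[pid] = float(max(0.0, mean + rng.normal(0.0, noise_sd)))
    return RegionCollection(peaks, crrs.genome_tag, scores)


# ---------------------------------------------------------------------------
# Full fixture bundle
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """Everything one end-to-end run needs, plus ground truth."""

    seed: int
    scale: str
    genomes: list[GenomeSequences]
    chrom_sizes: dict[str, int]
    feature_sets: list[RegionCollection]
    insulators: RegionCollection
    exons: RegionCollection
    crrs: RegionCollection
    build_config: CrrBuildConfig
    pwms: list[PWM]
    tracks: dict[str, RegionCollection]
    annotation: GeneAnnotation
    foreground_peaks: RegionCollection
    foreground_genes: list[str]
    truth: dict = field(default_factory=dict)
    auc_fraction: float = 0.2


_SCALES = {
    # per-chromosome slot layout: (n_chroms, chrom_size, slot_spacing)
    "tiny": (2, 50_000, 500),
    "small": (4, 250_000, 500),
}


def make_case(seed: int, scale: str = "tiny") -> FixtureBundle:
    """A complete deterministic study: genomes, CRRs (via the real
    builder), 20 motifs (one planted), 5 tracks (one enriched), gene
    annotation with introns, and region-mode + gene-mode foregrounds over
    the same truth.

    The tiny scale is 2 chromosomes x 50 kb yielding ~200 CRRs; the build
    targets 400 bp regions (min 30 bp) and analyses use an AUC window of
    the top 20% of the database (a window at least as large as the
    foreground, mirroring the genome-scale default where the 0.5% window
    far exceeds typical input sizes) — the same procedure as a genome-scale
    run, at desk scale. The planted motif is written into 21 of the 30
    foreground regions (70%).
    """
    if scale not in _SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    n_chrom, chrom_size, spacing = _SCALES[scale]
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": chrom_size for i in range(n_chrom)}
    tag = f"toy_{scale}"

    # --- builder inputs: 3 feature tracks + insulators + exons ------------
    slots: list[tuple[str, int]] = []
    for chrom, size in chrom_sizes.items():
        for s in range(200, size - 600, spacing):
            slots.append((chrom, s))
    feature_sets = []
    for t in range(3):
        regs = []
        for i, (chrom, s) in enumerate(slots):
            if rng.random() < 0.55:  # each track covers about half the slots
                a = s + int(rng.integers(0, 60))
                b = a + int(rng.integers(100, 240))
                regs.append(GenomicRegion(chrom, a, b, f"f{t}_{i}"))
        feature_sets.append(RegionCollection(regs, tag))
    ins_regs, ex_regs = [], []
    for i, (chrom, s) in enumerate(slots):
        u = rng.random()
        if u < 0.05:  # insulator dominating the slot
            ins_regs.append(GenomicRegion(chrom, s, s + 200, f"ins_{i}"))
        elif u < 0.10:  # small exon inside the slot -> split
            ex_regs.append(GenomicRegion(chrom, s + 80, s + 120, f"ex_{i}"))
    insulators = RegionCollection(ins_regs, tag)
    exons = RegionCollection(ex_regs, tag)
    config = CrrBuildConfig(min_size=30, target_size=400)
    crrs = build_crr_database(feature_sets, insulators, exons, config, chrom_sizes)

    # --- genomes: base + one "ortholog" genome ----------------------------
    gc = 0.5
    base = make_genome(int(rng.integers(2**31)), chrom_sizes, gc, tag=f"{tag}_g1")
    ortho_map = {
        r.region_id: (r.chrom, r.start, r.end)
        for r in crrs
        if rng.random() > 0.1  # ~10% of regions lack an ortholog
    }
    second = make_genome(
        int(rng.integers(2**31)), chrom_sizes, gc, tag=f"{tag}_g2"
    )
    second.orthologs = ortho_map

    # --- motifs: one planted + decoys -------------------------------------
    bg = np.full(4, 0.25)
    n_motifs = 20
    pwms = [
        make_pwm(rng, f"motif_{i:02d}", length=int(rng.integers(6, 11)), background=bg)
        for i in range(n_motifs)
    ]
    planted_pwm = pwms[0]

    # --- foreground: 30 CRRs, motif planted in 21 (70%) -------------------
    usable = [r.region_id for r in crrs if len(r) >= 3 * len(planted_pwm)]
    fg_ids = list(rng.choice(usable, size=min(30, len(usable)), replace=False))
    n_planted = max(1, int(round(0.7 * len(fg_ids))))
    planted_ids = fg_ids[:n_planted]
    base, truth_sites_1 = plant_motif(
        base, crrs, planted_pwm, planted_ids, sites_per_region=3,
        strength=0.3, seed=int(rng.integers(2**31)),
    )
    second, truth_sites_2 = plant_motif(
        second, crrs, planted_pwm, planted_ids, sites_per_region=3,
        strength=0.3, seed=int(rng.integers(2**31)),
    )

    # --- tracks: one enriched on the planted foreground -------------------
    tracks: dict[str, RegionCollection] = {}
    for t in range(5):
        enriched = fg_ids if t == 0 else []
        tracks[f"track_{t}"] = make_track(
            crrs,
            enriched,
            signal_high=10.0,
            signal_low=1.0,
            noise_sd=1.0,
            seed=int(rng.integers(2**31)),
            track_id=f"track_{t}",
        )

    # --- gene annotation: one gene per foreground CRR + decoy genes -------
    entries: dict[str, GeneEntry] = {}
    for i, rid in enumerate(fg_ids):
        r = crrs[rid]
        strand = "+" if i % 2 == 0 else "-"
        tss = min(max(0, r.midpoint + int(rng.integers(-200, 200))),
                  chrom_sizes[r.chrom] - 1)
        intron_start = min(tss + 500, chrom_sizes[r.chrom] - 400)
        entries[f"g{i:03d}"] = GeneEntry(
            r.chrom, strand, tss, [(intron_start, intron_start + 300)]
        )
    for j in range(20):  # decoy genes far from the foreground
        chrom = f"chr{(j % n_chrom) + 1}"
        tss = int(rng.integers(0, chrom_sizes[chrom]))
        entries[f"decoy{j:02d}"] = GeneEntry(chrom, "+", tss, [])
    annotation = GeneAnnotation(entries)
    fg_genes = [f"g{i:03d}" for i in range(len(fg_ids))]

    # --- region-mode foreground: peaks covering the foreground CRRs -------
    peak_regs, peak_scores = [], {}
    for i, rid in enumerate(fg_ids):
        r = crrs[rid]
        pid = f"peak_{i}"
        peak_regs.append(GenomicRegion(r.chrom, r.start, r.end, pid))
        peak_scores[pid] = float(rng.uniform(5, 50))
    foreground_peaks = RegionCollection(peak_regs, tag, peak_scores)

    truth = {
        "planted_motif": planted_pwm.motif_id,
        "planted_region_ids": list(planted_ids),
        "foreground_ids": list(fg_ids),
        "enriched_track": "track_0",
        "sites": truth_sites_1 + truth_sites_2,
        "seed": seed,
    }
    return FixtureBundle(
        seed=seed,
        scale=scale,
        genomes=[base, second],
        chrom_sizes=chrom_sizes,
        feature_sets=feature_sets,
        insulators=insulators,
        exons=exons,
        crrs=crrs,
        build_config=config,
        pwms=pwms,
        tracks=tracks,
        annotation=annotation,
        foreground_peaks=foreground_peaks,
        foreground_genes=fg_genes,
        truth=truth,
        auc_fraction=0.2,
    )


def write_bundle(bundle: FixtureBundle, out_dir: str | Path) -> None:
    """Persist every fixture file (FASTA, BEDs, PWMs, TSVs, truth.json);
    regenerating with the same seed reproduces each file byte-identically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for genome in bundle.genomes:
        with open(out / f"genome_{genome.tag}.fa", "w") as fh:
            for chrom in sorted(genome.sequences):
                fh.write(f">{chrom}\n")
                seq = genome.sequences[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        if genome.orthologs is not None:
            with open(out / f"orthologs_{genome.tag}.tsv", "w") as fh:
                fh.write("region_id\tchrom\tstart\tend\n")
                for rid in sorted(genome.orthologs):
                    c, s, e = genome.orthologs[rid]
                    fh.write(f"{rid}\t{c}\t{s}\t{e}\n")
    for i, fs in enumerate(bundle.feature_sets):
        write_bed(fs, out / f"features_{i}.bed")
    write_bed(bundle.insulators, out / "insulators.bed")
    write_bed(bundle.exons, out / "exons.bed")
    write_bed(bundle.crrs, out / "crrs.bed")
    write_pwms_cb(bundle.pwms, out / "motifs.cb")
    for tid, track in bundle.tracks.items():
        write_bed(track, out / f"{tid}.bed")
    with open(out / "genes.tsv", "w") as fh:
        fh.write("gene\tchrom\tstrand\ttss\n")
        for gene in sorted(bundle.annotation.genes()):
            e = bundle.annotation[gene]
            fh.write(f"{gene}\t{e.chrom}\t{e.strand}\t{e.tss}\n")
    write_bed(bundle.foreground_peaks, out / "foreground_peaks.bed")
    (out / "foreground_genes.txt").write_text(
        "\n".join(bundle.foreground_genes) + "\n"
    )
    (out / "truth.json").write_text(json.dumps(bundle.truth, indent=2) + "\n")
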