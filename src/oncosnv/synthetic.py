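"""Seeded synthetic fixtures with known ground truth.

Generates a toy genome (i.i.d. uniform nucleotides), gene annotations,
driver/neutral mutation catalogues and per-position score tracks so the
full pipeline — dataset construction, feature computation, greedy
integration, calibration and region scanning — can run end to end with
a machine-readable oracle of what was planted.

The catalogues emulate the structure of real driver/neutral inputs:
drivers carry geometric recurrence counts (catalogue-style observation
counts >= 1), neutrals co-locate near drivers with configurable
probability (the window-matching situation), and a chosen subset of
score tracks carries class-conditional Gaussian signal of effect size
delta while the rest are pure noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .io import GenomicInterval, AnnotationIndex, MutationRecord, ScoreTrack

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    n_chroms: int = 4
    chrom_length: int = 100_000
    gene_density: float = 1.0        # genes per 10 kb
    n_drivers: int = 200
    n_neutrals: int = 200
    recurrence_rho: float = 0.4      # geometric parameter; counts are >= 1
    neutral_placement: float = 0.8   # P(neutral placed within w of a driver)
    window: int = 1_000
    coding_fraction: float = 0.5     # fraction of drivers placed inside CDS
    track_names: tuple = ("cons46", "cons100", "mappability", "noise1", "noise2", "noise3")
    informative_tracks: tuple = ("cons46", "cons100")
    effect_size: float = 1.0         # class-mean separation in noise-sd units
    track_mean: float = 0.0
    track_sparsity: float = 0.9      # P(a position retains its value)
    seed: int = 0

    def __post_init__(self):
        if self.n_chroms < 1 or self.chrom_length < 1000:
            raise ValueError("need >= 1 chromosome of >= 1000 bp")
        if not 0 < self.recurrence_rho < 1:
            raise ValueError("recurrence_rho must lie in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not set(self.informative_tracks) <= set(self.track_names):
            raise ValueError("informative_tracks must be a subset of track_names")


def make_genome(cfg: SyntheticConfig) -> dict[str, str]:
    """i.i.d. uniform A/C/G/T sequence per chromosome, named '1'..'n'."""
    rng = np.random.default_rng(_stream_seed(cfg.seed, "genome"))
    return {str(i + 1): "".join(rng.choice(_BASES, size=cfg.chrom_length))
            for i in range(cfg.n_chroms)}


def _stream_seed(seed: int, label: str) -> int:
    h = seed * 2654435761 % (2 ** 31 - 1)
    for ch in label:
        h = (h * 31 + ord(ch)) % (2 ** 31 - 1)
    return h


def make_annotations(genome: dict[str, str], cfg: SyntheticConfig) -> list[GenomicInterval]:
    """Non-overlapping genes with exon/CDS/splice-site/start/stop/TSS
    sub-features, about gene_density genes per 10 kb."""
    spacing = int(10_000 / cfg.gene_density)
    gene_len = 2_000
    if spacing <= gene_len + 200:
        raise ValueError("gene_density infeasible for 2 kb gene bodies")
    intervals = []
    for chrom, seq in genome.items():
        start = 500
        while start + gene_len < len(seq):
            g0, g1 = start, start + gene_len
            intervals.append(GenomicInterval(chrom, g0, g1, "+", "gene"))
            intervals.append(GenomicInterval(chrom, g0, g0 + 1, "+", "TSS"))
            # two exons of 400 bp separated by an intron
            exons = [(g0 + 100, g0 + 500), (g1 - 500, g1 - 100)]
            for e0, e1 in exons:
                intervals.append(GenomicInterval(chrom, e0, e1, "+", "exon"))
                intervals.append(GenomicInterval(chrom, e0, e1, "+", "CDS"))
                intervals.append(GenomicInterval(chrom, max(0, e0 - 2), e0, "+", "splice_site"))
                intervals.append(GenomicInterval(chrom, e1, e1 + 2, "+", "splice_site"))
            intervals.append(GenomicInterval(chrom, exons[0][0], exons[0][0] + 3, "+", "start_codon"))
            intervals.append(GenomicInterval(chrom, exons[1][1] - 3, exons[1][1], "+", "stop_codon"))
            start += spacing
    return intervals


def make_mutations(genome: dict[str, str], annotations: list[GenomicInterval],
                   cfg: SyntheticConfig) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Driver and neutral catalogues with planted spatial structure."""
    rng = np.random.default_rng(_stream_seed(cfg.seed, "mutations"))
    cds = [iv for iv in annotations if iv.kind == "CDS"]
    chroms = sorted(genome, key=int)

    def draw_base_change(chrom, pos):
        ref = genome[chrom][pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return ref, str(alt)

    drivers = []
    taken = set()
    while len(drivers) < cfg.n_drivers:
        if cds and rng.random() < cfg.coding_fraction:
            iv = cds[rng.integers(len(cds))]
            chrom = iv.chrom
            pos = int(rng.integers(iv.start + 1, iv.end + 1))  # 1-based inside CDS
        else:
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(1, len(genome[chrom]) + 1))
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        ref, alt = draw_base_change(chrom, pos)
        recurrence = int(rng.geometric(cfg.recurrence_rho))
        drivers.append(MutationRecord(chrom, pos, ref, alt, recurrence=recurrence))

    neutrals = []
    while len(neutrals) < cfg.n_neutrals:
        if drivers and rng.random() < cfg.neutral_placement:
            d = drivers[rng.integers(len(drivers))]
            lo = max(1, d.pos - cfg.window)
            hi = min(len(genome[d.chrom]), d.pos + cfg.window)
            chrom = d.chrom
            pos = int(rng.integers(lo, hi + 1))
        else:
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(1, len(genome[chrom]) + 1))
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        ref, alt = draw_base_change(chrom, pos)
        neutrals.append(MutationRecord(chrom, pos, ref, alt, recurrence=0))
    return drivers, neutrals


def make_tracks(mutations_by_class: dict[str, list[MutationRecord]],
                cfg: SyntheticConfig) -> dict[str, ScoreTrack]:
    """Score tracks valued at mutation positions.

    Informative tracks draw Normal(mu + delta, 1) at driver positions and
    Normal(mu, 1) at neutral positions; other tracks are Normal(mu, 1)
    everywhere.  Each value is retained with probability track_sparsity.
    """
    rng = np.random.default_rng(_stream_seed(cfg.seed, "tracks"))
    tracks = {}
    for name in cfg.track_names:
        track = ScoreTrack(name)
        informative = name in cfg.informative_tracks
        for cls, muts in mutations_by_class.items():
            shift = cfg.effect_size if (informative and cls == "driver") else 0.0
            for m in muts:
                if rng.random() >= cfg.track_sparsity:
                    continue
                track.set(m.chrom, m.pos, rng.normal(cfg.track_mean + shift, 1.0))
        tracks[name] = track
    return tracks


def ground_truth_report(cfg: SyntheticConfig, counts: dict | None = None) -> dict:
    """Machine-readable oracle: the configuration that produced the
    fixture, in particular which tracks carry signal and at what effect
    size."""
    manifest = {"config": asdict(cfg)}
    manifest["config"]["track_names"] = list(cfg.track_names)
    manifest["config"]["informative_tracks"] = list(cfg.informative_tracks)
    manifest["informative_tracks"] = list(cfg.informative_tracks)
    manifest["effect_size"] = cfg.effect_size
    manifest["seed"] = cfg.seed
    if counts:
        manifest["counts"] = counts
    return manifest


@dataclass
class SyntheticWorld:
    """A complete seeded fixture: genome, annotations, catalogues,
    tracks and the ground-truth manifest."""

    cfg: SyntheticConfig
    genome: dict[str, str]
    intervals: list[GenomicInterval]
    drivers: list[MutationRecord]
    neutrals: list[MutationRecord]
    tracks: dict[str, ScoreTrack]
    manifest: dict = field(default_factory=dict)

    @property
    def annotations(self) -> AnnotationIndex:
        return AnnotationIndex(self.intervals)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_gff3(self.intervals, outdir / "annotations.gff3")
        from .io import write_mutation_table
        write_mutation_table(self.drivers, outdir / "drivers.tsv")
        write_mutation_table(self.neutrals, outdir / "neutrals.tsv")
        for name, track in self.tracks.items():
            with open(outdir / f"track_{name}.tsv", "w") as fh:
                for chrom in sorted(track._values, key=str):
                    for pos in sorted(track._values[chrom]):
                        fh.write(f"{chrom}\t{pos}\t{track._values[chrom][pos]:.6f}\n")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)


def simulate(cfg: SyntheticConfig) -> SyntheticWorld:
    """Generate the full fixture for a configuration; same seed, same
    bytes."""
    genome = make_genome(cfg)
    intervals = make_annotations(genome, cfg)
    drivers, neutrals = make_mutations(genome, intervals, cfg)
    tracks = make_tracks({"driver": drivers, "neutral": neutrals}, cfg)
    manifest = ground_truth_report(
        cfg, counts={"drivers": len(drivers), "neutrals": len(neutrals),
                     "intervals": len(intervals)})
    return SyntheticWorld(cfg, genome, intervals, drivers, neutrals, tracks, manifest)


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome, key=str):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(intervals, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            fh.write(f"{iv.chrom}\tsynthetic\t{iv.kind}\t{iv.start + 1}\t{iv.end}"
                     f"\t.\t{iv.strand}\t.\t.\n")
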