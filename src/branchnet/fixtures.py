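"""Deterministic synthetic study system.

Generates a toy multi-chromosome genome, two (or more precisely: positive and
negative) classes of fixed-length windows — the positive class carries a motif
planted at the window centre — and a per-base conservation track whose score is
Gaussian noise elevated over motif-covered bases. Every downstream stage
(preprocessing, training, evaluation, attribution) is testable end-to-end on
these files without any download.

Candidate windows live on a fixed grid with spacing equal to the window
length, which guarantees non-overlap and makes the capacity check exact:
``n_chroms * (chrom_length // window)`` windows exist in total.
"""

from __future__ import annotations

import reprlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import FixtureSpec
from .genomic_io import (
    COMPLEMENT,
    ConservationTrack,
    GenomicInterval,
    ReferenceGenome,
    write_bed,
    write_fasta,
    write_wig,
)

BASES = np.array(list("ACGT"))
POSITIVE_CLASS = "positive"
NEGATIVE_CLASS = "negative"


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))


def generate_reference(spec: FixtureSpec, fasta_path=None) -> ReferenceGenome:
    """Chromosomes chr1..chrN of i.i.d. uniform A/C/G/T bases."""
    rng = _rng(spec, 0)
    sequences = {
        f"chr{i + 1}": "".join(BASES[rng.integers(0, 4, size=spec.chrom_length)])
        for i in range(spec.n_chroms)
    }
    genome = ReferenceGenome(sequences)
    if fasta_path is not None:
        write_fasta(genome, fasta_path)
    return genome


@dataclass
class PlantedIntervals:
    genome: ReferenceGenome            # with motifs written in
    intervals: dict[str, list[GenomicInterval]]  # class name -> windows
    motif_positions: list[tuple[str, int, int]]  # (chrom, start, end) of each planted motif
    #: motif loci of positive-class windows only (the conservation signal set)
    positive_motif_positions: list[tuple[str, int, int]]


def plant_motif_intervals(genome: ReferenceGenome, spec: FixtureSpec,
                          bed_dir=None) -> PlantedIntervals:
    """Choose non-overlapping windows per class and write the motif into the
    genome at the centre of every positive window.

    Negative windows are guaranteed motif-free: grid windows that contain a
    chance occurrence of the motif are never selected for the negative class.
    With ``motif_in_negatives`` set, the motif is planted in both classes (the
    conservation track then carries the only class signal). A configurable
    fraction of windows is placed on the '−' strand, in which case the motif is
    written in reverse complement so the strand-aware extractor recovers it.
    """
    window, motif = spec.window, spec.motif
    grid = [
        (chrom, start)
        for chrom, seq in genome.sequences.items()
        for start in range(0, len(seq) - window + 1, window)
    ]
    rng = _rng(spec, 1)
    order = rng.permutation(len(grid))

    sequences = dict(genome.sequences)
    n_needed = 2 * spec.n_per_class
    if len(grid) < n_needed:
        smallest = min(genome.sequences, key=lambda c: len(genome.sequences[c]))
        raise ValueError(
            f"cannot place {n_needed} non-overlapping {window}-bp windows: only "
            f"{len(grid)} grid positions exist (limiting chromosome: {smallest} with "
            f"{len(genome.sequences[smallest]) // window} positions)"
        )

    def window_has_motif(chrom: str, start: int) -> bool:
        s = sequences[chrom][start : start + window]
        return motif in s or reverse_complement(motif) in s

    pos_windows: list[tuple[str, int]] = []
    neg_windows: list[tuple[str, int]] = []
    for idx in order:
        chrom, start = grid[idx]
        if len(pos_windows) < spec.n_per_class:
            pos_windows.append((chrom, start))
        elif len(neg_windows) < spec.n_per_class:
            if spec.motif_in_negatives or not window_has_motif(chrom, start):
                neg_windows.append((chrom, start))
        else:
            break
    if len(neg_windows) < spec.n_per_class:
        raise ValueError(
            f"could not find {spec.n_per_class} motif-free negative windows "
            f"(found {len(neg_windows)})"
        )

    strand_rng = _rng(spec, 2)

    def plant(chrom: str, start: int, strand: str) -> tuple[str, int, int]:
        centre = start + (window - len(motif)) // 2
        inserted = motif if strand == "+" else reverse_complement(motif)
        seq = sequences[chrom]
        sequences[chrom] = seq[:centre] + inserted + seq[centre + len(motif):]
        return (chrom, centre, centre + len(motif))

    def make_intervals(windows, label, plant_motif):
        out = []
        loci = []
        for i, (chrom, start) in enumerate(windows):
            strand = "-" if strand_rng.random() < spec.neg_strand_fraction else "+"
            if plant_motif:
                loci.append(plant(chrom, start, strand))
            out.append(GenomicInterval(chrom, start, start + window,
                                       name=f"{label}_{i}", strand=strand, label=label))
        return out, loci

    positives, pos_loci = make_intervals(pos_windows, POSITIVE_CLASS, plant_motif=True)
    negatives, neg_loci = make_intervals(neg_windows, NEGATIVE_CLASS,
                                         plant_motif=spec.motif_in_negatives)

    planted_genome = ReferenceGenome(sequences)
    intervals = {POSITIVE_CLASS: positives, NEGATIVE_CLASS: negatives}
    if bed_dir is not None:
        bed_dir = Path(bed_dir)
        bed_dir.mkdir(parents=True, exist_ok=True)
        for label, ivs in intervals.items():
            write_bed(ivs, bed_dir / f"{label}.bed")
    return PlantedIntervals(planted_genome, intervals, pos_loci + neg_loci, pos_loci)


def generate_conservation(genome: ReferenceGenome, spec: FixtureSpec,
                          motif_positions: list[tuple[str, int, int]],
                          wig_path=None) -> ConservationTrack:
    """Per-base Gaussian(0, noise_sd) noise over the whole genome, plus
    ``conservation_signal`` added over the given motif loci."""
    rng = _rng(spec, 3)
    track = ConservationTrack()
    for chrom, seq in genome.sequences.items():
        if spec.conservation_noise_sd > 0:
            noise = rng.normal(0.0, spec.conservation_noise_sd, size=len(seq))
        else:
            noise = np.zeros(len(seq))
        track.values[chrom] = dict(enumerate(noise.round(4)))
    for chrom, start, end in motif_positions:
        if chrom not in genome.sequences or end > len(genome.sequences[chrom]):
            raise ValueError(f"motif locus {chrom}:{start}-{end} outside the genome")
        for pos in range(start, end):
            track.values[chrom][pos] = track.values[chrom].get(pos, 0.0) + spec.conservation_signal
    if wig_path is not None:
        write_wig(track, wig_path)
    return track


@dataclass
class Fixture:
    """Everything the downstream pipeline needs, on disk and in memory."""

    spec: FixtureSpec
    genome: ReferenceGenome
    intervals: dict[str, list[GenomicInterval]]
    track: ConservationTrack
    positive_motif_positions: list[tuple[str, int, int]]
    fasta: Path | None = None
    beds: dict[str, Path] | None = None
    wig: Path | None = None

    def __repr__(self):  # the track dict is huge; keep repr readable
        return (f"Fixture(spec={self.spec!r}, classes={list(self.intervals)}, "
                f"genome={reprlib.repr(self.genome.chrom_lengths)})")


def make_fixture(spec: FixtureSpec, out_dir=None, with_conservation: bool = True) -> Fixture:
    """Run the three generators in sequence; optionally write FASTA/BED/WIG.

    The conservation signal is added over *positive-class* motif loci only, so
    that in the ``motif_in_negatives`` variant the track is the sole feature
    separating the classes.
    """
    genome = generate_reference(spec)
    planted = plant_motif_intervals(genome, spec)
    track = (generate_conservation(planted.genome, spec, planted.positive_motif_positions)
             if with_conservation else ConservationTrack())
    fasta = beds = wig = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / "genome.fa"
        write_fasta(planted.genome, fasta)
        beds = {}
        for label, ivs in planted.intervals.items():
            beds[label] = out_dir / f"{label}.bed"
            write_bed(ivs, beds[label])
        if with_conservation:
            wig = out_dir / "conservation.wig"
            write_wig(track, wig)
    return Fixture(spec, planted.genome, planted.intervals, track,
                   planted.positive_motif_positions, fasta, beds, wig)
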