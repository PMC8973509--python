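"""Interval preprocessing: fixed-length window normalisation, branch encoding
(sequence one-hot, secondary-structure dot-bracket one-hot, per-base
conservation), class balancing, and the four-way dataset split.

Intervals of any length are extended or trimmed around their midpoint to the
configured window, so windows are 'padded' with real neighbouring sequence
rather than N/zero padding. Windows that would leave the chromosome are
dropped (and counted), not clipped — clipping would reintroduce the
variable-length problem the extend/trim strategy exists to avoid.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from multiprocessing import Pool

import numpy as np
import yaml

from .config import RunConfig, SUBSET_NAMES
from .genomic_io import (
    COMPLEMENT,
    ConservationTrack,
    GenomicInterval,
    ReferenceGenome,
    logger,
    read_bed,
    read_conservation,
    read_fasta,
)

#: fixed one-hot column order for the sequence branch
SEQUENCE_ALPHABET = "ACGT"
#: fixed one-hot column order for the structure branch
STRUCTURE_ALPHABET = "(.)"
BRANCH_CHANNELS = {"sequence": 4, "structure": 3, "conservation": 1}


@dataclass
class EncodedSample:
    """Per-branch fixed-length matrices plus a one-hot class label."""

    branches: dict[str, np.ndarray]
    label: np.ndarray
    source: GenomicInterval


@dataclass
class DatasetBundle:
    """The four datasets. 'train' and 'validation' drive training,
    'evaluation' is tested directly afterwards, and 'blackbox' is a truly
    left-out set reserved for a final check after model selection."""

    train: list[EncodedSample] = field(default_factory=list)
    validation: list[EncodedSample] = field(default_factory=list)
    evaluation: list[EncodedSample] = field(default_factory=list)
    blackbox: list[EncodedSample] = field(default_factory=list)
    split_mode: str = "random"
    seed: int = 0
    class_names: list[str] = field(default_factory=list)

    def subsets(self) -> dict[str, list[EncodedSample]]:
        return {name: getattr(self, name) for name in SUBSET_NAMES}

    def arrays(self, subset: str) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Stack a subset into per-branch (n, L, C) arrays and (n, K) labels."""
        samples = getattr(self, subset)
        if not samples:
            raise ValueError(f"subset '{subset}' is empty")
        branch_names = list(samples[0].branches)
        inputs = {b: np.stack([s.branches[b] for s in samples]) for b in branch_names}
        labels = np.stack([s.label for s in samples])
        return inputs, labels

    # -- archive ------------------------------------------------------------
    def save(self, path, manifest: RunConfig | None = None) -> None:
        """Serialise to an .npz archive (plus the producing config as YAML)."""
        payload: dict[str, np.ndarray] = {
            "class_names": np.array(self.class_names),
            "split_mode": np.array(self.split_mode),
            "seed": np.array(self.seed),
        }
        if manifest is not None:
            payload["manifest_yaml"] = np.array(
                yaml.safe_dump(manifest.model_dump(mode="json"))
            )
        for name, samples in self.subsets().items():
            if not samples:
                continue
            for b in samples[0].branches:
                payload[f"{name}.branch.{b}"] = np.stack([s.branches[b] for s in samples])
            payload[f"{name}.labels"] = np.stack([s.label for s in samples])
            payload[f"{name}.sources"] = np.array(
                [f"{s.source.chrom}\t{s.source.start}\t{s.source.end}\t"
                 f"{s.source.name}\t{s.source.strand}\t{s.source.label}"
                 for s in samples]
            )
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path) -> "DatasetBundle":
        with np.load(path, allow_pickle=False) as data:
            bundle = cls(
                split_mode=str(data["split_mode"]),
                seed=int(data["seed"]),
                class_names=[str(c) for c in data["class_names"]],
            )
            for name in SUBSET_NAMES:
                if f"{name}.labels" not in data:
                    continue
                labels = data[f"{name}.labels"]
                sources = data[f"{name}.sources"]
                branch_names = [
                    k.split(".", 2)[2] for k in data.files if k.startswith(f"{name}.branch.")
                ]
                branches = {b: data[f"{name}.branch.{b}"] for b in branch_names}
                samples = []
                for i in range(labels.shape[0]):
                    chrom, start, end, iv_name, strand, label = str(sources[i]).split("\t")
                    samples.append(EncodedSample(
                        {b: branches[b][i] for b in branch_names},
                        labels[i],
                        GenomicInterval(chrom, int(start), int(end), iv_name, strand, label),
                    ))
                setattr(bundle, name, samples)
        return bundle


# ---------------------------------------------------------------------------
# Window normalisation and extraction


def normalize_interval(interval: GenomicInterval, window: int,
                       chrom_lengths: dict[str, int]) -> GenomicInterval | None:
    """Extend or trim an interval to exactly ``window`` bp around its midpoint.

    Midpoint and half-window both use floor, so results are bit-reproducible.
    Returns None when the normalised span leaves [0, chrom_length) — callers
    count and report such rejections.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if interval.chrom not in chrom_lengths:
        raise ValueError(f"unknown chromosome '{interval.chrom}'")
    mid = (interval.start + interval.end) // 2
    start = mid - window // 2
    end = start + window
    if start < 0 or end > chrom_lengths[interval.chrom]:
        return None
    return GenomicInterval(interval.chrom, start, end, interval.name,
                           interval.strand, interval.label)


def extract_sequence(reference: ReferenceGenome, interval: GenomicInterval) -> str:
    """The interval's bases; reverse-complemented for '−'-strand intervals."""
    seq = reference.sequences.get(interval.chrom)
    if seq is None:
        raise ValueError(f"unknown chromosome '{interval.chrom}'")
    if interval.end > len(seq):
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
            f"chromosome length {len(seq)}"
        )
    sub = seq[interval.start : interval.end]
    if interval.strand == "-":
        sub = sub.translate(COMPLEMENT)[::-1]
    return sub


def encode_sequence(seq: str) -> np.ndarray:
    """One-hot encode over the fixed column order A, C, G, T.

    U is treated as T; N becomes an all-zero row, which coincides with the
    attribution zero baseline so unknown bases receive zero attribution.
    """
    seq = seq.upper().replace("U", "T")
    illegal = set(seq) - set("ACGTN")
    if illegal:
        raise ValueError(f"cannot encode characters {sorted(illegal)}")
    mat = np.zeros((len(seq), 4))
    for i, base in enumerate(seq):
        if base != "N":
            mat[i, SEQUENCE_ALPHABET.index(base)] = 1.0
    return mat


def extract_conservation(track: ConservationTrack, interval: GenomicInterval) -> np.ndarray:
    """Per-base scores as an (L, 1) matrix; reversed on the '−' strand so the
    vector is co-oriented with the extracted sequence."""
    vec = track.get_range(interval.chrom, interval.start, interval.end)
    if interval.strand == "-":
        vec = vec[::-1]
    return vec[:, None]


# ---------------------------------------------------------------------------
# Secondary-structure folding

_PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRABLE


def nussinov_fold(seq: str, min_loop: int = 3) -> str:
    """Maximum base-pair dot-bracket structure (the built-in folding engine).

    Dynamic program maximising the number of AU/GC/GU pairs subject to a
    minimum hairpin loop of ``min_loop`` unpaired bases (a pair (i, j)
    requires j − i > min_loop). Traceback ties are broken by preferring the
    unpaired case, then the smallest pairing-partner index, so the result is
    deterministic. N pairs with nothing.
    """
    s = seq.upper().replace("T", "U")
    n = len(s)
    if n == 0:
        return ""
    best = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            m = best[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(s[i], s[k]):
                    inner = best[i + 1, k - 1] if k - 1 > i + 1 else 0
                    right = best[k + 1, j] if k + 1 < j else 0
                    m = max(m, 1 + inner + right)
            best[i, j] = m

    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            if best[i, j] == best[i + 1, j]:  # prefer leaving i unpaired
                i += 1
                continue
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(s[i], s[k]):
                    inner = best[i + 1, k - 1] if k - 1 > i + 1 else 0
                    right = best[k + 1, j] if k + 1 < j else 0
                    if best[i, j] == 1 + inner + right:
                        structure[i], structure[k] = "(", ")"
                        traceback(i + 1, k - 1)
                        i, j = k + 1, j
                        break
            else:  # pragma: no cover - DP consistency guard
                raise RuntimeError("traceback failed")

    traceback(0, n - 1)
    return "".join(structure)


def vienna_fold(seq: str) -> str:
    """Minimum-free-energy structure via the external RNAfold program."""
    try:
        proc = subprocess.run(
            ["RNAfold", "--noPS"], input=seq + "\n", capture_output=True,
            text=True, check=True,
        )
    except (OSError, subprocess.CalledProcessError) as exc:
        raise RuntimeError(f"RNAfold failed for sequence {seq[:30]}...: {exc}") from exc
    lines = proc.stdout.strip().splitlines()
    if len(lines) < 2:
        raise RuntimeError(f"unexpected RNAfold output for sequence {seq[:30]}...")
    return lines[1].split()[0]


FOLD_ENGINES = {"builtin": nussinov_fold, "vienna": vienna_fold}


def fold_structure(seq: str, engine="builtin") -> str:
    """Fold with the chosen engine and verify the dot-bracket contract
    (length preserved, brackets balanced)."""
    fold = FOLD_ENGINES[engine] if isinstance(engine, str) else engine
    db = fold(seq)
    if len(db) != len(seq) or set(db) - set("(.)"):
        raise RuntimeError(f"folding engine returned invalid structure for {seq[:30]}...")
    depth = 0
    for ch in db:
        depth += {"(": 1, ")": -1, ".": 0}[ch]
        if depth < 0:
            raise RuntimeError(f"unbalanced structure for sequence {seq[:30]}...")
    if depth != 0:
        raise RuntimeError(f"unbalanced structure for sequence {seq[:30]}...")
    return db


def encode_structure(db: str) -> np.ndarray:
    """One-hot over the column order '(', '.', ')' (purely syntactic)."""
    illegal = set(db) - set("(.)")
    if illegal:
        raise ValueError(f"cannot encode structure characters {sorted(illegal)}")
    mat = np.zeros((len(db), 3))
    for i, ch in enumerate(db):
        mat[i, STRUCTURE_ALPHABET.index(ch)] = 1.0
    return mat


# ---------------------------------------------------------------------------
# Class balancing and splitting


def reduce_class(samples: list, *, n: int | None = None, ratio: float | None = None,
                 seed: int = 0) -> list:
    """Uniform random subsample of one class, without replacement.

    Either an absolute target size ``n`` (capped at the class size — no
    upsampling) or a ``ratio`` in (0, 1]; the retained samples keep their
    original order.
    """
    if (n is None) == (ratio is None):
        raise ValueError("specify exactly one of n= or ratio=")
    if n is not None:
        if n < 0:
            raise ValueError("n must be >= 0")
        size = min(n, len(samples))
    else:
        if not 0 < ratio <= 1:
            raise ValueError("ratio must be in (0, 1]")
        size = round(ratio * len(samples))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    keep = np.sort(rng.choice(len(samples), size=size, replace=False))
    return [samples[i] for i in keep]


def split_random(samples: list[EncodedSample], ratios, seed: int = 0) -> DatasetBundle:
    """Stratified random split into train/validation/evaluation/blackbox.

    Within each class, the validation/evaluation/blackbox sizes are
    ``floor(ratio * n_class)`` and the remainder goes to train, so every
    subset's class mix matches the whole within one sample per class.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 4 or any(r < 0 for r in ratios) or abs(sum(ratios) - 1) > 1e-9:
        raise ValueError("ratios must be 4 non-negative numbers summing to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
    by_class: dict[bytes, list[int]] = {}
    for i, s in enumerate(samples):
        by_class.setdefault(s.label.tobytes(), []).append(i)

    parts: dict[str, list[EncodedSample]] = {name: [] for name in SUBSET_NAMES}
    for indices in by_class.values():
        idx = rng.permutation(indices)
        n_val = int(ratios[1] * len(idx))
        n_eval = int(ratios[2] * len(idx))
        n_bb = int(ratios[3] * len(idx))
        n_train = len(idx) - n_val - n_eval - n_bb
        bounds = np.cumsum([n_train, n_val, n_eval, n_bb])
        chunks = np.split(idx, bounds[:-1])
        for name, chunk in zip(SUBSET_NAMES, chunks):
            parts[name].extend(samples[i] for i in chunk)

    for name, ratio in zip(SUBSET_NAMES, ratios):
        if name != "blackbox" and ratio > 0 and not parts[name]:
            raise ValueError(f"subset '{name}' is empty at ratio {ratio}: too few samples")
    class_names = _class_names(samples)
    return DatasetBundle(split_mode="random", seed=seed, class_names=class_names, **parts)


def split_by_chromosome(samples: list[EncodedSample],
                        assignment: dict[str, str]) -> DatasetBundle:
    """Route each sample to the subset its chromosome is assigned to; subsets
    are chromosome-disjoint by construction. Chromosomes absent from the
    assignment are an error (never silently dropped)."""
    parts: dict[str, list[EncodedSample]] = {name: [] for name in SUBSET_NAMES}
    for s in samples:
        subset = assignment.get(s.source.chrom)
        if subset is None:
            raise ValueError(f"chromosome '{s.source.chrom}' has no subset assignment")
        if subset not in SUBSET_NAMES:
            raise ValueError(f"unknown subset '{subset}' for chromosome '{s.source.chrom}'")
        parts[subset].append(s)
    return DatasetBundle(split_mode="by_chromosome", class_names=_class_names(samples), **parts)


def _class_names(samples) -> list[str]:
    seen: dict[str, None] = {}
    for s in samples:
        seen.setdefault(s.source.label)
    return list(seen)


# ---------------------------------------------------------------------------
# Orchestrator


def encode_interval(interval: GenomicInterval, reference: ReferenceGenome,
                    branches: list[str], track: ConservationTrack | None,
                    fold_engine="builtin",
                    structure: str | None = None) -> dict[str, np.ndarray]:
    """Encode the selected branches of one already-normalised interval."""
    out: dict[str, np.ndarray] = {}
    seq = extract_sequence(reference, interval)
    if "sequence" in branches:
        out["sequence"] = encode_sequence(seq)
    if "structure" in branches:
        db = structure if structure is not None else fold_structure(seq, fold_engine)
        out["structure"] = encode_structure(db)
    if "conservation" in branches:
        if track is None:
            raise ValueError("conservation branch requested but no track provided")
        out["conservation"] = extract_conservation(track, interval)
    return out


def build_dataset(config: RunConfig,
                  reference: ReferenceGenome | None = None,
                  intervals: dict[str, list[GenomicInterval]] | None = None,
                  track: ConservationTrack | None = None,
                  archive_path=None) -> DatasetBundle:
    """Full preprocessing pipeline: read → normalise → encode → reduce → split.

    Inputs may be given in memory (fixture workflow) or read from the paths in
    the config. Rejected out-of-bounds intervals are counted and logged per
    class; a class losing all its samples is an error.
    """
    pp = config.preprocessing
    if reference is None:
        if not config.paths.fasta:
            raise ValueError("no reference genome given (paths.fasta unset)")
        reference = read_fasta(config.paths.fasta)
    if intervals is None:
        if len(config.paths.beds) < 2:
            raise ValueError("need at least 2 class BED files")
        intervals = {label: read_bed(path, label=label)
                     for label, path in config.paths.beds.items()}
    if len(intervals) < 2:
        raise ValueError("need at least 2 classes")
    if track is None and "conservation" in pp.branches:
        if not config.paths.conservation:
            raise ValueError("conservation branch requested but paths.conservation unset")
        track = read_conservation(config.paths.conservation)

    chrom_lengths = reference.chrom_lengths
    class_names = list(intervals)
    samples: list[EncodedSample] = []
    for k, label in enumerate(class_names):
        kept: list[GenomicInterval] = []
        rejected = 0
        for iv in intervals[label]:
            norm = normalize_interval(iv, pp.window, chrom_lengths)
            if norm is None:
                rejected += 1
            else:
                kept.append(norm)
        if rejected:
            logger.warning("class %s: %d interval(s) rejected at window normalisation",
                           label, rejected)
        if not kept:
            raise ValueError(f"class '{label}' has zero surviving samples")

        structures = None
        if "structure" in pp.branches:
            seqs = [extract_sequence(reference, iv) for iv in kept]
            if pp.cores > 1 and pp.fold_engine == "builtin":
                with Pool(pp.cores) as pool:
                    structures = pool.map(nussinov_fold, seqs)
            else:
                structures = [fold_structure(s, pp.fold_engine) for s in seqs]

        label_vec = np.zeros(len(class_names))
        label_vec[k] = 1.0
        class_samples = [
            EncodedSample(
                encode_interval(iv, reference, pp.branches, track,
                                pp.fold_engine,
                                structures[i] if structures else None),
                label_vec.copy(), iv,
            )
            for i, iv in enumerate(kept)
        ]

        if label in pp.reduce:
            amount = pp.reduce[label]
            if amount <= 1:
                class_samples = reduce_class(class_samples, ratio=float(amount),
                                             seed=config.seed)
            else:
                class_samples = reduce_class(class_samples, n=int(amount),
                                             seed=config.seed)
        samples.extend(class_samples)

    if config.split.mode == "random":
        bundle = split_random(samples, config.split.ratios, seed=config.seed)
    else:
        bundle = split_by_chromosome(samples, config.split.chromosome_assignment)
    bundle.class_names = class_names
    if archive_path is not None:
        bundle.save(archive_path, manifest=config)
    return bundle
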