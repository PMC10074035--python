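"""Seeded synthetic wild-type/knockout ChIP-seq experiment generator.

Emulates the structure a WT/KO motif-ranking run consumes, without any
read-level simulation: a random i.i.d. genome; WT peaks consisting of
signal peaks (a target motif site planted near the peak center with a
Gaussian positional offset) plus shared technical-noise peaks; KO peaks
consisting of the same shared-noise loci plus KO-only noise; and a
differential peak set obtained by locus subtraction (WT peaks at loci
absent from the KO set) standing in for differential peak calling, which
this package deliberately does not perform.  Decoy motifs are
column-shuffled copies of the target, preserving its column multiset and
information content.

All randomness flows from ``SimulationConfig.seed``; identical configs
produce byte-identical files.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, insort
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, NarrowPeakRecord, write_narrowpeak
from .motifs import ALPHABET, Pwm, reverse_complement, write_meme_motifs, Background

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SyntheticExperiment",
    "GenerationError",
    "default_target_motif",
    "shuffle_decoy",
    "generate_experiment",
]

CHROM = "chr1"


class GenerationError(RuntimeError):
    pass


def default_target_motif() -> Pwm:
    """A 12-bp synthetic target PWM (CRE-like consensus TGACGTCATGCA) with
    a 0.9-dominant base per column, ~16 bits of information content."""
    consensus = "TGACGTCATGCA"
    probs = np.full((len(consensus), 4), (1 - 0.9) / 3)
    for j, base in enumerate(consensus):
        probs[j, ALPHABET.index(base)] = 0.9
    return Pwm("TARGET.1", "synthetic_target", probs)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults emulate a modest knockout ChIP-seq comparison: 200 bound
    (signal) WT peaks of 500 bp with a site planted in 80% of them at a
    Gaussian offset (sigma 20 bp) from the summit, 50 technical-noise loci
    shared verbatim between WT and KO, 50 KO-only noise peaks, and 20
    column-shuffled decoy motifs alongside the target.
    """

    genome_length: int = 1_000_000
    gc_fraction: float = 0.41
    n_wt: int = 200
    n_ko: int = 50
    n_shared_noise: int = 50
    peak_width: int = 500
    target_motif: Pwm | None = None
    plant_prob: float = 0.8
    center_sigma: float = 20.0
    decoy_count: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= self.peak_width:
            raise ValueError("genome_length must exceed peak_width")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        if not 0 <= self.plant_prob <= 1:
            raise ValueError("plant_prob must be in [0, 1]")
        if min(self.n_wt, self.n_ko, self.n_shared_noise, self.decoy_count) < 0:
            raise ValueError("counts must be >= 0")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")


@dataclass
class SyntheticExperiment:
    """Paths to the generated files plus the ground truth."""

    genome: Path
    wt_peaks: Path
    ko_peaks: Path
    diff_peaks: Path
    motif_db: Path
    truth: pd.DataFrame
    truth_path: Path
    target_motif_id: str
    chrom_sizes: dict[str, int]


def _max_overlap_identity(a: str, b: str) -> int:
    """Maximum number of agreeing positions over all ungapped offsets of
    ``b`` (or its reverse complement) against ``a``."""
    best = 0
    for cand in (b, reverse_complement(b)):
        for shift in range(-(len(cand) - 1), len(a)):
            matches = sum(
                1
                for j in range(len(cand))
                if 0 <= shift + j < len(a) and a[shift + j] == cand[j]
            )
            best = max(best, matches)
    return best


def shuffle_decoy(pwm: Pwm, seed: int, label: str | None = None) -> Pwm:
    """Column-shuffled decoy: positions permuted, column multiset and
    information content unchanged, new id ``<id>_<label>``.

    Permutations are rejection-sampled to prefer derangements whose
    consensus does not realign to the parent consensus over more than half
    its positions at any offset on either strand — a shuffle that
    effectively reconstructs the motif, e.g. a cyclic shift of a
    palindromic consensus, would not be a decoy at all.
    """
    rng = np.random.default_rng(seed)
    m = pwm.length
    if m == 1:
        log.warning("motif %s has a single column; decoy is a copy", pwm.motif_id)
        perm = np.array([0])
    else:
        parent = pwm.consensus()
        cap = m // 2
        best_perm, best_score = None, m + 1
        for _ in range(200):
            perm = rng.permutation(m)
            if np.any(perm == np.arange(m)):
                continue
            shuffled = "".join(parent[j] for j in perm)
            score = _max_overlap_identity(parent, shuffled)
            if score < best_score:
                best_perm, best_score = perm, score
            if score <= cap:
                break
        perm = best_perm if best_perm is not None else rng.permutation(m)
        if best_score > cap:
            log.warning(
                "decoy for %s retains %d/%d consensus identity after 200 "
                "attempts",
                pwm.motif_id,
                best_score,
                m,
            )
    suffix = label if label is not None else f"shuf{seed}"
    return Pwm(f"{pwm.motif_id}_{suffix}", f"decoy_{suffix}", pwm.probs[perm])


def _place_loci(
    rng: np.random.Generator, n: int, width: int, genome_length: int
) -> list[int]:
    """Non-overlapping peak centers: rejection sampling with a sorted list."""
    half = width // 2
    lo, hi = half, genome_length - (width - half)
    centers: list[int] = []
    attempts = 0
    max_attempts = max(10_000, 200 * n)
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {n} non-overlapping peaks of width {width} "
                f"in a {genome_length} bp genome; increase genome_length"
            )
        c = int(rng.integers(lo, hi))
        i = bisect_left(centers, c)
        if i > 0 and c - centers[i - 1] < width:
            continue
        if i < len(centers) and centers[i] - c < width:
            continue
        insort(centers, c)
    return centers


def _peak_record(center: int, width: int, name: str) -> NarrowPeakRecord:
    half = width // 2
    iv = GenomicInterval(CHROM, center - half, center - half + width, name)
    return NarrowPeakRecord(iv, half, signal=0.0, p_score=-1.0, q_score=-1.0)


def _write_fasta(path: Path, name: str, seq: str, wrap: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), wrap):
            fh.write(seq[i : i + wrap] + "\n")


def generate_experiment(cfg: SimulationConfig, outdir) -> SyntheticExperiment:
    """Generate genome, WT/KO/differential narrowPeak files, a motif
    database (target + decoys) and a ground-truth site table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    target = cfg.target_motif or default_target_motif()
    m = target.length
    if cfg.peak_width < m:
        raise ValueError("peak_width must be at least the motif length")

    gc = cfg.gc_fraction
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome_codes = rng.choice(4, size=cfg.genome_length, p=base_probs)

    n_total = cfg.n_wt + cfg.n_shared_noise + cfg.n_ko
    centers = _place_loci(rng, n_total, cfg.peak_width, cfg.genome_length)
    # random assignment of disjoint loci to roles
    order = rng.permutation(n_total)
    signal_centers = sorted(centers[i] for i in order[: cfg.n_wt])
    shared_centers = sorted(
        centers[i] for i in order[cfg.n_wt : cfg.n_wt + cfg.n_shared_noise]
    )
    ko_only_centers = sorted(centers[i] for i in order[cfg.n_wt + cfg.n_shared_noise :])

    half = cfg.peak_width // 2
    truth_rows = []
    for idx, center in enumerate(signal_centers):
        if rng.random() >= cfg.plant_prob:
            continue
        disp = int(round(rng.normal(0.0, cfg.center_sigma)))
        site_start = center + disp - m // 2
        peak_start, peak_end = center - half, center - half + cfg.peak_width
        site_start = min(max(site_start, peak_start), peak_end - m)
        site = np.array(
            [rng.choice(4, p=target.probs[j]) for j in range(m)], dtype=genome_codes.dtype
        )
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            site = 3 - site[::-1]
        genome_codes[site_start : site_start + m] = site
        truth_rows.append(
            {
                "peak_name": f"wt_signal_{idx:04d}",
                "chrom": CHROM,
                "site_start": site_start,
                "site_end": site_start + m,
                "strand": strand,
                "displacement": site_start + m // 2 - center,
                "motif_id": target.motif_id,
            }
        )

    genome_seq = "".join(ALPHABET[c] for c in genome_codes)
    genome_path = outdir / "genome.fa"
    _write_fasta(genome_path, CHROM, genome_seq)

    wt_records = sorted(
        [
            _peak_record(c, cfg.peak_width, f"wt_signal_{i:04d}")
            for i, c in enumerate(signal_centers)
        ]
        + [
            _peak_record(c, cfg.peak_width, f"shared_noise_{i:04d}")
            for i, c in enumerate(shared_centers)
        ],
        key=lambda r: r.interval.key,
    )
    ko_records = sorted(
        [
            _peak_record(c, cfg.peak_width, f"shared_noise_{i:04d}")
            for i, c in enumerate(shared_centers)
        ]
        + [
            _peak_record(c, cfg.peak_width, f"ko_noise_{i:04d}")
            for i, c in enumerate(ko_only_centers)
        ],
        key=lambda r: r.interval.key,
    )
    # differential peaks: WT loci absent from KO == the signal peaks.
    # This locus subtraction is an approximation standing in for
    # differential peak calling.
    diff_records = [
        _peak_record(c, cfg.peak_width, f"wt_signal_{i:04d}")
        for i, c in enumerate(signal_centers)
    ]

    wt_path = outdir / "wt_peaks.narrowPeak"
    ko_path = outdir / "ko_peaks.narrowPeak"
    diff_path = outdir / "diff_peaks.narrowPeak"
    write_narrowpeak(wt_records, wt_path)
    write_narrowpeak(ko_records, ko_path)
    write_narrowpeak(diff_records, diff_path)

    decoys = [
        shuffle_decoy(target, seed=int(rng.integers(2**31)), label=f"shuf{i:02d}")
        for i in range(1, cfg.decoy_count + 1)
    ]
    motif_path = outdir / "motifs.meme"
    write_meme_motifs([target] + decoys, motif_path, background=Background(base_probs))

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "peak_name",
            "chrom",
            "site_start",
            "site_end",
            "strand",
            "displacement",
            "motif_id",
        ],
    )
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    log.info(
        "synthetic experiment: %d WT signal (%d planted), %d shared-noise, "
        "%d KO-only peaks",
        cfg.n_wt,
        len(truth_rows),
        cfg.n_shared_noise,
        cfg.n_ko,
    )
    return SyntheticExperiment(
        genome=genome_path,
        wt_peaks=wt_path,
        ko_peaks=ko_path,
        diff_peaks=diff_path,
        motif_db=motif_path,
        truth=truth,
        truth_path=truth_path,
        target_motif_id=target.motif_id,
        chrom_sizes={CHROM: cfg.genome_length},
    )
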