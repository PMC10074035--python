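"""PWM motif model, MEME minimal-format and FASTA I/O, log-odds scanning.

The scanner reports one best match per sequence (both strands), the
CentriMo-style convention that central-enrichment statistics are built on.
Sequence centers are defined at the fractional coordinate (L-1)/2, so the
center displacement of a match may be half-integral when L - m is odd.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .intervals import GenomicInterval, ParseError, PeakSet

log = logging.getLogger(__name__)

ALPHABET = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)  # 4 == N / unknown
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

__all__ = [
    "Pwm",
    "Background",
    "SequenceRecord",
    "BestMatch",
    "read_meme_motifs",
    "read_meme",
    "write_meme_motifs",
    "read_fasta",
    "log_odds",
    "best_match",
    "scan_best_matches",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


@dataclass(frozen=True)
class Pwm:
    """A position weight matrix: ``probs[j, b]`` is the probability of base
    ``ACGT[b]`` at motif position ``j``.

    Rows are renormalized on construction; a row off unity by more than
    1e-3 is rejected as malformed.
    """

    motif_id: str
    name: str = ""
    probs: np.ndarray = field(default=None)  # type: ignore[assignment]
    nsites: int | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError(f"motif {self.motif_id}: probs must be (m, 4), m >= 1")
        if np.any(probs < 0):
            raise ValueError(f"motif {self.motif_id}: negative probability")
        sums = probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"motif {self.motif_id}: row {bad} sums to {sums[bad]:.6f}, not 1"
            )
        object.__setattr__(self, "probs", probs / sums[:, None])

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def __len__(self) -> int:
        return self.length

    def consensus(self) -> str:
        return "".join(ALPHABET[b] for b in self.probs.argmax(axis=1))

    def information_content(self) -> float:
        """Total information content in bits, against a uniform background."""
        p = np.clip(self.probs, 1e-12, 1.0)
        return float(np.sum(p * np.log2(p * 4.0)))


@dataclass(frozen=True)
class Background:
    """0-order base composition (A, C, G, T), pseudocount-floored."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,):
            raise ValueError("background must have 4 frequencies (A, C, G, T)")
        if np.any(f <= 0):
            raise ValueError("background frequencies must be strictly positive")
        object.__setattr__(self, "freqs", f / f.sum())

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_sequences(
        cls, seqs: Iterable["SequenceRecord"], floor: float = 1e-4
    ) -> "Background":
        """Estimate 0-order frequencies from sequences, flooring at ``floor``
        so log-odds stay finite even for skewed compositions."""
        counts = np.zeros(4)
        for rec in seqs:
            codes = _CODE[np.frombuffer(rec.bases.encode("ascii"), dtype=np.uint8)]
            counts += np.bincount(codes[codes < 4], minlength=4)
        if counts.sum() == 0:
            return cls.uniform()
        freqs = np.maximum(counts / counts.sum(), floor)
        return cls(freqs)


@dataclass(frozen=True)
class SequenceRecord:
    """A DNA sequence, optionally linked back to the genomic peak it was
    extracted from (``origin``)."""

    seq_id: str
    bases: str
    origin: GenomicInterval | None = None

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        if len(bases) < 1:
            raise ValueError(f"sequence {self.seq_id}: empty")
        if self.origin is not None and len(self.origin) != len(bases):
            raise ValueError(
                f"sequence {self.seq_id}: origin length {len(self.origin)} != "
                f"sequence length {len(bases)}"
            )
        object.__setattr__(self, "bases", bases)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class BestMatch:
    """Best-scoring motif site in one sequence.

    ``offset`` is the 0-based start of the matched window on the forward
    strand coordinates; ``center_displacement`` is the signed distance (bp)
    of the window center from the sequence center, half-integral when the
    two parities differ.
    """

    seq_id: str
    offset: int
    strand: str
    log_odds: float
    center_displacement: float


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

_NUM_ROW = re.compile(r"^[\s0-9.eE+-]+$")


def _parse_meme(path) -> tuple[list[Pwm], Background | None]:
    lines = Path(path).read_text().splitlines()
    it = iter(enumerate(lines, start=1))

    version_seen = False
    for lineno, line in it:
        if line.strip():
            if not line.lstrip().startswith("MEME version"):
                raise ParseError(f"{path}: missing 'MEME version' header line")
            version_seen = True
            break
    if not version_seen:
        raise ParseError(f"{path}: missing 'MEME version' header line")

    motifs: list[Pwm] = []
    background: Background | None = None
    i = 0
    body = lines
    # restart a simple index-based walk after the version line
    start_idx = next(
        idx for idx, line in enumerate(body) if line.lstrip().startswith("MEME version")
    )
    i = start_idx + 1
    n = len(body)

    def parse_background(j: int) -> tuple[Background, int]:
        freqs: dict[str, float] = {}
        while j < n:
            toks = body[j].split()
            if not toks or toks[0].upper() == "MOTIF" or not _looks_like_freq_pairs(toks):
                break
            for base, val in zip(toks[0::2], toks[1::2]):
                freqs[base.upper()] = float(val)
            j += 1
        try:
            vec = np.array([freqs[b] for b in ALPHABET])
        except KeyError as exc:
            raise ParseError(f"{path}: background block missing base {exc}") from exc
        return Background(vec), j

    def _looks_like_freq_pairs(toks: list[str]) -> bool:
        if len(toks) % 2 != 0:
            return False
        try:
            [float(v) for v in toks[1::2]]
        except ValueError:
            return False
        return all(t.upper() in "ACGT" for t in toks[0::2])

    while i < n:
        line = body[i].strip()
        if line.lower().startswith("background letter frequencies"):
            background, i = parse_background(i + 1)
            continue
        if line.upper().startswith("MOTIF"):
            toks = line.split()
            if len(toks) < 2:
                raise ParseError(f"{path}: line {i + 1}: MOTIF line missing identifier")
            motif_id = toks[1]
            name = toks[2] if len(toks) > 2 else ""
            i += 1
            # seek the letter-probability header
            stated_w: int | None = None
            stated_nsites: int | None = None
            while i < n and not body[i].strip().lower().startswith(
                "letter-probability matrix"
            ):
                if body[i].strip().upper().startswith("MOTIF"):
                    raise ParseError(
                        f"{path}: motif {motif_id}: no letter-probability matrix"
                    )
                i += 1
            if i >= n:
                raise ParseError(
                    f"{path}: motif {motif_id}: no letter-probability matrix"
                )
            header = body[i]
            m_w = re.search(r"\bw\s*=\s*(\d+)", header)
            m_ns = re.search(r"\bnsites\s*=\s*(\d+)", header)
            m_al = re.search(r"\balength\s*=\s*(\d+)", header)
            if m_w:
                stated_w = int(m_w.group(1))
            if m_ns:
                stated_nsites = int(m_ns.group(1))
            if m_al and int(m_al.group(1)) != 4:
                raise ParseError(
                    f"{path}: motif {motif_id}: alength {m_al.group(1)} != 4"
                )
            i += 1
            rows: list[list[float]] = []
            while i < n:
                s = body[i].strip()
                if not s:
                    if rows:
                        break
                    i += 1
                    continue
                if not _NUM_ROW.match(s):
                    break
                vals = [float(v) for v in s.split()]
                if len(vals) != 4:
                    raise ParseError(
                        f"{path}: motif {motif_id}: matrix row with {len(vals)} "
                        "values, expected 4"
                    )
                rows.append(vals)
                i += 1
            if stated_w is not None and stated_w != len(rows):
                raise ParseError(
                    f"{path}: motif {motif_id}: header states w={stated_w} but "
                    f"{len(rows)} rows parsed"
                )
            if not rows:
                raise ParseError(f"{path}: motif {motif_id}: empty matrix")
            try:
                pwm = Pwm(motif_id, name, np.array(rows), stated_nsites)
            except ValueError as exc:
                raise ParseError(f"{path}: {exc}") from exc
            motifs.append(pwm)
            continue
        i += 1
    return motifs, background


def read_meme_motifs(path) -> list[Pwm]:
    """Read all MOTIF blocks from a MEME minimal-format motif file."""
    return _parse_meme(path)[0]


def read_meme(path) -> tuple[list[Pwm], Background | None]:
    """Read motifs plus the file-level background block, when present."""
    return _parse_meme(path)


def write_meme_motifs(
    motifs: Sequence[Pwm], path, background: Background | None = None
) -> None:
    """Write motifs in MEME minimal format (version 4)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = background.freqs if background is not None else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {f:.5f}" for b, f in zip(ALPHABET, bg)) + "\n\n"
        )
        for pwm in motifs:
            fh.write(f"MOTIF {pwm.motif_id} {pwm.name}".rstrip() + "\n")
            nsites = f" nsites= {pwm.nsites}" if pwm.nsites else ""
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length}{nsites}\n"
            )
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{v:8.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path, regions: PeakSet | None = None) -> list[SequenceRecord]:
    """Read sequences from FASTA.

    Without ``regions``: one record per FASTA entry.  With ``regions``: the
    file is treated as an indexed genome and one record per region is
    extracted, with ``origin`` linking it back to its peak.  A region
    extending past its chromosome raises a bounds error naming the region.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    try:
        if regions is None:
            return [SequenceRecord(name, str(fa[name][:])) for name in fa.keys()]
        out: list[SequenceRecord] = []
        for iv in regions:
            if iv.chrom not in fa:
                raise KeyError(f"chromosome {iv.chrom!r} absent from {path}")
            clen = len(fa[iv.chrom])
            if iv.end > clen:
                raise ValueError(
                    f"region {iv.chrom}:{iv.start}-{iv.end} extends past "
                    f"chromosome end ({clen})"
                )
            seq = str(fa[iv.chrom][iv.start : iv.end])
            seq_id = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
            out.append(SequenceRecord(seq_id, seq, origin=iv))
        return out
    finally:
        fa.close()


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def log_odds(pwm: Pwm, bg: Background, pseudocount: float = 0.01) -> np.ndarray:
    """Log-odds matrix in bits:
    ``log2(((1 - c) * p[j, b] + c * bg[b]) / bg[b])`` for pseudocount
    fraction ``c``.  With ``c = 0`` a zero probability scores ``-inf``,
    which simply makes windows requiring that base ineligible.
    """
    if not 0 <= pseudocount < 1:
        raise ValueError(f"pseudocount must be in [0, 1), got {pseudocount}")
    with np.errstate(divide="ignore"):
        return np.log2(
            ((1 - pseudocount) * pwm.probs + pseudocount * bg.freqs) / bg.freqs
        )


def _encode(bases: str) -> np.ndarray:
    return _CODE[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]


def _score_tables(lodds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(m, 5) forward and reverse-complement lookup tables; column 4 (N)
    scores -inf so any window containing N is ineligible."""
    m = lodds.shape[0]
    fwd = np.full((m, 5), -np.inf)
    fwd[:, :4] = lodds
    rev = np.full((m, 5), -np.inf)
    rev[:, :4] = lodds[::-1, ::-1]
    return fwd, rev


def scan_best_matches(
    seqs: Sequence[SequenceRecord],
    pwm: Pwm,
    bg: Background,
    min_score: float = 0.0,
    pseudocount: float = 0.01,
) -> list[BestMatch | None]:
    """Best match per sequence over both strands, or None when the sequence
    is shorter than the motif or has no eligible window scoring at least
    ``min_score`` bits.

    Ties are broken toward the center (smallest |center displacement|),
    then the + strand, then the leftmost offset.
    """
    lodds = log_odds(pwm, bg, pseudocount)
    tab_fwd, tab_rev = _score_tables(lodds)
    m = pwm.length
    results: list[BestMatch | None] = [None] * len(seqs)

    by_len: dict[int, list[int]] = {}
    for i, rec in enumerate(seqs):
        by_len.setdefault(len(rec), []).append(i)

    motif_pos = np.arange(m)
    for L, idxs in by_len.items():
        if L < m:
            log.info(
                "skipping %d sequence(s) of length %d < motif length %d",
                len(idxs),
                L,
                m,
            )
            continue
        P = L - m + 1
        codes = np.stack([_encode(seqs[i].bases) for i in idxs])  # (n, L)
        windows = sliding_window_view(codes, m, axis=1)  # (n, P, m)
        with np.errstate(invalid="ignore"):
            s_fwd = tab_fwd[motif_pos, windows].sum(axis=-1)  # (n, P)
            s_rev = tab_rev[motif_pos, windows].sum(axis=-1)
        scores = np.concatenate([s_fwd, s_rev], axis=1)  # (n, 2P)
        scores = np.where(scores >= min_score, scores, -np.inf)

        offsets = np.tile(np.arange(P), 2)
        strand_code = np.repeat([0, 1], P)  # 0: '+', 1: '-'
        disp = offsets - (L - m) / 2.0
        absd = np.abs(disp)

        nrow = len(idxs)
        keys = (
            np.broadcast_to(offsets, (nrow, 2 * P)),
            np.broadcast_to(strand_code, (nrow, 2 * P)),
            np.broadcast_to(absd, (nrow, 2 * P)),
            -scores,
        )
        order = np.lexsort(keys, axis=-1)
        best = order[:, 0]
        row = np.arange(nrow)
        best_scores = scores[row, best]
        for r_i, seq_i in enumerate(idxs):
            if not np.isfinite(best_scores[r_i]):
                continue
            j = int(best[r_i])
            results[seq_i] = BestMatch(
                seq_id=seqs[seq_i].seq_id,
                offset=int(offsets[j]),
                strand="+" if strand_code[j] == 0 else "-",
                log_odds=float(best_scores[r_i]),
                center_displacement=float(disp[j]),
            )
    return results


def best_match(
    seq: SequenceRecord,
    pwm: Pwm,
    bg: Background,
    min_score: float = 0.0,
    pseudocount: float = 0.01,
) -> BestMatch | None:
    """Single-sequence convenience wrapper around :func:`scan_best_matches`."""
    return scan_best_matches([seq], pwm, bg, min_score, pseudocount)[0]
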