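"""CentriMo-style central enrichment of motifs within uniform-width peaks.

For every motif the best match per sequence is located, and the counts of
matches falling inside centered windows of increasing width are tested
against a positional null: a binomial upper tail in non-differential mode
(a best match lands uniformly among the L - m + 1 possible positions), or a
one-sided Fisher exact test of positive-set versus negative-set in-window
counts in differential mode.  Raw p-values are corrected into E-values by
multiplying by the number of tests performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import PeakSet
from .motifs import Background, BestMatch, Pwm, SequenceRecord, scan_best_matches

log = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "ScanConfig",
    "EnrichmentResult",
    "EnrichmentReport",
    "candidate_windows",
    "site_distribution",
    "binomial_central_pvalue",
    "fisher_differential_pvalue",
    "scan_enrichment",
    "report_to_frame",
    "write_report",
]


@dataclass(frozen=True)
class WindowSpec:
    """A centered displacement window.

    ``half_width`` is the largest |center displacement| (bp) admitted;
    ``covered_positions`` (w) of the ``total_positions`` (L - m + 1)
    possible best-site centers fall inside, giving the binomial success
    probability ``p_win = w / (L - m + 1)``.
    """

    half_width: float
    covered_positions: int
    total_positions: int

    def __post_init__(self) -> None:
        if not 1 <= self.covered_positions <= self.total_positions:
            raise ValueError(
                f"covered_positions {self.covered_positions} outside "
                f"[1, {self.total_positions}]"
            )

    @property
    def p_win(self) -> float:
        return self.covered_positions / self.total_positions


@dataclass
class ScanConfig:
    """Knobs for motif scanning and window evaluation.

    ``correction`` selects the multiple-testing burden used for E-values:
    ``"windows"`` counts every (motif, window) test; ``"motifs"`` counts
    motifs only, matching tools that correct over the database size alone.
    """

    pseudocount: float = 0.01
    min_score: float = 0.0
    max_window: int | None = None
    background: Background | None = None
    alpha: float = 0.1
    correction: str = "windows"

    def __post_init__(self) -> None:
        if self.correction not in ("windows", "motifs"):
            raise ValueError(f"unknown correction mode {self.correction!r}")


@dataclass
class EnrichmentResult:
    motif_id: str
    mode: str  # "binomial" | "fisher"
    best_window: WindowSpec
    k_pos: int
    n_pos: int
    p_raw: float
    e_value: float = np.nan
    corrected_p: float = np.nan
    significant: bool = False
    k_neg: int | None = None
    n_neg: int | None = None
    matched_pos_peaks: PeakSet = field(default_factory=PeakSet)
    matched_neg_peaks: PeakSet = field(default_factory=PeakSet)
    n_windows: int = 0
    rank: int | None = None


@dataclass
class EnrichmentReport:
    """Per-motif enrichment results ranked by increasing E-value."""

    results: list[EnrichmentResult]
    n_tests: int
    mode: str
    skipped: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.results)

    def get(self, motif_id: str) -> EnrichmentResult | None:
        for res in self.results:
            if res.motif_id == motif_id:
                return res
        return None


def candidate_windows(
    L: int, m: int, max_window: int | None = None
) -> list[WindowSpec]:
    """All centered displacement windows, narrowest first.

    Displacements take the L - m + 1 values ``offset - (L - m)/2``; windows
    grow symmetrically about 0, covering 1, 3, 5, ... positions when the
    center displacement 0 is attainable and 2, 4, ... positions when the
    parity makes displacements half-integral.
    """
    if m > L:
        raise ValueError(f"motif length {m} exceeds sequence length {L}")
    P = L - m + 1
    disp = np.arange(P) - (P - 1) / 2.0
    absvals, counts = np.unique(np.abs(disp), return_counts=True)
    out: list[WindowSpec] = []
    covered = 0
    for hw, c in zip(absvals, counts):
        covered += int(c)
        if max_window is not None and covered > max_window:
            break
        out.append(WindowSpec(float(hw), covered, P))
    return out


def site_distribution(
    matches: Iterable[BestMatch | None], L: int, m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of best-match center displacements.

    Returns ``(bins, counts)`` where ``bins`` lists every possible
    displacement for sequences of length ``L``; counts sum to the number of
    sequences with a best match.  Matches inconsistent with a length-``L``
    sequence (a mixed-length input) raise ``ValueError``.
    """
    P = L - m + 1
    bins = np.arange(P) - (P - 1) / 2.0
    counts = np.zeros(P, dtype=int)
    for match in matches:
        if match is None:
            continue
        if not 0 <= match.offset < P or match.center_displacement != (
            match.offset - (L - m) / 2.0
        ):
            raise ValueError(
                f"match at offset {match.offset} (displacement "
                f"{match.center_displacement}) inconsistent with uniform "
                f"sequence length {L}"
            )
        counts[match.offset] += 1
    return bins, counts


def binomial_central_pvalue(k: int, n: int, win: WindowSpec) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(n, p_win); 1.0 when k == 0."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, win.p_win))


def fisher_differential_pvalue(
    k_pos: int, n_pos: int, k_neg: int, n_neg: int
) -> float:
    """One-sided Fisher exact p-value for enrichment of in-window best
    matches in the positive set, from the table
    ``[[k_pos, n_pos - k_pos], [k_neg, n_neg - k_neg]]``.
    """
    if not (0 <= k_pos <= n_pos and 0 <= k_neg <= n_neg):
        raise ValueError("need 0 <= k <= n for both sets")
    if n_pos + n_neg == 0:
        raise ValueError("need n_pos + n_neg > 0")
    if k_pos == 0:
        return 1.0
    res = stats.fisher_exact(
        [[k_pos, n_pos - k_pos], [k_neg, n_neg - k_neg]], alternative="greater"
    )
    return min(float(res.pvalue), 1.0)


def _matched_origins(
    seqs: Sequence[SequenceRecord],
    matches: Sequence[BestMatch | None],
    half_width: float,
    label: str,
) -> PeakSet:
    out = []
    for rec, match in zip(seqs, matches):
        if match is None or abs(match.center_displacement) > half_width:
            continue
        if rec.origin is not None:
            out.append(rec.origin)
    return PeakSet(out, label=label)


def _uniform_length(seqs: Sequence[SequenceRecord], what: str) -> int:
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(
            f"{what} sequences must have uniform length, got lengths "
            f"{sorted(lengths)}"
        )
    return lengths.pop()


def scan_enrichment(
    pos_seqs: Sequence[SequenceRecord],
    neg_seqs: Sequence[SequenceRecord] | None,
    motifs: Sequence[Pwm],
    cfg: ScanConfig | None = None,
) -> EnrichmentReport:
    """Score central enrichment of every motif and rank by E-value.

    Differential (Fisher) mode is selected by passing a negative sequence
    set (``neg_seqs is not None``); otherwise the binomial positional test
    is used.  In differential mode the best window is chosen on the
    positive-set binomial statistic and the Fisher test is then computed at
    that window.  Sequences with no best match count in neither k nor n.
    """
    cfg = cfg or ScanConfig()
    if not motifs:
        raise ValueError("motif list is empty")
    if not pos_seqs:
        raise ValueError("no positive sequences")
    L = _uniform_length(pos_seqs, "positive")
    mode = "binomial" if neg_seqs is None else "fisher"
    if mode == "fisher":
        if neg_seqs:
            L_neg = _uniform_length(neg_seqs, "negative")
            if L_neg != L:
                raise ValueError(
                    f"positive ({L}) and negative ({L_neg}) sequence lengths differ"
                )
        else:
            log.warning(
                "differential mode with an empty negative set: Fisher test is "
                "degenerate (p = 1 unless the table is vacuous)"
            )
    bg = cfg.background or Background.from_sequences(pos_seqs)

    results: list[EnrichmentResult] = []
    skipped: list[str] = []
    for pwm in motifs:
        if pwm.length > L:
            log.info(
                "motif %s (length %d) longer than sequences (%d): skipped",
                pwm.motif_id,
                pwm.length,
                L,
            )
            skipped.append(pwm.motif_id)
            continue
        windows = candidate_windows(L, pwm.length, cfg.max_window)
        pos_matches = scan_best_matches(
            pos_seqs, pwm, bg, cfg.min_score, cfg.pseudocount
        )
        pos_absd = np.sort(
            [abs(m.center_displacement) for m in pos_matches if m is not None]
        )
        n_pos = len(pos_absd)
        half_widths = np.array([w.half_width for w in windows])
        k_by_window = np.searchsorted(pos_absd, half_widths, side="right")

        best_i, best_p = 0, np.inf
        for i, win in enumerate(windows):  # ascending width: ties -> narrowest
            p = binomial_central_pvalue(int(k_by_window[i]), n_pos, win)
            if p < best_p:
                best_i, best_p = i, p
        best_win = windows[best_i]
        k_pos = int(k_by_window[best_i])

        k_neg = n_neg = None
        neg_matches: list[BestMatch | None] = []
        if mode == "fisher":
            neg_matches = scan_best_matches(
                neg_seqs or [], pwm, bg, cfg.min_score, cfg.pseudocount
            )
            good = [m for m in neg_matches if m is not None]
            n_neg = len(good)
            k_neg = sum(
                1
                for m in good
                if abs(m.center_displacement) <= best_win.half_width
            )
            p_raw = fisher_differential_pvalue(k_pos, n_pos, k_neg, n_neg)
        else:
            p_raw = best_p

        results.append(
            EnrichmentResult(
                motif_id=pwm.motif_id,
                mode=mode,
                best_window=best_win,
                k_pos=k_pos,
                n_pos=n_pos,
                k_neg=k_neg,
                n_neg=n_neg,
                p_raw=float(min(p_raw, 1.0)),
                matched_pos_peaks=_matched_origins(
                    pos_seqs, pos_matches, best_win.half_width, "pos"
                ),
                matched_neg_peaks=_matched_origins(
                    neg_seqs or [], neg_matches, best_win.half_width, "neg"
                ),
                n_windows=len(windows),
            )
        )

    if cfg.correction == "motifs":
        n_tests = len(results)
    else:
        n_tests = sum(res.n_windows for res in results)
    for res in results:
        res.e_value = min(res.p_raw, 1.0) * n_tests
        res.corrected_p = min(res.p_raw * n_tests, 1.0)
        res.significant = res.corrected_p <= cfg.alpha

    results.sort(
        key=lambda r: (
            r.e_value,
            -(r.k_pos / r.n_pos if r.n_pos else 0.0),
            r.motif_id,
        )
    )
    for rank, res in enumerate(results, start=1):
        res.rank = rank
    return EnrichmentReport(results=results, n_tests=n_tests, mode=mode, skipped=skipped)


def report_to_frame(report: EnrichmentReport) -> pd.DataFrame:
    rows = []
    for res in report.results:
        rows.append(
            {
                "motif_id": res.motif_id,
                "mode": res.mode,
                "rank": res.rank,
                "window_half_width": res.best_window.half_width,
                "window_positions": res.best_window.covered_positions,
                "total_positions": res.best_window.total_positions,
                "k_pos": res.k_pos,
                "n_pos": res.n_pos,
                "k_neg": res.k_neg,
                "n_neg": res.n_neg,
                "p_raw": res.p_raw,
                "e_value": res.e_value,
                "corrected_p": res.corrected_p,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "motif_id",
            "mode",
            "rank",
            "window_half_width",
            "window_positions",
            "total_positions",
            "k_pos",
            "n_pos",
            "k_neg",
            "n_neg",
            "p_raw",
            "e_value",
            "corrected_p",
            "significant",
        ],
    )


def write_report(report: EnrichmentReport, path) -> None:
    report_to_frame(report).to_csv(path, sep="\t", index=False)
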