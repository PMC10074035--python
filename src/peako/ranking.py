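"""The knockout-aware motif ranking metric r.

For each motif, three matched-peak sets feed the score: A_WT and A_KO, the
positive- and negative-set peaks matched by the differential enrichment arm
(Pipeline A), and B, the peaks matched by the non-differential arm run on
differentially called peaks (Pipeline B).  The score

    r = |merge(intersect_keep_a(subtract_all(A_WT, A_KO), B))| / |A_WT|

is the proportion of A_WT peaks that survive whole-interval removal of
anything overlapping A_KO, overlap a B peak by at least 1 bp, and remain
after merging overlapping/book-ended/duplicate regions.  The merge step
guarantees 0 <= r <= 1.  Motifs whose multiple-testing corrected p-value
exceeds the significance threshold (default 0.1) are filtered before
ranking and listed after all retained motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .intervals import PeakSet, intersect_keep_a, merge_intervals, subtract_all

__all__ = [
    "PeakoInput",
    "PeakoRecord",
    "peako_score",
    "numerator_regions",
    "filter_significant",
    "rank_motifs",
    "score_and_rank",
    "records_to_frame",
]

FILTER_MODES = ("both", "either", "pipeline-a")


@dataclass
class PeakoInput:
    """Per-motif matched peak sets and carried significance values.

    ``e_value_a`` / ``e_value_b`` are the corrected E-values from the two
    enrichment reports; ``corrected_p_a`` / ``corrected_p_b`` are the
    corresponding Bonferroni-corrected p-values (capped at 1) used by the
    significance filter.  A missing side (motif absent from that report) is
    represented by ``None`` and treated as non-significant.
    """

    motif_id: str
    a_wt: PeakSet = field(default_factory=PeakSet)
    a_ko: PeakSet = field(default_factory=PeakSet)
    b: PeakSet = field(default_factory=PeakSet)
    e_value_a: float | None = None
    e_value_b: float | None = None
    corrected_p_a: float | None = None
    corrected_p_b: float | None = None


@dataclass
class PeakoRecord:
    motif_id: str
    numerator: int
    denominator: int
    r: float
    rank: int | None = None
    filtered: bool = False
    reason: str = ""
    e_value_a: float | None = None
    e_value_b: float | None = None


def numerator_regions(a_wt: PeakSet, a_ko: PeakSet, b: PeakSet) -> PeakSet:
    """The merged regions counted by the numerator of r."""
    survivors = subtract_all(a_wt.deduplicated(), a_ko)
    supported = intersect_keep_a(survivors, b)
    return merge_intervals(supported)


def peako_score(
    a_wt: PeakSet, a_ko: PeakSet, b: PeakSet
) -> tuple[int, int, float]:
    """Compute (numerator, denominator, r) for one motif.

    A_WT is deduplicated by coordinate before counting so |A_WT| is well
    defined; r is 0 when A_WT is empty (callers flag this as ``empty_wt``).
    """
    a_wt = a_wt.deduplicated()
    numerator = len(numerator_regions(a_wt, a_ko, b))
    denominator = len(a_wt)
    r = numerator / denominator if denominator else 0.0
    return numerator, denominator, r


def _corrected(p: float | None, e: float | None) -> float:
    """Corrected p for filtering; falls back to the E-value capped at 1."""
    if p is not None:
        return p
    if e is not None:
        return min(e, 1.0)
    return math.inf


def filter_significant(
    inputs: list[PeakoInput], alpha: float = 0.1, mode: str = "both"
) -> tuple[list[PeakoInput], list[PeakoInput]]:
    """Partition motifs into (retained, filtered) by corrected p <= alpha.

    The rule removes only corrected p-values strictly greater than
    ``alpha``, so p == alpha is retained.  ``mode`` selects which arm(s)
    must be significant: ``both`` (default, both peak sets enter r),
    ``either``, or ``pipeline-a``.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if mode not in FILTER_MODES:
        raise ValueError(f"unknown filter mode {mode!r}; choose from {FILTER_MODES}")
    kept: list[PeakoInput] = []
    dropped: list[PeakoInput] = []
    for inp in inputs:
        sig_a = _corrected(inp.corrected_p_a, inp.e_value_a) <= alpha
        sig_b = _corrected(inp.corrected_p_b, inp.e_value_b) <= alpha
        if mode == "both":
            ok = sig_a and sig_b
        elif mode == "either":
            ok = sig_a or sig_b
        else:
            ok = sig_a
        (kept if ok else dropped).append(inp)
    return kept, dropped


def rank_motifs(records: list[PeakoRecord]) -> list[PeakoRecord]:
    """Rank motifs by descending r; ties broken by smaller Pipeline A
    E-value, then smaller Pipeline B E-value, then motif id.

    Filtered motifs are listed after all retained motifs, ordered
    alphanumerically by motif id (their ranks are reported but carry no
    evidence).
    """
    inf = math.inf
    retained = [rec for rec in records if not rec.filtered]
    filtered = [rec for rec in records if rec.filtered]
    retained.sort(
        key=lambda rec: (
            -rec.r,
            rec.e_value_a if rec.e_value_a is not None else inf,
            rec.e_value_b if rec.e_value_b is not None else inf,
            rec.motif_id,
        )
    )
    filtered.sort(key=lambda rec: rec.motif_id)
    ranked = retained + filtered
    for rank, rec in enumerate(ranked, start=1):
        rec.rank = rank
    return ranked


def score_and_rank(
    inputs: list[PeakoInput], alpha: float = 0.1, mode: str = "both"
) -> list[PeakoRecord]:
    """Filter, score and rank: the full motif-ranking step."""
    kept, dropped = filter_significant(inputs, alpha=alpha, mode=mode)
    records: list[PeakoRecord] = []
    for inp in kept:
        num, den, r = peako_score(inp.a_wt, inp.a_ko, inp.b)
        rec = PeakoRecord(
            inp.motif_id, num, den, r, e_value_a=inp.e_value_a, e_value_b=inp.e_value_b
        )
        if den == 0:
            rec.filtered = True
            rec.reason = "empty_wt"
        records.append(rec)
    for inp in dropped:
        num, den, r = peako_score(inp.a_wt, inp.a_ko, inp.b)
        records.append(
            PeakoRecord(
                inp.motif_id,
                num,
                den,
                r,
                filtered=True,
                reason="insignificant",
                e_value_a=inp.e_value_a,
                e_value_b=inp.e_value_b,
            )
        )
    return rank_motifs(records)


def records_to_frame(records: list[PeakoRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": rec.rank,
                "motif_id": rec.motif_id,
                "r": rec.r,
                "numerator": rec.numerator,
                "denominator": rec.denominator,
                "filtered": rec.filtered,
                "reason": rec.reason or ".",
                "e_value_a": rec.e_value_a,
                "e_value_b": rec.e_value_b,
            }
            for rec in records
        ],
        columns=[
            "rank",
            "motif_id",
            "r",
            "numerator",
            "denominator",
            "filtered",
            "reason",
            "e_value_a",
            "e_value_b",
        ],
    )
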