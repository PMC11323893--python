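"""Truth-vs-callset comparison: one-to-one SV matching and precision /
recall / F1, for scoring callsets against an implanted truth set."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import SVRecord


@dataclass(frozen=True)
class MatchParams:
    """Eligibility thresholds for pairing a call with a truth SV."""

    refdist: int = 500        # max |start difference| in bp
    pctsize: float = 0.7      # min length ratio min(len)/max(len)
    require_type_match: bool = True

    def __post_init__(self) -> None:
        if self.refdist < 0:
            raise ValueError("refdist must be >= 0")
        if not (0 < self.pctsize <= 1):
            raise ValueError("pctsize must be in (0, 1]")


@dataclass(frozen=True)
class BenchmarkResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }


def eligible(t: SVRecord, c: SVRecord, params: MatchParams) -> bool:
    if t.contig != c.contig:
        return False
    if params.require_type_match and t.svtype != c.svtype:
        return False
    if abs(t.start - c.start) > params.refdist:
        return False
    return min(t.length, c.length) / max(t.length, c.length) >= params.pctsize


def match_callsets(
    truth: Sequence[SVRecord],
    calls: Sequence[SVRecord],
    params: MatchParams = MatchParams(),
) -> list[tuple[SVRecord, SVRecord]]:
    """One-to-one matching of calls to truth SVs.

    Eligible pairs are first consumed greedily in order of ascending
    start distance (ties: ascending length difference, then record
    ids); a deterministic augmenting-path pass then extends the greedy
    matching to maximum cardinality, so no eligible pairing is lost to
    an unlucky greedy choice.  Each truth SV and each call is used at
    most once.
    """
    pairs = [
        (abs(t.start - c.start), abs(t.length - c.length),
         t.record_id, c.record_id, ti, ci)
        for ti, t in enumerate(truth)
        for ci, c in enumerate(calls)
        if eligible(t, c, params)
    ]
    pairs.sort()
    match_of_t: dict[int, int] = {}
    match_of_c: dict[int, int] = {}
    for _, _, _, _, ti, ci in pairs:
        if ti in match_of_t or ci in match_of_c:
            continue
        match_of_t[ti] = ci
        match_of_c[ci] = ti

    # adjacency in greedy preference order, for the augmentation pass
    adj: dict[int, list[int]] = {}
    for _, _, _, _, ti, ci in pairs:
        adj.setdefault(ti, []).append(ci)

    def try_augment(ti: int, seen: set[int]) -> bool:
        for ci in adj.get(ti, ()):
            if ci in seen:
                continue
            seen.add(ci)
            other = match_of_c.get(ci)
            if other is None or try_augment(other, seen):
                match_of_t[ti] = ci
                match_of_c[ci] = ti
                return True
        return False

    for ti in sorted(adj):
        if ti not in match_of_t:
            try_augment(ti, set())

    return [(truth[ti], calls[ci]) for ti, ci in sorted(match_of_t.items())]


def benchmark_metrics(
    matching: Sequence[tuple[SVRecord, SVRecord]],
    truth: Sequence[SVRecord],
    calls: Sequence[SVRecord],
) -> BenchmarkResult:
    tp = len(matching)
    return BenchmarkResult(tp=tp, fp=len(calls) - tp, fn=len(truth) - tp)


def benchmark(
    truth: Sequence[SVRecord],
    calls: Sequence[SVRecord],
    params: MatchParams = MatchParams(),
) -> BenchmarkResult:
    """Convenience wrapper: match then score."""
    return benchmark_metrics(match_callsets(truth, calls, params), truth, calls)
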