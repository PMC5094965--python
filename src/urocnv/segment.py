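"""Circular binary segmentation of log2-ratio profiles.

Each chromosome's usable bins are recursively partitioned: the candidate
change is the arc (contiguous run, complement taken circularly) maximizing
the two-sample t statistic between arc and complement, accepted when a
permutation test on the tested span yields p <= alpha. The recursion
continues inside accepted pieces. Parameters (alpha, permutation count,
seed) are recorded in the output so any segmentation is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import CentromereTable, GenomeBins, InvalidInputError
from .normalize import LogRatioProfile

FILTER_NONE = "none"
FILTER_TOO_SMALL = "too_small"
FILTER_CENTROMERE = "centromere"


@dataclass
class Segment:
    chrom: str
    start: int               # bp, 0-based
    end: int                 # bp, half-open
    first_bin: int           # genome bin index of first member bin
    last_bin: int            # genome bin index of last member bin
    n_bins: int              # number of usable member bins
    mean_log2: float
    rank_stat: float         # |mean_log2| * sqrt(n_bins)
    filtered: str = FILTER_NONE

    @property
    def is_filtered(self) -> bool:
        return self.filtered != FILTER_NONE


@dataclass
class SegmentedProfile:
    profile: LogRatioProfile
    segments: list[Segment]
    parameters: dict = field(default_factory=dict)

    @property
    def unfiltered(self) -> list[Segment]:
        return [s for s in self.segments if not s.is_filtered]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "chrom": s.chrom, "start": s.start, "end": s.end,
            "n_bins": s.n_bins, "mean_log2": s.mean_log2,
            "rank_stat": s.rank_stat, "filtered_reason": s.filtered,
        } for s in self.segments])

    def to_bed(self, path) -> None:
        import pandas as pd
        rows = [{
            "chrom": s.chrom, "start": s.start, "end": s.end,
            "name": f"seg_{i}", "score": round(1000 * abs(s.mean_log2)),
            "strand": ".", "mean_log2": s.mean_log2, "n_bins": s.n_bins,
            "rank_stat": s.rank_stat, "filtered_reason": s.filtered,
        } for i, s in enumerate(self.segments)]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def _arc_t_stats(S: np.ndarray, Q: np.ndarray, k: int, n: int) -> np.ndarray:
    """t statistics of all arcs of length k vs their complements.

    ``S``/``Q`` are zero-prefixed cumulative sums of values/squares; rows
    may be a batch. Returns array of shape (..., n - k + 1).
    """
    m = n - k
    sum1 = S[..., k:] - S[..., :-k] if k > 0 else None
    sq1 = Q[..., k:] - Q[..., :-k]
    total, total_sq = S[..., -1:], Q[..., -1:]
    mean1 = sum1 / k
    mean2 = (total - sum1) / m
    ss_within = (total_sq - sq1 - m * mean2 ** 2) + (sq1 - k * mean1 ** 2)
    df = max(n - 2, 1)
    var_p = np.maximum(ss_within / df, 0.0)
    denom = np.sqrt(var_p * (1.0 / k + 1.0 / m))
    diff = np.abs(mean1 - mean2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom,
                     np.where(diff > 0, np.inf, 0.0))
    return t


def _max_arc_stat(x: np.ndarray) -> tuple[float, int, int]:
    """Best arc (i, j), 0 <= i < j <= n, (j - i) < n, by the t statistic.

    Ties are broken toward the earliest genomic position (lexicographically
    smallest (i, j))."""
    n = len(x)
    S = np.concatenate(([0.0], np.cumsum(x)))
    Q = np.concatenate(([0.0], np.cumsum(x * x)))
    best, best_i, best_j = -np.inf, 0, 0
    for k in range(1, n):
        t = _arc_t_stats(S, Q, k, n)
        i = int(np.argmax(t))
        tk = float(t[i])
        if tk > best + 1e-12:
            best, best_i, best_j = tk, i, i + k
        elif abs(tk - best) <= 1e-12 and (i, i + k) < (best_i, best_j):
            best_i, best_j = i, i + k
    return best, best_i, best_j


def _perm_p_value(x: np.ndarray, observed: float, n_permutations: int,
                  alpha: float, rng: np.random.Generator) -> float:
    """Permutation p-value of the max arc statistic, with early stop.

    Permutations run in batches; once the exceedance count guarantees
    p > alpha the remaining batches are skipped (the decision is already
    fixed)."""
    n = len(x)
    stop_count = int(np.floor(alpha * (n_permutations + 1)))
    exceed, done = 0, 0
    batch = max(1, min(200, int(4e6 / max(n * n, 1)) or 1, n_permutations))
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        X = rng.permuted(np.tile(x, (b, 1)), axis=1)
        S = np.concatenate((np.zeros((b, 1)), np.cumsum(X, axis=1)), axis=1)
        Q = np.concatenate((np.zeros((b, 1)), np.cumsum(X * X, axis=1)),
                           axis=1)
        maxes = np.full(b, -np.inf)
        for k in range(1, n):
            t = _arc_t_stats(S, Q, k, n)
            np.maximum(maxes, t.max(axis=1), out=maxes)
        exceed += int((maxes >= observed - 1e-12).sum())
        done += b
        if exceed > stop_count:
            break
    return (1 + exceed) / (1 + n_permutations)


def _segment_array(x: np.ndarray, alpha: float, n_permutations: int,
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    """Recursive CBS on one array; returns half-open index spans."""
    n = len(x)
    if n < 2:
        return [(0, n)]
    stat, i, j = _max_arc_stat(x)
    if not (stat > 0):
        return [(0, n)]
    p = _perm_p_value(x, stat, n_permutations, alpha, rng)
    if p > alpha:
        return [(0, n)]
    out: list[tuple[int, int]] = []
    for a, b in ((0, i), (i, j), (j, n)):
        if b > a:
            for s, e in _segment_array(x[a:b], alpha, n_permutations, rng):
                out.append((a + s, a + e))
    return out


def segment_profile(profile: LogRatioProfile, alpha: float = 0.01,
                    n_permutations: int = 1000,
                    seed: int = 17) -> SegmentedProfile:
    """Segment a log2-ratio profile chromosome by chromosome.

    Chromosomes are independent; within each, usable bins form the data
    vector (masked/unusable bins are skipped, so a segment may bridge a
    masked gap). Each segment is annotated with its arithmetic mean log2
    ratio and the ranking statistic |mean| * sqrt(n_bins).
    """
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha must be in (0, 1)")
    bins = profile.bins
    if int(profile.usable.sum()) < 2:
        raise InvalidInputError("fewer than 2 usable bins")
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    for chrom in bins.chrom_sizes.names:
        idx = bins.chrom_index(chrom)
        usable_idx = idx[profile.usable[idx]]
        if len(usable_idx) == 0:
            continue
        x = profile.log2_ratio[usable_idx]
        for s, e in _segment_array(x, alpha, n_permutations, rng):
            member = usable_idx[s:e]
            mean = float(x[s:e].mean())
            segments.append(Segment(
                chrom=chrom,
                start=int(bins.start[member[0]]),
                end=int(bins.end[member[-1]]),
                first_bin=int(member[0]), last_bin=int(member[-1]),
                n_bins=len(member), mean_log2=mean,
                rank_stat=abs(mean) * np.sqrt(len(member)),
            ))
    return SegmentedProfile(profile, segments, {
        "alpha": alpha, "n_permutations": n_permutations, "seed": seed})


def filter_segments(segmented: SegmentedProfile, min_bins: int = 4,
                    centromeres: CentromereTable | None = None,
                    pad: int | None = None) -> SegmentedProfile:
    """Mark segments excluded from scoring, keeping them in the record.

    Segments with at most ``min_bins`` bins are marked ``too_small``
    (repetitive-sequence artifacts tend to be short); segments overlapping
    a centromere padded by ``pad`` (default 1 Mb) are marked
    ``centromere``. Marking, not deletion, so reports can show why a
    segment was dropped.
    """
    if min_bins < 1:
        raise InvalidInputError("min_bins must be >= 1")
    padded = centromeres.padded(pad) if centromeres is not None else {}
    out = []
    for seg in segmented.segments:
        reason = FILTER_NONE
        if seg.n_bins <= min_bins:
            reason = FILTER_TOO_SMALL
        elif seg.chrom in padded:
            lo, hi = padded[seg.chrom]
            if seg.start < hi and seg.end > lo:
                reason = FILTER_CENTROMERE
        out.append(replace(seg, filtered=reason))
    params = dict(segmented.parameters)
    params.update({"min_bins": min_bins,
                   "centromere_pad": (pad if pad is not None else
                                      getattr(centromeres, "pad", None))})
    return SegmentedProfile(segmented.profile, out, params)
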