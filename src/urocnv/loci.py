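"""Gene-locus amplification/deletion calls and cross-sample minimal-overlap
regions.

A gene call looks up the unfiltered segment best matching the gene span and
thresholds its mean log2 ratio. Minimal-overlap analysis intersects
same-direction aberrant segments across samples to find the shared core
regions — the depth-based analogue of recurrent CNV discovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import GeneLocus, InvalidInputError, tcra_locus
from .segment import Segment, SegmentedProfile

AMPLIFIED = "amplified"
DELETED = "deleted"
NEUTRAL = "neutral"
NO_DATA = "no_data"

DEFAULT_GAIN_THRESHOLD = 0.15
DEFAULT_LOSS_THRESHOLD = 0.15


@dataclass
class LocusCall:
    sample_id: str
    gene: GeneLocus
    status: str
    supporting_mean_log2: float | None = None
    supporting_segment: Segment | None = None


@dataclass
class MinimalOverlapRegion:
    chrom: str
    start: int
    end: int
    direction: str                     # "amplification" | "deletion"
    supporting_samples: list[str]
    cytoband: str | None = None


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def call_gene_locus(segmented: SegmentedProfile, gene: GeneLocus,
                    gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
                    loss_threshold: float = DEFAULT_LOSS_THRESHOLD) -> LocusCall:
    """Call a gene amplified/deleted/neutral from its best-matching segment.

    Among unfiltered segments overlapping the gene, the one with maximal
    reciprocal overlap (min of overlap/segment-length and overlap/gene-
    length) supplies the supporting mean; the call compares it with the
    thresholds. No overlapping segment gives ``no_data``.
    """
    if gain_threshold <= 0 or loss_threshold <= 0:
        raise InvalidInputError("thresholds must be positive")
    chroms = {s.chrom for s in segmented.segments}
    if gene.chrom not in chroms:
        raise InvalidInputError(
            f"gene chromosome {gene.chrom} absent from segmentation")
    sample_id = segmented.profile.sample_id
    best, best_key = None, (-1.0, -1.0)
    for seg in segmented.unfiltered:
        if seg.chrom != gene.chrom:
            continue
        ov = _overlap(seg.start, seg.end, gene.start, gene.end)
        if ov == 0:
            continue
        recip = min(ov / (seg.end - seg.start), ov / (gene.end - gene.start))
        key = (recip, ov)
        if key > best_key:
            best, best_key = seg, key
    if best is None:
        return LocusCall(sample_id, gene, NO_DATA)
    mean = best.mean_log2
    if mean >= gain_threshold:
        status = AMPLIFIED
    elif mean <= -loss_threshold:
        status = DELETED
    else:
        status = NEUTRAL
    return LocusCall(sample_id, gene, status, mean, best)


def aberrant_segments(segmented: SegmentedProfile, direction: str,
                      gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
                      loss_threshold: float = DEFAULT_LOSS_THRESHOLD
                      ) -> list[Segment]:
    """Unfiltered segments exceeding the aberrance threshold in one direction."""
    if direction == "amplification":
        return [s for s in segmented.unfiltered
                if s.mean_log2 >= gain_threshold]
    if direction == "deletion":
        return [s for s in segmented.unfiltered
                if s.mean_log2 <= -loss_threshold]
    raise InvalidInputError(f"unknown direction {direction!r}")


def _subtract_excluded(intervals: list[tuple[int, int]],
                       excludes: list[tuple[int, int]]
                       ) -> list[tuple[int, int]]:
    out = intervals
    for xs, xe in excludes:
        nxt = []
        for s, e in out:
            if e <= xs or s >= xe:
                nxt.append((s, e))
            else:
                if s < xs:
                    nxt.append((s, xs))
                if e > xe:
                    nxt.append((xe, e))
        out = nxt
    return out


def minimal_overlap_regions(per_sample_segments: dict[str, list[Segment]],
                            direction: str, min_samples: int = 2,
                            exclude_loci: list[GeneLocus] | None = None
                            ) -> list[MinimalOverlapRegion]:
    """Shared core intervals of same-direction aberrant segments.

    The genome is decomposed at every segment boundary; elementary
    intervals covered by segments from at least ``min_samples`` samples
    are kept and adjacent intervals with identical supporting sample sets
    are merged, so every emitted region is fully covered by each of its
    supporters. Regions overlapping an exclude locus (default: the TCRA
    pseudo-amplification locus) are clipped out first.
    """
    if min_samples < 2:
        raise InvalidInputError("min_samples must be >= 2")
    if exclude_loci is None:
        exclude_loci = [tcra_locus()]
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for sample, segs in per_sample_segments.items():
        for seg in segs:
            ivals = _subtract_excluded(
                [(seg.start, seg.end)],
                [(g.start, g.end) for g in exclude_loci
                 if g.chrom == seg.chrom])
            for s, e in ivals:
                by_chrom.setdefault(seg.chrom, []).append((s, e, sample))
    regions: list[MinimalOverlapRegion] = []
    for chrom in sorted(by_chrom):
        ivals = by_chrom[chrom]
        points = sorted({p for s, e, _ in ivals for p in (s, e)})
        prev = None  # (start, end, frozenset of samples)
        for lo, hi in zip(points[:-1], points[1:]):
            support = frozenset(sample for s, e, sample in ivals
                                if s <= lo and e >= hi)
            if len(support) >= min_samples:
                if prev is not None and prev[2] == support and prev[1] == lo:
                    prev = (prev[0], hi, support)
                else:
                    if prev is not None:
                        regions.append(MinimalOverlapRegion(
                            chrom, prev[0], prev[1], direction,
                            sorted(prev[2])))
                    prev = (lo, hi, support)
            else:
                if prev is not None:
                    regions.append(MinimalOverlapRegion(
                        chrom, prev[0], prev[1], direction, sorted(prev[2])))
                    prev = None
        if prev is not None:
            regions.append(MinimalOverlapRegion(
                chrom, prev[0], prev[1], direction, sorted(prev[2])))
    return regions


def treatment_related_regions(pair_profiles: list[SegmentedProfile],
                              genes: list[GeneLocus], min_samples: int = 2,
                              gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
                              loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
                              exclude_loci: list[GeneLocus] | None = None
                              ) -> pd.DataFrame:
    """Genes covered by shared treatment-change regions across sample pairs.

    Runs :func:`minimal_overlap_regions` on the aberrant segments of
    segmented post/pre profiles, in each direction, then reports each gene
    overlapped by a shared region together with the supporting pair ids.
    """
    if not genes:
        raise InvalidInputError("empty gene list")
    rows = []
    for direction in ("amplification", "deletion"):
        per_sample = {
            sp.profile.sample_id: aberrant_segments(
                sp, direction, gain_threshold, loss_threshold)
            for sp in pair_profiles}
        regions = minimal_overlap_regions(per_sample, direction, min_samples,
                                          exclude_loci)
        for gene in genes:
            for region in regions:
                if (region.chrom == gene.chrom
                        and _overlap(region.start, region.end,
                                     gene.start, gene.end) > 0):
                    rows.append({
                        "gene": gene.name, "chrom": gene.chrom,
                        "direction": direction,
                        "region_start": region.start,
                        "region_end": region.end,
                        "sample_pairs": ",".join(region.supporting_samples),
                    })
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "direction", "region_start",
                       "region_end", "sample_pairs"])
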