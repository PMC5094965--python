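"""Genome abnormality score (UGA/PGA), the TEff treatment-efficacy index,
group comparison and paired-profile clustering.

The abnormality score sums the absolute mean log2 ratios of the ten
highest-ranking unfiltered segments; it rises with the tumor-derived
fraction of the cfDNA and with the number and size of aberrant segments,
so it serves as a tumor-fraction proxy. TEff = log2(pre/post) * 100
summarizes score change under treatment: positive values mean the genomic
abnormality declined.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .genome import InvalidInputError
from .normalize import LogRatioProfile
from .segment import Segment, SegmentedProfile

RANK_ABS_MEAN = "abs_mean"
RANK_ABS_MEAN_SQRT_N = "abs_mean_sqrt_n"


@dataclass
class AbnormalityScore:
    sample_id: str
    score: float
    k: int                                   # segments actually summed
    contributing_segments: list[Segment]
    specimen_type: str = "urine"             # "urine" -> UGA, "plasma" -> PGA
    rank_by: str = RANK_ABS_MEAN


@dataclass
class TEffIndex:
    patient_id: str
    pre_score: AbnormalityScore
    post_score: AbnormalityScore
    value: float


def uga_score(segmented: SegmentedProfile, k: int = 10,
              rank_by: str = RANK_ABS_MEAN,
              specimen_type: str = "urine") -> AbnormalityScore:
    """Sum of the top-k absolute segment means among unfiltered segments.

    Segments are ranked descending by ``rank_by`` (|mean| by default, or
    |mean|*sqrt(n_bins)); ties go to the larger segment, then genomic
    order. When fewer than k unfiltered segments exist all are summed and
    the actual count is recorded. No unfiltered segments gives score 0.
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if rank_by not in (RANK_ABS_MEAN, RANK_ABS_MEAN_SQRT_N):
        raise InvalidInputError(f"unknown ranking {rank_by!r}")
    segs = segmented.unfiltered

    def sort_key(item):
        order, seg = item
        stat = (abs(seg.mean_log2) if rank_by == RANK_ABS_MEAN
                else seg.rank_stat)
        return (-stat, -seg.n_bins, order)

    ranked = [seg for _, seg in sorted(enumerate(segs), key=sort_key)]
    top = ranked[:k]
    return AbnormalityScore(
        sample_id=segmented.profile.sample_id,
        score=float(sum(abs(s.mean_log2) for s in top)),
        k=len(top), contributing_segments=top,
        specimen_type=specimen_type, rank_by=rank_by)


def teff_index(pre: AbnormalityScore, post: AbnormalityScore,
               patient_id: str | None = None) -> TEffIndex:
    """TEff index = log2(pre_score / post_score) * 100.

    Positive when the abnormality score declined after treatment.
    Undefined (error) when either score is non-positive — a zero score
    carries no ratio information.
    """
    if pre.score <= 0 or post.score <= 0:
        raise InvalidInputError(
            f"TEff undefined for non-positive scores "
            f"(pre={pre.score}, post={post.score})")
    if patient_id is None:
        patient_id = pre.sample_id
    return TEffIndex(patient_id, pre, post,
                     float(np.log2(pre.score / post.score) * 100.0))


def compare_groups(scores: list[AbnormalityScore],
                   labels: list[str]) -> tuple[float, float, dict]:
    """Two-sided Wilcoxon rank-sum comparison of scores between two groups.

    Returns (statistic, p-value, per-group medians). Exact p-value when
    both groups are small and tie-free, normal approximation otherwise.
    """
    from scipy import stats

    if len(scores) != len(labels):
        raise InvalidInputError("scores and labels differ in length")
    values = np.array([s.score for s in scores], dtype=float)
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise InvalidInputError(f"need exactly 2 groups, got {groups}")
    a = values[[l == groups[0] for l in labels]]
    b = values[[l == groups[1] for l in labels]]
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("each group needs >= 2 scores")
    method = "exact" if (len(a) + len(b) <= 25
                         and len(np.unique(values)) == len(values)) else "auto"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    medians = {groups[0]: float(np.median(a)), groups[1]: float(np.median(b))}
    return float(res.statistic), float(res.pvalue), medians


_PAIR_RE = re.compile(r"^(?P<patient>.+?)(?P<specimen>[USus])(?P<tp>\d+)$")


def _patient_of(sample_id: str) -> str:
    m = _PAIR_RE.match(sample_id)
    return m.group("patient") if m else sample_id


def cluster_paired_profiles(profiles: list[LogRatioProfile],
                            min_co_usable: int = 50):
    """Average-linkage clustering of profiles under 1 - Pearson distance.

    Distances use bins usable in both profiles; pairs sharing fewer than
    ``min_co_usable`` such bins are flagged unreliable. For every patient
    contributing exactly two samples (ids like ``1050U1``/``1050U2``) the
    report records whether the two are mutual nearest neighbours.

    Returns (linkage matrix, condensed distance vector, report dict).
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    n = len(profiles)
    if n < 4:
        raise InvalidInputError("need >= 4 profiles to cluster")
    fp = profiles[0].bins.fingerprint()
    for p in profiles[1:]:
        if p.bins.fingerprint() != fp:
            raise InvalidInputError("profiles on different bin tilings")
    D = np.zeros((n, n))
    unreliable = []
    for i in range(n):
        for j in range(i + 1, n):
            co = profiles[i].usable & profiles[j].usable
            if int(co.sum()) < min_co_usable:
                unreliable.append((profiles[i].sample_id,
                                   profiles[j].sample_id))
                D[i, j] = D[j, i] = 2.0
                continue
            xi = profiles[i].log2_ratio[co]
            xj = profiles[j].log2_ratio[co]
            sx, sy = xi.std(), xj.std()
            r = 0.0 if sx == 0 or sy == 0 else float(np.corrcoef(xi, xj)[0, 1])
            D[i, j] = D[j, i] = 1.0 - r
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method="average")

    nn = np.argmin(D + np.diag(np.full(n, np.inf)), axis=1)
    by_patient: dict[str, list[int]] = {}
    for i, p in enumerate(profiles):
        by_patient.setdefault(_patient_of(p.sample_id), []).append(i)
    pair_status = {}
    for patient, idxs in by_patient.items():
        if len(idxs) == 2:
            i, j = idxs
            pair_status[patient] = bool(nn[i] == j and nn[j] == i)
    report = {
        "n_profiles": n,
        "pairs_mutual_nn": sum(pair_status.values()),
        "pairs_total": len(pair_status),
        "pair_status": pair_status,
        "unreliable_pairs": unreliable,
    }
    return Z, condensed, report
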