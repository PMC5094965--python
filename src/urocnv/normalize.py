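"""cfDNA/gDNA log2-ratio profiles and GC-bias correction.

The per-bin ratio of globally scaled cfDNA counts to matched germline
counts cancels constitutional copy number; the log2 transform makes gains
and losses symmetric around 0. Residual dependence of the log2 ratio on bin
GC content (library-prep amplification bias) is removed by subtracting a
smooth fit of ratio on GC, re-centred so the correction is level-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeBins, InvalidInputError, assert_same_bins
from .counting import BinCounts


@dataclass
class LogRatioProfile:
    """Per-bin log2 ratio vector with a usable-bin flag.

    Unusable bins (genome-masked, zero numerator, low-coverage denominator)
    carry NaN and are excluded from every downstream computation; missing
    values never become zeros.
    """

    sample_id: str
    bins: GenomeBins
    log2_ratio: np.ndarray          # NaN where not usable
    usable: np.ndarray              # bool
    gc_corrected: bool = False
    numerator_id: str = ""
    denominator_id: str = ""

    @property
    def values(self) -> np.ndarray:
        """log2 ratios at usable bins."""
        return self.log2_ratio[self.usable]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "chrom": self.bins.chrom, "start": self.bins.start,
            "end": self.bins.end, "log2_ratio": self.log2_ratio,
            "usable": self.usable.astype(int)})

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#sample_id={self.sample_id}\t"
                     f"gc_corrected={int(self.gc_corrected)}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def ratio_profile(numerator: BinCounts, denominator: BinCounts,
                  min_denominator_raw: int = 10,
                  sample_id: str | None = None) -> LogRatioProfile:
    """log2(numerator_scaled / denominator_scaled) per bin.

    Bins are usable only where the genome mask is clear, the scaled
    numerator is positive, and the raw denominator has at least
    ``min_denominator_raw`` reads (guards the log against germline
    dropout bins).
    """
    assert_same_bins(numerator.bins, denominator.bins)
    for c in (numerator, denominator):
        if c.scaled is None:
            raise InvalidInputError(f"{c.sample_id}: counts not scaled")
    bins = numerator.bins
    usable = (~bins.masked
              & (numerator.scaled > 0)
              & (denominator.raw >= min_denominator_raw))
    lr = np.full(bins.n_bins, np.nan)
    lr[usable] = np.log2(numerator.scaled[usable]
                         / denominator.scaled[usable])
    return LogRatioProfile(
        sample_id or f"{numerator.sample_id}/{denominator.sample_id}",
        bins, lr, usable, False,
        numerator.sample_id, denominator.sample_id)


def treatment_change_profile(pre: BinCounts, post: BinCounts,
                             min_denominator_raw: int = 10,
                             sample_id: str | None = None) -> LogRatioProfile:
    """Direct post/pre log2 ratio profile for treatment-change analysis.

    Same contract as :func:`ratio_profile` with numerator = post-treatment
    and denominator = pre-treatment scaled counts; labelled with the
    "post/pre" pairing convention (e.g. ``1050U2/U1``).
    """
    if sample_id is None:
        import re
        pat = re.compile(r"^(?P<patient>.+?)(?P<spec>[USus])(?P<tp>\d+)$")
        m_pre, m_post = pat.match(pre.sample_id), pat.match(post.sample_id)
        if (m_pre and m_post
                and m_pre.group("patient") == m_post.group("patient")
                and m_pre.group("spec") == m_post.group("spec")):
            sample_id = (f"{post.sample_id}/"
                         f"{m_pre.group('spec')}{m_pre.group('tp')}")
        else:
            sample_id = f"{post.sample_id}/{pre.sample_id}"
    return ratio_profile(post, pre, min_denominator_raw, sample_id)


def _loess_fit(gc: np.ndarray, lr: np.ndarray, span: float) -> np.ndarray:
    from statsmodels.nonparametric.smoothers_lowess import lowess
    fit = lowess(lr, gc, frac=span, return_sorted=False)
    return np.asarray(fit)


def _strata_median_fit(gc: np.ndarray, lr: np.ndarray,
                       width: float) -> np.ndarray:
    strata = np.floor(gc / width).astype(int)
    fit = np.empty_like(lr)
    for s in np.unique(strata):
        sel = strata == s
        fit[sel] = np.median(lr[sel])
    return fit


def gc_correct(profile: LogRatioProfile, method: str = "loess",
               span_or_width: float | None = None) -> LogRatioProfile:
    """Remove the GC trend from a log2-ratio profile.

    ``method`` is ``"loess"`` (locally weighted regression of ratio on GC,
    default span 0.3) or ``"gc-strata-median"`` (median per GC stratum,
    default width 0.01). The fitted trend is subtracted and its median added
    back, so the profile level — and hence the abnormality score — is
    preserved. Usable flags never change.
    """
    usable = profile.usable
    if usable.sum() < 100:
        raise InvalidInputError(
            f"only {int(usable.sum())} usable bins; GC fit unidentifiable")
    gc = profile.bins.gc[usable]
    if np.isnan(gc).any():
        raise InvalidInputError("GC fraction unknown for some usable bins")
    lr = profile.log2_ratio[usable]
    if method == "loess":
        fit = _loess_fit(gc, lr, 0.3 if span_or_width is None else span_or_width)
    elif method == "gc-strata-median":
        fit = _strata_median_fit(gc, lr,
                                 0.01 if span_or_width is None else span_or_width)
    else:
        raise InvalidInputError(f"unknown GC method {method!r}")
    corrected = np.full_like(profile.log2_ratio, np.nan)
    corrected[usable] = lr - fit + np.median(fit)
    return LogRatioProfile(profile.sample_id, profile.bins, corrected,
                           usable.copy(), True,
                           profile.numerator_id, profile.denominator_id)
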