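"""Synthetic paired cfDNA/gDNA bin counts with known copy-number truth.

The generator follows the standard two-population mixture: a tumor fraction
``f`` of the cfDNA carries integer copy-number states ``cn`` while the rest
is diploid, so the expected scaled ratio in a bin is ``1 + f*(cn-2)/2`` and
the expected log2 ratio is ``log2(1 + f*(cn-2)/2)``. Counts are drawn per
bin from a negative binomial whose variance is ``dispersion`` times the
mean (default 1.3, matching the overdispersion of real shallow-WGS bin
counts), with an optional smooth GC-dependent coverage bias shared by the
cfDNA and gDNA of a pair. Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import ChromSizes, GeneLocus, GenomeBins, InvalidInputError, \
    tile_genome
from .counting import BinCounts


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated sample."""

    seed: int
    bins: GenomeBins
    tumor_fraction: float
    cn: np.ndarray                       # integer copy state per bin (2 = neutral)
    gc_bias: tuple[float, float] = (0.0, 0.0)   # (linear, quadratic) in (gc-0.45)
    depth: float = 150.0                 # mean reads per bin
    dispersion: float = 1.3              # variance / mean of the count noise
    pair_label: str = "pre"              # "pre" | "post" | "gdna"

    def __post_init__(self) -> None:
        self.cn = np.asarray(self.cn, dtype=int)
        if len(self.cn) != self.bins.n_bins:
            raise InvalidInputError("cn vector length != n_bins")
        if self.depth <= 0 or self.dispersion <= 0:
            raise InvalidInputError("depth and dispersion must be positive")
        mix = 1.0 + self.tumor_fraction * (self.cn - 2) / 2.0
        if (mix <= 0).any():
            raise InvalidInputError(
                "f*(cn-2)/2 <= -1 in some bin: negative expected coverage")

    def expected_log2(self) -> np.ndarray:
        """Expected log2 ratio per bin, log2(1 + f*(cn-2)/2)."""
        return np.log2(1.0 + self.tumor_fraction * (self.cn - 2) / 2.0)

    def gc_multiplier(self) -> np.ndarray:
        b, c = self.gc_bias
        gc = np.nan_to_num(self.bins.gc, nan=0.45)
        d = gc - 0.45
        return np.maximum(1.0 + b * d + c * d * d, 0.05)

    def expected_means(self) -> np.ndarray:
        """Per-bin expected counts, renormalized so the unmasked mean = depth."""
        mix = 1.0 + self.tumor_fraction * (self.cn - 2) / 2.0
        mu = self.gc_multiplier() * mix
        unmasked = ~self.bins.masked
        mu = mu / mu[unmasked].mean() * self.depth
        return mu

    def truth_table(self) -> pd.DataFrame:
        """Constant-CN runs as a BED-like table with expected log2 ratios."""
        rows = []
        exp = self.expected_log2()
        for chrom in self.bins.chrom_sizes.names:
            idx = self.bins.chrom_index(chrom)
            if len(idx) == 0:
                continue
            cn = self.cn[idx]
            breaks = np.flatnonzero(np.diff(cn)) + 1
            for s, e in zip(np.r_[0, breaks], np.r_[breaks, len(cn)]):
                rows.append({
                    "chrom": chrom,
                    "start": int(self.bins.start[idx[s]]),
                    "end": int(self.bins.end[idx[e - 1]]),
                    "cn": int(cn[s]),
                    "expected_log2": float(exp[idx[s]]),
                })
        return pd.DataFrame(rows)


def toy_genome(n_bins: int = 5000, n_chroms: int = 22,
               window: int = 60_000, seed: int = 0) -> GenomeBins:
    """Small multi-chromosome genome with smoothly varying synthetic GC.

    Default: 22 toy chromosomes totalling 5,000 bins — large enough for
    segmentation and scoring to behave realistically, small enough for
    fast tests.
    """
    per = np.full(n_chroms, n_bins // n_chroms)
    per[: n_bins - per.sum()] += 1
    sizes = ChromSizes(tuple((f"chr{i + 1}", int(p) * window)
                             for i, p in enumerate(per)),
                       assembly_label=f"toy{n_bins}x{window}")
    bins = tile_genome(sizes, window)
    rng = np.random.default_rng(seed)
    t = np.arange(bins.n_bins)
    bins.gc = np.clip(0.42 + 0.08 * np.sin(t / 37.0)
                      + rng.normal(0, 0.015, bins.n_bins), 0.25, 0.65)
    return bins


def neutral_truth(bins: GenomeBins, f: float = 0.2, depth: float = 150.0,
                  dispersion: float = 1.3, seed: int = 0,
                  pair_label: str = "pre") -> SyntheticTruth:
    return SyntheticTruth(seed, bins, f, np.full(bins.n_bins, 2),
                          depth=depth, dispersion=dispersion,
                          pair_label=pair_label)


def place_segment(truth: SyntheticTruth, chrom: str, frac_start: float,
                  frac_end: float, cn: int) -> tuple[int, int]:
    """Set a CN state on a fraction of one chromosome; returns bp span."""
    idx = truth.bins.chrom_index(chrom)
    lo = idx[int(np.floor(frac_start * len(idx)))]
    hi = idx[min(int(np.ceil(frac_end * len(idx))), len(idx)) - 1]
    truth.cn[lo:hi + 1] = cn
    return int(truth.bins.start[lo]), int(truth.bins.end[hi])


def simulate_counts(truth: SyntheticTruth, sample_id: str,
                    rng: np.random.Generator | None = None) -> BinCounts:
    """Draw per-bin counts from the truth's negative-binomial model."""
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    mu = truth.expected_means()
    if truth.dispersion <= 1.0 + 1e-12:
        raw = rng.poisson(mu)
    else:
        r = mu / (truth.dispersion - 1.0)
        p = 1.0 / truth.dispersion
        raw = np.where(mu > 0, rng.negative_binomial(np.maximum(r, 1e-9), p), 0)
    return BinCounts(sample_id, truth.bins, raw.astype(np.int64))


def simulate_pair(truth: SyntheticTruth,
                  truth_post: SyntheticTruth | None = None,
                  gdna_truth: SyntheticTruth | None = None,
                  seed: int | None = None,
                  sample_prefix: str = "sim"):
    """Simulate a matched (gdna, cfDNA [, post-treatment cfDNA]) set.

    The gDNA sample shares the GC-bias curve but is copy-neutral unless an
    explicit ``gdna_truth`` is given (used for the TCRA-artifact scenario,
    where the germline control itself carries a deletion). Returns the
    counts plus the truth table(s).
    """
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)
    if gdna_truth is None:
        gdna_truth = replace(truth, cn=np.full(truth.bins.n_bins, 2),
                             pair_label="gdna")
    else:
        gdna_truth = replace(gdna_truth, pair_label="gdna")
    gdna = simulate_counts(gdna_truth, f"{sample_prefix}G", rng)
    cf = simulate_counts(truth, f"{sample_prefix}U1", rng)
    out = [gdna, cf]
    truths = {"pre": truth.truth_table(), "gdna": gdna_truth.truth_table()}
    if truth_post is not None:
        if truth_post.bins.fingerprint() != truth.bins.fingerprint():
            raise InvalidInputError("pre/post truths on different bins")
        out.append(simulate_counts(truth_post, f"{sample_prefix}U2", rng))
        truths["post"] = truth_post.truth_table()
    return (*out, truths)


@dataclass
class Scenario:
    """A named simulation preset with its relevant toy gene loci."""

    name: str
    truth: SyntheticTruth
    truth_post: SyntheticTruth | None = None
    gdna_truth: SyntheticTruth | None = None
    loci: list[GeneLocus] = field(default_factory=list)


def scenario_library(bins: GenomeBins | None = None, f: float = 0.2,
                     depth: float = 150.0, dispersion: float = 1.3,
                     seed: int = 0) -> dict[str, Scenario]:
    """Named presets mirroring the study's qualitative findings.

    ``null`` (no aberrations), ``ar_gain``, ``pten_loss``,
    ``tmprss2_erg_loss`` (interstitial loss between the two loci),
    ``crpc_like`` (many aberrant segments) vs ``hspc_like`` (few),
    ``treatment_pair`` (post-treatment emergent gain over a toy LGR4), and
    ``tcra_artifact`` (deletion in the gDNA truth only, producing
    pseudo-gain in the ratio).
    """
    if bins is None:
        bins = toy_genome(seed=seed)

    def base(label="pre", s=seed):
        return neutral_truth(bins, f=f, depth=depth, dispersion=dispersion,
                             seed=s, pair_label=label)

    def locus(name, chrom, lo_frac, hi_frac):
        idx = bins.chrom_index(chrom)
        lo = bins.start[idx[int(lo_frac * len(idx))]]
        hi = bins.end[idx[int(hi_frac * len(idx)) - 1]]
        return GeneLocus(name, chrom, int(lo), int(hi))

    lib: dict[str, Scenario] = {}

    lib["null"] = Scenario("null", base())

    t = base()
    place_segment(t, "chr20", 0.30, 0.70, 4)
    lib["ar_gain"] = Scenario("ar_gain", t,
                              loci=[locus("AR", "chr20", 0.40, 0.60)])

    t = base()
    place_segment(t, "chr10", 0.35, 0.75, 1)
    lib["pten_loss"] = Scenario("pten_loss", t,
                                loci=[locus("PTEN", "chr10", 0.45, 0.65)])

    t = base()
    place_segment(t, "chr21", 0.40, 0.70, 1)
    lib["tmprss2_erg_loss"] = Scenario(
        "tmprss2_erg_loss", t,
        loci=[locus("ERG", "chr21", 0.38, 0.44),
              locus("TMPRSS2", "chr21", 0.66, 0.72)])

    t = base()
    for chrom, lo, hi, cn in [("chr1", 0.1, 0.4, 3), ("chr3", 0.5, 0.9, 1),
                              ("chr5", 0.2, 0.5, 4), ("chr8", 0.6, 0.95, 3),
                              ("chr10", 0.3, 0.6, 1), ("chr13", 0.1, 0.5, 1),
                              ("chr17", 0.4, 0.8, 3), ("chr20", 0.3, 0.7, 4)]:
        place_segment(t, chrom, lo, hi, cn)
    lib["crpc_like"] = Scenario("crpc_like", t)

    t = base()
    place_segment(t, "chr8", 0.6, 0.95, 3)
    place_segment(t, "chr10", 0.3, 0.6, 1)
    lib["hspc_like"] = Scenario("hspc_like", t)

    pre = base()
    post = base("post", seed + 1)
    place_segment(post, "chr11", 0.25, 0.65, 4)
    lib["treatment_pair"] = Scenario(
        "treatment_pair", pre, truth_post=post,
        loci=[locus("LGR4", "chr11", 0.35, 0.55)])

    cf = base()
    gd = base("gdna")
    place_segment(gd, "chr14", 0.10, 0.40, 1)
    gd = replace(gd, tumor_fraction=1.0)   # germline deletion: full dosage
    lib["tcra_artifact"] = Scenario(
        "tcra_artifact", cf, gdna_truth=gd,
        loci=[locus("TCRA", "chr14", 0.15, 0.35)])

    return lib


def get_scenario(name: str, **kwargs) -> Scenario:
    lib = scenario_library(**kwargs)
    if name not in lib:
        raise InvalidInputError(
            f"unknown scenario {name!r}; available: {sorted(lib)}")
    return lib[name]


MAX_TOY_BAM_GENOME = 10_000_000  # bp


def write_toy_bam(counts: BinCounts, path, read_length: int = 50) -> str:
    """Write a coordinate-sorted, indexed toy BAM realizing given counts.

    Reads are single-end, placed with leftmost bases spread inside each
    bin, so counting by leftmost base recovers the raw vector exactly.
    Only desk-scale toy genomes are accepted.
    """
    import pysam

    bins = counts.bins
    total = sum(length for _, length in bins.chrom_sizes.entries)
    if total > MAX_TOY_BAM_GENOME:
        raise InvalidInputError(
            f"toy genome is {total} bp; BAM export capped at "
            f"{MAX_TOY_BAM_GENOME} bp")
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length}
               for name, length in bins.chrom_sizes.entries],
    }
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        serial = 0
        for i in range(bins.n_bins):
            n = int(counts.raw[i])
            if n == 0:
                continue
            tid = bins.chrom_sizes.names.index(str(bins.chrom[i]))
            width = int(bins.end[i] - bins.start[i])
            span = max(1, width - read_length)
            offsets = np.linspace(0, span - 1, n).astype(int)
            for off in offsets:
                a = pysam.AlignedSegment()
                a.query_name = f"r{serial}"
                serial += 1
                a.query_sequence = "A" * read_length
                a.flag = 0
                a.reference_id = tid
                a.reference_start = int(bins.start[i]) + int(off)
                a.mapping_quality = 60
                a.cigarstring = f"{read_length}M"
                bam.write(a)
    pysam.index(path)
    return path
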