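"""Per-bin read counting from alignments, count-table IO, and global-mean
scaling.

Counting assigns each primary, mapped, non-duplicate read to the bin
containing its leftmost aligned base. Scaling divides by the mean raw count
over unmasked bins so every sample sits on a common depth-1 scale before
ratio formation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome import GenomeBins, InvalidInputError, assert_same_bins


@dataclass
class BinCounts:
    """Per-sample read counts aligned to a :class:`GenomeBins` tiling."""

    sample_id: str
    bins: GenomeBins
    raw: np.ndarray                       # non-negative ints, one per bin
    scaled: np.ndarray | None = None      # raw / mean(raw over unmasked)
    n_mappable_reads: int | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw)
        if len(self.raw) != self.bins.n_bins:
            raise InvalidInputError(
                f"{self.sample_id}: {len(self.raw)} counts for "
                f"{self.bins.n_bins} bins")
        if (self.raw < 0).any():
            raise InvalidInputError(f"{self.sample_id}: negative counts")
        if self.n_mappable_reads is None:
            self.n_mappable_reads = int(self.raw.sum())


@dataclass(frozen=True)
class SequencingSummary:
    """One row of a per-sample sequencing statistics table."""

    sample_id: str
    raw_reads: int
    mappable_reads: int
    percent_mapped: float     # 100 * mappable / raw, 2 decimals
    reads_per_bin: int        # round(mappable / n_bins)


def _reconcile_chrom(name: str, known: set[str]) -> str | None:
    if name in known:
        return name
    alt = name[3:] if name.startswith("chr") else "chr" + name
    return alt if alt in known else None


def count_bam(alignment_file, bins: GenomeBins, min_mapq: int = 1,
              sample_id: str | None = None) -> BinCounts:
    """Count reads per bin from a coordinate-sorted, indexed BAM.

    Each primary, mapped, non-duplicate, non-QC-fail read with
    MAPQ >= ``min_mapq`` increments exactly the bin containing its leftmost
    aligned base. Chromosome names are reconciled with or without the
    "chr" prefix.
    """
    import pysam

    path = str(alignment_file)
    raw = np.zeros(bins.n_bins, dtype=np.int64)
    with pysam.AlignmentFile(path) as bam:
        if not bam.has_index():
            raise InvalidInputError(f"BAM is not indexed: {path}")
        known = set(bam.references)
        n_hit_chroms = 0
        for chrom in bins.chrom_sizes.names:
            ref = _reconcile_chrom(chrom, known)
            if ref is None:
                continue
            n_hit_chroms += 1
            idx = bins.chrom_index(chrom)
            starts = bins.start[idx]
            window = bins.window_size
            for read in bam.fetch(ref):
                if (read.is_unmapped or read.is_secondary
                        or read.is_supplementary or read.is_duplicate
                        or read.is_qcfail or read.mapping_quality < min_mapq):
                    continue
                b = read.reference_start // window
                if b < len(idx) and read.reference_start >= starts[0]:
                    raw[idx[b]] += 1
        if n_hit_chroms == 0:
            raise InvalidInputError(
                f"no chromosomes of the tiling found in {path}")
    return BinCounts(sample_id or path, bins, raw)


def write_counts(counts: BinCounts, path) -> None:
    """Write a 4-column counts TSV (chrom, start, end, count)."""
    with open(path, "w") as fh:
        fh.write(f"#sample_id={counts.sample_id}\n")
        fh.write("#chrom\tstart\tend\tcount\n")
        pd.DataFrame({
            "chrom": counts.bins.chrom, "start": counts.bins.start,
            "end": counts.bins.end, "count": counts.raw,
        }).to_csv(fh, sep="\t", header=False, index=False)


def read_count_table(path, bins: GenomeBins,
                     sample_id: str | None = None) -> BinCounts:
    """Read a 4-column counts TSV and align it to ``bins``.

    Rows may be in any order but must match the bin boundaries exactly;
    the first missing or unexpected bin is named in the error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "count"])
    if (df["count"] < 0).any():
        row = df[df["count"] < 0].iloc[0]
        raise InvalidInputError(
            f"negative count at {row.chrom}:{row.start}-{row.end}")
    key = pd.MultiIndex.from_arrays([df["chrom"], df["start"], df["end"]])
    want = pd.MultiIndex.from_arrays([bins.chrom, bins.start, bins.end])
    series = pd.Series(df["count"].to_numpy(), index=key)
    if series.index.has_duplicates:
        dup = series.index[series.index.duplicated()][0]
        raise InvalidInputError(f"duplicate bin row {dup}")
    missing = want.difference(series.index)
    if len(missing) > 0:
        c, s, e = missing[0]
        raise InvalidInputError(f"missing bin {c}:{s}-{e} in {path}")
    extra = series.index.difference(want)
    if len(extra) > 0:
        c, s, e = extra[0]
        raise InvalidInputError(f"unexpected bin {c}:{s}-{e} in {path}")
    raw = series.reindex(want).to_numpy()
    if sample_id is None:
        with open(path) as fh:
            first = fh.readline()
        sample_id = (first.strip().split("=", 1)[1]
                     if first.startswith("#sample_id=") else str(path))
    return BinCounts(sample_id, bins, raw)


def scale_to_global_mean(counts: BinCounts) -> BinCounts:
    """Rescale raw counts to the sample's global mean over unmasked bins.

    After scaling the mean of ``scaled`` over unmasked bins is exactly 1,
    so matched samples of different depth become directly comparable.
    """
    unmasked = ~counts.bins.masked
    mean = counts.raw[unmasked].mean() if unmasked.any() else 0.0
    if mean <= 0:
        raise InvalidInputError(
            f"{counts.sample_id}: no reads in unmasked bins")
    return replace(counts, scaled=counts.raw / mean)


def sequencing_summary(raw_reads: int, counts: BinCounts) -> SequencingSummary:
    """Summary-statistics row: percent mapped and mean reads per bin."""
    if raw_reads == 0:
        raise InvalidInputError("raw_reads is zero")
    mappable = int(counts.n_mappable_reads)
    if raw_reads < mappable:
        raise InvalidInputError("raw_reads < mappable reads")
    return SequencingSummary(
        counts.sample_id, raw_reads, mappable,
        round(100.0 * mappable / raw_reads, 2),
        round(mappable / counts.bins.n_bins),
    )


def load_sequencing_stats() -> pd.DataFrame:
    """Packaged per-sample WGS statistics table (33 urine cfDNA libraries)."""
    src = importlib.resources.files("urocnv.data") / "sequencing_stats.tsv"
    with importlib.resources.as_file(src) as path:
        return pd.read_csv(path, sep="\t")
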