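"""Fixed-width bin tiling of a reference genome, GC annotation, centromere
masking, and gene loci.

The tiling is the coordinate system for everything downstream: read counts,
log2-ratio profiles and segments are all vectors aligned to one
:class:`GenomeBins` object. Coordinates are 0-based half-open throughout;
BED export follows the BED standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _hg19


class InvalidInputError(ValueError):
    """Raised when an operation receives structurally invalid input."""


@dataclass(frozen=True)
class ChromSizes:
    """Ordered chromosome name/length table.

    Parameters
    ----------
    entries
        Ordered ``(name, length_bp)`` pairs. Order is preserved and defines
        the genomic sort order of all downstream vectors.
    assembly_label
        Free-text assembly tag, stamped into outputs.
    """

    entries: tuple[tuple[str, int], ...]
    assembly_label: str = "hg19"

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(names) != len(set(names)):
            raise InvalidInputError("duplicate chromosome names")
        for name, length in self.entries:
            if length <= 0:
                raise InvalidInputError(f"non-positive length for {name}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def hg19(cls) -> "ChromSizes":
        """The 24 hg19 primary chromosomes (chr1..chr22, chrX, chrY)."""
        return cls(tuple(_hg19.CHROM_SIZES), "hg19")

    @classmethod
    def from_tsv(cls, path, assembly_label: str = "custom") -> "ChromSizes":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "length"])
        if df.empty:
            raise InvalidInputError(f"empty chrom-sizes file: {path}")
        return cls(tuple(zip(df["chrom"], df["length"].astype(int))),
                   assembly_label)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.entries).to_csv(path, sep="\t", header=False,
                                          index=False)


@dataclass(frozen=True)
class CentromereTable:
    """Per-chromosome centromere spans (0-based half-open)."""

    entries: dict[str, tuple[int, int]]
    pad: int = 1_000_000

    def __post_init__(self) -> None:
        for chrom, (start, end) in self.entries.items():
            if not 0 <= start < end:
                raise InvalidInputError(f"bad centromere span for {chrom}")

    @classmethod
    def hg19(cls, pad: int = 1_000_000) -> "CentromereTable":
        return cls(dict(_hg19.CENTROMERES), pad)

    def padded(self, pad: int | None = None) -> dict[str, tuple[int, int]]:
        p = self.pad if pad is None else pad
        return {c: (max(0, s - p), e + p) for c, (s, e) in self.entries.items()}


@dataclass(frozen=True)
class GeneLocus:
    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InvalidInputError(f"{self.name}: start >= end")


def default_gene_loci() -> list[GeneLocus]:
    """AR, PTEN, TMPRSS2, ERG, NOTCH1, MYCL (hg19)."""
    return [GeneLocus(*row) for row in _hg19.GENE_LOCI]


def treatment_gene_loci() -> list[GeneLocus]:
    """The nine treatment-change genes, published coordinates."""
    return [GeneLocus(*row) for row in _hg19.TREATMENT_GENE_LOCI]


def tcra_locus() -> GeneLocus:
    """T-cell receptor alpha locus (default exclude-list entry)."""
    return GeneLocus(*_hg19.TCRA_LOCUS)


def read_gene_bed(path) -> list[GeneLocus]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "name"])
    return [GeneLocus(r["name"], r.chrom, int(r.start), int(r.end))
            for r in df.itertuples(index=False)]


def write_gene_bed(loci: list[GeneLocus], path) -> None:
    pd.DataFrame([(g.chrom, g.start, g.end, g.name) for g in loci]).to_csv(
        path, sep="\t", header=False, index=False)


@dataclass
class GenomeBins:
    """Ordered fixed-width tiling of the reference.

    Bins are stored as parallel numpy arrays sorted by (chromosome order,
    start); the bins of each chromosome occupy one contiguous index range.
    ``gc`` is NaN until :func:`annotate_gc` runs; ``masked`` marks bins
    excluded from scaling means and from usable profile positions.
    """

    window_size: int
    chrom_sizes: ChromSizes
    chrom: np.ndarray          # per-bin chromosome name (object dtype)
    start: np.ndarray          # per-bin start, 0-based
    end: np.ndarray            # per-bin end, half-open
    gc: np.ndarray = field(default=None)        # type: ignore[assignment]
    masked: np.ndarray = field(default=None)    # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gc is None:
            self.gc = np.full(len(self.start), np.nan)
        if self.masked is None:
            self.masked = np.zeros(len(self.start), dtype=bool)

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def width(self) -> np.ndarray:
        return self.end - self.start

    def chrom_index(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == name)

    def copy(self) -> "GenomeBins":
        return GenomeBins(self.window_size, self.chrom_sizes,
                          self.chrom.copy(), self.start.copy(),
                          self.end.copy(), self.gc.copy(),
                          self.masked.copy())

    def fingerprint(self) -> tuple:
        """Identity used to check that two vectors share one tiling."""
        return (self.chrom_sizes.assembly_label, self.window_size,
                self.n_bins, tuple(self.chrom_sizes.entries))

    def to_bed(self, path) -> None:
        score = np.where(np.isnan(self.gc), 0,
                         np.round(np.nan_to_num(self.gc) * 1000)).astype(int)
        name = np.where(self.masked, "masked", "bin")
        pd.DataFrame({
            "chrom": self.chrom, "start": self.start, "end": self.end,
            "name": name, "score": score, "strand": ".",
        }).to_csv(path, sep="\t", header=False, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "start": self.start,
                             "end": self.end, "gc": self.gc,
                             "masked": self.masked})


def write_bins_tsv(bins: GenomeBins, path) -> None:
    """Write the tiling (with GC and mask flags) as a headered TSV."""
    with open(path, "w") as fh:
        fh.write(f"#assembly={bins.chrom_sizes.assembly_label}\t"
                 f"window_size={bins.window_size}\n")
        bins.to_frame().to_csv(fh, sep="\t", index=False)


def read_bins_tsv(path) -> GenomeBins:
    """Read a tiling written by :func:`write_bins_tsv`."""
    with open(path) as fh:
        header = fh.readline().strip()
    meta = dict(part.split("=", 1) for part in header.lstrip("#").split("\t"))
    df = pd.read_csv(path, sep="\t", comment="#")
    sizes = []
    for chrom in df["chrom"].unique():
        sizes.append((chrom, int(df.loc[df["chrom"] == chrom, "end"].max())))
    cs = ChromSizes(tuple(sizes), meta.get("assembly", "custom"))
    return GenomeBins(int(meta["window_size"]), cs,
                      df["chrom"].to_numpy(dtype=object),
                      df["start"].to_numpy(dtype=np.int64),
                      df["end"].to_numpy(dtype=np.int64),
                      df["gc"].to_numpy(dtype=float),
                      df["masked"].to_numpy(dtype=bool))


def assert_same_bins(a: GenomeBins, b: GenomeBins) -> None:
    if a.fingerprint() != b.fingerprint():
        raise InvalidInputError(
            f"bin tilings differ: {a.fingerprint()[:3]} vs {b.fingerprint()[:3]}")


def tile_genome(chrom_sizes: ChromSizes, window_size: int = 60_000) -> GenomeBins:
    """Tile every chromosome into consecutive ``window_size`` bins.

    The last bin of each chromosome is truncated at the chromosome end, so
    the tiling is an exact partition of [0, length) and the total bin count
    is the sum of per-chromosome ceilings (51,607 for the hg19 primaries at
    60 kb).
    """
    if window_size <= 0:
        raise InvalidInputError("window_size must be positive")
    if len(chrom_sizes) == 0:
        raise InvalidInputError("empty chromosome sizes")
    chroms, starts, ends = [], [], []
    for name, length in chrom_sizes.entries:
        s = np.arange(0, length, window_size, dtype=np.int64)
        e = np.minimum(s + window_size, length)
        chroms.append(np.full(len(s), name, dtype=object))
        starts.append(s)
        ends.append(e)
    return GenomeBins(window_size, chrom_sizes,
                      np.concatenate(chroms), np.concatenate(starts),
                      np.concatenate(ends))


def annotate_gc(bins: GenomeBins, reference,
                max_ambiguous_frac: float = 0.5) -> GenomeBins:
    """Annotate per-bin GC fraction from a reference sequence source.

    ``reference`` is any mapping from chromosome name to a sliceable
    sequence (a plain dict of strings, or a ``pyfaidx.Fasta``). GC fraction
    is (G+C)/(A+C+G+T); bins with more than ``max_ambiguous_frac``
    ambiguous bases are flagged masked and left with unknown GC.
    """
    out = bins.copy()
    for name in bins.chrom_sizes.names:
        idx = bins.chrom_index(name)
        if len(idx) == 0:
            continue
        try:
            seq = reference[name]
        except KeyError as exc:
            raise InvalidInputError(
                f"reference is missing chromosome {name}") from exc
        for i in idx:
            sub = str(seq[bins.start[i]:bins.end[i]]).upper()
            counts = {b: sub.count(b) for b in "ACGT"}
            acgt = sum(counts.values())
            n_amb = len(sub) - acgt
            if len(sub) == 0 or n_amb > max_ambiguous_frac * len(sub):
                out.masked[i] = True
                out.gc[i] = np.nan
            else:
                out.gc[i] = (counts["G"] + counts["C"]) / acgt
    return out


def apply_centromere_mask(bins: GenomeBins, centromeres: CentromereTable,
                          pad: int | None = None) -> GenomeBins:
    """Mask every bin overlapping a centromere padded by ``pad`` bp.

    Centromeric 60 kb windows sit in highly repetitive sequence where
    shallow-WGS counts are unreliable; the +/-1 Mb default pad follows the
    segment-filtering convention used for the abnormality score.
    """
    if pad is None:
        pad = centromeres.pad
    if pad < 0:
        raise InvalidInputError("pad must be >= 0")
    out = bins.copy()
    known = set(bins.chrom_sizes.names)
    for chrom, (cs, ce) in centromeres.entries.items():
        if chrom not in known:
            import warnings
            warnings.warn(f"centromere chromosome {chrom} not in bins; skipped")
            continue
        lo, hi = max(0, cs - pad), ce + pad
        idx = bins.chrom_index(chrom)
        hit = (bins.start[idx] < hi) & (bins.end[idx] > lo)
        out.masked[idx[hit]] = True
    return out
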