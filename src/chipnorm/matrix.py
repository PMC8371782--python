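"""Scale-regions and TSS-centered signal matrices from bigWig tracks.

The scale-regions layout rescales every gene body to a common length
(default 40 kb) by averaging the piecewise-constant track signal over
equal-width genomic sub-intervals, and appends fixed-width flanks
(default ±4 kb) binned at ``bin_size`` (default 10 bp).  Rows are laid
out 5'→3' in gene orientation, so minus-strand rows are reversed
relative to genomic coordinates.  Uncovered bigWig positions count as
signal 0.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pyBigWig

from .errors import ValidationError
from .io import GeneModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatrixLayout:
    """Geometry of a scale-regions matrix."""

    body_length: int = 40000
    flank: int = 4000
    bin_size: int = 10

    def __post_init__(self):
        for name in ("body_length", "flank", "bin_size"):
            v = getattr(self, name)
            if v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        if self.body_length % self.bin_size or self.flank % self.bin_size:
            raise ValidationError(
                "body_length and flank must be divisible by bin_size"
            )

    @property
    def n_body_bins(self) -> int:
        return self.body_length // self.bin_size

    @property
    def n_flank_bins(self) -> int:
        return self.flank // self.bin_size

    @property
    def n_bins(self) -> int:
        return self.n_body_bins + 2 * self.n_flank_bins


@dataclass
class DensityMatrix:
    """Genes x bins mean-signal matrix for one sample."""

    sample_id: str
    gene_ids: list[str]
    layout: MatrixLayout
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            self.layout.n_bins,
        ):
            raise ValidationError(
                f"matrix shape {self.values.shape} != "
                f"({len(self.gene_ids)}, {self.layout.n_bins})"
            )
        if np.isnan(self.values).any():
            raise ValidationError("matrix contains NaN")

    def overall_mean(self) -> float:
        return float(self.values.mean())

    def to_tsv(self, path) -> None:
        """Debug export: gzipped TSV with a one-line layout header."""
        with gzip.open(path, "wt") as fh:
            fh.write(
                f"#sample={self.sample_id}\tbody_length={self.layout.body_length}"
                f"\tflank={self.layout.flank}\tbin_size={self.layout.bin_size}\n"
            )
            for gid, row in zip(self.gene_ids, self.values):
                fh.write(gid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


class SignalTrack:
    """Read handle on a bigWig density track.

    Queries outside chromosome bounds are zero-padded; uncovered
    intervals (NaN in the bigWig) read as 0, following the convention
    that density tracks denote absence of reads by absence of intervals.
    """

    def __init__(self, path):
        self.path = str(path)
        self._bw = pyBigWig.open(self.path)
        if self._bw is None:  # pragma: no cover
            raise ValidationError(f"cannot open bigWig {path}")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self._bw.chroms())

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal over [start, end), zero-padded beyond edges."""
        size = self.chrom_sizes.get(chrom)
        if size is None:
            raise ValidationError(f"chromosome {chrom!r} absent from {self.path}")
        if end <= start:
            raise ValidationError(f"empty query [{start}, {end})")
        out = np.zeros(end - start, dtype=float)
        qs, qe = max(start, 0), min(end, size)
        if qs < qe:
            vals = np.asarray(self._bw.values(chrom, qs, qe), dtype=float)
            np.nan_to_num(vals, copy=False)
            out[qs - start : qe - start] = vals
        return out

    def intervals(self, chrom: str):
        """(start, end, value) runs for one chromosome; () when empty."""
        return self._bw.intervals(chrom) or ()

    def close(self) -> None:
        self._bw.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def _resample_to_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Average a per-base signal over n_bins equal-width sub-intervals.

    Sub-interval edges may fall inside a base; that base contributes to
    both neighbors proportionally to the overlap (exact coverage
    weighting via the cumulative integral of the step function).
    """
    length = values.size
    cum = np.concatenate(([0.0], np.cumsum(values)))
    edges = np.linspace(0.0, length, n_bins + 1)
    cum_at_edges = np.interp(edges, np.arange(length + 1), cum)
    widths = length / n_bins
    return np.diff(cum_at_edges) / widths


def compute_matrix(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    layout: MatrixLayout = MatrixLayout(),
    sample_id: str = "",
) -> DensityMatrix:
    """Build the scale-regions genes x bins matrix for one track.

    Genes on chromosomes absent from the track, or with a body shorter
    than one bin, are dropped with a logged count.  Flank stretches
    beyond chromosome edges contribute 0.
    """
    if not genes:
        raise ValidationError("empty gene list")
    sizes = track.chrom_sizes
    usable: list[GeneModel] = []
    n_missing_chrom = n_short = 0
    for g in genes:
        if g.chrom not in sizes:
            n_missing_chrom += 1
        elif g.end - g.start < layout.bin_size:
            n_short += 1
        else:
            usable.append(g)
    if n_missing_chrom:
        logger.warning(
            "dropped %d genes on chromosomes absent from %s",
            n_missing_chrom,
            track.path,
        )
    if n_short:
        logger.warning("dropped %d genes with body shorter than one bin", n_short)
    if not usable:
        raise ValidationError("no usable genes for matrix computation")

    flank, bs = layout.flank, layout.bin_size
    rows = np.empty((len(usable), layout.n_bins), dtype=float)
    for i, g in enumerate(usable):
        window = track.values(g.chrom, g.start - flank, g.end + flank)
        body = window[flank : flank + (g.end - g.start)]
        left = window[:flank].reshape(-1, bs).mean(axis=1)
        right = window[flank + (g.end - g.start) :].reshape(-1, bs).mean(axis=1)
        body_bins = _resample_to_bins(body, layout.n_body_bins)
        row = np.concatenate([left, body_bins, right])
        if g.strand == "-":
            row = row[::-1]
        rows[i] = row
    return DensityMatrix(
        sample_id=sample_id,
        gene_ids=[g.gene_id for g in usable],
        layout=layout,
        values=rows,
    )


def compute_tss_matrix(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    half_window: int = 4000,
    bin_size: int = 10,
    sample_id: str = "",
) -> tuple[list[str], np.ndarray]:
    """Reference-point matrix: mean signal per bin around each TSS.

    Returns ``(gene_ids, genes x (2*half_window/bin_size) array)`` laid
    out 5'→3' (minus-strand rows reversed).
    """
    if not genes:
        raise ValidationError("empty gene list")
    if half_window % bin_size:
        raise ValidationError("half_window must be divisible by bin_size")
    sizes = track.chrom_sizes
    usable = [g for g in genes if g.chrom in sizes]
    dropped = len(genes) - len(usable)
    if dropped:
        logger.warning("dropped %d genes on absent chromosomes", dropped)
    if not usable:
        raise ValidationError("no usable genes for TSS matrix")
    n_bins = 2 * half_window // bin_size
    rows = np.empty((len(usable), n_bins), dtype=float)
    for i, g in enumerate(usable):
        window = track.values(g.chrom, g.tss - half_window, g.tss + half_window)
        row = window.reshape(-1, bin_size).mean(axis=1)
        if g.strand == "-":
            row = row[::-1]
        rows[i] = row
    return [g.gene_id for g in usable], rows


def mean_profile(matrix: DensityMatrix) -> np.ndarray:
    """Column-wise mean signal across genes (the profile fed to the fits)."""
    if matrix.values.shape[0] < 1:
        raise ValidationError("matrix has no gene rows")
    return matrix.values.mean(axis=0)
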