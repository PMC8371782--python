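"""Gene annotations and expression matrices.

Coordinates are 0-based half-open everywhere inside the package (the
BED/bigWig convention); GTF's 1-based inclusive coordinates are converted
at the parser boundary.  Expression values are kept on whatever scale the
user provides, tagged with a :class:`Units` label; FPKM/TPM are rescaled
per gene by exon length so that values become proportional to CPM before
any cross-sample variability ranking.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

_STRANDS = {"+", "-"}
# unicode minus sometimes survives copy-paste from manuscripts/spreadsheets
_STRAND_ALIASES = {"−": "-", "+": "+", "-": "-"}


class Units(str, Enum):
    """Expression unit tag.

    CPM and unlogged MICROARRAY values are used as-is; FPKM and TPM are
    gene-length normalized and must be multiplied back by exon length
    (see :func:`to_cpm_like`) before cross-sample SD ranking.
    """

    CPM = "CPM"
    FPKM = "FPKM"
    TPM = "TPM"
    MICROARRAY = "MICROARRAY"


@dataclass(frozen=True)
class GeneModel:
    """One gene: location, strand and total (merged) exonic length."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str
    exon_length: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.exon_length < 1:
            raise ValidationError(
                f"gene {self.gene_id}: exon_length must be >= 1, got {self.exon_length}"
            )

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on '+', ``end`` on '-'."""
        return self.start if self.strand == "+" else self.end

    @property
    def te(self) -> int:
        """Transcription end site (the 3' extremity)."""
        return self.end if self.strand == "+" else self.start


class ExpressionTable:
    """Genes x samples matrix of non-negative expression values.

    Thin wrapper over a pandas DataFrame (genes as index, samples as
    columns) plus a :class:`Units` tag.
    """

    def __init__(self, frame: pd.DataFrame, units: Units):
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if frame.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if frame.shape[1] < 2:
            raise ValidationError(
                f"expression table needs >= 2 samples, got {frame.shape[1]}"
            )
        values = frame.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("expression table contains missing values")
        if (values < 0).any():
            raise ValidationError("expression table contains negative values")
        self.frame = frame.astype(float)
        self.units = Units(units)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.shape
        return f"ExpressionTable({g} genes x {s} samples, units={self.units.value})"


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def _merged_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_s, cur_e = None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _parse_gtf(path) -> list[GeneModel]:
    spans: dict[str, tuple[str, str, int, int]] = {}  # from 'gene' features
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}  # chrom, strand seen for any feature
    order: list[str] = []

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}",
                    path=path,
                    line=lineno,
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("gene", "exon"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError("non-integer coordinates", path=path, line=lineno)
            strand = _STRAND_ALIASES.get(strand, strand)
            if strand not in _STRANDS:
                raise ParseError(
                    f"missing or invalid strand {strand!r}", path=path, line=lineno
                )
            m = _GENE_ID_RE.search(attrs)
            if not m:
                raise ParseError("no gene_id attribute", path=path, line=lineno)
            gid = m.group(1)
            # GTF is 1-based inclusive -> 0-based half-open
            start, end = start1 - 1, end1
            if start >= end:
                raise ParseError(
                    f"empty interval for {gid}", path=path, line=lineno
                )
            if gid in meta:
                if meta[gid] != (chrom, strand):
                    raise ParseError(
                        f"gene {gid} spans multiple chromosomes/strands",
                        path=path,
                        line=lineno,
                    )
            else:
                meta[gid] = (chrom, strand)
                order.append(gid)
            if feature == "gene":
                if gid in spans:
                    raise ParseError(f"duplicate gene_id {gid}", path=path, line=lineno)
                spans[gid] = (chrom, strand, start, end)
            else:
                exons.setdefault(gid, []).append((start, end))

    models = []
    for gid in order:
        chrom, strand = meta[gid]
        exon_list = exons.get(gid, [])
        if gid in spans:
            _, _, start, end = spans[gid]
        elif exon_list:
            start = min(s for s, _ in exon_list)
            end = max(e for _, e in exon_list)
        else:  # pragma: no cover - unreachable given feature filter
            continue
        exon_length = _merged_length(exon_list) if exon_list else end - start
        models.append(GeneModel(gid, chrom, start, end, strand, exon_length))
    if not models:
        raise ParseError("no gene or exon features found", path=path)
    return models


def _parse_bed(path) -> list[GeneModel]:
    models = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = re.split(r"\s+", line.strip())
            if len(fields) < 6:
                raise ParseError(
                    f"BED needs >= 6 columns, got {len(fields)}", path=path, line=lineno
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError("non-integer coordinates", path=path, line=lineno)
            strand = _STRAND_ALIASES.get(strand, strand)
            if strand not in _STRANDS:
                raise ParseError(
                    f"missing or invalid strand {strand!r}", path=path, line=lineno
                )
            if name in seen:
                raise ParseError(f"duplicate gene_id {name}", path=path, line=lineno)
            seen.add(name)
            models.append(GeneModel(name, chrom, start, end, strand, end - start))
    if not models:
        raise ParseError("no BED records found", path=path)
    return models


def read_gene_annotation(path, dialect: str | None = None) -> list[GeneModel]:
    """Parse a GTF or BED6 gene annotation into :class:`GeneModel` records.

    Parameters
    ----------
    path:
        GTF (ensembl-style ``gene_id "X";`` attributes) or BED6 file,
        optionally gzipped.
    dialect:
        ``"gtf"`` or ``"bed"``; inferred from the file extension when None.

    For GTF, the gene span comes from the ``gene`` feature (or the exon
    envelope when absent) and ``exon_length`` is the length of the union
    of the gene's exon intervals.  For BED, ``exon_length`` is the full
    span ``end - start``.
    """
    path = Path(path)
    if dialect is None:
        stem = path.name[:-3] if path.name.endswith(".gz") else path.name
        ext = Path(stem).suffix.lower()
        if ext in (".gtf", ".gff", ".gff3"):
            dialect = "gtf"
        elif ext == ".bed":
            dialect = "bed"
        else:
            raise ValidationError(
                f"cannot infer annotation dialect from {path.name!r}; pass dialect="
            )
    dialect = dialect.lower()
    if dialect == "gtf":
        return _parse_gtf(path)
    if dialect == "bed":
        return _parse_bed(path)
    raise ValidationError(f"unknown annotation dialect {dialect!r}")


def write_bed(models: Sequence[GeneModel], path, scores=None) -> None:
    """Write BED6 records sorted by (chrom, start)."""
    rows = sorted(models, key=lambda g: (g.chrom, g.start, g.gene_id))
    with open(path, "w") as fh:
        for g in rows:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_expression(path, units: Units | str) -> ExpressionTable:
    """Read a gene x sample expression TSV (first column: gene ids).

    Rows containing any missing/non-numeric value are dropped with a
    logged count.  Negative values are a hard error.
    """
    units = Units(units)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    if df.shape[1] < 2:
        raise ValidationError(
            f"expression table needs >= 2 sample columns, got {df.shape[1]}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    keep = ~numeric.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "dropped %d expression rows with missing/non-numeric values", n_dropped
        )
    numeric = numeric.loc[keep]
    if numeric.empty:
        raise ValidationError("no complete expression rows")
    if (numeric.to_numpy() < 0).any():
        raise ValidationError("negative expression values")
    numeric.index = numeric.index.astype(str)
    return ExpressionTable(numeric, units)


def to_cpm_like(table: ExpressionTable, genes: Sequence[GeneModel]) -> ExpressionTable:
    """Rescale FPKM/TPM values to be proportional to CPM.

    FPKM/TPM divide read counts by gene length; multiplying each gene's
    values by its exon length in kilobases undoes that, leaving values
    proportional (per sample) to CPM.  CPM and MICROARRAY tables are
    returned unchanged.  Genes absent from the annotation are dropped
    with a logged count.
    """
    if table.units in (Units.CPM, Units.MICROARRAY):
        return table
    length_kb = {g.gene_id: g.exon_length / 1000.0 for g in genes}
    known = [gid for gid in table.gene_ids if gid in length_kb]
    missing = len(table.gene_ids) - len(known)
    if missing:
        logger.warning("dropped %d expression genes missing from annotation", missing)
    if not known:
        raise ValidationError("no expression genes found in annotation")
    zero = [gid for gid in known if length_kb[gid] == 0]
    if zero:
        raise ValidationError(f"genes with exon_length 0: {zero[:5]}")
    sub = table.frame.loc[known]
    factors = np.array([length_kb[gid] for gid in known])
    rescaled = sub.mul(factors, axis=0)
    return ExpressionTable(rescaled, Units.CPM)
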