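"""Selection of transcriptionally constant anchor genes.

The normalization assumes that genes whose expression does not change
across samples carry, on average, the same true ChIP signal in every
sample.  To pick such genes at every expression level, genes are ranked
by mean expression, partitioned into ``n_bins`` contiguous equal-size
groups, and within each group the fraction ``percent`` with the smallest
cross-sample standard deviation is kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import ExpressionTable, GeneModel, Units, write_bed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConstantGeneSet:
    """Genes selected as cross-sample invariant, plus the selection knobs."""

    gene_ids: tuple[str, ...]
    n_expression_bins: int = 100
    percent: float = 10.0

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gid: str) -> bool:
        return gid in set(self.gene_ids)


def select_constant_genes(
    table: ExpressionTable, n_bins: int = 100, percent: float = 10.0
) -> ConstantGeneSet:
    """Pick the least-variable genes within each expression stratum.

    Genes are sorted by across-sample mean (ties broken by gene id),
    split into ``n_bins`` contiguous groups of near-equal size (the
    remainder spread over the lowest-expression groups), and within each
    group the ``ceil(percent/100 * group_size)`` genes with the smallest
    sample standard deviation are selected.  Zero-expression genes are
    retained: stably silent genes are valid anchors too.

    The table must be in CPM or unlogged microarray units — convert
    FPKM/TPM with :func:`chipnorm.io.to_cpm_like` first.
    """
    if table.units not in (Units.CPM, Units.MICROARRAY):
        raise ValidationError(
            f"select_constant_genes needs CPM or MICROARRAY units, got "
            f"{table.units.value}; convert with to_cpm_like first"
        )
    if not (0 < percent <= 100):
        raise ValidationError(f"percent must be in (0, 100], got {percent}")
    n_genes = len(table.gene_ids)
    if n_genes < n_bins:
        raise ValidationError(
            f"{n_genes} genes < {n_bins} expression bins; use a smaller n_bins"
        )

    values = table.values
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    gene_ids = np.asarray(table.gene_ids, dtype=object)

    # sort by mean, deterministic tie-break on gene id
    order = np.lexsort((gene_ids, means))

    base, rem = divmod(n_genes, n_bins)
    selected: list[str] = []
    pos = 0
    for b in range(n_bins):
        size = base + (1 if b < rem else 0)
        idx = order[pos : pos + size]
        pos += size
        take = math.ceil(percent / 100.0 * size)
        bin_sds = sds[idx]
        bin_ids = gene_ids[idx]
        inner = np.lexsort((bin_ids, bin_sds))[:take]
        selected.extend(bin_ids[inner])

    return ConstantGeneSet(
        gene_ids=tuple(sorted(selected)), n_expression_bins=n_bins, percent=percent
    )


def write_constant_bed(
    genes: ConstantGeneSet, models: Sequence[GeneModel], path
) -> int:
    """Write the selected genes as a sorted BED6 file.

    Selected genes missing from the annotation are dropped with a logged
    count.  Returns the number of records written.
    """
    by_id = {m.gene_id: m for m in models}
    present = [by_id[g] for g in genes.gene_ids if g in by_id]
    missing = len(genes.gene_ids) - len(present)
    if missing:
        logger.warning("dropped %d selected genes missing from annotation", missing)
    write_bed(present, path)
    return len(present)
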