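"""Self-contained synthetic test worlds.

Generates a toy genome with non-overlapping genes, an expression table
in which a designated fraction of genes is exactly invariant across
samples, and one density track per sample obtained by distorting a
shared base track with a known per-sample affine map (plus optional
multiplicative noise).  The base track is a uniform background plus one
Gaussian promoter peak per gene whose height is proportional to the
gene's expression — the structure the normalization relies on: genes
with constant expression carry, on average, constant signal.

Numerical conventions chosen so that ground truth survives file I/O:

* signal is piecewise constant at ``resolution`` bp (default 10);
* values are quantized to multiples of 1/256, hence exactly
  representable in bigWig's 32-bit float storage; with dyadic
  (alpha, beta) the affine relation between samples is bit-exact
  after a write/read round trip;
* truth "constant" genes are stratified across the expression range
  (every (1/constant_fraction)-th gene in base-expression order), so
  each mean-expression bin of the selector contains invariant genes —
  the situation the method is designed for.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .track_io import write_bigwig_from_array

logger = logging.getLogger(__name__)

_QUANT = 256.0  # value grid: multiples of 1/256 are exact in float32


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic world; same spec + seed -> identical files."""

    n_genes: int = 200
    n_samples: int = 2
    n_chroms: int = 2
    constant_fraction: float = 0.1
    alphas: tuple[float, ...] | None = None  # per-sample slope vs base (default 1s)
    betas: tuple[float, ...] | None = None  # per-sample offset (default 0s)
    noise_sd: float = 0.0  # multiplicative track noise, relative SD
    seed: int = 0
    chrom_length: int | None = None  # bp; auto-sized when None
    gene_length_range: tuple[int, int] = (1000, 5000)
    gene_spacing: int = 10000  # min gap between gene spans, bp
    peak_sd: float = 300.0  # promoter peak width, bp
    peak_height_scale: float = 0.1  # peak height = scale * expression
    background: float = 0.5
    expr_meanlog: float = 3.0
    expr_sdlog: float = 1.5
    fold_sd: float = 0.5  # typical cross-sample spread of variable genes
    fold_min: float = 0.1  # minimum spread: variable genes vary by >= 10%
    expr_noise_sdlog: float = 0.01  # measurement noise on expression
    resolution: int = 10  # signal is piecewise constant at this step, bp
    units: str = "CPM"

    def __post_init__(self):
        if not (0 < self.constant_fraction < 1):
            raise ValidationError("constant_fraction must be in (0, 1)")
        if self.n_samples < 2:
            raise ValidationError("need >= 2 samples")
        for name in ("alphas", "betas"):
            v = getattr(self, name)
            if v is not None and len(v) != self.n_samples:
                raise ValidationError(f"{name} must have n_samples entries")
        lo, hi = self.gene_length_range
        if lo < self.resolution or hi < lo:
            raise ValidationError("bad gene_length_range")


@dataclass
class WorldPaths:
    """Files written by :func:`make_world`."""

    out_dir: Path
    gtf: Path
    expression: Path
    bigwigs: dict[str, Path]
    truth: Path


def _quantize(arr: np.ndarray) -> np.ndarray:
    return np.round(arr * _QUANT) / _QUANT


def make_world(spec: FixtureSpec, out_dir) -> WorldPaths:
    """Generate GTF + expression TSV + per-sample bigWigs + truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    res = spec.resolution

    alphas = spec.alphas or tuple([1.0] * spec.n_samples)
    betas = spec.betas or tuple([0.0] * spec.n_samples)
    sample_ids = [f"sample{i + 1}" for i in range(spec.n_samples)]

    # --- gene placement -------------------------------------------------
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    per_chrom = math.ceil(spec.n_genes / spec.n_chroms)
    margin = 6000  # room for flanks/TSS windows at chromosome edges
    lo, hi = spec.gene_length_range
    genes = []  # (gene_id, chrom, start, end, strand)
    needed_length = 0
    gi = 0
    for chrom in chrom_names:
        cursor = margin
        for _ in range(per_chrom):
            if gi >= spec.n_genes:
                break
            length = int(rng.integers(lo // res, hi // res + 1)) * res
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{gi + 1:05d}"
            genes.append((gid, chrom, cursor, cursor + length, strand))
            cursor += length + spec.gene_spacing
            gi += 1
        needed_length = max(needed_length, cursor + margin)
    needed_length = math.ceil(needed_length / res) * res
    if spec.chrom_length is None:
        chrom_length = needed_length
    else:
        chrom_length = spec.chrom_length
        if chrom_length < needed_length:
            raise ValidationError(
                f"genes don't fit: need chrom_length >= {needed_length}, "
                f"got {chrom_length}"
            )
    chrom_sizes = {c: chrom_length for c in chrom_names}

    # --- expression -----------------------------------------------------
    base_expr = np.exp(rng.normal(spec.expr_meanlog, spec.expr_sdlog, spec.n_genes))
    n_constant = round(spec.constant_fraction * spec.n_genes)
    step = int(round(1.0 / spec.constant_fraction))
    expr_order = np.argsort(base_expr, kind="stable")
    const_positions = (np.arange(n_constant) * step + step // 2) % spec.n_genes
    constant_idx = np.sort(expr_order[const_positions])
    is_constant = np.zeros(spec.n_genes, dtype=bool)
    is_constant[constant_idx] = True

    # Variable genes get per-sample fold changes that (i) are centered so
    # the cross-sample mean stays at the base level — variability is
    # isolated from expression level and the mean-expression ordering
    # equals the base ordering, keeping truth-constant genes stratified
    # one per selection bin — and (ii) have a guaranteed minimum spread
    # (fold_min), so "variable" genes really do vary relative to the
    # ~expr_noise_sdlog measurement noise on constant genes.
    pattern = rng.normal(size=(spec.n_genes, spec.n_samples))
    pattern -= pattern.mean(axis=1, keepdims=True)
    norms = pattern.std(axis=1, ddof=1, keepdims=True)
    norms[norms == 0] = 1.0
    pattern /= norms
    spread = rng.uniform(
        spec.fold_min,
        max(2 * spec.fold_sd - spec.fold_min, spec.fold_min),
        size=(spec.n_genes, 1),
    )
    fold = np.maximum(1.0 + spread * pattern, 0.05)
    fold[is_constant, :] = 1.0
    noise = (
        np.exp(rng.normal(0.0, spec.expr_noise_sdlog, (spec.n_genes, spec.n_samples)))
        if spec.expr_noise_sdlog > 0
        else 1.0
    )
    expr = base_expr[:, None] * fold * noise

    # --- base signal ----------------------------------------------------
    n_bins = chrom_length // res
    base = {c: np.full(n_bins, spec.background) for c in chrom_names}
    for (gid, chrom, start, end, strand), e in zip(genes, base_expr):
        tss = start if strand == "+" else end
        height = spec.peak_height_scale * e
        span = int(4 * spec.peak_sd)
        b0 = max((tss - span) // res, 0)
        b1 = min((tss + span) // res + 1, n_bins)
        centers = (np.arange(b0, b1) + 0.5) * res
        base[chrom][b0:b1] += height * np.exp(
            -((centers - tss) ** 2) / (2 * spec.peak_sd**2)
        )
    for chrom in chrom_names:
        base[chrom] = _quantize(base[chrom])

    # --- per-sample tracks ----------------------------------------------
    bigwigs: dict[str, Path] = {}
    for s, sid in enumerate(sample_ids):
        arrays = {}
        for chrom in chrom_names:
            arr = alphas[s] * base[chrom] + betas[s]
            if spec.noise_sd > 0:
                arr = arr * (1.0 + rng.normal(0.0, spec.noise_sd, arr.size))
            arrays[chrom] = np.maximum(arr, 0.0)
        path = out_dir / f"{sid}.bw"
        write_bigwig_from_array(chrom_sizes, arrays, path, resolution=res)
        bigwigs[sid] = path

    # --- annotation (two exons per gene; exonic length = 80% of span) ---
    gtf_path = out_dir / "genes.gtf"
    with open(gtf_path, "w") as fh:
        for gid, chrom, start, end, strand in genes:
            length = end - start
            e1_end = start + (4 * length) // 10
            e2_start = start + (6 * length) // 10
            attrs = f'gene_id "{gid}";'
            # GTF is 1-based inclusive
            fh.write(
                f"{chrom}\tchipnorm\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{chrom}\tchipnorm\texon\t{start + 1}\t{e1_end}\t.\t{strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{chrom}\tchipnorm\texon\t{e2_start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )

    # --- expression table ------------------------------------------------
    expr_path = out_dir / "expression.tsv"
    write_expr = expr
    if spec.units == "FPKM":
        exon_kb = np.array(
            [((e - s) * 8 // 10) / 1000.0 for _, _, s, e, _ in genes]
        )
        write_expr = expr / exon_kb[:, None]
    with open(expr_path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(sample_ids) + "\n")
        for (gid, *_), row in zip(genes, write_expr):
            fh.write(gid + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")

    # --- truth ------------------------------------------------------------
    truth_path = out_dir / "truth.json"
    truth = {
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(spec).items()
        },
        "sample_ids": sample_ids,
        "alphas": list(alphas),
        "betas": list(betas),
        "constant_genes": [genes[i][0] for i in np.flatnonzero(is_constant)],
        "genes": [
            {
                "gene_id": gid,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "base_expression": float(base_expr[i]),
            }
            for i, (gid, chrom, start, end, strand) in enumerate(genes)
        ],
        "chrom_sizes": chrom_sizes,
    }
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return WorldPaths(
        out_dir=out_dir,
        gtf=gtf_path,
        expression=expr_path,
        bigwigs=bigwigs,
        truth=truth_path,
    )
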