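"""The two normalization strategies.

Affine (linear with intercept): regress each sample's constant-gene mean
profile on a reference sample's profile, then invert the fit on the raw
track values, ``v -> max(0, (v - beta) / alpha)``.

Group-wise quantile: pool the constant-gene matrices of all samples,
split genes into k groups by overall signal intensity, quantile-
normalize the k x n_samples matrix of group means across samples
(rank-wise replacement by the across-sample mean), and carry each
sample's (group mean -> target) pairs into a monotone value map that is
applied to the raw track.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import ValidationError
from .matrix import DensityMatrix, SignalTrack
from .track_io import transform_track

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AffineModel:
    """Fitted linear relation of one sample's mean profile to a reference."""

    sample_id: str
    reference_id: str
    alpha: float
    beta: float

    def __post_init__(self):
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValidationError("non-finite affine coefficients")
        if self.alpha <= 0:
            raise ValidationError(
                f"fitted slope alpha={self.alpha:.4g} <= 0 for sample "
                f"{self.sample_id}; the samples are not positively related — "
                "consider quantile normalization"
            )

    def correct(self, values: np.ndarray) -> np.ndarray:
        """max(0, (v - beta) / alpha) applied elementwise."""
        return np.maximum(0.0, (np.asarray(values, dtype=float) - self.beta) / self.alpha)


def choose_reference(matrices: Sequence[DensityMatrix]) -> str:
    """Sample whose overall mean matrix value is the median across samples.

    For an even sample count the lower median is returned; exact ties in
    the overall mean are broken by sample id for determinism.
    """
    if len(matrices) < 2:
        raise ValidationError("choose_reference needs >= 2 samples")
    ranked = sorted(matrices, key=lambda m: (m.overall_mean(), m.sample_id))
    return ranked[(len(ranked) - 1) // 2].sample_id


def fit_affine(
    sample_profile: np.ndarray,
    reference_profile: np.ndarray,
    sample_id: str = "sample",
    reference_id: str = "reference",
) -> AffineModel:
    """Ordinary least squares of sample on reference, with intercept."""
    y = np.asarray(sample_profile, dtype=float)
    x = np.asarray(reference_profile, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValidationError("profiles must be 1-D and of equal length")
    if np.unique(x).size < 2:
        raise ValidationError(
            "reference profile is constant; slope is unidentifiable"
        )
    xm, ym = x.mean(), y.mean()
    xc = x - xm
    alpha = float(np.dot(xc, y - ym) / np.dot(xc, xc))
    beta = float(ym - alpha * xm)
    return AffineModel(
        sample_id=sample_id, reference_id=reference_id, alpha=alpha, beta=beta
    )


def apply_affine(track: SignalTrack, model: AffineModel, out_path) -> None:
    """Write the affine-corrected track; interval boundaries preserved."""
    transform_track(track, model.correct, out_path)


@dataclass(frozen=True)
class GeneGroups:
    """k contiguous gene groups ordered by overall mean signal intensity."""

    k: int
    assignment: dict[str, int]  # gene_id -> group index 1..k (ascending intensity)
    groups: tuple[tuple[str, ...], ...]  # group index-1 -> gene ids

    def __post_init__(self):
        sizes = [len(g) for g in self.groups]
        if len(self.groups) != self.k or max(sizes) - min(sizes) > 1:
            raise ValidationError("group sizes must differ by at most 1")


def build_gene_groups(matrices: Sequence[DensityMatrix], k: int = 20) -> GeneGroups:
    """Split genes into k near-equal groups by overall signal intensity.

    The per-gene statistic is the mean over all bins and all samples.
    Remainder genes go to the lowest-intensity groups; ties are broken
    by gene id.
    """
    if not matrices:
        raise ValidationError("no matrices")
    gene_ids = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.gene_ids != gene_ids or m.layout != matrices[0].layout:
            raise ValidationError("matrices must share gene set and layout")
    n = len(gene_ids)
    if n < k:
        raise ValidationError(f"{n} genes < k={k} groups")
    overall = np.mean([m.values.mean(axis=1) for m in matrices], axis=0)
    ids = np.asarray(gene_ids, dtype=object)
    order = np.lexsort((ids, overall))
    base, rem = divmod(n, k)
    groups: list[tuple[str, ...]] = []
    assignment: dict[str, int] = {}
    pos = 0
    for g in range(k):
        size = base + (1 if g < rem else 0)
        members = tuple(ids[order[pos : pos + size]])
        pos += size
        groups.append(members)
        for gid in members:
            assignment[gid] = g + 1
    return GeneGroups(k=k, assignment=assignment, groups=tuple(groups))


def _pava_increasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto non-decreasing sequences."""
    y = np.asarray(y, dtype=float).copy()
    n = y.size
    # blocks as (sum, count) merged left-to-right
    sums = list(y)
    counts = [1] * n
    i = 0
    while i < len(sums) - 1:
        if sums[i] / counts[i] > sums[i + 1] / counts[i + 1] + 0.0:
            sums[i] += sums.pop(i + 1)
            counts[i] += counts.pop(i + 1)
            if i > 0:
                i -= 1
        else:
            i += 1
    out = np.empty(n)
    pos = 0
    for s, c in zip(sums, counts):
        out[pos : pos + c] = s / c
        pos += c
    return out


class QuantileMap:
    """Monotone value map sending a sample's group means to common targets.

    A monotone cubic (PCHIP) curve through the (knots_in, knots_out)
    pairs, after collapsing duplicate inputs (averaging their targets)
    and an isotonic correction of the targets; with fewer than 4 distinct
    knots the map falls back to monotone piecewise-linear interpolation.
    Beyond the outermost knots the map extends linearly with the terminal
    segment slope; outputs are clamped at 0.
    """

    def __init__(self, sample_id: str, knots_in: np.ndarray, knots_out: np.ndarray):
        self.sample_id = sample_id
        x = np.asarray(knots_in, dtype=float)
        y = np.asarray(knots_out, dtype=float)
        if x.shape != y.shape or x.ndim != 1 or x.size < 2:
            raise ValidationError("need >= 2 knot pairs of equal length")
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        # collapse duplicate inputs by averaging their targets
        ux, inv = np.unique(x, return_inverse=True)
        uy = np.zeros_like(ux)
        cnt = np.zeros_like(ux)
        np.add.at(uy, inv, y)
        np.add.at(cnt, inv, 1.0)
        uy /= cnt
        if ux.size < x.size:
            logger.warning(
                "sample %s: collapsed %d duplicate knots", sample_id, x.size - ux.size
            )
        if ux.size < 2:
            raise ValidationError("fewer than 2 distinct knots")
        uy = _pava_increasing(uy)
        self.knots_in = ux
        self.knots_out = uy
        if ux.size < 4:
            logger.warning(
                "sample %s: only %d distinct knots; using piecewise-linear map",
                sample_id,
                ux.size,
            )
            self.method = "linear"
            self._interp: Callable[[np.ndarray], np.ndarray] = lambda v: np.interp(
                v, ux, uy
            )
        else:
            self.method = "pchip"
            self._interp = PchipInterpolator(ux, uy, extrapolate=False)
        dx_lo = ux[1] - ux[0]
        dx_hi = ux[-1] - ux[-2]
        self._slope_lo = (uy[1] - uy[0]) / dx_lo if dx_lo > 0 else 1.0
        self._slope_hi = (uy[-1] - uy[-2]) / dx_hi if dx_hi > 0 else 1.0

    def __call__(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        out = np.empty_like(v, dtype=float)
        x, y = self.knots_in, self.knots_out
        lo = v < x[0]
        hi = v > x[-1]
        mid = ~(lo | hi)
        out[mid] = np.asarray(self._interp(v[mid]), dtype=float)
        out[lo] = y[0] + self._slope_lo * (v[lo] - x[0])
        out[hi] = y[-1] + self._slope_hi * (v[hi] - x[-1])
        return np.maximum(0.0, out)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "method": self.method,
            "knots_in": self.knots_in.tolist(),
            "knots_out": self.knots_out.tolist(),
        }


def group_means(matrix: DensityMatrix, groups: GeneGroups) -> np.ndarray:
    """Per-group mean over all bins of all member genes, ascending groups."""
    idx = {gid: i for i, gid in enumerate(matrix.gene_ids)}
    out = np.empty(groups.k)
    for g, members in enumerate(groups.groups):
        rows = [idx[gid] for gid in members if gid in idx]
        if not rows:
            raise ValidationError(f"group {g + 1} has no genes in matrix")
        out[g] = matrix.values[rows].mean()
    return out


def fit_quantile_map(
    matrices: Sequence[DensityMatrix], groups: GeneGroups
) -> list[QuantileMap]:
    """Learn one monotone map per sample from group-wise quantile targets.

    Builds the k x n_samples matrix of group-mean intensities, replaces
    each sample's values rank-wise by the across-sample mean of the
    values at that rank (classic quantile normalization), and fits each
    sample's map through its (original mean, target) knot pairs.
    """
    if len(matrices) < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    G = np.column_stack([group_means(m, groups) for m in matrices])
    order = np.argsort(G, axis=0, kind="stable")
    G_sorted = np.take_along_axis(G, order, axis=0)
    targets_by_rank = G_sorted.mean(axis=1)
    T = np.empty_like(G)
    for j in range(G.shape[1]):
        T[order[:, j], j] = targets_by_rank
    return [
        QuantileMap(m.sample_id, knots_in=G[:, j], knots_out=T[:, j])
        for j, m in enumerate(matrices)
    ]


def apply_quantile_map(track: SignalTrack, qmap: QuantileMap, out_path) -> None:
    """Write the track with every value passed through the monotone map."""
    transform_track(track, qmap, out_path)
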