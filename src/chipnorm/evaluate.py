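"""Zone statistics and before/after TSS profile plots.

Normalization success is scored on the average signal around the TSSs of
the constant genes: the 8 kb window is split into three zones —
upstream (−4, −1) kb, promoter-proximal (−1, +1) kb, downstream
(+1, +4) kb — and for every sample pair the percent difference in area
under the mean profile is computed with the pair mean as denominator,
``100 * |A_i − A_j| / ((A_i + A_j)/2)``, symmetric and bounded by 200%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import ValidationError
from .io import GeneModel
from .matrix import SignalTrack, compute_tss_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ZoneSpec:
    """Three TSS-relative zones (bp), non-overlapping and ordered."""

    zone1: tuple[int, int] = (-4000, -1000)
    zone2: tuple[int, int] = (-1000, 1000)
    zone3: tuple[int, int] = (1000, 4000)

    def __post_init__(self):
        zones = self.zones
        for a, b in zones:
            if a >= b:
                raise ValidationError(f"empty zone ({a}, {b})")
        for (a1, b1), (a2, b2) in zip(zones, zones[1:]):
            if b1 > a2:
                raise ValidationError("zones must be ordered and non-overlapping")

    @property
    def zones(self) -> tuple[tuple[int, int], ...]:
        return (self.zone1, self.zone2, self.zone3)


@dataclass
class ZoneStats:
    """Pairwise percent area differences per zone, plus per-zone averages."""

    sample_ids: list[str]
    pairwise: list[np.ndarray]  # one symmetric samples x samples matrix per zone
    averages: list[float]  # mean over unordered pairs, per zone

    def to_dict(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "zone_averages_percent": [round(a, 6) for a in self.averages],
            "pairwise_percent": [m.round(6).tolist() for m in self.pairwise],
        }


def tss_mean_profile(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    half_window: int = 4000,
    bin_size: int = 10,
) -> np.ndarray:
    """Mean strand-oriented signal per bin around the genes' TSSs."""
    _, rows = compute_tss_matrix(
        track, genes, half_window=half_window, bin_size=bin_size
    )
    return rows.mean(axis=0)


def zone_auc(
    profile: np.ndarray,
    zone: tuple[int, int],
    bin_size: int = 10,
    window_start: int | None = None,
) -> float:
    """Riemann area of the profile over one zone.

    Sums ``value * bin_size`` over bins whose centers fall in
    ``[zone_start, zone_end)``.  ``window_start`` defaults to a window
    centered on the TSS (``-len(profile)*bin_size/2``).
    """
    profile = np.asarray(profile, dtype=float)
    if window_start is None:
        window_start = -(profile.size * bin_size) // 2
    a, b = zone
    centers = window_start + (np.arange(profile.size) + 0.5) * bin_size
    if a < centers[0] - bin_size / 2 or b > centers[-1] + bin_size / 2:
        raise ValidationError(
            f"zone ({a}, {b}) outside profile extent "
            f"[{window_start}, {window_start + profile.size * bin_size})"
        )
    mask = (centers >= a) & (centers < b)
    return float(profile[mask].sum() * bin_size)


def zone_percent_difference(
    profiles: Sequence[np.ndarray],
    zones: ZoneSpec = ZoneSpec(),
    bin_size: int = 10,
    sample_ids: Sequence[str] | None = None,
) -> ZoneStats:
    """Average pairwise percent area difference per zone.

    For each unordered sample pair (i, j) and zone,
    ``100 * |A_i − A_j| / ((A_i + A_j)/2)``; a pair with both areas 0
    contributes 0 with a warning.
    """
    n = len(profiles)
    if n < 2:
        raise ValidationError("need >= 2 profiles")
    lengths = {np.asarray(p).size for p in profiles}
    if len(lengths) != 1:
        raise ValidationError("profiles must have equal length")
    if sample_ids is None:
        sample_ids = [f"sample{i + 1}" for i in range(n)]
    pairwise: list[np.ndarray] = []
    averages: list[float] = []
    for zone in zones.zones:
        areas = [zone_auc(p, zone, bin_size=bin_size) for p in profiles]
        mat = np.zeros((n, n))
        diffs = []
        for i in range(n):
            for j in range(i + 1, n):
                denom = (areas[i] + areas[j]) / 2.0
                if denom == 0:
                    logger.warning(
                        "both areas zero in zone %s for pair (%s, %s)",
                        zone,
                        sample_ids[i],
                        sample_ids[j],
                    )
                    d = 0.0
                else:
                    d = 100.0 * abs(areas[i] - areas[j]) / denom
                mat[i, j] = mat[j, i] = d
                diffs.append(d)
        pairwise.append(mat)
        averages.append(float(np.mean(diffs)))
    return ZoneStats(sample_ids=list(sample_ids), pairwise=pairwise, averages=averages)


def plot_before_after(
    profiles_before: Mapping[str, np.ndarray],
    profiles_after: Mapping[str, np.ndarray] | None,
    zones: ZoneSpec = ZoneSpec(),
    out_prefix="profiles",
    bin_size: int = 10,
) -> list[str]:
    """Overlay per-sample TSS profiles before (and after) normalization.

    Writes SVG and PNG; zone boundaries are drawn as dashed lines.
    Returns the written paths.
    """
    panels = [("before normalization", profiles_before)]
    if profiles_after:
        panels.append(("after normalization", profiles_after))
    fig, axes = plt.subplots(
        1, len(panels), figsize=(6 * len(panels), 4), squeeze=False, sharey=True
    )
    for ax, (title, profs) in zip(axes[0], panels):
        for sid in sorted(profs):
            p = np.asarray(profs[sid], dtype=float)
            x = -(p.size * bin_size) // 2 + (np.arange(p.size) + 0.5) * bin_size
            ax.plot(x, p, label=sid, lw=1.2)
        for a, b in zones.zones:
            ax.axvline(a, color="grey", ls="--", lw=0.6)
        ax.axvline(zones.zones[-1][1], color="grey", ls="--", lw=0.6)
        ax.set_title(title)
        ax.set_xlabel("distance to TSS (bp)")
        ax.legend(fontsize=8)
    axes[0][0].set_ylabel("mean density")
    fig.tight_layout()
    paths = [f"{out_prefix}.svg", f"{out_prefix}.png"]
    for p in paths:
        fig.savefig(p, dpi=150)
    plt.close(fig)
    return paths
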