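"""bigWig writing helpers.

bigWig stores values as 32-bit floats; transformations preserve interval
boundaries so normalized tracks stay aligned with their inputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable

import numpy as np
import pyBigWig

from .errors import ChipnormError
from .matrix import SignalTrack


def transform_track(
    track: SignalTrack, func: Callable[[np.ndarray], np.ndarray], out_path
) -> None:
    """Apply ``func`` to every interval value of ``track``; write a bigWig.

    Interval boundaries and chromosome sizes are copied unchanged.
    Chromosomes are written in sorted name order.
    """
    out_path = Path(out_path)
    sizes = track.chrom_sizes
    header = sorted(sizes.items())
    bw = pyBigWig.open(str(out_path), "w")
    if bw is None:  # pragma: no cover
        raise ChipnormError(f"cannot open {out_path} for writing")
    try:
        bw.addHeader(header)
        for chrom, _size in header:
            ivs = track.intervals(chrom)
            if not ivs:
                continue
            starts = [int(s) for s, _, _ in ivs]
            ends = [int(e) for _, e, _ in ivs]
            vals = func(np.array([v for _, _, v in ivs], dtype=float))
            bw.addEntries(
                [chrom] * len(starts), starts, ends=ends, values=[float(v) for v in vals]
            )
    finally:
        bw.close()


def write_bigwig_from_array(
    chrom_sizes: dict[str, int],
    arrays: dict[str, np.ndarray],
    path,
    resolution: int = 1,
) -> None:
    """Write per-chromosome signal arrays as a run-length-encoded bigWig.

    ``arrays[chrom][i]`` is the signal over
    ``[i*resolution, (i+1)*resolution)``.  Adjacent equal values are
    merged into one interval; the whole array extent is covered, so a
    re-read returns the array exactly (values pass through bigWig's
    32-bit float storage).  Negative values are rejected.
    """
    path = Path(path)
    for chrom, arr in arrays.items():
        if chrom not in chrom_sizes:
            raise ChipnormError(f"array chromosome {chrom!r} missing from sizes")
        arr = np.asarray(arr)
        if (arr < 0).any():
            raise ChipnormError(f"negative signal values on {chrom}")
        if arr.size * resolution > chrom_sizes[chrom]:
            raise ChipnormError(f"array longer than chromosome {chrom}")
    header = sorted(chrom_sizes.items())
    bw = pyBigWig.open(str(path), "w")
    if bw is None:  # pragma: no cover
        raise ChipnormError(f"cannot open {path} for writing")
    try:
        bw.addHeader(header)
        for chrom, _size in header:
            if chrom not in arrays:
                continue
            arr = np.asarray(arrays[chrom], dtype=float)
            if arr.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(arr)) + 1
            starts_idx = np.concatenate(([0], breaks))
            ends_idx = np.concatenate((breaks, [arr.size]))
            starts = (starts_idx * resolution).tolist()
            ends = (ends_idx * resolution).tolist()
            vals = arr[starts_idx].tolist()
            bw.addEntries([chrom] * len(starts), starts, ends=ends, values=vals)
    finally:
        bw.close()
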