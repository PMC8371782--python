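"""End-to-end runs: normalization and expression profiling.

`run_normalize` chains the stages: select constant genes from the
expression table, build per-sample scale-regions matrices over them,
learn the affine or quantile correction, rewrite the tracks, and score
the result with zone statistics on TSS profiles before and after.  All
effective parameters land in a provenance JSON so a run can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .constant_genes import select_constant_genes, write_constant_bed
from .errors import PipelineError, ValidationError
from .evaluate import ZoneSpec, plot_before_after, tss_mean_profile, zone_percent_difference
from .expression_profile import profile_by_stratum, stratify_expression
from .io import Units, read_expression, read_gene_annotation, to_cpm_like
from .matrix import MatrixLayout, SignalTrack, compute_matrix, mean_profile
from .normalize import (
    AffineModel,
    apply_affine,
    apply_quantile_map,
    build_gene_groups,
    choose_reference,
    fit_affine,
    fit_quantile_map,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Effective parameters of one run; defaults mirror the method's."""

    samples: dict[str, str]  # sample_id -> bigWig path
    expression_path: str
    units: str = "CPM"
    annotation_path: str = ""
    method: str = "linear"  # linear | quantile
    percent: float = 10.0
    expression_bins: int = 100
    body_length: int = 40000
    flank: int = 4000
    bin_size: int = 10
    k: int = 20
    reference: str = "auto"
    half_window: int = 4000
    out_dir: str = "chipnorm_out"
    seed: int = 42
    # plot-expression only
    expression_sample: str | None = None
    log_expression: bool = True

    def validate(self, need_tracks: bool = True) -> None:
        if self.method not in ("linear", "quantile"):
            raise ValidationError(f"unknown method {self.method!r}")
        for name in ("percent", "expression_bins", "body_length", "flank",
                     "bin_size", "k", "half_window"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if need_tracks and len(self.samples) < 2:
            raise ValidationError("need >= 2 samples")
        for p in [self.expression_path, self.annotation_path, *self.samples.values()]:
            if p and not Path(p).exists():
                raise ValidationError(f"input file not found: {p}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _provenance(config: RunConfig, command: str) -> dict:
    inputs = {"expression": config.expression_path}
    if config.annotation_path:
        inputs["annotation"] = config.annotation_path
    inputs.update({f"track:{sid}": p for sid, p in config.samples.items()})
    return {
        "tool": "chipnorm",
        "version": __version__,
        "command": command,
        "config": asdict(config),
        "input_sha256": {k: _sha256(v) for k, v in inputs.items()},
    }


class _StageRunner:
    """Runs stages, names failures, removes partial outputs on error."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.written: list[Path] = []

    def track_output(self, path) -> Path:
        p = Path(path)
        self.written.append(p)
        return p

    def cleanup(self) -> None:
        for p in self.written:
            try:
                p.unlink(missing_ok=True)
            except OSError:  # pragma: no cover
                pass


def run_normalize(config: RunConfig) -> dict:
    """Full normalization run; returns the report dict (also on disk)."""
    config.validate(need_tracks=True)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runner = _StageRunner(out_dir)
    stage = "setup"
    tracks: dict[str, SignalTrack] = {}
    try:
        stage = "read inputs"
        models = read_gene_annotation(config.annotation_path)
        table = read_expression(config.expression_path, Units(config.units))
        table = to_cpm_like(table, models)
        tracks = {sid: SignalTrack(p) for sid, p in config.samples.items()}
        sizes = [t.chrom_sizes for t in tracks.values()]
        if any(s != sizes[0] for s in sizes[1:]):
            raise ValidationError("chromosome sizes differ between tracks")

        stage = "select constant genes"
        constant = select_constant_genes(
            table, n_bins=config.expression_bins, percent=config.percent
        )
        bed_path = runner.track_output(out_dir / "constant_genes.bed")
        write_constant_bed(constant, models, bed_path)
        by_id = {m.gene_id: m for m in models}
        constant_models = [by_id[g] for g in constant.gene_ids if g in by_id]
        if not constant_models:
            raise ValidationError("no constant genes found in annotation")

        stage = "build density matrices"
        layout = MatrixLayout(
            body_length=config.body_length,
            flank=config.flank,
            bin_size=config.bin_size,
        )
        sample_ids = sorted(tracks)
        matrices = [
            compute_matrix(tracks[sid], constant_models, layout, sample_id=sid)
            for sid in sample_ids
        ]

        stage = "fit normalization"
        params: dict[str, dict] = {}
        normalized_paths: dict[str, Path] = {}
        if config.method == "linear":
            if config.reference == "auto":
                reference = choose_reference(matrices)
            else:
                if config.reference not in tracks:
                    raise ValidationError(
                        f"reference {config.reference!r} is not a sample"
                    )
                reference = config.reference
            ref_profile = mean_profile(
                next(m for m in matrices if m.sample_id == reference)
            )
            for m in matrices:
                if m.sample_id == reference:
                    params[m.sample_id] = {"alpha": 1.0, "beta": 0.0, "reference": True}
                    continue
                model = fit_affine(
                    mean_profile(m), ref_profile,
                    sample_id=m.sample_id, reference_id=reference,
                )
                params[m.sample_id] = {
                    "alpha": model.alpha, "beta": model.beta, "reference": False,
                }
                out_bw = runner.track_output(
                    out_dir / f"{m.sample_id}.linear.normalized.bw"
                )
                apply_affine(tracks[m.sample_id], model, out_bw)
                normalized_paths[m.sample_id] = out_bw
        else:
            reference = None
            groups = build_gene_groups(matrices, k=config.k)
            qmaps = fit_quantile_map(matrices, groups)
            for qm in qmaps:
                params[qm.sample_id] = qm.to_dict()
                out_bw = runner.track_output(
                    out_dir / f"{qm.sample_id}.quantile.normalized.bw"
                )
                apply_quantile_map(tracks[qm.sample_id], qm, out_bw)
                normalized_paths[qm.sample_id] = out_bw

        stage = "evaluate"
        zones = ZoneSpec()
        before = {
            sid: tss_mean_profile(
                tracks[sid], constant_models,
                half_window=config.half_window, bin_size=config.bin_size,
            )
            for sid in sample_ids
        }
        after: dict[str, np.ndarray] = {}
        for sid in sample_ids:
            if sid in normalized_paths:
                with SignalTrack(normalized_paths[sid]) as nt:
                    after[sid] = tss_mean_profile(
                        nt, constant_models,
                        half_window=config.half_window, bin_size=config.bin_size,
                    )
            else:  # reference passes through unchanged
                after[sid] = before[sid]
        stats_before = zone_percent_difference(
            [before[s] for s in sample_ids], zones,
            bin_size=config.bin_size, sample_ids=sample_ids,
        )
        stats_after = zone_percent_difference(
            [after[s] for s in sample_ids], zones,
            bin_size=config.bin_size, sample_ids=sample_ids,
        )
        for p in plot_before_after(
            before, after, zones,
            out_prefix=str(out_dir / "tss_profiles"), bin_size=config.bin_size,
        ):
            runner.track_output(p)

        stage = "write report"
        report = {
            "method": config.method,
            "reference": reference,
            "n_constant_genes": len(constant_models),
            "parameters": params,
            "zones": {"zone1": zones.zone1, "zone2": zones.zone2, "zone3": zones.zone3},
            "zone_stats_before": stats_before.to_dict(),
            "zone_stats_after": stats_after.to_dict(),
            "normalized_tracks": {
                sid: p.name for sid, p in normalized_paths.items()
            },
        }
        report_path = runner.track_output(out_dir / "report.json")
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        prov_path = runner.track_output(out_dir / "provenance.json")
        with open(prov_path, "w") as fh:
            json.dump(_provenance(config, "normalize"), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return report
    except Exception as exc:
        runner.cleanup()
        if isinstance(exc, (ValidationError, PipelineError)):
            raise
        raise PipelineError(stage, exc) from exc
    finally:
        for t in tracks.values():
            t.close()


def run_plot_expression(config: RunConfig) -> dict:
    """Expression-stratified TSS profiling for one track."""
    config.validate(need_tracks=False)
    if len(config.samples) != 1:
        raise ValidationError("plot-expression takes exactly one track")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runner = _StageRunner(out_dir)
    stage = "setup"
    try:
        stage = "read inputs"
        models = read_gene_annotation(config.annotation_path)
        table = read_expression(config.expression_path, Units(config.units))
        table = to_cpm_like(table, models)
        (sid, track_path), = config.samples.items()

        stage = "stratify expression"
        strata = stratify_expression(
            table,
            sample_id=config.expression_sample,
            seed=config.seed,
            log_transform=config.log_expression,
        )
        strata_path = runner.track_output(out_dir / "expression_strata.tsv")
        with open(strata_path, "w") as fh:
            fh.write("gene_id\tstratum\n")
            for gid in sorted(strata.assignment):
                fh.write(f"{gid}\t{strata.assignment[gid]}\n")

        stage = "profile by stratum"
        with SignalTrack(track_path) as track:
            profiles = profile_by_stratum(
                track, strata, models,
                half_window=config.half_window, bin_size=config.bin_size,
                out_prefix=str(out_dir / "expression_profiles"),
            )
        for ext in ("svg", "png"):
            runner.track_output(out_dir / f"expression_profiles.{ext}")

        stage = "write report"
        center = config.half_window // config.bin_size
        report = {
            "sample": sid,
            "strata_counts": {
                lab: len(strata.genes(lab)) for lab in ("low", "medium", "high")
            },
            "centers_log1p" if config.log_expression else "centers": list(
                strata.centers
            ),
            "tss_bin_means": {
                lab: float(p[center]) for lab, p in profiles.items()
            },
        }
        prov_path = runner.track_output(out_dir / "provenance.json")
        with open(prov_path, "w") as fh:
            json.dump(
                _provenance(config, "plot-expression"), fh, indent=1, sort_keys=True
            )
            fh.write("\n")
        report_path = runner.track_output(out_dir / "expression_report.json")
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return report
    except Exception as exc:
        runner.cleanup()
        if isinstance(exc, (ValidationError, PipelineError)):
            raise
        raise PipelineError(stage, exc) from exc
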