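import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pytest

from chipnorm import (
    ExpressionTable,
    FixtureSpec,
    GeneModel,
    SignalTrack,
    WorldPaths,
    make_world,
    read_expression,
    read_gene_annotation,
)


@dataclass
class World:
    """A generated fixture world plus its parsed contents."""

    spec: FixtureSpec
    paths: WorldPaths
    models: list
    table: ExpressionTable
    truth: dict

    @property
    def models_by_id(self):
        return {m.gene_id: m for m in self.models}

    def open_track(self, sample_id: str) -> SignalTrack:
        return SignalTrack(self.paths.bigwigs[sample_id])

    def constant_models(self, gene_ids):
        by_id = self.models_by_id
        return [by_id[g] for g in gene_ids if g in by_id]


def build_world(spec: FixtureSpec, out_dir) -> World:
    paths = make_world(spec, out_dir)
    return World(
        spec=spec,
        paths=paths,
        models=read_gene_annotation(paths.gtf),
        table=read_expression(paths.expression, "CPM"),
        truth=json.loads(Path(paths.truth).read_text()),
    )


@pytest.fixture(scope="session")
def exact_world(tmp_path_factory) -> World:
    """1000 genes, 2 samples, sample2 = 2*sample1 + 5, no track noise."""
    spec = FixtureSpec(
        n_genes=1000, n_samples=2, alphas=(1.0, 2.0), betas=(0.0, 5.0),
        noise_sd=0.0, seed=1,
    )
    return build_world(spec, tmp_path_factory.mktemp("exact_world"))


@pytest.fixture(scope="session")
def noisy_world(tmp_path_factory) -> World:
    """Same geometry with 1% multiplicative track noise."""
    spec = FixtureSpec(
        n_genes=1000, n_samples=2, alphas=(1.0, 2.0), betas=(0.0, 5.0),
        noise_sd=0.01, seed=5,
    )
    return build_world(spec, tmp_path_factory.mktemp("noisy_world"))


@pytest.fixture(scope="session")
def small_world(tmp_path_factory) -> World:
    """200 genes, mild affine distortion; cheap enough for CLI runs."""
    spec = FixtureSpec(
        n_genes=200, n_samples=2, alphas=(1.0, 1.5), betas=(0.0, 2.0),
        noise_sd=0.0, seed=9,
    )
    return build_world(spec, tmp_path_factory.mktemp("small_world"))


@pytest.fixture(scope="session")
def multi_world(tmp_path_factory) -> World:
    """Five samples with spread distortions, for reference/zone statistics."""
    spec = FixtureSpec(
        n_genes=300, n_samples=5,
        alphas=(0.5, 1.0, 1.5, 2.0, 3.0), betas=(0.0, 1.0, 2.0, 0.5, 4.0),
        noise_sd=0.0, seed=13,
    )
    return build_world(spec, tmp_path_factory.mktemp("multi_world"))


def make_gene(gene_id="g1", chrom="chr1", start=1000, end=2000, strand="+",
              exon_length=None) -> GeneModel:
    return GeneModel(
        gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand,
        exon_length=exon_length if exon_length is not None else end - start,
    )
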