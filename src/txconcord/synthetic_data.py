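"""Ground-truthed synthetic multi-platform expression data.

The concordance analysis is defined on consortium-scale measurements that are
not redistributable, so this module generates datasets with the statistical
structure the analysis presumes, together with the ground truth needed to
score it:

* a gene universe of ``n_genes`` (default 275, a chromosome-sized set of
  protein-coding genes) in which a small *silent* fraction (default 2/275,
  i.e. about two genes) is truly unexpressed;
* heavy-tailed true abundances for expressed genes, drawn log-normally
  (``lambda_g`` in arbitrary copies);
* a per-platform observation model: multiplicative efficiency, log-normal
  measurement noise, abundance-dependent dropout ``d0 * exp(-lambda /
  lambda0)`` (low-copy transcripts are the ones a platform misses), and a
  small false-positive rate on silent genes whose spurious signal lies in
  ``(0, 0.1]`` — below the first non-zero cutoff of the default ladder, so a
  0.1 cutoff removes exactly this noise band;
* optional batch drift between two measurement campaigns: a multiplicative
  decay ``exp(-kappa * q_g)`` where ``q_g`` is the abundance rank-quantile,
  so highly abundant transcripts drift the most (mimicking faster
  degradation of abundant transcripts in samples profiled years apart),
  plus extra log-scale noise.  Drift never wakes a silent gene.

Everything is deterministic under a seed: each (platform, batch) observation
uses an independent random stream keyed by the seed and stable CRC32 hashes
of the platform and batch tags, with a fixed per-gene draw layout inside the
stream.  Adding a platform or batch therefore never perturbs another one's
draws.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_tables import ExpressionTable, GeneUniverse, write_expression_table, round6

__all__ = [
    "TruthModel",
    "PlatformModel",
    "BatchDrift",
    "SyntheticTruth",
    "SyntheticDataset",
    "DEFAULT_UNITS",
    "default_platform_models",
    "generate_truth",
    "observe",
    "generate_dataset",
]

DEFAULT_UNITS = {
    "short_read": "RPKM",
    "long_read": "norm_count",
    "qpcr": "abundance_score",
    "other": "signal",
}


@dataclass(frozen=True)
class TruthModel:
    """True transcriptome state: which genes are expressed and how abundantly.

    ``silent_fraction`` is the per-gene probability of being truly
    unexpressed (lambda = 0); the default 2/275 echoes a chromosome-sized
    universe in which about two genes yield no transcript at all.  Expressed
    genes draw lambda from a log-normal with parameters ``mean_log`` /
    ``sd_log`` (defaults 1.0 / 2.0), giving the heavy right tail typical of
    bulk expression.
    """

    n_genes: int = 275
    silent_fraction: float = 2.0 / 275.0
    mean_log: float = 1.0
    sd_log: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError(f"n_genes must be positive, got {self.n_genes}")
        if not 0.0 <= self.silent_fraction <= 1.0:
            raise ValueError(f"silent_fraction must be in [0, 1], got {self.silent_fraction}")
        if self.sd_log <= 0:
            raise ValueError(f"sd_log must be > 0, got {self.sd_log}")


@dataclass(frozen=True)
class PlatformModel:
    """Observation model of one measurement technology.

    ``efficiency`` scales true abundance to expected signal in the platform's
    native unit; ``noise_sd_log`` is log-scale measurement noise.  Dropout
    (detection failure of a truly expressed gene) has probability
    ``dropout_d0 * exp(-lambda / dropout_lambda0)`` — certain detection for
    abundant transcripts, coin-flip at best for the rarest.  Silent genes
    produce a spurious positive signal with probability
    ``false_positive_rate``, uniform on ``(0, fp_max]``; the long-read
    default rate is 10x the others, reflecting the higher per-base error of
    nanopore reads.
    """

    platform: str = "short_read"
    efficiency: float = 1.0
    noise_sd_log: float = 0.3
    dropout_d0: float = 0.5
    dropout_lambda0: float = 1.0
    false_positive_rate: float = 0.001
    fp_max: float = 0.1

    def __post_init__(self) -> None:
        if self.efficiency <= 0:
            raise ValueError(f"efficiency must be > 0, got {self.efficiency}")
        for name in ("dropout_d0", "false_positive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd_log < 0:
            raise ValueError(f"noise_sd_log must be >= 0, got {self.noise_sd_log}")
        if self.dropout_lambda0 <= 0:
            raise ValueError(f"dropout_lambda0 must be > 0, got {self.dropout_lambda0}")
        if self.fp_max <= 0:
            raise ValueError(f"fp_max must be > 0, got {self.fp_max}")

    def dropout_rate(self, lam: float | np.ndarray) -> float | np.ndarray:
        """Probability that a truly expressed gene of abundance ``lam`` yields
        no signal at all; non-increasing in ``lam``."""
        return self.dropout_d0 * np.exp(-np.asarray(lam) / self.dropout_lambda0)


def default_platform_models() -> tuple[PlatformModel, PlatformModel, PlatformModel]:
    """The three-technology default: short-read, long-read, qPCR.

    Only the false-positive rate differs (long-read 0.01 vs 0.001): the
    defaults encode qualitative structure, not calibrated estimates of any
    real instrument.
    """
    return (
        PlatformModel(platform="short_read", false_positive_rate=0.001),
        PlatformModel(platform="long_read", false_positive_rate=0.01),
        PlatformModel(platform="qpcr", false_positive_rate=0.001),
    )


@dataclass(frozen=True)
class BatchDrift:
    """Systematic change between two measurement campaigns of one sample.

    The second campaign's signal is multiplied by ``exp(-decay_rate * q_g)``
    where ``q_g`` in [0, 1] is the gene's abundance rank-quantile among
    expressed genes, so the most abundant transcripts decay the most; extra
    log-scale noise (``extra_noise_sd_log``) models campaign-specific
    technical variation.  Silent genes stay silent.
    """

    decay_rate: float = 0.2
    extra_noise_sd_log: float = 0.1

    def __post_init__(self) -> None:
        if self.decay_rate <= 0:
            raise ValueError(f"decay_rate must be > 0, got {self.decay_rate}")
        if self.extra_noise_sd_log < 0:
            raise ValueError(f"extra_noise_sd_log must be >= 0, got {self.extra_noise_sd_log}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-gene ground truth plus the model that generated it."""

    gene_ids: tuple[str, ...]
    lam: np.ndarray  # true abundance lambda_g; 0 for silent genes
    expressed: np.ndarray  # boolean presence flag
    model: TruthModel

    @property
    def universe(self) -> GeneUniverse:
        return GeneUniverse(genes=self.gene_ids, label="synthetic")

    @property
    def rank_quantile(self) -> np.ndarray:
        """Abundance rank-quantile q in [0, 1] among expressed genes (0 elsewhere)."""
        q = np.zeros(len(self.gene_ids))
        idx = np.flatnonzero(self.expressed)
        if idx.size == 1:
            q[idx] = 1.0
        elif idx.size > 1:
            order = np.argsort(np.argsort(self.lam[idx], kind="stable"), kind="stable")
            q[idx] = order / (idx.size - 1)
        return q


def _stream(seed: int, platform: str, batch: str) -> np.random.Generator:
    """Independent random stream for one (platform, batch) observation."""
    key = (zlib.crc32(platform.encode()), zlib.crc32(batch.encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def generate_truth(model: TruthModel) -> SyntheticTruth:
    """Draw the true transcriptome state under ``model`` (deterministic in seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=model.seed))
    n = model.n_genes
    width = max(4, len(str(n)))
    gene_ids = tuple(f"G{i + 1:0{width}d}" for i in range(n))
    silent = rng.random(n) < model.silent_fraction
    lam = np.where(silent, 0.0, rng.lognormal(model.mean_log, model.sd_log, size=n))
    return SyntheticTruth(gene_ids=gene_ids, lam=lam, expressed=~silent, model=model)


def observe(
    truth: SyntheticTruth,
    platform: PlatformModel,
    drift: BatchDrift | None = None,
    batch: str = "b1",
    sample: str = "synthetic",
) -> ExpressionTable:
    """Realize one platform's measurement of the true transcriptome.

    An expressed gene drops out with probability ``dropout_rate(lambda)``;
    otherwise its value is ``efficiency * lambda * exp(noise)`` times the
    drift factor when a drifted batch is requested.  A silent gene yields a
    spurious value in ``(0, fp_max]`` with the platform's false-positive
    probability, else exactly 0.
    """
    n = len(truth.gene_ids)
    rng = _stream(truth.model.seed, platform.platform, batch)
    # fixed draw layout: one array per role, gene i uses index i of each
    u_drop = rng.random(n)
    z_noise = rng.standard_normal(n)
    u_fp = rng.random(n)
    u_fp_mag = rng.random(n)
    z_drift = rng.standard_normal(n)

    lam = truth.lam
    expressed = truth.expressed

    log_factor = platform.noise_sd_log * z_noise
    if drift is not None:
        log_factor = log_factor - drift.decay_rate * truth.rank_quantile
        log_factor = log_factor + drift.extra_noise_sd_log * z_drift
    signal = platform.efficiency * lam * np.exp(log_factor)

    detected = expressed & (u_drop >= platform.dropout_rate(lam))
    spurious = (~expressed) & (u_fp < platform.false_positive_rate)

    values = np.zeros(n)
    values[detected] = signal[detected]
    values[spurious] = platform.fp_max * (1.0 - u_fp_mag[spurious])

    return ExpressionTable(
        platform=platform.platform,
        sample=sample,
        batch=batch,
        unit=DEFAULT_UNITS.get(platform.platform, "signal"),
        values={g: float(v) for g, v in zip(truth.gene_ids, values)},
    )


@dataclass(frozen=True)
class SyntheticDataset:
    """A labeled bundle: realized tables plus the truth that generated them."""

    truth: SyntheticTruth
    tables: tuple[ExpressionTable, ...]

    @property
    def universe(self) -> GeneUniverse:
        return self.truth.universe


def generate_dataset(
    truth_model: TruthModel,
    platform_models: Sequence[PlatformModel] | None = None,
    drift: BatchDrift | None = None,
    sample: str = "synthetic",
    out_dir: str | Path | None = None,
) -> SyntheticDataset:
    """Generate one table per platform (two batches per platform under drift).

    With ``drift`` given, each platform is observed twice: batch ``b1``
    un-drifted and batch ``b2`` with the drift applied, emulating two
    measurement campaigns of the same sample.  When ``out_dir`` is given the
    tables, a truth-labels TSV (gene_id, lambda, expressed) and a JSON
    parameter manifest are written there.
    """
    if platform_models is None:
        platform_models = default_platform_models()
    if len(platform_models) < 2:
        raise ValueError("need at least two platform models")
    tags = [pm.platform for pm in platform_models]
    if len(set(tags)) != len(tags):
        raise ValueError(f"duplicate platform tags: {tags}")

    truth = generate_truth(truth_model)
    tables: list[ExpressionTable] = []
    for pm in platform_models:
        tables.append(observe(truth, pm, drift=None, batch="b1", sample=sample))
        if drift is not None:
            tables.append(observe(truth, pm, drift=drift, batch="b2", sample=sample))
    dataset = SyntheticDataset(truth=truth, tables=tuple(tables))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for t in dataset.tables:
            write_expression_table(t, out / f"{t.platform}_{t.sample}_{t.batch}.tsv")
        with (out / "truth.tsv").open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene_id\tlambda\texpressed\n")
            for g, lam, ex in zip(truth.gene_ids, truth.lam, truth.expressed):
                fh.write(f"{g}\t{float(lam)!r}\t{int(ex)}\n")
        manifest = {
            "truth_model": asdict(truth_model),
            "platform_models": [asdict(pm) for pm in platform_models],
            "batch_drift": asdict(drift) if drift is not None else None,
            "sample": sample,
            "tables": [
                {"platform": t.platform, "sample": t.sample, "batch": t.batch, "unit": t.unit}
                for t in dataset.tables
            ],
        }
        with (out / "manifest.json").open("w", encoding="utf-8", newline="\n") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=2)
            fh.write("\n")
    return dataset
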