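"""Scaled-down end-to-end benchmark of the reconstruction pipeline.

Desk-scale stand-in for the full study: the same phantom geometry on a
coarser grid with a 21x21 reconstruction window (n = 441), one field
strength (0.10 T), all 19 stenosis configurations, and 10 time samples
per pulsation period (190 samples, split 152/38).  The networks are the
reduced-width variants that honor the reference block patterns, trained
for 800 (CAE) and 500 (CNN) iterations.  The whole pipeline -- simulate,
train CAE, transform, train CNN and BP, tune the Tikhonov weight,
evaluate clean and noisy -- runs in a couple of minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domain_transform import transform_batch
from .evaluation import (
    EvalReport,
    PipelineContext,
    evaluate,
    noise_sweep,
    select_tikhonov_lambda,
)
from .forward import SampleSet, SimulationConfig, generate_dataset
from .networks import TrainConfig, TrainedModel, encode, train_bp, train_cae, train_cnn
from .phantom import FlowConfig, build_phantom, default_config

__all__ = ["BenchmarkConfig", "BenchmarkResult", "run_benchmark"]


@dataclass
class BenchmarkConfig:
    seed: int = 1
    scale: str = "small"          # phantom scale; "small" gives the 21x21 window
    B_values: tuple = (0.10,)
    dt: float = 0.09              # 10 time samples over the 0.85 s period
    cae_lr: float = 3e-3
    cae_iterations: int = 800
    cae_channels: int = 12
    cnn_lr: float = 1e-3
    cnn_iterations: int = 500
    bp_lr: float = 1e-3
    bp_iterations: int = 300
    batch_size: int = 817
    snr_list: tuple = (60.0, 50.0, 40.0, 30.0, 20.0)
    methods: tuple = ("tikhonov", "bp", "cae_cnn")


@dataclass
class BenchmarkResult:
    dataset: SampleSet
    cae: TrainedModel
    cnn: TrainedModel
    bp: TrainedModel | None
    ctx: PipelineContext
    tikhonov_lam: float
    clean_reports: dict         # method -> EvalReport (noiseless)
    noise_reports: list = field(default_factory=list)  # EvalReport per (method, SNR)

    def report_at(self, method: str, snr_db: float) -> EvalReport:
        for r in self.noise_reports:
            if r.method == method and r.snr_db == snr_db:
                return r
        raise KeyError(f"no report for {method} at {snr_db} dB")


def run_benchmark(
    cfg: BenchmarkConfig | None = None,
    run_noise_sweep: bool = True,
    dataset: SampleSet | None = None,
) -> BenchmarkResult:
    """Run the full scaled pipeline and return models, context and reports."""
    cfg = cfg if cfg is not None else BenchmarkConfig()
    if dataset is None:
        phantom = build_phantom(default_config(cfg.scale))
        dataset = generate_dataset(
            phantom,
            SimulationConfig(B_values=cfg.B_values, seed=cfg.seed),
            FlowConfig(dt=cfg.dt),
        )
    tr = dataset.train_idx
    cae = train_cae(
        dataset.W,
        TrainConfig(learning_rate=cfg.cae_lr, iterations=cfg.cae_iterations, batch_size=1, seed=cfg.seed),
        p=cfg.cae_channels,
    )
    Wp = encode(cae, dataset.W)
    feats, _ = transform_batch(dataset.U, Wp)
    cnn = train_cnn(
        feats[tr],
        dataset.V[tr],
        TrainConfig(learning_rate=cfg.cnn_lr, iterations=cfg.cnn_iterations, batch_size=cfg.batch_size, seed=cfg.seed),
    )
    bp = None
    if "bp" in cfg.methods:
        bp = train_bp(
            dataset.U[tr],
            dataset.V[tr],
            TrainConfig(learning_rate=cfg.bp_lr, iterations=cfg.bp_iterations, batch_size=cfg.batch_size, seed=cfg.seed),
        )
    # tune lam on a held-out slice of the training split
    n_val = max(10, len(tr) // 5)
    lam = select_tikhonov_lambda(dataset.W, dataset.U[tr[:n_val]], dataset.V[tr[:n_val]])
    ctx = PipelineContext(
        W=dataset.W, tikhonov_lam=lam, feature_tensor=Wp, cnn=cnn, bp=bp
    )
    clean = {
        m: evaluate(m, dataset, ctx, seed=cfg.seed) for m in cfg.methods
    }
    noise = (
        noise_sweep(list(cfg.methods), dataset, ctx, cfg.snr_list, seed=cfg.seed)
        if run_noise_sweep
        else []
    )
    return BenchmarkResult(
        dataset=dataset,
        cae=cae,
        cnn=cnn,
        bp=bp,
        ctx=ctx,
        tikhonov_lam=lam,
        clean_reports=clean,
        noise_reports=noise,
    )
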