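"""Synthetic ORF-screen generator with planted effects and ground truth.

Emulates the screen design end to end so every downstream stage is testable
without raw sequencing data: ORF conditions transduced in replicate and
organised in batches (each batch carrying its own empty-vector control
samples), per-gene log2 baselines with a detection floor, per-gene additive
batch shifts shared by all samples of a batch, additive Gaussian log2 noise
per sample, and per-ORF planted log2 effects of known sign and magnitude.
The planted (gene, condition, effect) triples come back as a
:class:`ScreenTruth` for recovery scoring.

Defaults mirror the study conditions the pipeline is validated under:
ORFs in triplicate across three batches, planted |log2 effect| in [1.5, 3]
(2.8- to 8-fold), 50 hits per ORF out of 5,000 genes, per-sample log2 noise
SD 0.25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .normalize import CONTROL_LABEL, ExpressionMatrix, SampleSheet
from .screen import HitSet

__all__ = [
    "SimulationConfig",
    "ScreenTruth",
    "simulate_screen",
    "score_recovery",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic screen.

    The noise model is additive Gaussian on the log2 scale; batch effects
    are per-gene additive log2 shifts shared by every sample of a batch.
    With ``output_scale="counts"`` the log2 expression is exponentiated,
    scaled by per-sample library-size factors (gamma, CV ``libsize_cv``)
    and sampled as negative-binomial counts via a gamma-Poisson mixture
    whose gamma CV is ``noise_sd``.
    """

    n_genes: int = 5000
    n_orfs: int = 10
    replicates_per_orf: int = 3
    n_batches: int = 3
    controls_per_batch: int = 3
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    noise_sd: float = 0.25
    batch_sd: float = 0.3
    hits_per_orf: int = 50
    effect_low: float = 1.5
    effect_high: float = 3.0
    frac_undetectable: float = 0.1
    detection_floor_log2: float = 3.0
    libsize_cv: float = 0.1
    output_scale: str = "log2"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_orfs", "replicates_per_orf", "n_batches",
                     "controls_per_batch"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.noise_sd < 0 or self.batch_sd < 0 or self.libsize_cv < 0:
            raise ValueError("noise_sd, batch_sd and libsize_cv must be nonnegative")
        if self.hits_per_orf < 0 or self.hits_per_orf > self.n_genes:
            raise ValueError("hits_per_orf must be in [0, n_genes]")
        if not 0 <= self.frac_undetectable <= 1:
            raise ValueError("frac_undetectable must be in [0, 1]")
        if self.effect_low > self.effect_high:
            raise ValueError("effect_low must be <= effect_high")
        if self.hits_per_orf and self.effect_low < 1:
            # sub-threshold planted effects are allowed for power studies,
            # but they cannot satisfy the fold>2 hit criterion
            warnings.warn(
                "effect_low < 1: planted effects may fall below the fold-change "
                "threshold and will not be recoverable as hits",
                stacklevel=2,
            )
        if self.output_scale not in ("log2", "counts"):
            raise ValueError("output_scale must be 'log2' or 'counts'")


@dataclass
class ScreenTruth:
    """Planted ground truth: one (gene, condition, signed log2 effect) per row."""

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "condition", "effect"])
    )

    def __post_init__(self) -> None:
        if self.entries.duplicated(["gene", "condition"]).any():
            raise ValueError("at most one planted entry per (gene, condition)")

    def triples(self) -> set[tuple[str, str, str]]:
        """Signed triples (gene, condition, 'up'|'down')."""
        e = self.entries
        return {
            (g, c, "up" if x > 0 else "down")
            for g, c, x in zip(e["gene"], e["condition"], e["effect"])
        }

    def conditions(self) -> set[str]:
        return set(self.entries["condition"])

    def __len__(self) -> int:
        return len(self.entries)


def simulate_screen(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[ExpressionMatrix, SampleSheet, ScreenTruth]:
    """Generate one synthetic screen: matrix, sample sheet and ground truth.

    ORFs are assigned round-robin to batches; each batch additionally gets
    ``controls_per_batch`` empty-vector control samples. Planted effects are
    added only to the target ORF's replicate columns; their genes are drawn
    from the detectable pool (a gene below the detection floor can never be
    a hit) and signs are Bernoulli(1/2). A ``frac_undetectable`` subset of
    genes has its baseline pinned one log2 unit below the detection floor.
    Identical seed gives identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])
    orfs = [f"ORF{i + 1:02d}" for i in range(cfg.n_orfs)]
    orf_batch = {orf: f"B{(i % cfg.n_batches) + 1}" for i, orf in enumerate(orfs)}
    batches = [f"B{b + 1}" for b in range(cfg.n_batches)]

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    n_undet = int(round(cfg.frac_undetectable * cfg.n_genes))
    undet = rng.choice(cfg.n_genes, size=n_undet, replace=False)
    baseline[undet] = cfg.detection_floor_log2 - 1.0
    detectable = np.setdiff1d(np.arange(cfg.n_genes), undet)

    batch_shift = rng.normal(0.0, cfg.batch_sd, (cfg.n_genes, cfg.n_batches))
    batch_col = {b: j for j, b in enumerate(batches)}

    truth_rows = []
    planted: dict[str, np.ndarray] = {}
    for orf in orfs:
        eff = np.zeros(cfg.n_genes)
        if cfg.hits_per_orf:
            if cfg.hits_per_orf > len(detectable):
                raise ValueError("hits_per_orf exceeds the detectable gene pool")
            idx = rng.choice(detectable, size=cfg.hits_per_orf, replace=False)
            mag = rng.uniform(cfg.effect_low, cfg.effect_high, cfg.hits_per_orf)
            sign = rng.choice([-1.0, 1.0], size=cfg.hits_per_orf)
            eff[idx] = sign * mag
            for i, g in enumerate(idx):
                truth_rows.append(
                    {"gene": genes[g], "condition": orf, "effect": sign[i] * mag[i]}
                )
        planted[orf] = eff

    sample_rows = []
    columns: dict[str, np.ndarray] = {}
    for orf in orfs:
        b = orf_batch[orf]
        for r in range(1, cfg.replicates_per_orf + 1):
            sid = f"{orf}_r{r}"
            mu = baseline + batch_shift[:, batch_col[b]] + planted[orf]
            noise = rng.normal(0.0, cfg.noise_sd, cfg.n_genes) if cfg.noise_sd else 0.0
            columns[sid] = mu + noise
            sample_rows.append(
                {"sample": sid, "condition": orf, "replicate": str(r),
                 "batch": b, "is_control": False}
            )
    for b in batches:
        for r in range(1, cfg.controls_per_batch + 1):
            sid = f"CTRL_{b}_r{r}"
            mu = baseline + batch_shift[:, batch_col[b]]
            noise = rng.normal(0.0, cfg.noise_sd, cfg.n_genes) if cfg.noise_sd else 0.0
            columns[sid] = mu + noise
            sample_rows.append(
                {"sample": sid, "condition": CONTROL_LABEL, "replicate": str(r),
                 "batch": b, "is_control": True}
            )

    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    if cfg.output_scale == "counts":
        expr = np.power(2.0, values.to_numpy())
        libfac = _gamma_cv(rng, 1.0, cfg.libsize_cv, expr.shape[1])
        mean = expr * libfac
        if cfg.noise_sd > 0:
            mean = mean * _gamma_cv(rng, 1.0, cfg.noise_sd, mean.shape)
        counts = rng.poisson(mean).astype(float)
        values = pd.DataFrame(counts, index=values.index, columns=values.columns)
        matrix = ExpressionMatrix(values, scale="counts")
    else:
        matrix = ExpressionMatrix(values, scale="log2")

    sheet = SampleSheet(pd.DataFrame(sample_rows))
    truth = ScreenTruth(
        pd.DataFrame(truth_rows, columns=["gene", "condition", "effect"])
    )
    return matrix, sheet, truth


def _gamma_cv(rng: np.random.Generator, mean: float, cv: float, size):
    """Gamma draws with the given mean and coefficient of variation."""
    if cv == 0:
        return np.full(size, mean) if not np.isscalar(size) else np.full(size, mean)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean * cv**2, size)


def score_recovery(
    hitsets: Mapping[str, HitSet],
    truth: ScreenTruth,
    tier: str = "hit",
) -> dict:
    """Score called hits against planted truth on (gene, condition, sign) triples.

    Returns sensitivity, precision and F1 (all in [0, 1]) plus raw counts
    and per-direction tallies. Undefined ratios (no calls, or empty truth)
    are reported as 0.0 with the matching ``*_defined`` flag set False.
    """
    missing = truth.conditions() - set(hitsets)
    if missing:
        raise ValueError(f"truth condition(s) absent from hit sets: {sorted(missing)}")
    called: set[tuple[str, str, str]] = set()
    for cond, hs in hitsets.items():
        called |= {(g, cond, d) for g, d in hs.signed(tier)}
    true = truth.triples()
    tp = called & true
    n_called, n_true, n_tp = len(called), len(true), len(tp)
    sens_def, prec_def = n_true > 0, n_called > 0
    sensitivity = n_tp / n_true if sens_def else 0.0
    precision = n_tp / n_called if prec_def else 0.0
    f1 = (
        2 * sensitivity * precision / (sensitivity + precision)
        if sensitivity + precision > 0
        else 0.0
    )
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "f1": f1,
        "n_true": n_true,
        "n_called": n_called,
        "n_matched": n_tp,
        "n_true_up": sum(1 for t in true if t[2] == "up"),
        "n_true_down": sum(1 for t in true if t[2] == "down"),
        "n_called_up": sum(1 for t in called if t[2] == "up"),
        "n_called_down": sum(1 for t in called if t[2] == "down"),
        "sensitivity_defined": sens_def,
        "precision_defined": prec_def,
    }


def write_truth(truth: ScreenTruth, path) -> None:
    truth.entries.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_truth(path) -> ScreenTruth:
    return ScreenTruth(pd.read_csv(path, sep="\t", dtype={"gene": str, "condition": str}))
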