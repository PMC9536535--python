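"""The screening statistic: baseline, log2 effects, robust Z-scores, hit calls.

For every detectable gene the screen measures the log2 fold-induction ``x``
of each ORF condition relative to a transcriptome-wide baseline ``b_g`` (the
per-gene median of merged log2 expression across all conditions, controls
included). The fold-change equivalent of an effect is ``FC = 2**x`` — an
effect of 1 is a two-fold induction. Each gene's expected range of variation
``s_g`` is estimated robustly (MAD x 1.4826 of its effects across all
conditions, floored to avoid degenerate zero-variance genes), giving
``Z = x / s_g``. Genes classify as:

* ``below_detection`` — baseline under the detection floor (log2 value 3);
* ``within``          — |Z| <= 2, inside the expected range;
* ``suggestive``      — 2 < |Z| <= 4, suggestively outside the range;
* ``outside``         — |Z| > 4, outside the expected range.

A HIT is a detected gene whose fold effect exceeds two (|x| > 1) AND whose
expression lies outside the expected range (|Z| > 4); the 2 < |Z| <= 4 band
with fold > 2 forms a suggestive tier. All thresholds are configurable via
:class:`ScreenConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .normalize import (
    CONTROL_LABEL,
    ConditionProfiles,
    ExpressionMatrix,
    SampleSheet,
    anchor_batches,
    merge_replicates,
    normalize_log2,
)

__all__ = [
    "ScreenConfig",
    "HitSet",
    "CLASS_LABELS",
    "compute_baseline",
    "compute_effects",
    "effect_to_fc",
    "estimate_expected_variation",
    "classify",
    "build_effect_table",
    "call_hits",
    "count_hits",
    "ma_table",
    "screen_pipeline",
]

#: MAD-to-sigma consistency constant under normality.
MAD_SCALE = 1.4826

CLASS_LABELS = ("below_detection", "within", "suggestive", "outside")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and estimator choices for hit calling.

    fold_threshold
        Minimum fold effect for a hit (must be > 1); a hit needs
        ``|x| > log2(fold_threshold)``. Default 2.
    z_hit, z_suggestive
        |Z| bounds of the "outside" and "suggestive" classes. Defaults 4 and 2.
    detection_floor_log2
        Genes whose baseline log2 expression falls below this floor are
        below detection and never classified or called. Default 3.
    variance_estimator
        ``"mad"`` (MAD x 1.4826, robust, default) or ``"sd"`` (sample
        standard deviation) for the per-gene expected-variation scale.
    variance_floor
        Lower bound on the per-gene scale; ``None`` (default) floors at
        0.25 x the median scale over detected genes.
    replicate_level_variance
        Estimate the scale from replicate-level effects instead of merged
        condition-level effects (requires passing the replicate matrix to
        :func:`screen_pipeline`). Default False.
    include_control_in_baseline
        Whether the pooled control profile contributes one condition to the
        baseline median. Default True.
    """

    fold_threshold: float = 2.0
    z_hit: float = 4.0
    z_suggestive: float = 2.0
    detection_floor_log2: float = 3.0
    variance_estimator: str = "mad"
    variance_floor: float | None = None
    replicate_level_variance: bool = False
    include_control_in_baseline: bool = True

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if self.z_suggestive <= 0 or self.z_hit <= 0:
            raise ValueError("z thresholds must be positive")
        if self.z_suggestive >= self.z_hit:
            raise ValueError("z_suggestive must be < z_hit")
        if self.variance_estimator not in ("mad", "sd"):
            raise ValueError("variance_estimator must be 'mad' or 'sd'")
        if self.variance_floor is not None and self.variance_floor < 0:
            raise ValueError("variance_floor must be nonnegative")

    @property
    def log2_fold_threshold(self) -> float:
        return math.log2(self.fold_threshold)


@dataclass
class HitSet:
    """Hits called for one ORF condition.

    ``table`` has one row per gene with columns ``gene, direction, tier``
    (direction in {up, down}, tier in {hit, suggestive}).
    """

    condition: str
    table: pd.DataFrame

    def genes(self, tier: str = "hit") -> list[str]:
        return self.table.loc[self.table["tier"] == tier, "gene"].tolist()

    def signed(self, tier: str = "hit") -> set[tuple[str, str]]:
        t = self.table.loc[self.table["tier"] == tier]
        return set(zip(t["gene"], t["direction"]))


# ---------------------------------------------------------------------------
# Statistic


def compute_baseline(
    profiles: ConditionProfiles, include_control: bool = True
) -> pd.Series:
    """Per-gene baseline: median of merged log2 expression across conditions.

    The pooled control profile counts as one condition (default). Even
    condition counts take the mean of the middle two values.
    """
    cols = list(profiles.conditions)
    if not include_control and CONTROL_LABEL in cols:
        cols.remove(CONTROL_LABEL)
    if len(cols) < 2:
        raise ValueError("baseline needs at least 2 condition profiles")
    return profiles.values[cols].median(axis=1).rename("baseline")


def compute_effects(profiles: ConditionProfiles, baseline: pd.Series) -> pd.DataFrame:
    """Per-gene, per-condition log2 effect ``x = profile - baseline``."""
    if not profiles.genes.equals(baseline.index):
        raise ValueError("gene universe mismatch between profiles and baseline")
    return profiles.values.sub(baseline, axis=0)


def effect_to_fc(x):
    """Fold-change equivalent of a log2 effect: ``FC = 2**x``."""
    return np.power(2.0, x)


def estimate_expected_variation(
    effects: pd.DataFrame,
    detected: pd.Series,
    config: ScreenConfig = ScreenConfig(),
) -> pd.Series:
    """Per-gene expected-variation scale ``s_g`` from effects across conditions.

    For each detected gene the scale is the MAD of its effects across all
    conditions times 1.4826 (or the sample SD in ``sd`` mode), floored at
    ``config.variance_floor`` — by default 0.25 x the median scale over
    detected genes, so zero-variance genes cannot yield infinite Z.
    Undetected genes get NaN.
    """
    if effects.shape[1] < 3:
        raise ValueError("expected-variation scale needs >= 3 conditions")
    vals = effects.to_numpy(dtype=float)
    if config.variance_estimator == "mad":
        med = np.median(vals, axis=1, keepdims=True)
        raw = np.median(np.abs(vals - med), axis=1) * MAD_SCALE
    else:
        raw = np.std(vals, axis=1, ddof=1)
    s = pd.Series(raw, index=effects.index, name="scale")
    det = detected.reindex(effects.index).fillna(False).astype(bool)
    floor = config.variance_floor
    if floor is None:
        med_s = float(s[det].median()) if det.any() else float("nan")
        floor = 0.25 * med_s
    if not det.any():
        return pd.Series(np.nan, index=effects.index, name="scale")
    if not (floor > 0):
        raise ValueError(
            "variance floor is not positive; set ScreenConfig.variance_floor "
            "explicitly for degenerate (zero-variation) inputs"
        )
    s = s.clip(lower=floor)
    s[~det] = np.nan
    return s


def classify(
    baseline: pd.Series, z: pd.DataFrame, config: ScreenConfig = ScreenConfig()
) -> pd.DataFrame:
    """Four-way class label per gene per condition.

    ``below_detection`` when the gene's baseline is under the detection
    floor; otherwise ``within`` (|Z| <= z_suggestive), ``suggestive``
    (z_suggestive < |Z| <= z_hit) or ``outside`` (|Z| > z_hit).
    """
    absz = z.abs()
    labels = pd.DataFrame("within", index=z.index, columns=z.columns, dtype=object)
    labels[absz > config.z_suggestive] = "suggestive"
    labels[absz > config.z_hit] = "outside"
    below = baseline.reindex(z.index) < config.detection_floor_log2
    labels.loc[below, :] = "below_detection"
    return labels


def build_effect_table(
    profiles: ConditionProfiles,
    config: ScreenConfig = ScreenConfig(),
    scale_effects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the whole statistic and return one long-format effect table.

    One row per (gene, condition) with columns ``gene, condition, baseline,
    effect, fc, scale, z, detected, label``. ``scale_effects`` optionally
    supplies a different effect matrix (e.g. replicate-level) for the
    variance estimation step.
    """
    baseline = compute_baseline(profiles, config.include_control_in_baseline)
    effects = compute_effects(profiles, baseline)
    detected = (baseline >= config.detection_floor_log2).rename("detected")
    var_src = effects if scale_effects is None else scale_effects
    s = estimate_expected_variation(var_src, detected, config)
    z = effects.div(s, axis=0)
    labels = classify(baseline, z, config)

    n_genes, n_conds = effects.shape
    eff = effects.to_numpy().ravel()
    long = pd.DataFrame(
        {
            "gene": np.repeat(effects.index.to_numpy(), n_conds),
            "condition": np.tile(effects.columns.to_numpy(), n_genes),
            "baseline": np.repeat(baseline.to_numpy(), n_conds),
            "effect": eff,
            "fc": effect_to_fc(eff),
            "scale": np.repeat(s.to_numpy(), n_conds),
            "z": z.to_numpy().ravel(),
            "detected": np.repeat(detected.to_numpy(), n_conds),
            "label": labels.to_numpy().ravel(),
        }
    )
    return long


def call_hits(
    effect_table: pd.DataFrame, config: ScreenConfig = ScreenConfig()
) -> dict[str, HitSet]:
    """Two-tier hit calls per ORF condition.

    tier ``hit``: detected, |x| > log2(fold_threshold) and class ``outside``;
    tier ``suggestive``: same fold criterion with class ``suggestive``.
    Direction is the sign of the effect. The control condition yields no
    hit set.
    """
    thr = config.log2_fold_threshold
    hitsets: dict[str, HitSet] = {}
    for cond, grp in effect_table.groupby("condition", sort=False):
        if cond == CONTROL_LABEL:
            continue
        sel = grp.loc[
            grp["detected"]
            & (grp["effect"].abs() > thr)
            & grp["label"].isin(["outside", "suggestive"])
        ]
        table = pd.DataFrame(
            {
                "gene": sel["gene"].to_numpy(),
                "direction": np.where(sel["effect"] > 0, "up", "down"),
                "tier": np.where(sel["label"] == "outside", "hit", "suggestive"),
            }
        ).sort_values(["tier", "gene"], ignore_index=True)
        hitsets[str(cond)] = HitSet(str(cond), table)
    return hitsets


def count_hits(hitsets: Mapping[str, HitSet]) -> pd.DataFrame:
    """Per-condition up/down/total counts of hit-tier entries.

    Ordered descending by total, ties broken alphabetically by condition.
    """
    rows = []
    for cond, hs in hitsets.items():
        hit = hs.table.loc[hs.table["tier"] == "hit"]
        n_up = int((hit["direction"] == "up").sum())
        n_down = int((hit["direction"] == "down").sum())
        rows.append({"condition": cond, "n_up": n_up, "n_down": n_down,
                     "n_total": n_up + n_down})
    out = pd.DataFrame(rows, columns=["condition", "n_up", "n_down", "n_total"])
    return out.sort_values(
        ["n_total", "condition"], ascending=[False, True], ignore_index=True
    )


def ma_table(effect_table: pd.DataFrame) -> pd.DataFrame:
    """Plot-data export: (baseline, effect, class) per gene per condition.

    The rows back an MA-style scatter — baseline log2 median expression on
    the x-axis, log2 effect on the y-axis, coloured by class label.
    """
    return effect_table[["condition", "gene", "baseline", "effect", "label"]].copy()


# ---------------------------------------------------------------------------
# End-to-end convenience


def screen_pipeline(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    config: ScreenConfig = ScreenConfig(),
    pseudocount: float = 1.0,
    anchor: bool = True,
) -> tuple[pd.DataFrame, dict[str, HitSet], pd.DataFrame]:
    """Normalize, anchor, merge, score and call a whole screen.

    Returns ``(effect_table, hitsets, counts)``.
    """
    log2m = normalize_log2(matrix, pseudocount)
    if anchor:
        log2m = anchor_batches(log2m, sheet)
    profiles = merge_replicates(log2m, sheet)
    scale_src = None
    if config.replicate_level_variance:
        baseline = compute_baseline(profiles, config.include_control_in_baseline)
        scale_src = log2m.values.sub(baseline, axis=0)
    effect_table = build_effect_table(profiles, config, scale_effects=scale_src)
    hitsets = call_hits(effect_table, config)
    counts = count_hits(hitsets)
    return effect_table, hitsets, counts
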