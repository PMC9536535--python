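"""Replicate concordance and shared-hit overlap statistics.

Two quality/structure questions follow hit calling. First, do independent
replicate sets of the same ORF agree? — answered by the Pearson correlation
of their per-gene log2 effects over the detected-gene universe. Second, do
different ORFs perturb a common set of genes? — answered by pairwise hit-set
overlap with an exact upper-tail hypergeometric p-value (the significance
test is this package's addition: the overlap statistic itself, not a
literature value). The same machinery scores a hit set against user-supplied
GMT gene sets with Benjamini-Hochberg adjustment.

The universe for all overlap tests is the set of detected genes in the
screen: only a detectable gene can ever be a hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import CONTROL_LABEL, ExpressionMatrix, SampleSheet, merge_replicates
from .screen import HitSet, ScreenConfig, compute_baseline

__all__ = [
    "OverlapResult",
    "replicate_concordance",
    "split_replicate_effects",
    "shared_hits",
    "gene_set_overlap",
    "read_gmt",
]


@dataclass
class OverlapResult:
    """Overlap of two gene sets against a finite universe."""

    a_label: str
    b_label: str
    shared: list[str]
    n_a: int
    n_b: int
    n_shared: int
    universe: int
    jaccard: float
    p_value: float

    def as_row(self) -> dict:
        return {
            "a": self.a_label,
            "b": self.b_label,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_shared": self.n_shared,
            "universe": self.universe,
            "jaccard": self.jaccard,
            "p_value": self.p_value,
            "shared": ",".join(self.shared),
        }


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if min(K, n) > N:
        raise ValueError("set sizes exceed the universe")
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def replicate_concordance(
    effects_a: pd.Series,
    effects_b: pd.Series,
    method: str = "pearson",
) -> tuple[float, pd.DataFrame]:
    """Correlation of two effect vectors for one condition.

    Both vectors must cover the same detected-gene universe; the paired
    per-gene table is returned alongside r for plotting. Pearson on log2
    effects by default; ``method="spearman"`` for ranks.
    """
    shared = effects_a.index.intersection(effects_b.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared detected genes")
    a = effects_a.loc[shared].to_numpy(dtype=float)
    b = effects_b.loc[shared].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in an effect vector")
    if method == "pearson":
        r = float(stats.pearsonr(a, b).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(a, b).statistic)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    paired = pd.DataFrame({"gene": shared, "effect_set1": a, "effect_set2": b})
    return r, paired


def split_replicate_effects(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    condition: str,
    config: ScreenConfig = ScreenConfig(),
) -> tuple[pd.Series, pd.Series]:
    """Effects of two independent replicate halves of one condition.

    Splits the condition's replicate columns into two halves, merges each
    half separately, and computes each half's log2 effect against the
    baseline built from the full screen. Only detected genes are returned.
    Expects an anchored log2 matrix.
    """
    t = sheet.table
    samp = t.loc[t["condition"] == condition, "sample"].tolist()
    if len(samp) < 2:
        raise ValueError(f"condition {condition!r} needs >= 2 replicates to split")
    half = len(samp) // 2
    profiles = merge_replicates(matrix, sheet)
    baseline = compute_baseline(profiles, config.include_control_in_baseline)
    detected = baseline >= config.detection_floor_log2
    e1 = matrix.values[samp[:half]].mean(axis=1) - baseline
    e2 = matrix.values[samp[half:]].mean(axis=1) - baseline
    return e1[detected], e2[detected]


def shared_hits(
    hitsets: Mapping[str, HitSet],
    universe_size: int,
    direction_mode: str = "signed",
    tier: str = "hit",
) -> list[OverlapResult]:
    """Pairwise hit-set overlap across ORF conditions.

    ``direction_mode="signed"`` (default) counts a gene as shared only when
    both conditions call it in the same direction; ``"unsigned"`` ignores
    direction. p-values are exact upper-tail hypergeometric with population
    ``universe_size`` (the detected genes), successes |A| and draws |B|.
    """
    if direction_mode not in ("signed", "unsigned"):
        raise ValueError("direction_mode must be 'signed' or 'unsigned'")
    if len(hitsets) < 2:
        raise ValueError("need at least two hit sets")
    results = []
    conds = [c for c in hitsets if c != CONTROL_LABEL]
    for a, b in combinations(conds, 2):
        ga, gb = set(hitsets[a].genes(tier)), set(hitsets[b].genes(tier))
        if max(len(ga), len(gb)) > universe_size:
            raise ValueError("universe smaller than a hit set")
        if direction_mode == "signed":
            sa, sb = hitsets[a].signed(tier), hitsets[b].signed(tier)
            shared_genes = sorted(g for g, d in sa & sb)
        else:
            shared_genes = sorted(ga & gb)
        k = len(shared_genes)
        union = len(ga | gb)
        results.append(
            OverlapResult(
                a_label=a,
                b_label=b,
                shared=shared_genes,
                n_a=len(ga),
                n_b=len(gb),
                n_shared=k,
                universe=universe_size,
                jaccard=k / union if union else 0.0,
                p_value=hypergeom_upper_tail(k, universe_size, len(ga), len(gb)),
            )
        )
    return results


def gene_set_overlap(
    hitset: HitSet,
    gmt_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    tier: str = "hit",
) -> pd.DataFrame:
    """Hypergeometric enrichment of one hit set against GMT gene sets.

    Each GMT set is intersected with the detected-gene universe before
    testing; one exact upper-tail test per set, Benjamini-Hochberg adjusted
    across sets. Returns a DataFrame sorted by p-value.
    """
    if not gmt_sets:
        raise ValueError("empty GMT collection")
    uni = set(universe)
    hits = set(hitset.genes(tier)) & uni
    rows = []
    for name, members in gmt_sets.items():
        mem = set(members) & uni
        k = len(hits & mem)
        rows.append(
            {
                "set": name,
                "n_set": len(mem),
                "n_hits": len(hits),
                "n_shared": k,
                "universe": len(uni),
                "p_value": hypergeom_upper_tail(k, len(uni), len(mem), len(hits)),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values(["p_value", "set"], ignore_index=True)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: tab-delimited set name, description, member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: need >= 3 fields")
            name, _desc, *genes = parts
            sets[name] = [g for g in genes if g]
    if not sets:
        raise ValueError("empty GMT file")
    return sets
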