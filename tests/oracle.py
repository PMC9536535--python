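"""Brute-force reference implementation of the screen statistic.

Re-derives anchoring, merging, baseline, effects, robust scales, Z-scores,
class labels and hit calls with explicit Python loops and per-gene direct
formula evaluation — no matrix algebra — so the vectorized pipeline can be
checked against it value-for-value. Kept deliberately independent of
orfscreen internals: it touches only public data containers.
"""

from __future__ import annotations

import math

import numpy as np

MAD_SCALE = 1.4826


def oracle_screen(matrix, sheet, config):
    """Direct-formula evaluation of the full statistic on a log2 matrix.

    Returns a dict with per-gene ``baseline``, ``detected``, ``scale`` and
    per-(gene, condition) ``effect``, ``z``, ``label``, plus ``hits`` as
    {condition: {gene: (direction, tier)}}.
    """
    rows = sheet.table.to_dict("records")
    genes = list(matrix.values.index)
    vals = {g: dict(matrix.values.loc[g]) for g in genes}

    # control-anchored batch merging
    ctrl_samples = [r["sample"] for r in rows if r["is_control"]]
    batches = list(dict.fromkeys(r["batch"] for r in rows))
    anchored = {g: dict(vals[g]) for g in genes}
    for g in genes:
        global_mean = np.mean([vals[g][s] for s in ctrl_samples])
        for b in batches:
            batch_ctrl = [r["sample"] for r in rows if r["batch"] == b and r["is_control"]]
            shift = np.mean([vals[g][s] for s in batch_ctrl]) - global_mean
            for r in rows:
                if r["batch"] == b:
                    anchored[g][r["sample"]] = vals[g][r["sample"]] - shift

    # replicate merging: per-condition mean, controls pooled
    conditions = list(dict.fromkeys(r["condition"] for r in rows if not r["is_control"]))
    profiles = {}
    for c in conditions:
        samp = [r["sample"] for r in rows if r["condition"] == c]
        profiles[c] = {g: np.mean([anchored[g][s] for s in samp]) for g in genes}
    profiles["CONTROL"] = {
        g: np.mean([anchored[g][s] for s in ctrl_samples]) for g in genes
    }
    cols = conditions + ["CONTROL"]

    baseline = {g: np.median([profiles[c][g] for c in cols]) for g in genes}
    effect = {(g, c): profiles[c][g] - baseline[g] for g in genes for c in cols}
    detected = {g: baseline[g] >= config.detection_floor_log2 for g in genes}

    raw = {}
    for g in genes:
        x = [effect[(g, c)] for c in cols]
        if config.variance_estimator == "mad":
            med = np.median(x)
            raw[g] = np.median([abs(v - med) for v in x]) * MAD_SCALE
        else:
            raw[g] = np.std(np.array(x), ddof=1)
    floor = config.variance_floor
    if floor is None:
        floor = 0.25 * float(np.median([raw[g] for g in genes if detected[g]]))
    scale = {g: (max(raw[g], floor) if detected[g] else float("nan")) for g in genes}

    z, label = {}, {}
    for g in genes:
        for c in cols:
            zv = effect[(g, c)] / scale[g] if detected[g] else float("nan")
            z[(g, c)] = zv
            if not detected[g]:
                label[(g, c)] = "below_detection"
            elif abs(zv) > config.z_hit:
                label[(g, c)] = "outside"
            elif abs(zv) > config.z_suggestive:
                label[(g, c)] = "suggestive"
            else:
                label[(g, c)] = "within"

    thr = math.log2(config.fold_threshold)
    hits = {}
    for c in conditions:
        calls = {}
        for g in genes:
            if not detected[g] or abs(effect[(g, c)]) <= thr:
                continue
            if label[(g, c)] == "outside":
                tier = "hit"
            elif label[(g, c)] == "suggestive":
                tier = "suggestive"
            else:
                continue
            calls[g] = ("up" if effect[(g, c)] > 0 else "down", tier)
        hits[c] = calls

    return {
        "baseline": baseline,
        "detected": detected,
        "scale": scale,
        "effect": effect,
        "z": z,
        "label": label,
        "hits": hits,
    }


def random_screen(rng, max_genes=100, max_samples=12):
    """A random small log2 matrix plus a consistent sample sheet."""
    import pandas as pd

    from orfscreen import ExpressionMatrix, SampleSheet

    n_batches = int(rng.integers(1, 3))
    n_conds = int(rng.integers(2, 4))
    reps = int(rng.integers(1, 4))
    ctrl_per_batch = int(rng.integers(1, 3))
    n_samples = n_conds * reps + n_batches * ctrl_per_batch
    while n_samples > max_samples:
        reps = max(1, reps - 1)
        ctrl_per_batch = 1
        n_samples = n_conds * reps + n_batches * ctrl_per_batch
    n_genes = int(rng.integers(10, max_genes + 1))

    rows = []
    for i in range(n_conds):
        b = f"B{i % n_batches + 1}"
        for r in range(reps):
            rows.append(
                {"sample": f"C{i}_r{r}", "condition": f"C{i}", "replicate": str(r),
                 "batch": b, "is_control": False}
            )
    for b in range(n_batches):
        for r in range(ctrl_per_batch):
            rows.append(
                {"sample": f"CTRL_B{b + 1}_r{r}", "condition": "CONTROL",
                 "replicate": str(r), "batch": f"B{b + 1}", "is_control": True}
            )
    sheet = SampleSheet(pd.DataFrame(rows))
    values = pd.DataFrame(
        rng.uniform(0.0, 10.0, (n_genes, len(rows))),
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[r["sample"] for r in rows],
    )
    return ExpressionMatrix(values, scale="log2"), sheet
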