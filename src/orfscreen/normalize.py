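"""Expression-matrix IO, log2 normalization, batch anchoring and replicate merging.

An ORF-overexpression screen produces a genes x samples expression matrix in
which each ORF condition was transduced in several replicate infections,
organised in batches that each carry their own empty-vector control samples.
This module brings such a matrix onto a common log2 scale, anchors batches on
their shared empty-vector controls, and collapses replicates into one
condition-level log2 profile per ORF (plus one profile for the pooled
controls) — the input to hit calling in :mod:`orfscreen.screen`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL_LABEL",
    "ExpressionMatrix",
    "SampleSheet",
    "ConditionProfiles",
    "read_matrix",
    "write_matrix",
    "read_samples",
    "write_samples",
    "validate_screen",
    "normalize_log2",
    "anchor_batches",
    "merge_replicates",
]

#: Condition label reserved for empty-vector control samples.
CONTROL_LABEL = "CONTROL"

_SCALES = ("counts", "log2")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with a scale tag.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    scale
        ``"counts"`` for raw (non-negative) counts or intensities,
        ``"log2"`` for log2-normalized values.
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        idx, cols = self.values.index, self.values.columns
        dup_genes = idx[idx.duplicated()].unique().tolist()
        if dup_genes:
            raise ValueError(f"duplicate gene id(s): {dup_genes}")
        dup_samples = cols[cols.duplicated()].unique().tolist()
        if dup_samples:
            raise ValueError(f"duplicate sample id(s): {dup_samples}")
        vals = self.values.to_numpy(dtype=float)
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")
        if self.scale == "counts" and vals.size and (vals < 0).any():
            raise ValueError("counts-scale values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SampleSheet:
    """Per-sample annotations: condition, replicate, batch, control flag.

    ``table`` has one row per sample with columns
    ``sample, condition, replicate, batch, is_control``. Control samples
    carry the condition label :data:`CONTROL_LABEL`.
    """

    table: pd.DataFrame

    REQUIRED = ("sample", "condition", "replicate", "batch", "is_control")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing column(s): {missing}")
        t = self.table
        dups = t["sample"][t["sample"].duplicated()].unique().tolist()
        if dups:
            raise ValueError(f"duplicate sample id(s): {dups}")
        self.table = t.assign(is_control=t["is_control"].map(_parse_bool)).reset_index(
            drop=True
        )
        bad = self.table.loc[
            self.table["is_control"] & (self.table["condition"] != CONTROL_LABEL)
        ]
        if len(bad):
            raise ValueError(
                "control samples must carry condition label "
                f"{CONTROL_LABEL!r}: {bad['sample'].tolist()}"
            )
        if (self.table["condition"] == CONTROL_LABEL).any() and not self.table.loc[
            self.table["condition"] == CONTROL_LABEL, "is_control"
        ].all():
            raise ValueError(
                f"samples labelled {CONTROL_LABEL!r} must have is_control=true"
            )

    @property
    def samples(self) -> pd.Index:
        return pd.Index(self.table["sample"])

    @property
    def conditions(self) -> list[str]:
        """Non-control condition labels in sheet order."""
        cond = self.table.loc[~self.table["is_control"], "condition"]
        return list(dict.fromkeys(cond))

    def batches(self) -> list[str]:
        return list(dict.fromkeys(self.table["batch"].astype(str)))


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer, float)):
        return bool(int(x))
    s = str(x).strip().lower()
    if s in ("1", "true", "t", "yes", "y"):
        return True
    if s in ("0", "false", "f", "no", "n"):
        return False
    raise ValueError(f"cannot interpret is_control value {x!r} as boolean")


@dataclass
class ConditionProfiles:
    """Condition-level merged log2 profiles.

    ``values`` is genes x conditions (one column per ORF condition plus a
    :data:`CONTROL_LABEL` column); ``n_replicates`` records how many samples
    were merged into each column.
    """

    values: pd.DataFrame
    n_replicates: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    @property
    def conditions(self) -> pd.Index:
        return self.values.columns

    @property
    def genes(self) -> pd.Index:
        return self.values.index


# ---------------------------------------------------------------------------
# IO


def read_matrix(path, scale: str) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), scale=scale)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.6f")


def read_samples(path) -> SampleSheet:
    """Read a sample-sheet TSV (sample, condition, replicate, batch, is_control)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(df)


def write_samples(sheet: SampleSheet, path) -> None:
    out = sheet.table.copy()
    out["is_control"] = out["is_control"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def validate_screen(matrix: ExpressionMatrix, sheet: SampleSheet) -> None:
    """Check matrix/sheet consistency and the screen-design invariants.

    Raises ``ValueError`` if sample ids disagree, any batch lacks a control
    sample, or any condition's samples span more than one batch.
    """
    mat_samples = set(matrix.samples)
    sheet_samples = set(sheet.samples)
    if mat_samples != sheet_samples:
        only_mat = sorted(mat_samples - sheet_samples)
        only_sheet = sorted(sheet_samples - mat_samples)
        raise ValueError(
            "matrix/sample-sheet mismatch: "
            f"matrix-only={only_mat}, sheet-only={only_sheet}"
        )
    t = sheet.table
    no_ctrl = sorted(
        str(b)
        for b, grp in t.groupby("batch", sort=False)
        if not grp["is_control"].any()
    )
    if no_ctrl:
        raise ValueError(f"batch(es) without control samples: {no_ctrl}")
    multi = {
        c: sorted(map(str, grp["batch"].unique()))
        for c, grp in t.loc[~t["is_control"]].groupby("condition", sort=False)
        if grp["batch"].nunique() > 1
    }
    if multi:
        raise ValueError(f"condition(s) spanning multiple batches: {multi}")


# ---------------------------------------------------------------------------
# Normalization


def normalize_log2(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Bring a matrix onto the log2 scale.

    Counts-scale input is library-size normalized per column to counts per
    million, then transformed as ``log2(cpm + pseudocount)``. log2-scale
    input passes through unchanged. Scaling any raw column by a constant
    therefore leaves its normalized column unchanged.
    """
    if matrix.scale == "log2":
        return matrix
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    vals = matrix.values
    totals = vals.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"all-zero column(s): {zero}")
    cpm = vals / totals * 1e6
    return ExpressionMatrix(np.log2(cpm + pseudocount), scale="log2")


def anchor_batches(matrix: ExpressionMatrix, sheet: SampleSheet) -> ExpressionMatrix:
    """Align batches on the empty-vector controls, per gene.

    For every gene and batch, subtracts (batch control mean - global control
    mean) from all samples of the batch, so control means become equal across
    batches while within-batch differences are untouched. Idempotent.
    """
    if matrix.scale != "log2":
        raise ValueError("anchor_batches expects a log2-scale matrix")
    validate_screen(matrix, sheet)
    t = sheet.table
    ctrl_samples = t.loc[t["is_control"], "sample"]
    global_mean = matrix.values[ctrl_samples].mean(axis=1)
    out = matrix.values.copy()
    for _, grp in t.groupby("batch", sort=False):
        batch_ctrl = grp.loc[grp["is_control"], "sample"]
        shift = matrix.values[batch_ctrl].mean(axis=1) - global_mean
        out[grp["sample"]] = out[grp["sample"]].sub(shift, axis=0)
    return ExpressionMatrix(out, scale="log2")


def merge_replicates(matrix: ExpressionMatrix, sheet: SampleSheet) -> ConditionProfiles:
    """Collapse replicate samples into condition-level profiles.

    Each condition's profile is the unweighted per-gene arithmetic mean of
    its replicate columns on the log2 scale (the geometric mean of the
    fold-changes); all control samples, across batches, pool into one
    :data:`CONTROL_LABEL` profile.
    """
    if matrix.scale != "log2":
        raise ValueError("merge_replicates expects a log2-scale matrix")
    validate_screen(matrix, sheet)
    t = sheet.table
    cols: dict[str, pd.Series] = {}
    n_reps: dict[str, int] = {}
    for cond in sheet.conditions:
        samp = t.loc[t["condition"] == cond, "sample"]
        if not len(samp):
            raise ValueError(f"condition {cond!r} has zero samples")
        cols[cond] = matrix.values[samp].mean(axis=1)
        n_reps[cond] = len(samp)
    ctrl = t.loc[t["is_control"], "sample"]
    if not len(ctrl):
        raise ValueError("no control samples in sheet")
    cols[CONTROL_LABEL] = matrix.values[ctrl].mean(axis=1)
    n_reps[CONTROL_LABEL] = len(ctrl)
    values = pd.DataFrame(cols, index=matrix.genes)
    return ConditionProfiles(values, pd.Series(n_reps, name="n_replicates"))
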