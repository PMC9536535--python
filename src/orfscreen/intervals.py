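"""Genomic-interval utilities: BED IO, intersection, factors binding all promoters.

Answers the question "which factors have binding evidence at every promoter
in a query set?" given promoter windows and per-factor peak intervals, both
as BED (0-based, half-open; abutting intervals do not overlap). Strand is
ignored — promoter windows are expected to be pre-computed by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

__all__ = ["IntervalSet", "read_bed", "write_bed", "intersect", "factors_binding_all"]


@dataclass
class IntervalSet:
    """BED-style records: (chrom, start, end, name), 0-based half-open."""

    records: pd.DataFrame

    REQUIRED = ("chrom", "start", "end", "name")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"interval set missing column(s): {missing}")
        r = self.records
        if r[["start", "end"]].isna().any().any():
            raise ValueError("NaN coordinates")
        if (r["start"] >= r["end"]).any():
            bad = r.loc[r["start"] >= r["end"]].index.tolist()
            raise ValueError(f"start must be < end (rows {bad})")
        self.records = r.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


def read_bed(path) -> IntervalSet:
    """Read BED with >= 3 columns (chrom, start, end[, name]); extra columns dropped."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"malformed BED line {lineno}: non-integer coordinates"
                ) from exc
            name = parts[3] if len(parts) > 3 else f"interval_{lineno}"
            rows.append({"chrom": parts[0], "start": start, "end": end, "name": name})
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))


def write_bed(ivset: IntervalSet, path) -> None:
    ivset.records[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def intersect(a: IntervalSet, b: IntervalSet) -> pd.DataFrame:
    """All overlapping record pairs between two interval sets.

    A pair overlaps iff it shares a chromosome and ``max(starts) <
    min(ends)`` — half-open semantics, so abutting intervals never overlap.
    Returns one row per pair with the a_/b_ prefixed records plus the row
    indices ``a_index``/``b_index``, sorted by (a_index, b_index).
    """
    trees: dict[str, IntervalTree] = {}
    for j, rec in b.records.iterrows():
        trees.setdefault(rec["chrom"], IntervalTree()).addi(
            int(rec["start"]), int(rec["end"]), j
        )
    rows = []
    for i, rec in a.records.iterrows():
        tree = trees.get(rec["chrom"])
        if tree is None:
            continue
        for hit in tree.overlap(int(rec["start"]), int(rec["end"])):
            j = hit.data
            brec = b.records.loc[j]
            rows.append(
                {
                    "a_index": i,
                    "b_index": j,
                    "chrom": rec["chrom"],
                    "a_start": rec["start"],
                    "a_end": rec["end"],
                    "a_name": rec["name"],
                    "b_start": brec["start"],
                    "b_end": brec["end"],
                    "b_name": brec["name"],
                }
            )
    cols = ["a_index", "b_index", "chrom", "a_start", "a_end", "a_name",
            "b_start", "b_end", "b_name"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["a_index", "b_index"], ignore_index=True)


def factors_binding_all(promoters: IntervalSet, peaks: IntervalSet) -> list[str]:
    """Factors whose peaks overlap every promoter in the query set.

    Peaks are grouped by their ``name`` column (one factor per name); a
    factor qualifies iff, for each promoter, at least one of its peaks
    overlaps it. Returns factor names sorted alphabetically. Adding peaks
    can only add factors, never remove one.
    """
    if len(promoters) == 0:
        raise ValueError("empty promoter set")
    pairs = intersect(promoters, peaks)
    n_promoters = len(promoters)
    qualifying = []
    for factor, grp in pairs.groupby("b_name"):
        if grp["a_index"].nunique() == n_promoters:
            qualifying.append(str(factor))
    return sorted(qualifying)
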