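"""DEG threshold filtering and Venn-overlap bookkeeping.

This module consumes differential-expression result tables (one row per gene
with a log2 fold-change, a BH-adjusted p-value, and the raw read sum across
all replicates and conditions) and applies the standard bulk-RNA-seq
bookkeeping: a low-count prefilter (genes with a read sum below 10 are
removed before testing), the DEG rule |log2FC| >= 1 and padj <= 0.05 with
inclusive boundaries, and exact region counts for two- or three-way Venn
comparisons of the resulting up/down sets.  The differential test itself
(e.g. a DESeq2 fit) is upstream and out of scope — only its result table is
consumed here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "DEGSets",
    "read_de_table",
    "low_count_prefilter",
    "filter_degs",
    "venn_counts",
]

REQUIRED_COLUMNS = ("gene_id", "log2fc", "padj", "total_reads")


@dataclass(frozen=True)
class DEGSets:
    """Up/down-regulated gene-id sets for one comparison."""

    label: str
    up: frozenset
    down: frozenset
    n_untested: int = 0  # genes with missing padj (independent filtering upstream)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and down-regulated")

    @property
    def n_total(self) -> int:
        return len(self.up) + len(self.down)


def read_de_table(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a DE result table (CSV or TSV by extension), remapping column names.

    ``column_map`` maps the file's column names onto the canonical
    gene_id/log2fc/padj/total_reads.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"DE table {path} missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"DE table {path} has duplicate gene ids")
    return df


def low_count_prefilter(table: pd.DataFrame, min_total_reads: int = 10) -> pd.DataFrame:
    """Remove genes whose read sum across all replicates and conditions is
    below ``min_total_reads`` (strictly-less-than removal: a sum of exactly
    10 is kept)."""
    if "total_reads" not in table.columns:
        raise ValueError("table has no total_reads column")
    return table[table["total_reads"] >= min_total_reads].copy()


def filter_degs(
    table: pd.DataFrame,
    label: str,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> DEGSets:
    """Apply the DEG rule |log2fc| >= lfc_threshold and padj <= alpha.

    Both boundaries are inclusive.  Genes with missing padj are excluded from
    both sets and counted in ``n_untested``.
    """
    tested = table[table["padj"].notna()]
    sig = tested[tested["padj"] <= alpha]
    up = frozenset(sig.loc[sig["log2fc"] >= lfc_threshold, "gene_id"])
    down = frozenset(sig.loc[sig["log2fc"] <= -lfc_threshold, "gene_id"])
    return DEGSets(
        label=label, up=up, down=down, n_untested=int(table["padj"].isna().sum())
    )


def _regions(labels: Sequence[str]) -> list[tuple[str, ...]]:
    out = []
    for r in range(1, len(labels) + 1):
        out.extend(itertools.combinations(labels, r))
    return out


def venn_counts(sets: Sequence[DEGSets]) -> dict:
    """Exact Venn region cardinalities for 2 or 3 comparisons, up and down
    separately.

    Region keys join member labels with "&"; a region counts genes present in
    exactly those comparisons' sets and no others.  Region totals sum to
    |union| for up and down independently (inclusion–exclusion sanity holds
    by construction).
    """
    if len(sets) not in (2, 3):
        raise ValueError("venn_counts supports 2 or 3 comparisons")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicated comparison labels: {labels}")

    by_label_up = {s.label: set(s.up) for s in sets}
    by_label_down = {s.label: set(s.down) for s in sets}

    result: dict[str, dict[str, int]] = {}
    for members in _regions(labels):
        others = [l for l in labels if l not in members]
        counts = {}
        for direction, by_label in (("up", by_label_up), ("down", by_label_down)):
            region = set.intersection(*(by_label[m] for m in members))
            for o in others:
                region -= by_label[o]
            counts[direction] = len(region)
        counts["total"] = counts["up"] + counts["down"]
        result["&".join(members)] = counts
    return result
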