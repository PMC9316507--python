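"""Catalog summaries and tabular reporting."""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import pandas as pd

from .fixtures import parse_exon_list

__all__ = [
    "summarize_catalog",
    "summarize_mirna_table",
    "write_catalog",
    "read_catalog",
]


def summarize_catalog(catalog: pd.DataFrame) -> dict:
    """Summary of a circRNA catalog (pipeline output or the packaged table).

    Expects columns ``exons`` (printed exon list) and ``length_nt``.  Each
    circRNA contributes once per exon index to the per-exon occurrence
    counts.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    exon_counts: Counter[int] = Counter()
    for text in catalog["exons"]:
        for idx, _ in parse_exon_list(text):
            exon_counts[idx] += 1
    most_frequent = max(sorted(exon_counts), key=lambda i: exon_counts[i])
    return {
        "n_circrnas": int(len(catalog)),
        "exon_occurrences": dict(sorted(exon_counts.items())),
        "most_frequent_exon": int(most_frequent),
        "most_frequent_exon_count": int(exon_counts[most_frequent]),
        "min_length_nt": int(catalog["length_nt"].min()),
        "max_length_nt": int(catalog["length_nt"].max()),
    }


def summarize_mirna_table(table: pd.DataFrame) -> dict[str, int]:
    """Number of distinct circRNAs listing each miRNA among their top hits."""
    if len(table) == 0:
        return {}
    counts = table.groupby("mirna_id")["circ_id"].nunique()
    return {str(k): int(v) for k, v in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))}


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
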