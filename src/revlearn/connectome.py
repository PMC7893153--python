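"""Pairwise synaptic connectivity summaries from synapse tables.

Works on neuPrint-style CSV exports: one row per synaptic contact with
presynaptic/postsynaptic cell ids and types, a compartment ROI label, and
coordinates.  Typical use restricts to fully traced neurons, one hemisphere
(when a ``side`` column is present) and a dendritic-compartment ROI
whitelist, then counts synapses per (pre cell, post cell) pair and averages
over a fixed cell roster so zero-synapse candidate pairs count toward the
type-pair mean.

No network I/O happens here; a live connectome query is just another way to
produce the same CSV schema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import SchemaError

__all__ = [
    "REQUIRED_COLUMNS",
    "ConnectivitySummary",
    "load_synapse_table",
    "filter_synapses",
    "pair_counts",
    "connectivity_matrix",
    "plot_synapse_locations",
]

REQUIRED_COLUMNS = ("pre_id", "pre_type", "post_id", "post_type", "roi")


def load_synapse_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a synapse CSV; unknown columns are preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"synapse table missing column(s): {missing}")
    if table[["pre_id", "post_id"]].isna().any().any():
        raise SchemaError("synapse table has empty cell ids")
    return table


def filter_synapses(
    table: pd.DataFrame,
    require_traced: bool = False,
    rois: Sequence[str] | None = None,
    side: str | None = None,
) -> pd.DataFrame:
    """Row filters: tracing status, ROI whitelist, hemisphere.

    ``rois=None`` keeps everything (an empty set keeps nothing).  Asking for
    a filter whose column is absent is a no-op with a warning rather than an
    error, mirroring how partially annotated exports are handled in
    practice.
    """
    out = table
    if require_traced:
        if {"pre_traced", "post_traced"} <= set(out.columns):
            out = out[out["pre_traced"].astype(bool) & out["post_traced"].astype(bool)]
        else:
            warnings.warn(
                "tracing filter requested but no pre_traced/post_traced columns; skipping",
                stacklevel=2,
            )
    if rois is not None:
        out = out[out["roi"].isin(set(rois))]
    if side is not None:
        if "side" in out.columns:
            out = out[out["side"] == side]
        else:
            warnings.warn(
                "hemisphere filter requested but no side column; skipping",
                stacklevel=2,
            )
    return out.reset_index(drop=True)


@dataclass
class ConnectivitySummary:
    """Per-cell-pair synapse counts for one (pre_type, post_type) pair."""

    pre_type: str
    post_type: str
    counts: pd.Series  # MultiIndex (pre_id, post_id) -> synapse count
    n_pairs: int
    mean_count: float
    total: int
    zeros_included: bool

    def to_dict(self) -> dict:
        return {
            "pre_type": self.pre_type,
            "post_type": self.post_type,
            "n_pairs": self.n_pairs,
            "mean_count": self.mean_count,
            "total": self.total,
            "zeros_included": self.zeros_included,
            "counts": {
                f"{pre}->{post}": int(c) for (pre, post), c in self.counts.items()
            },
        }


def pair_counts(
    table: pd.DataFrame,
    pre_type: str,
    post_type: str,
    roster: Mapping[str, Sequence[str]] | None = None,
    include_zero_pairs: bool = False,
) -> ConnectivitySummary:
    """Synapse counts per (pre cell, post cell) pair for the requested types.

    With ``include_zero_pairs=True`` a ``roster`` mapping each type to its
    full cell-id list is required, and candidate pairs with no synapses enter
    the mean as zeros — this is the convention behind statements like "an
    average of N synapses onto each of the ten cells".  Without it, only
    observed pairs are averaged.
    """
    sub = table[(table["pre_type"] == pre_type) & (table["post_type"] == post_type)]
    counts = sub.groupby(["pre_id", "post_id"]).size().astype(int)
    counts.index.names = ["pre_id", "post_id"]

    if include_zero_pairs:
        if roster is None or pre_type not in roster or post_type not in roster:
            raise ValueError(
                "include_zero_pairs=True requires a roster for both types"
            )
        full = pd.MultiIndex.from_product(
            [list(roster[pre_type]), list(roster[post_type])],
            names=["pre_id", "post_id"],
        )
        counts = counts.reindex(full, fill_value=0)

    total = int(counts.sum())
    n_pairs = int(len(counts))
    mean_count = float(counts.mean()) if n_pairs else 0.0
    return ConnectivitySummary(
        pre_type=pre_type,
        post_type=post_type,
        counts=counts,
        n_pairs=n_pairs,
        mean_count=mean_count,
        total=total,
        zeros_included=include_zero_pairs,
    )


def connectivity_matrix(
    table: pd.DataFrame,
    pre_types: Sequence[str],
    post_types: Sequence[str],
) -> pd.DataFrame:
    """Total synapse counts between type lists, ordered as given.

    ``matrix.loc[pre, post]`` is the number of table rows from ``pre`` cells
    onto ``post`` cells; the grand sum therefore equals the number of rows
    matching any requested (pre, post) type combination.
    """
    sub = table[
        table["pre_type"].isin(set(pre_types))
        & table["post_type"].isin(set(post_types))
    ]
    pivot = sub.groupby(["pre_type", "post_type"]).size().unstack(fill_value=0)
    return pivot.reindex(index=list(pre_types), columns=list(post_types), fill_value=0).astype(
        int
    )


def plot_synapse_locations(
    table: pd.DataFrame,
    post_id: str,
    ax=None,
    coords: tuple[str, str] = ("x", "y"),
):
    """2-D scatter of synapse locations onto one postsynaptic cell."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    sub = table[table["post_id"] == post_id]
    for pre, grp in sub.groupby("pre_id"):
        ax.scatter(grp[coords[0]], grp[coords[1]], s=8, label=str(pre))
    ax.set_xlabel(coords[0])
    ax.set_ylabel(coords[1])
    ax.set_title(f"synapses onto {post_id}")
    if sub["pre_id"].nunique() <= 10:
        ax.legend(fontsize=6)
    return ax
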