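"""Differential-table operations: pseudo-count transform, FDR flagging, and
crossing of transcript differential results with a miRNA -> target map.

The crossing asks, of the transcripts that are known miRNA targets and were
measured: how many are significantly up-regulated, and how many of those are
targets of at least one significantly down-regulated miRNA — the pattern
expected when a repressive small RNA is lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

DE_COLUMNS = ["feature_id", "mean_a", "mean_b", "fdr"]


def pseudocount_transform(means) -> np.ndarray:
    """Add +1 to raw read-count means (scatterplot input on log axes).

    Order-preserving; negative inputs raise ``ValueError``.
    """
    arr = np.asarray(means, dtype=float)
    if np.any(arr < 0):
        raise ValueError("means must be non-negative")
    return arr + 1.0


def flag_differential(records: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Flag records with FDR strictly below ``alpha`` as differential.

    Adds ``flagged`` (bool) and ``direction`` in {up, down, none}; direction
    is derived from the sign of ``mean_b - mean_a`` and is ``none`` for
    unflagged records or equal means. Idempotent and order-independent.
    """
    missing = set(DE_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"differential table missing columns: {sorted(missing)}")
    df = records.copy()
    df["flagged"] = df["fdr"] < alpha
    delta = df["mean_b"] - df["mean_a"]
    df["direction"] = np.select(
        [df["flagged"] & (delta > 0), df["flagged"] & (delta < 0)],
        ["up", "down"],
        default="none",
    )
    return df


@dataclass
class CrossingSummary:
    n_targets_considered: int
    n_targets_up: int
    n_targets_up_of_down_mirnas: int
    frac_targets_up: float
    frac_targets_up_of_down_mirnas: float
    n_unmatched: int  # transcripts in the map but absent from the table


def cross_targets(
    transcript_records: pd.DataFrame,
    mirna_records: pd.DataFrame,
    target_map: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> CrossingSummary:
    """Cross transcript and miRNA differential tables with a target map.

    ``target_map`` needs columns mirna_id, transcript_id (pairs unique).
    Considered transcripts are those present in both the map and the
    transcript table; fractions are relative to that denominator. Transcripts
    mapped but unmeasured are excluded and counted in ``n_unmatched``.
    """
    if target_map.empty:
        logger.warning("empty target map: crossing summary is all zeros")
        return CrossingSummary(0, 0, 0, 0.0, 0.0, 0)
    pairs = target_map[["mirna_id", "transcript_id"]].drop_duplicates()

    tx = flag_differential(transcript_records, alpha=alpha)
    mi = flag_differential(mirna_records, alpha=alpha)

    mapped = set(pairs["transcript_id"])
    measured = set(tx["feature_id"])
    considered = mapped & measured
    n_unmatched = len(mapped - measured)

    up_tx = set(
        tx.loc[(tx["direction"] == "up") & tx["feature_id"].isin(considered),
               "feature_id"]
    )
    down_mirnas = set(mi.loc[mi["direction"] == "down", "feature_id"])
    tx_of_down = set(
        pairs.loc[pairs["mirna_id"].isin(down_mirnas), "transcript_id"]
    )
    up_of_down = up_tx & tx_of_down

    n = len(considered)
    return CrossingSummary(
        n_targets_considered=n,
        n_targets_up=len(up_tx),
        n_targets_up_of_down_mirnas=len(up_of_down),
        frac_targets_up=len(up_tx) / n if n else 0.0,
        frac_targets_up_of_down_mirnas=len(up_of_down) / n if n else 0.0,
        n_unmatched=n_unmatched,
    )


def scatter_table(records: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Scatter-ready table: feature, x = mean_a + 1, y = mean_b + 1, flag."""
    df = flag_differential(records, alpha=alpha)
    return pd.DataFrame(
        {
            "feature_id": df["feature_id"],
            "x": pseudocount_transform(df["mean_a"]),
            "y": pseudocount_transform(df["mean_b"]),
            "flagged": df["flagged"],
            "direction": df["direction"],
        }
    )
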