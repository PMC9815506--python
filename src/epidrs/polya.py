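"""Poly(A)-tail QC filtering, per-transcript summaries and length histograms."""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_tables import ValidationError

log = logging.getLogger(__name__)

DEFAULT_ACCEPTED_TAGS = frozenset({"PASS"})


def filter_polya_pass(
    records: pd.DataFrame,
    accepted_tags: Iterable[str] = DEFAULT_ACCEPTED_TAGS,
) -> pd.DataFrame:
    """Keep records whose qc_tag is in ``accepted_tags`` (default: PASS only)."""
    accepted = set(accepted_tags)
    keep = records["qc_tag"].isin(accepted)
    removed = records.loc[~keep, "qc_tag"].value_counts()
    for tag, n in removed.items():
        log.info("poly(A) QC filter: removed %d records with tag %s", n, tag)
    out = records[keep].reset_index(drop=True)
    out.attrs["n_removed_by_tag"] = {str(k): int(v) for k, v in removed.items()}
    return out


def polya_summaries(
    records: pd.DataFrame, condition_map: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(transcript, condition) poly(A) summaries plus per-condition grand means.

    Returns ``(summaries, grand)``: summaries has columns ``transcript_id,
    condition, n_reads, mean_length, median_length``; grand has one row per
    condition with the per-read grand mean/median and the mean over
    per-transcript means (both central-tendency conventions are emitted).
    """
    df = records.copy()
    unknown = set(df["sample_id"].unique()) - set(condition_map)
    if unknown:
        raise ValidationError(f"poly(A) sample ids without condition: "
                              f"{sorted(unknown)}")
    df["condition"] = df["sample_id"].map(condition_map)
    summaries = (
        df.groupby(["transcript_id", "condition"], sort=True)["polya_length"]
        .agg(n_reads="count", mean_length="mean", median_length="median")
        .reset_index()
    )
    per_read = df.groupby("condition", sort=True)["polya_length"].agg(
        n_reads="count", grand_mean="mean", grand_median="median"
    )
    per_transcript = summaries.groupby("condition", sort=True)["mean_length"].mean()
    grand = per_read.copy()
    grand["mean_of_transcript_means"] = per_transcript
    return summaries, grand.reset_index()


def polya_histogram(
    records: pd.DataFrame,
    bin_width: float = 10.0,
    length_range: tuple[float, float] = (0.0, 400.0),
    condition_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Binned poly(A) length counts (per condition when a map is given).

    Lengths beyond the range go into an overflow bin so the counts conserve
    the total record number.
    """
    if (records["polya_length"] < 0).any():
        raise ValidationError("negative poly(A) length in histogram input")
    lo, hi = length_range
    edges = np.arange(lo, hi + bin_width, bin_width)
    df = records.copy()
    if condition_map is not None:
        df["condition"] = df["sample_id"].map(condition_map)
    else:
        df["condition"] = "all"
    rows = []
    for cond, group in df.groupby("condition", sort=True):
        lengths = group["polya_length"].to_numpy()
        counts, _ = np.histogram(lengths, bins=edges)
        for left, right, n in zip(edges[:-1], edges[1:], counts):
            rows.append({"bin_left": left, "bin_right": right,
                         "count": int(n), "condition": cond})
        overflow = int((lengths >= edges[-1]).sum())
        rows.append({"bin_left": edges[-1], "bin_right": np.inf,
                     "count": overflow, "condition": cond})
    return pd.DataFrame(rows,
                        columns=["bin_left", "bin_right", "count", "condition"])
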