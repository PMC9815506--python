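"""Tally arithmetic and run-report helpers.

The tallies here are deliberately tiny, explicit functions: downstream
summaries (totals of up+down splits, per-transcript over/under counts,
filter bookkeeping) must be auditable arithmetic, not side effects buried in
the callers.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .io_tables import ValidationError


def tally_total(*subset_counts: int) -> int:
    """Total of disjoint subset counts (e.g. upregulated + downregulated)."""
    if any(c < 0 for c in subset_counts):
        raise ValidationError(f"negative subset count in {subset_counts}")
    return int(sum(subset_counts))


def diffmod_tally(results: pd.DataFrame) -> dict[str, int]:
    """Position- and transcript-level tallies of a diffmod scan.

    Returns counts of over/under positions, transcripts carrying each, the
    transcripts carrying both, and the union (note union = over + under -
    both; the two ways of counting "modified transcripts" are both surfaced).
    """
    over = results[results["status"] == "over"]
    under = results[results["status"] == "under"]
    t_over = set(over["transcript_id"])
    t_under = set(under["transcript_id"])
    return {
        "positions_tested": int(len(results)),
        "positions_over": int(len(over)),
        "positions_under": int(len(under)),
        "positions_significant": tally_total(len(over), len(under)),
        "transcripts_over": len(t_over),
        "transcripts_under": len(t_under),
        "transcripts_both": len(t_over & t_under),
        "transcripts_union": len(t_over | t_under),
    }


def check_filter_arithmetic(n_in: int, n_kept: int, n_removed: int) -> None:
    """Every filter must satisfy input = retained + removed."""
    if n_in != n_kept + n_removed:
        raise ValidationError(
            f"filter arithmetic broken: {n_in} != {n_kept} + {n_removed}"
        )


def overlap_to_frame(report) -> pd.DataFrame:
    rows = {
        "only_de": report.only_a,
        "only_mod": report.only_b,
        "only_prot": report.only_c,
        "de_and_mod": report.ab_only,
        "de_and_prot": report.ac_only,
        "mod_and_prot": report.bc_only,
        "all_three": report.abc,
        "at_least_two": report.total_at_least_two,
    }
    return pd.DataFrame({"subset": list(rows), "count": list(rows.values())})


def format_tally(tally: Mapping[str, int]) -> str:
    return "\n".join(f"{k}\t{v}" for k, v in tally.items())
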