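"""Per-position differential modification calling between two conditions.

Replicates are pooled into one 2x2 table per transcript position
(modified/unmodified x control/treatment), positions with fewer than
``min_cov`` pooled reads in either condition are discarded, and each
surviving table is tested with a two-sided Fisher exact test.  Effect size
is the log2 ratio of pseudocounted modified fractions.
"""

from __future__ import annotations

import logging
import math
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .io_tables import ModCallTable, ValidationError

log = logging.getLogger(__name__)

#: relative tolerance for counting a table's probability as tied with the
#: observed table in the two-sided sum
TIE_REL_TOL = 1e-7
_TIE_NUM = 10**7  # integer form: include k iff num_k * 1e7 <= num_obs * (1e7 + 1)

POOLED_COLUMNS = [
    "transcript_id", "position", "ref_base", "m_c", "N_c", "m_t", "N_t",
]


def pool_counts(table: ModCallTable) -> pd.DataFrame:
    """Sum coverage and modified counts over replicates within each condition.

    Returns one row per (transcript_id, position) with columns
    ``m_c, N_c, m_t, N_t``; positions absent in a sample contribute zero.
    The frame's ``attrs`` record the (control, treatment) labels.
    """
    df = table.df.copy()
    df["condition"] = df["sample_id"].map(table.condition_map)
    grouped = (
        df.groupby(["transcript_id", "position", "condition"], sort=True)
        .agg(N=("coverage", "sum"), m=("modified_count", "sum"))
        .reset_index()
    )
    wide = grouped.pivot(
        index=["transcript_id", "position"], columns="condition", values=["N", "m"]
    )
    ctrl, treat = table.conditions
    for top in ("N", "m"):
        for cond in (ctrl, treat):
            if (top, cond) not in wide.columns:
                wide[(top, cond)] = 0.0
    pooled = pd.DataFrame(
        {
            "N_c": wide[("N", ctrl)].fillna(0).astype(np.int64),
            "m_c": wide[("m", ctrl)].fillna(0).astype(np.int64),
            "N_t": wide[("N", treat)].fillna(0).astype(np.int64),
            "m_t": wide[("m", treat)].fillna(0).astype(np.int64),
        }
    ).reset_index()
    ref = (
        df.groupby(["transcript_id", "position"], sort=True)["ref_base"]
        .first()
        .reset_index()
    )
    pooled = pooled.merge(ref, on=["transcript_id", "position"])
    pooled = pooled[POOLED_COLUMNS]
    pooled.attrs["conditions"] = (ctrl, treat)
    return pooled


def coverage_filter(pooled: pd.DataFrame, min_cov: int = 50) -> pd.DataFrame:
    """Keep positions with at least ``min_cov`` pooled reads in BOTH conditions."""
    if min_cov < 1:
        raise ValidationError(f"min_cov must be >= 1, got {min_cov}")
    keep = (pooled["N_c"] >= min_cov) & (pooled["N_t"] >= min_cov)
    removed = int((~keep).sum())
    log.info("coverage filter (min %d per condition): kept %d, removed %d",
             min_cov, int(keep.sum()), removed)
    out = pooled[keep].reset_index(drop=True)
    out.attrs.update(pooled.attrs)
    out.attrs["n_removed_low_coverage"] = removed
    return out


@lru_cache(maxsize=1_000_000)
def fisher_exact_2x2(m_c: int, u_c: int, m_t: int, u_t: int) -> float:
    """Two-sided Fisher exact p for the table [[m_c, m_t], [u_c, u_t]].

    Conditions on all margins and sums hypergeometric probabilities that do
    not exceed the observed table's probability (ties within ``TIE_REL_TOL``
    relative are included).  Probabilities are accumulated as exact integer
    numerators over the common denominator, so the result is exact up to one
    final float division.
    """
    for v in (m_c, u_c, m_t, u_t):
        if v < 0:
            raise ValidationError(f"negative cell in 2x2 table: "
                                  f"({m_c}, {u_c}, {m_t}, {u_t})")
    M = m_c + u_c + m_t + u_t          # grand total
    if M == 0:
        raise ValidationError("all four cells zero: no margin is positive")
    K = m_c + m_t                      # modified-row total
    n = m_c + u_c                      # control-column total
    lo, hi = max(0, K + n - M), min(K, n)
    num_obs = math.comb(K, m_c) * math.comb(M - K, n - m_c)
    threshold = num_obs * (_TIE_NUM + 1)
    num_sum = 0
    denom = 0
    for k in range(lo, hi + 1):
        num_k = math.comb(K, k) * math.comb(M - K, n - k)
        denom += num_k
        if num_k * _TIE_NUM <= threshold:
            num_sum += num_k
    return min(num_sum / denom, 1.0)


def log2fc_mod(
    m_c: float, N_c: float, m_t: float, N_t: float, pseudocount: float = 0.5
) -> float:
    """log2 of the treatment/control ratio of pseudocounted modified fractions.

    f = (m + pseudocount) / (N + 2*pseudocount) per condition; antisymmetric
    under condition swap and zero when the fractions are equal.
    """
    if N_c == 0 and N_t == 0:
        raise ValidationError("log2fc undefined: zero depth in both conditions")
    f_c = (m_c + pseudocount) / (N_c + 2 * pseudocount)
    f_t = (m_t + pseudocount) / (N_t + 2 * pseudocount)
    return float(np.log2(f_t / f_c))


def _classify(p: np.ndarray, lfc: np.ndarray, alpha: float, lfc_min: float
              ) -> np.ndarray:
    status = np.full(len(p), "ns", dtype=object)
    status[(p < alpha) & (lfc > lfc_min)] = "over"
    status[(p < alpha) & (lfc < -lfc_min)] = "under"
    return status


def diffmod_scan(
    table: ModCallTable,
    min_cov: int = 50,
    alpha: float = 0.05,
    lfc_min: float = 0.5,
    adjust: str = "none",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Full caller: pool -> coverage filter -> Fisher test -> classify.

    Returns one row per retained position with pooled counts, pseudocounted
    fractions ``f_c``/``f_t``, ``log2fc``, raw ``p_value``, BH ``q_value``
    and ``status`` in {over, under, ns}.  With ``adjust="bh"`` the q-value is
    used for the significance gate instead of the raw p-value.
    """
    if adjust not in {"none", "bh"}:
        raise ValidationError(f"adjust must be 'none' or 'bh', got {adjust!r}")
    pooled = pool_counts(table)
    kept = coverage_filter(pooled, min_cov=min_cov)
    results = kept.copy()
    if len(results) == 0:
        for col in ("f_c", "f_t", "log2fc", "p_value", "q_value"):
            results[col] = pd.Series(dtype=float)
        results["status"] = pd.Series(dtype=object)
        return results

    m_c = results["m_c"].to_numpy()
    N_c = results["N_c"].to_numpy()
    m_t = results["m_t"].to_numpy()
    N_t = results["N_t"].to_numpy()
    results["f_c"] = (m_c + pseudocount) / (N_c + 2 * pseudocount)
    results["f_t"] = (m_t + pseudocount) / (N_t + 2 * pseudocount)
    results["log2fc"] = np.log2(results["f_t"] / results["f_c"])
    results["p_value"] = [
        fisher_exact_2x2(int(a), int(b - a), int(c), int(d - c))
        for a, b, c, d in zip(m_c, N_c, m_t, N_t)
    ]
    results["q_value"] = false_discovery_control(results["p_value"], method="bh")
    gate = results["q_value"] if adjust == "bh" else results["p_value"]
    results["status"] = _classify(
        gate.to_numpy(), results["log2fc"].to_numpy(), alpha, lfc_min
    )
    results.attrs.update(kept.attrs)
    results.attrs["thresholds"] = {
        "min_cov": min_cov, "alpha": alpha, "lfc_min": lfc_min,
        "adjust": adjust, "pseudocount": pseudocount,
    }
    n_over = int((results["status"] == "over").sum())
    n_under = int((results["status"] == "under").sum())
    log.info("diffmod scan: %d positions tested, %d over, %d under",
             len(results), n_over, n_under)
    return results


def base_composition(ref_bases) -> dict[str, float]:
    """Percentage of positions per ref_base (A, C, G, U; sums to 100)."""
    bases = list(ref_bases)
    if not bases:
        raise ValidationError("base_composition of an empty position set")
    counts = pd.Series(bases).value_counts()
    out = {b: 100.0 * counts.get(b, 0) / len(bases) for b in "ACGU"}
    return out


def base_composition_by_condition(
    pooled: pd.DataFrame, min_fraction: float = 0.0
) -> dict[str, dict[str, float]]:
    """Per-condition base composition of positions carrying modification.

    A position counts for a condition when its pooled modified fraction in
    that condition exceeds ``min_fraction``.
    """
    ctrl, treat = pooled.attrs.get("conditions", ("control", "treatment"))
    out = {}
    for label, m_col, n_col in ((ctrl, "m_c", "N_c"), (treat, "m_t", "N_t")):
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = pooled[m_col] / pooled[n_col]
        sel = pooled.loc[frac.fillna(0) > min_fraction, "ref_base"]
        out[label] = base_composition(sel)
    return out


def transcript_mod_ratio(pooled: pd.DataFrame, condition: str) -> pd.Series:
    """Per-transcript modification ratio sum(m)/sum(N) for one condition.

    ``condition`` may be an actual label (resolved via ``attrs['conditions']``)
    or the role name ``"control"``/``"treatment"``.  Transcripts with zero
    total coverage in the condition are omitted (logged).
    """
    ctrl, treat = pooled.attrs.get("conditions", ("control", "treatment"))
    if condition in (ctrl, "control"):
        m_col, n_col = "m_c", "N_c"
    elif condition in (treat, "treatment"):
        m_col, n_col = "m_t", "N_t"
    else:
        raise ValidationError(f"unknown condition {condition!r}")
    sums = pooled.groupby("transcript_id")[[m_col, n_col]].sum()
    zero = sums[sums[n_col] == 0]
    if len(zero):
        log.info("transcript_mod_ratio: omitting %d transcripts with zero "
                 "coverage in %s", len(zero), condition)
    sums = sums[sums[n_col] > 0]
    ratio = sums[m_col] / sums[n_col]
    ratio.name = f"mod_ratio_{condition}"
    return ratio


def write_diffmod(results: pd.DataFrame, path) -> None:
    """Write scan results as TSV with 1-based positions."""
    out = results.copy()
    out["position"] = out["position"] + 1
    cols = ["transcript_id", "position", "ref_base", "m_c", "N_c", "m_t", "N_t",
            "f_c", "f_t", "log2fc", "p_value", "q_value", "status"]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
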