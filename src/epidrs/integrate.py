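"""CPM normalization, expression filtering, the pairwise Pearson correlation
suite across omics layers, and the multi-omics significant-set overlap."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import AbundanceMatrix, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its two-sided p for one variable pair in one condition."""

    pair: tuple[str, str]
    condition: str
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class OverlapReport:
    """Counts of features significant in 1, 2 or all 3 approaches.

    Pairwise counts are exclusive (features in exactly those two sets);
    ``total_at_least_two`` = sum of the three exclusive pairs + the triple.
    """

    only_a: int
    only_b: int
    only_c: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int

    @property
    def total_at_least_two(self) -> int:
        return self.ab_only + self.ac_only + self.bc_only + self.abc

    @property
    def total(self) -> int:
        return (self.only_a + self.only_b + self.only_c
                + self.total_at_least_two)


def cpm(counts: AbundanceMatrix) -> AbundanceMatrix:
    """Counts-per-million: cell / column_total * 1e6."""
    if counts.kind == "cpm":
        raise ValidationError("matrix is already CPM-normalized")
    totals = counts.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"zero library size for sample(s) "
                              f"{list(zero.index)}")
    return AbundanceMatrix(counts.values / totals * 1e6, kind="cpm")


def expression_filter(
    cpm_matrix: AbundanceMatrix, min_cpm: float = 2.0, min_samples: int = 2
) -> AbundanceMatrix:
    """Keep rows with at least ``min_samples`` cells >= ``min_cpm`` (inclusive)."""
    if cpm_matrix.kind != "cpm":
        raise ValidationError(f"expression_filter needs a CPM matrix, "
                              f"got kind={cpm_matrix.kind!r}")
    keep = (cpm_matrix.values >= min_cpm).sum(axis=1) >= min_samples
    removed = int((~keep).sum())
    log.info("expression filter (>=%g cpm in >=%d samples): kept %d, removed %d",
             min_cpm, min_samples, int(keep.sum()), removed)
    out = AbundanceMatrix(cpm_matrix.values[keep], kind="cpm")
    out.values.attrs["n_removed_low_expression"] = removed
    return out


def pearson_with_p(
    x, y, pair: tuple[str, str] = ("x", "y"), condition: str = "all"
) -> CorrelationResult:
    """Product-moment r with two-sided p from the t transform (n-2 df).

    NaN cells are removed pairwise-complete (n adjusted, logged); constant
    vectors and n < 3 are errors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = ~(np.isnan(x) | np.isnan(y))
    if (~ok).any():
        log.info("pearson_with_p %s/%s: dropped %d incomplete pairs",
                 *pair, int((~ok).sum()))
        x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValidationError(f"need n >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant vector: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(pair=pair, condition=condition, r=r,
                             p_value=min(p, 1.0) if p > 0 else p, n=n)


def log_abundance_by_condition(
    cpm_matrix: AbundanceMatrix, condition_map: Mapping[str, str]
) -> dict[str, pd.Series]:
    """Per-condition transcript amount: log2(CPM + 1) averaged over replicates."""
    if cpm_matrix.kind != "cpm":
        raise ValidationError("log_abundance_by_condition needs a CPM matrix")
    out: dict[str, pd.Series] = {}
    logged = np.log2(cpm_matrix.values + 1.0)
    for cond in sorted(set(condition_map.values())):
        samples = [s for s in cpm_matrix.samples if condition_map.get(s) == cond]
        if not samples:
            continue
        series = logged[samples].mean(axis=1)
        series.name = f"log_abundance_{cond}"
        out[cond] = series
    return out


#: the six variable pairs computed per condition
SUITE_PAIRS: tuple[tuple[str, str], ...] = (
    ("mod_ratio", "log_abundance"),
    ("m6a_ratio", "log_abundance"),
    ("polya_mean", "m6a_ratio"),
    ("polya_mean", "log_abundance"),
    ("m6a_ratio", "log_protein"),
    ("polya_mean", "log_protein"),
)


def correlation_suite(
    mod_ratios: Mapping[str, pd.Series],
    m6a_ratios: Mapping[str, pd.Series],
    log_abundance: Mapping[str, pd.Series],
    polya_means: Mapping[str, pd.Series],
    log_protein: Mapping[str, pd.Series] | None = None,
    id_map: pd.DataFrame | None = None,
) -> list[CorrelationResult]:
    """The per-condition pairwise Pearson suite across omics layers.

    Every argument maps a condition label to a transcript-indexed Series
    (``log_protein`` is protein-indexed and translated through ``id_map``).
    Pairs with fewer than 3 common features are skipped with a warning.
    """
    layers: dict[str, Mapping[str, pd.Series]] = {
        "mod_ratio": mod_ratios,
        "m6a_ratio": m6a_ratios,
        "log_abundance": log_abundance,
        "polya_mean": polya_means,
    }
    if log_protein is not None:
        if id_map is None:
            raise ValidationError("protein layer requires an id_map")
        translate = dict(zip(id_map["protein_id"], id_map["transcript_id"]))
        layers["log_protein"] = {
            cond: series.rename(index=translate)
            for cond, series in log_protein.items()
        }
    conditions = sorted(set(mod_ratios) | set(m6a_ratios))
    results: list[CorrelationResult] = []
    for cond in conditions:
        for name_x, name_y in SUITE_PAIRS:
            lx = layers.get(name_x, {}).get(cond)
            ly = layers.get(name_y, {}).get(cond)
            if lx is None or ly is None:
                continue
            common = lx.index.intersection(ly.index)
            if len(common) < 3:
                log.warning("correlation %s~%s (%s): only %d common features, "
                            "skipped", name_x, name_y, cond, len(common))
                continue
            results.append(
                pearson_with_p(lx.loc[common], ly.loc[common],
                               pair=(name_x, name_y), condition=cond)
            )
    return results


def correlations_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable_x": [r.pair[0] for r in results],
            "variable_y": [r.pair[1] for r in results],
            "condition": [r.condition for r in results],
            "r": [r.r for r in results],
            "p_value": [r.p_value for r in results],
            "n": [r.n for r in results],
        }
    )


def multiomics_overlap(set_de, set_mod, set_prot) -> OverlapReport:
    """Exclusive overlap counts among three significant-feature id sets."""
    a, b, c = set(set_de), set(set_mod), set(set_prot)
    abc = a & b & c
    return OverlapReport(
        only_a=len(a - b - c),
        only_b=len(b - a - c),
        only_c=len(c - a - b),
        ab_only=len((a & b) - c),
        ac_only=len((a & c) - b),
        bc_only=len((b & c) - a),
        abc=len(abc),
    )


def read_significance_table(path) -> set[str]:
    """Ids flagged significant in a TSV ``feature_id, p_or_fdr, logFC,
    significant`` (the significant column is authoritative)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"feature_id": str})
    required = {"feature_id", "significant"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return set(df.loc[df["significant"].astype(int) == 1, "feature_id"])
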