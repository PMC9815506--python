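"""RRACH m6A site scanning, kmer frequencies and metagene density profiles.

RRACH: R R A C H with R in {A, G} and H in {A, U, C}; the central A (offset
+2 inside the 5-mer) is the methylatable position.  There are 12 concrete
RRACH 5-mers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffmod import diffmod_scan
from .io_tables import ModCallTable, TranscriptAnnotation, ValidationError

log = logging.getLogger(__name__)

RRACH_KMERS: tuple[str, ...] = tuple(
    sorted(a + b + "A" + "C" + h for a, b, h in product("AG", "AG", "AUC"))
)

_R = frozenset(b"AG")
_H = frozenset(b"AUC")
REGIONS = ("5UTR", "CDS", "3UTR")


@dataclass(frozen=True)
class M6ASite:
    """One candidate m6A position: the central A of an RRACH 5-mer."""

    transcript_id: str
    position: int            # 0-based offset of the A
    kmer: str
    region: str = "unassigned"

    def __post_init__(self) -> None:
        k = self.kmer
        if not (len(k) == 5 and k[0] in "AG" and k[1] in "AG" and k[2] == "A"
                and k[3] == "C" and k[4] in "AUC"):
            raise ValidationError(f"{k!r} is not an RRACH 5-mer")


@dataclass
class MetageneProfile:
    """Area-normalized site-density histogram on a relative axis.

    ``axis`` is ``"full"`` (coordinate in [0, 1]) or ``"regions"``
    (coordinate in [0, 3]: 5'UTR, CDS and 3'UTR each scaled to unit length).
    ``densities`` maps a condition tag to a per-bin density array.
    """

    edges: np.ndarray
    densities: dict[str, np.ndarray]
    axis: str
    n_sites: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond, dens in self.densities.items():
            for left, right, d in zip(self.edges[:-1], self.edges[1:], dens):
                rows.append({"bin_left": left, "bin_right": right,
                             "density": d, "condition": cond})
        return pd.DataFrame(rows)


def find_rrach_sites(sequence: str, transcript_id: str) -> list[M6ASite]:
    """All central-A positions of RRACH 5-mers in an RNA sequence.

    Overlapping occurrences are all reported; positions within 2 nt of either
    sequence end cannot host a full 5-mer and are never reported.
    """
    raw = sequence.encode("ascii")
    arr = np.frombuffer(raw, dtype=np.uint8)
    valid = np.isin(arr, np.frombuffer(b"ACGU", dtype=np.uint8))
    if not valid.all():
        offset = int(np.argmin(valid))
        raise ValidationError(
            f"{transcript_id}: non-RNA character {sequence[offset]!r} "
            f"at offset {offset}"
        )
    if len(arr) < 5:
        return []
    is_r = np.isin(arr, np.frombuffer(b"AG", dtype=np.uint8))
    is_h = np.isin(arr, np.frombuffer(b"AUC", dtype=np.uint8))
    hit = (
        is_r[:-4]
        & is_r[1:-3]
        & (arr[2:-2] == ord("A"))
        & (arr[3:-1] == ord("C"))
        & is_h[4:]
    )
    return [
        M6ASite(transcript_id, int(start + 2), sequence[start : start + 5])
        for start in np.flatnonzero(hit)
    ]


def assign_regions(
    sites: Sequence[M6ASite],
    annotations: Mapping[str, TranscriptAnnotation],
) -> list[M6ASite]:
    """Return sites re-labelled with their 5UTR/CDS/3UTR region."""
    out = []
    for site in sites:
        ann = annotations.get(site.transcript_id)
        region = ann.region_of(site.position) if ann else "unassigned"
        out.append(M6ASite(site.transcript_id, site.position, site.kmer, region))
    return out


def kmer_frequencies(sites: Sequence[M6ASite]) -> pd.Series:
    """Relative frequency of each of the 12 RRACH 5-mers among sites.

    Zero-count kmers are present with frequency 0.  An empty input yields an
    all-zero table flagged via ``result.attrs["degenerate"]``.
    """
    counts = pd.Series(0, index=list(RRACH_KMERS), dtype=float)
    if not sites:
        log.warning("kmer_frequencies: empty site set")
        counts.attrs["degenerate"] = True
        return counts
    for site in sites:
        if site.kmer not in counts.index:
            raise ValidationError(f"corrupt site with non-RRACH kmer {site.kmer!r}")
        counts[site.kmer] += 1
    freq = counts / counts.sum()
    freq.attrs["degenerate"] = False
    return freq


def _as_condition_dict(
    sites: Sequence[M6ASite] | Mapping[str, Sequence[M6ASite]],
) -> dict[str, Sequence[M6ASite]]:
    if isinstance(sites, Mapping):
        return dict(sites)
    return {"all": sites}


def metagene_full(
    sites: Sequence[M6ASite] | Mapping[str, Sequence[M6ASite]],
    annotations: Mapping[str, TranscriptAnnotation],
    n_bins: int = 30,
) -> MetageneProfile:
    """Site density over the relative transcript coordinate pos/(length-1).

    The coordinate lies in [0, 1]; the last bin is right-closed.  Densities
    are normalized to unit area per condition.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    densities: dict[str, np.ndarray] = {}
    n_sites: dict[str, int] = {}
    for cond, cond_sites in _as_condition_dict(sites).items():
        coords = []
        for site in cond_sites:
            ann = annotations[site.transcript_id]
            if ann.length < 2:
                log.warning("metagene_full: skipping site on length-%d "
                            "transcript %s", ann.length, site.transcript_id)
                continue
            coords.append(site.position / (ann.length - 1))
        counts, _ = np.histogram(coords, bins=edges)
        total = counts.sum()
        width = 1.0 / n_bins
        densities[cond] = (
            counts / (total * width) if total else np.zeros(n_bins)
        )
        n_sites[cond] = int(total)
    return MetageneProfile(edges, densities, axis="full", n_sites=n_sites)


def _region_coordinate(site: M6ASite, ann: TranscriptAnnotation) -> float:
    region = ann.region_of(site.position)
    start, end = ann.region_span(region)
    r = REGIONS.index(region)
    return r + (site.position - start) / (end - start)


def metagene_regions(
    sites: Sequence[M6ASite] | Mapping[str, Sequence[M6ASite]],
    annotations: Mapping[str, TranscriptAnnotation],
    bins_per_region: int = 20,
) -> MetageneProfile:
    """Site density on the three-region axis [0,3] (5'UTR | CDS | 3'UTR).

    Each region of each transcript is scaled to unit length; a site exactly
    at cds_start maps to coordinate 1.0 (first CDS bin), at cds_end to 2.0.
    Unit area per condition over the whole [0, 3] axis.
    """
    n_bins = 3 * bins_per_region
    edges = np.linspace(0.0, 3.0, n_bins + 1)
    densities: dict[str, np.ndarray] = {}
    n_sites: dict[str, int] = {}
    for cond, cond_sites in _as_condition_dict(sites).items():
        coords = [
            _region_coordinate(s, annotations[s.transcript_id]) for s in cond_sites
        ]
        counts, _ = np.histogram(coords, bins=edges)
        total = counts.sum()
        width = 3.0 / n_bins
        densities[cond] = (
            counts / (total * width) if total else np.zeros(n_bins)
        )
        n_sites[cond] = int(total)
    return MetageneProfile(edges, densities, axis="regions", n_sites=n_sites)


def assign_site_conditions(
    sites: Sequence[M6ASite],
    pooled: pd.DataFrame,
    min_fraction: float = 0.1,
) -> dict[str, list[M6ASite]]:
    """Split sites into per-condition "methylated" sets.

    A site belongs to a condition's set when the pooled modified fraction at
    its position in that condition is at least ``min_fraction``.  Sites with
    no counts are dropped.
    """
    ctrl, treat = pooled.attrs.get("conditions", ("control", "treatment"))
    idx = pooled.set_index(["transcript_id", "position"])
    out: dict[str, list[M6ASite]] = {ctrl: [], treat: []}
    for site in sites:
        key = (site.transcript_id, site.position)
        if key not in idx.index:
            continue
        row = idx.loc[key]
        for cond, m_col, n_col in ((ctrl, "m_c", "N_c"), (treat, "m_t", "N_t")):
            if row[n_col] > 0 and row[m_col] / row[n_col] >= min_fraction:
                out[cond].append(site)
    return out


def m6a_diff(
    table: ModCallTable,
    sites: Sequence[M6ASite],
    min_cov: int = 50,
    alpha: float = 0.05,
    lfc_min: float = 0.5,
    adjust: str = "none",
) -> tuple[pd.DataFrame, int, int]:
    """Differential m6A deposition at RRACH A positions.

    Restricts the modcall table to the given sites and runs the per-position
    caller.  Returns ``(results, n_p_significant, n_p_and_lfc_significant)``:
    the first count applies the p-value gate alone, the second additionally
    requires |log2fc| > ``lfc_min`` (the two-tier summary).
    """
    keys = {(s.transcript_id, s.position) for s in sites}
    sub = table.subset_positions(keys)
    sub = ModCallTable(
        sub.df[sub.df["ref_base"] == "A"],
        table.condition_map,
        condition_order=table.conditions,
    )
    results = diffmod_scan(sub, min_cov=min_cov, alpha=alpha,
                           lfc_min=lfc_min, adjust=adjust)
    if len(results) == 0:
        return results, 0, 0
    gate = results["q_value"] if adjust == "bh" else results["p_value"]
    n_p = int((gate < alpha).sum())
    n_both = int(((gate < alpha) & (results["log2fc"].abs() > lfc_min)).sum())
    log.info("m6a_diff: %d sites p<%g, of which %d also |log2fc|>%g",
             n_p, alpha, n_both, lfc_min)
    return results, n_p, n_both


def sites_to_frame(sites: Sequence[M6ASite]) -> pd.DataFrame:
    """Site list as a TSV-ready frame (1-based positions)."""
    return pd.DataFrame(
        {
            "transcript_id": [s.transcript_id for s in sites],
            "position": [s.position + 1 for s in sites],
            "kmer": [s.kmer for s in sites],
            "region": [s.region for s in sites],
        }
    )
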