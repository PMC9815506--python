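"""Table and sequence I/O plus run-level read summary statistics.

Internal convention: transcript positions are 0-based, half-open intervals.
Every file on disk uses 1-based inclusive positions; the conversion happens
here and only here.  The ref_base alphabet is RNA (``T`` on input is mapped
to ``U`` and logged once per file).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

RNA_BASES = frozenset("ACGU")

MODCALL_COLUMNS = [
    "transcript_id",
    "position",
    "ref_base",
    "sample_id",
    "coverage",
    "modified_count",
]


class ValidationError(ValueError):
    """An input table violates one of its invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Transcript length and CDS interval (0-based, half-open).

    The three regions are 5'UTR = [0, cds_start), CDS = [cds_start, cds_end)
    and 3'UTR = [cds_end, length).
    """

    transcript_id: str
    length: int
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= self.length):
            raise ValidationError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"inconsistent with length {self.length}"
            )

    def region_of(self, position: int) -> str:
        """Region label for a 0-based position (start-inclusive, end-exclusive)."""
        if not 0 <= position < self.length:
            raise ValidationError(
                f"{self.transcript_id}: position {position} outside [0, {self.length})"
            )
        if position < self.cds_start:
            return "5UTR"
        if position < self.cds_end:
            return "CDS"
        return "3UTR"

    def region_span(self, region: str) -> tuple[int, int]:
        spans = {
            "5UTR": (0, self.cds_start),
            "CDS": (self.cds_start, self.cds_end),
            "3UTR": (self.cds_end, self.length),
        }
        return spans[region]


@dataclass(frozen=True)
class PolyARecord:
    """One read's poly(A) length estimate with its QC tag."""

    read_id: str
    transcript_id: str
    polya_length: float
    qc_tag: str
    sample_id: str

    def __post_init__(self) -> None:
        if self.polya_length < 0:
            raise ValidationError(f"{self.read_id}: negative poly(A) length")
        if not self.qc_tag:
            raise ValidationError(f"{self.read_id}: empty qc_tag")


@dataclass
class AbundanceMatrix:
    """Feature x sample matrix of non-negative values.

    ``kind`` records what the cells are: ``counts``, ``cpm`` or ``protein``.
    """

    values: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if (self.values.to_numpy() < 0).any():
            r, c = np.argwhere(self.values.to_numpy() < 0)[0]
            raise ValidationError(
                f"negative cell at ({self.values.index[r]}, {self.values.columns[c]})"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


class ModCallTable:
    """Per (transcript, position, sample) coverage and modified-read counts.

    The central object of the pipeline.  Wraps a DataFrame with columns
    ``transcript_id, position, ref_base, sample_id, coverage, modified_count``
    (position 0-based) and a sample -> condition mapping with exactly two
    condition labels.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        condition_map: Mapping[str, str],
        condition_order: Sequence[str] | None = None,
        annotations: Mapping[str, TranscriptAnnotation] | None = None,
    ) -> None:
        missing = [c for c in MODCALL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"modcall table missing columns {missing}")
        df = df.loc[:, MODCALL_COLUMNS].reset_index(drop=True)
        df["position"] = df["position"].astype(np.int64)
        df["coverage"] = df["coverage"].astype(np.int64)
        df["modified_count"] = df["modified_count"].astype(np.int64)

        bad = df[(df["coverage"] < 0) | (df["modified_count"] < 0)]
        if len(bad):
            raise ValidationError(f"negative count in row {bad.index[0]}: "
                                  f"{bad.iloc[0].to_dict()}")
        bad = df[df["modified_count"] > df["coverage"]]
        if len(bad):
            raise ValidationError(
                f"modified_count > coverage in row {bad.index[0]}: "
                f"{bad.iloc[0].to_dict()}"
            )
        bad = df[df["position"] < 0]
        if len(bad):
            raise ValidationError(f"negative position in row {bad.index[0]}")
        if not df["ref_base"].isin(RNA_BASES).all():
            offender = df.loc[~df["ref_base"].isin(RNA_BASES), "ref_base"].iloc[0]
            raise ValidationError(f"ref_base {offender!r} not in {sorted(RNA_BASES)}")
        keys = df[["transcript_id", "position", "sample_id"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].to_dict()
            raise ValidationError(f"duplicate (transcript, position, sample): {dup}")

        samples = set(df["sample_id"].unique())
        unknown = samples - set(condition_map)
        if unknown:
            raise ValidationError(f"sample ids without a condition: {sorted(unknown)}")
        labels = sorted(set(condition_map.values()))
        if len(labels) != 2:
            raise ValidationError(
                f"exactly two condition labels required, got {labels}"
            )
        if condition_order is None:
            condition_order = labels
            log.info("condition order not given; using %s as (control, treatment)",
                     labels)
        if sorted(condition_order) != labels:
            raise ValidationError(
                f"condition_order {condition_order} does not match labels {labels}"
            )

        if annotations:
            lengths = df["transcript_id"].map(
                {t: a.length for t, a in annotations.items()}
            )
            bad = df[(~lengths.isna()) & (df["position"] >= lengths)]
            if len(bad):
                raise ValidationError(
                    f"position beyond transcript length in row {bad.index[0]}: "
                    f"{bad.iloc[0].to_dict()}"
                )

        self._df = df
        self.condition_map = dict(condition_map)
        self.conditions: tuple[str, str] = (condition_order[0], condition_order[1])

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def control(self) -> str:
        return self.conditions[0]

    @property
    def treatment(self) -> str:
        return self.conditions[1]

    def samples_of(self, condition: str) -> list[str]:
        return sorted(s for s, c in self.condition_map.items() if c == condition)

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModCallTable):
            return NotImplemented
        a = self._df.sort_values(MODCALL_COLUMNS[:4]).reset_index(drop=True)
        b = other._df.sort_values(MODCALL_COLUMNS[:4]).reset_index(drop=True)
        return a.equals(b) and self.condition_map == other.condition_map

    def subset_positions(self, keys: Iterable[tuple[str, int]]) -> "ModCallTable":
        """Restrict to the given (transcript_id, 0-based position) keys."""
        wanted = set(keys)
        mask = [
            (t, p) in wanted
            for t, p in zip(self._df["transcript_id"], self._df["position"])
        ]
        return ModCallTable(
            self._df[mask], self.condition_map, condition_order=self.conditions
        )


# ---------------------------------------------------------------------------
# modcall TSV
# ---------------------------------------------------------------------------


def read_modcalls(
    path: str | Path,
    condition_map: Mapping[str, str],
    condition_order: Sequence[str] | None = None,
    annotations: Mapping[str, TranscriptAnnotation] | None = None,
) -> ModCallTable:
    """Read the canonical modcall TSV (1-based positions on disk).

    Columns: ``transcript_id, position, ref_base, sample_id, coverage,
    modified_count``; ``#``-prefixed comment lines are allowed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"transcript_id": str})
    if "position" not in df.columns:
        raise ValidationError(f"{path}: not a modcall table (no 'position' column)")
    df["position"] = df["position"].astype(np.int64) - 1  # to 0-based
    df = _normalize_ref_base(df, str(path))
    return ModCallTable(df, condition_map, condition_order, annotations)


def write_modcalls(table: ModCallTable, path: str | Path) -> None:
    """Write the canonical modcall TSV (positions converted to 1-based)."""
    out = table.df.copy()
    out["position"] = out["position"] + 1
    out.to_csv(path, sep="\t", index=False)


def _normalize_ref_base(df: pd.DataFrame, source: str) -> pd.DataFrame:
    if (df["ref_base"] == "T").any():
        log.info("%s: mapping ref_base T -> U (RNA alphabet)", source)
        df = df.copy()
        df["ref_base"] = df["ref_base"].replace({"T": "U"})
    return df


# ---------------------------------------------------------------------------
# Tombo-style track import
# ---------------------------------------------------------------------------


def import_tombo_tracks(
    coverage_track: str | Path | pd.DataFrame,
    fraction_track: str | Path | pd.DataFrame,
    sample_id: str,
) -> pd.DataFrame:
    """Merge per-position coverage and fraction-modified tracks for one sample.

    Tracks are TSVs ``transcript_id, position, value`` (1-based on disk).
    ``modified_count = round(fraction * coverage)`` with ties rounded away
    from zero.  Returns a modcall-table fragment (no ref_base column).
    """
    cov = _read_track(coverage_track, "coverage")
    frac = _read_track(fraction_track, "fraction")
    if ((frac["value"] < 0) | (frac["value"] > 1)).any():
        bad = frac[(frac["value"] < 0) | (frac["value"] > 1)].iloc[0]
        raise ValidationError(
            f"fraction {bad['value']} outside [0, 1] at "
            f"({bad['transcript_id']}, {bad['position'] + 1})"
        )
    merged = cov.merge(
        frac,
        on=["transcript_id", "position"],
        how="outer",
        suffixes=("_cov", "_frac"),
        indicator=True,
    )
    orphans = merged[merged["_merge"] != "both"]
    if len(orphans):
        keys = [
            (t, p + 1)
            for t, p in zip(orphans["transcript_id"], orphans["position"])
        ]
        raise ValidationError(
            f"keys present in only one track: {keys[:10]}"
            + (" ..." if len(keys) > 10 else "")
        )
    coverage = merged["value_cov"].to_numpy(dtype=np.int64)
    fraction = merged["value_frac"].to_numpy(dtype=float)
    # nearest integer, ties away from zero (values are non-negative here)
    modified = np.floor(fraction * coverage + 0.5).astype(np.int64)
    modified = np.minimum(modified, coverage)
    log.info("tombo import %s: rounding fraction*coverage to nearest, "
             "ties away from zero", sample_id)
    return pd.DataFrame(
        {
            "transcript_id": merged["transcript_id"],
            "position": merged["position"],
            "sample_id": sample_id,
            "coverage": coverage,
            "modified_count": modified,
        }
    )


def _read_track(track: str | Path | pd.DataFrame, name: str) -> pd.DataFrame:
    if isinstance(track, pd.DataFrame):
        df = track.copy()
    else:
        df = pd.read_csv(track, sep="\t", comment="#", dtype={"transcript_id": str})
    expected = {"transcript_id", "position", "value"}
    if not expected.issubset(df.columns):
        raise ValidationError(f"{name} track must have columns {sorted(expected)}")
    df["position"] = df["position"].astype(np.int64) - 1
    return df


# ---------------------------------------------------------------------------
# annotations, sequences
# ---------------------------------------------------------------------------


def read_annotations(
    path: str | Path,
    lengths: Mapping[str, int] | None = None,
) -> dict[str, TranscriptAnnotation]:
    """Read transcript annotations from a TSV or a GFF3 file.

    TSV columns: ``transcript_id, length, cds_start, cds_end`` with 1-based
    inclusive CDS coordinates.  GFF3: one ``CDS`` feature per transcript with
    seqid = transcript_id; transcript lengths come from ``##sequence-region``
    directives or the ``lengths`` argument.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("##gff-version") or path.suffix.lower() in {".gff", ".gff3"}:
        return _read_annotations_gff3(path, lengths)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"transcript_id": str})
    annotations: dict[str, TranscriptAnnotation] = {}
    for row in df.itertuples(index=False):
        if row.transcript_id in annotations:
            raise ValidationError(f"duplicate transcript_id {row.transcript_id}")
        annotations[row.transcript_id] = TranscriptAnnotation(
            row.transcript_id,
            int(row.length),
            int(row.cds_start) - 1,      # 1-based inclusive -> 0-based
            int(row.cds_end),            # inclusive -> exclusive
        )
    return annotations


def _read_annotations_gff3(
    path: Path, lengths: Mapping[str, int] | None
) -> dict[str, TranscriptAnnotation]:
    region_lengths: dict[str, int] = dict(lengths or {})
    cds: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, seqid, start, end = line.split()[:4]
                region_lengths.setdefault(seqid, int(end))
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8 or fields[2] != "CDS":
                continue
            seqid, start, end = fields[0], int(fields[3]), int(fields[4])
            if seqid in cds:
                raise ValidationError(f"duplicate CDS feature for {seqid}")
            cds[seqid] = (start - 1, end)  # to 0-based half-open
    annotations = {}
    for seqid, (cds_start, cds_end) in cds.items():
        if seqid not in region_lengths:
            raise ValidationError(
                f"{seqid}: no transcript length (##sequence-region or lengths arg)"
            )
        annotations[seqid] = TranscriptAnnotation(
            seqid, region_lengths[seqid], cds_start, cds_end
        )
    return annotations


def write_annotations(
    annotations: Mapping[str, TranscriptAnnotation], path: str | Path
) -> None:
    rows = [
        {
            "transcript_id": a.transcript_id,
            "length": a.length,
            "cds_start": a.cds_start + 1,
            "cds_end": a.cds_end,
        }
        for a in annotations.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read transcript sequences; DNA ``T`` is mapped to RNA ``U``."""
    sequences: dict[str, str] = {}
    mapped = False
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if "T" in seq:
            mapped = True
            seq = seq.replace("T", "U")
        sequences[record.id] = seq
    if mapped:
        log.info("%s: mapped T -> U (RNA alphabet)", path)
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# poly(A), matrices, id map, condition map
# ---------------------------------------------------------------------------

KNOWN_QC_TAGS = {"PASS", "ADAPTER", "NOREGION", "SUFFCLIP", "READ_FAILED_LOAD"}

_POLYA_RENAMES = {"readname": "read_id", "contig": "transcript_id"}


def read_polya(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a nanopolish-polya-style TSV into a PolyARecord frame.

    Requires at least ``readname, contig, polya_length, qc_tag``; extra
    columns are ignored.  ``sample_id`` comes from a column of that name if
    present, otherwise from the argument.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"readname", "contig", "polya_length", "qc_tag"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing poly(A) columns {sorted(missing)}")
    df = df.rename(columns=_POLYA_RENAMES)
    if "sample_id" not in df.columns:
        if sample_id is None:
            raise ValidationError(
                f"{path}: no sample_id column and no sample_id argument"
            )
        df["sample_id"] = sample_id
    df = df[["read_id", "transcript_id", "polya_length", "qc_tag", "sample_id"]]
    if (df["polya_length"] < 0).any():
        bad = df[df["polya_length"] < 0].iloc[0]
        raise ValidationError(f"negative poly(A) length for read {bad['read_id']}")
    unknown = set(df["qc_tag"].unique()) - KNOWN_QC_TAGS
    if unknown:
        log.warning("%s: unknown qc_tag values kept verbatim: %s", path,
                    sorted(unknown))
    return df


def write_polya(records: pd.DataFrame, path: str | Path) -> None:
    out = records.rename(columns={v: k for k, v in _POLYA_RENAMES.items()})
    out.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, kind: str) -> AbundanceMatrix:
    """Read a TSV matrix (first column = feature id, rest = samples)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return AbundanceMatrix(df, kind=kind)


def write_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = out.index.name or "feature_id"
    out.to_csv(path, sep="\t")


def read_id_map(path: str | Path) -> pd.DataFrame:
    """Read a transcript <-> protein id mapping TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"transcript_id", "protein_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing id-map columns {sorted(missing)}")
    return df[["transcript_id", "protein_id"]]


def read_condition_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> condition TSV (order of first appearance
    of the condition labels defines (control, treatment))."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"sample_id", "condition"}.issubset(df.columns):
        raise ValidationError(f"{path}: need columns sample_id, condition")
    return dict(zip(df["sample_id"], df["condition"]))


def write_condition_map(condition_map: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(condition_map), "condition": list(condition_map.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# read summary statistics
# ---------------------------------------------------------------------------


def _round2(x: float) -> float:
    """Round half away from zero to 2 decimals (report convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_read_stats(
    per_sample_lengths: Mapping[str, Sequence[float]] | None = None,
    per_sample_quality_max: Mapping[str, float] | None = None,
    precomputed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample read summary statistics plus a grand-mean row.

    Either pass raw ``per_sample_lengths`` (and optionally
    ``per_sample_quality_max``), or a ``precomputed`` frame indexed by sample
    with columns ``mean_length, median_length, max_length, max_quality`` —
    in which case only the grand-mean row is computed.  The grand-mean row
    (index ``"mean"``) is the arithmetic mean of each column, rounded half-up
    to 2 decimals.
    """
    if precomputed is not None:
        stats = precomputed.astype(float).copy()
    else:
        if not per_sample_lengths:
            raise ValidationError("no samples given")
        rows = {}
        for sample, lengths in per_sample_lengths.items():
            arr = np.asarray(lengths, dtype=float)
            if arr.size == 0:
                raise ValidationError(f"sample {sample}: no read lengths")
            rows[sample] = {
                "mean_length": float(arr.mean()),
                "median_length": float(np.median(arr)),
                "max_length": float(arr.max()),
                "max_quality": float(per_sample_quality_max[sample])
                if per_sample_quality_max and sample in per_sample_quality_max
                else np.nan,
            }
        stats = pd.DataFrame.from_dict(rows, orient="index")

    if "mean" in stats.index:
        raise ValidationError("'mean' is reserved for the grand-mean row")
    # exact decimal accumulation so printed 2-decimal inputs round correctly
    grand = {}
    for col in stats.columns:
        vals = stats[col].dropna()
        if len(vals) == 0:
            grand[col] = np.nan
            continue
        total = sum(Decimal(repr(v)) for v in vals)
        mean = total / Decimal(len(vals))
        grand[col] = float(mean.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    stats.loc["mean"] = grand
    return stats
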