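"""Seeded synthetic-data generator with planted ground truth.

Emits a complete input bundle (sequences, annotations, modcalls, poly(A)
records, count and protein matrices, id map) whose statistical structure
matches what the downstream analysis assumes:

- two conditions x ``replicates`` samples, negative-binomial coverage;
- Bernoulli per-read modification with a per-transcript baseline rate and
  planted condition effects placed preferentially in 3'UTR RRACH sites of
  treated samples;
- poly(A) lengths from a gamma distribution truncated to configured bounds,
  with the per-transcript mean coupled to that transcript's modification
  ratio;
- log-normal transcript counts negatively coupled, and protein abundances
  positively coupled (treatment only), to the modification ratio.

Coupling noise scales are calibrated at generation time from the realized
spread of the modification ratios, so the configured target correlations
hold in expectation regardless of the other settings.  Identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import special, stats

from . import io_tables
from .io_tables import (
    AbundanceMatrix,
    ModCallTable,
    TranscriptAnnotation,
    ValidationError,
)
from .metagene import RRACH_KMERS, find_rrach_sites

log = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """All knobs of the generator; every random draw flows from ``seed``."""

    n_transcripts: int = 300
    length_min: int = 600
    length_max: int = 2400
    utr5_frac: float = 0.15
    utr3_frac: float = 0.25
    replicates: int = 3
    conditions: tuple[str, str] = ("control", "treated")

    coverage_mean: float = 100.0
    coverage_dispersion: float = 10.0
    positions_per_transcript: int = 20
    rrach_positions_per_transcript: int = 3  # RRACH sites always in modcalls

    f0_mean: float = 0.05          # baseline per-read modification probability
    f0_concentration: float = 50.0  # Beta concentration of per-transcript baselines
    n_planted: int = 50
    f1: float = 0.4
    utr3_placement_prob: float = 0.9

    polya_mean: float = 91.0
    polya_min: float = 40.0
    polya_max: float = 250.0
    polya_shape: float = 4.0
    polya_mod_target_r: float = 0.2
    reads_per_transcript: int = 10  # poly(A) reads per transcript per sample
    polya_qc_fail_prob: float = 0.05

    abundance_target_r: float = -0.4
    abundance_base_log2: float = 6.0
    abundance_log2_sd: float = 1.5
    replicate_log2_sd: float = 0.25

    protein_target_r: float = 0.18
    protein_base_log2: float = 10.0
    protein_log2_sd: float = 1.0
    protein_fraction: float = 0.7

    seed: int = 0

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        if not (0.0 <= self.f0_mean <= 1.0 and 0.0 <= self.f1 <= 1.0):
            raise ValidationError("f0_mean and f1 must lie in [0, 1]")
        for name in ("n_transcripts", "length_min", "length_max", "replicates",
                     "positions_per_transcript", "reads_per_transcript"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_planted < 0 or self.n_planted > self.n_transcripts:
            raise ValidationError("need 0 <= n_planted <= n_transcripts")
        if len(self.conditions) != 2:
            raise ValidationError("exactly two condition labels required")
        if not self.polya_min < self.polya_mean < self.polya_max:
            raise ValidationError("polya_mean must lie inside the bounds")
        if self.f1 == self.f0_mean and self.n_planted > 0:
            log.warning("f1 == f0_mean: planted sites carry no effect "
                        "(power will be nil)")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        data = asdict(self)
        data["conditions"] = list(self.conditions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class TruthLedger:
    """Ground truth of the planted effects, for recovery testing.

    ``sites``: one row per planted site (transcript, 0-based position, region,
    kmer, f0, f1).  ``transcripts``: per-transcript true modification ratios,
    poly(A) target means and log2 abundances per condition.
    """

    sites: pd.DataFrame
    transcripts: pd.DataFrame
    seed: int


@dataclass
class SimBundle:
    config: SimConfig
    sequences: dict[str, str]
    annotations: dict[str, TranscriptAnnotation]
    condition_map: dict[str, str]
    modcalls: ModCallTable
    polya: pd.DataFrame
    counts: AbundanceMatrix
    proteins: AbundanceMatrix
    id_map: pd.DataFrame
    truth: TruthLedger


# ---------------------------------------------------------------------------
# truncated-gamma poly(A) machinery
# ---------------------------------------------------------------------------


def _trunc_gamma_moments(theta: np.ndarray, shape: float, lo: float, hi: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of Gamma(shape, theta) truncated to [lo, hi]."""
    theta = np.asarray(theta, dtype=float)
    z = special.gammainc(shape, hi / theta) - special.gammainc(shape, lo / theta)
    m1 = (
        shape * theta
        * (special.gammainc(shape + 1, hi / theta)
           - special.gammainc(shape + 1, lo / theta))
        / z
    )
    m2 = (
        shape * (shape + 1) * theta**2
        * (special.gammainc(shape + 2, hi / theta)
           - special.gammainc(shape + 2, lo / theta))
        / z
    )
    return m1, m2 - m1**2


def _theta_for_mean(target_mean: np.ndarray, shape: float, lo: float, hi: float
                    ) -> np.ndarray:
    """Invert the truncated-gamma mean via a dense monotone grid."""
    grid = np.linspace(1.0, 120.0, 4000)
    means, _ = _trunc_gamma_moments(grid, shape, lo, hi)
    target = np.clip(target_mean, means[0] + 1e-9, means[-1] - 1e-9)
    return np.interp(target, means, grid)


def _sample_trunc_gamma(rng: np.random.Generator, theta: np.ndarray,
                        shape: float, lo: float, hi: float) -> np.ndarray:
    """Inverse-CDF sampling restricted to [lo, hi] (exact truncation)."""
    c_lo = special.gammainc(shape, lo / theta)
    c_hi = special.gammainc(shape, hi / theta)
    u = c_lo + rng.random(theta.shape) * (c_hi - c_lo)
    return stats.gamma.ppf(u, a=shape, scale=theta)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGU"))


def _sample_names(config: SimConfig) -> tuple[list[str], dict[str, str]]:
    names, cmap = [], {}
    for cond in config.conditions:
        for r in range(1, config.replicates + 1):
            name = f"{cond}_{r}"
            names.append(name)
            cmap[name] = cond
    return names, cmap


def simulate_dataset(config: SimConfig) -> SimBundle:
    """Generate the full synthetic input bundle plus its truth ledger."""
    rng = np.random.default_rng(config.seed)
    ctrl, treat = config.conditions
    samples, condition_map = _sample_names(config)
    treat_samples = {s for s, c in condition_map.items() if c == treat}

    # --- transcripts, annotations, sequences -------------------------------
    tids = [f"tx{i:05d}" for i in range(config.n_transcripts)]
    lengths = rng.integers(config.length_min, config.length_max + 1,
                           config.n_transcripts)
    annotations: dict[str, TranscriptAnnotation] = {}
    sequences: dict[str, str] = {}
    seq_arrays: dict[str, np.ndarray] = {}
    for tid, length in zip(tids, lengths):
        cds_start = max(1, int(round(config.utr5_frac * length)))
        cds_end = min(length - 1, int(round((1.0 - config.utr3_frac) * length)))
        annotations[tid] = TranscriptAnnotation(tid, int(length), cds_start, cds_end)
        seq_arrays[tid] = _BASES[rng.integers(0, 4, int(length))]

    # --- planted differential sites ----------------------------------------
    planted_tids = sorted(
        rng.choice(config.n_transcripts, size=config.n_planted, replace=False)
    )
    truth_sites = []
    planted_pos: dict[str, int] = {}
    for ti in planted_tids:
        tid = tids[ti]
        ann = annotations[tid]
        if rng.random() < config.utr3_placement_prob:
            region = "3UTR"
        else:
            region = "CDS" if rng.random() < 0.75 else "5UTR"
        start, end = ann.region_span(region)
        lo = max(start, 2)
        hi = min(end, ann.length - 2)  # A offset must allow a full 5-mer
        if hi <= lo:
            raise ValidationError(
                f"{tid}: region {region} too short to host a planted site"
            )
        pos = int(rng.integers(lo, hi))
        kmer = RRACH_KMERS[int(rng.integers(0, len(RRACH_KMERS)))]
        seq_arrays[tid][pos - 2 : pos + 3] = list(kmer)
        planted_pos[tid] = pos
        truth_sites.append(
            {"transcript_id": tid, "position": pos, "region": region,
             "kmer": kmer, "f0": np.nan, "f1": config.f1}
        )
    sequences = {tid: "".join(arr) for tid, arr in seq_arrays.items()}

    # --- per-transcript baseline rates and modcalls ------------------------
    kappa = config.f0_concentration
    f0_t = rng.beta(config.f0_mean * kappa, (1.0 - config.f0_mean) * kappa,
                    config.n_transcripts)
    for row in truth_sites:
        row["f0"] = f0_t[tids.index(row["transcript_id"])]

    nb_n = config.coverage_dispersion
    nb_p = nb_n / (nb_n + config.coverage_mean)
    is_treat = np.array([s in treat_samples for s in samples])
    modcall_frames = []
    ratio_true = {ctrl: np.empty(config.n_transcripts),
                  treat: np.empty(config.n_transcripts)}
    # methylation score over the transcript's emitted RRACH sites; this is
    # what RRACH-restricted ratios estimate downstream
    m6a_score = {ctrl: np.empty(config.n_transcripts),
                 treat: np.empty(config.n_transcripts)}
    for i, tid in enumerate(tids):
        ann = annotations[tid]
        planted = planted_pos.get(tid)
        rrach_pool = np.array(
            [s.position for s in find_rrach_sites(sequences[tid], tid)
             if s.position != planted],
            dtype=np.int64,
        )
        n_rrach = min(config.rrach_positions_per_transcript, len(rrach_pool))
        rrach_sel = (rng.choice(rrach_pool, size=n_rrach, replace=False)
                     if n_rrach else np.array([], dtype=np.int64))
        pool = np.setdiff1d(np.arange(ann.length),
                            [] if planted is None else [planted])
        k = min(config.positions_per_transcript, len(pool))
        positions = rng.choice(pool, size=k, replace=False)
        positions = np.union1d(positions, rrach_sel)
        if planted is not None:
            positions = np.union1d(positions, [planted])
        n_pos = len(positions)
        ratio_true[ctrl][i] = f0_t[i]
        extra = (config.f1 - f0_t[i]) / n_pos if planted is not None else 0.0
        ratio_true[treat][i] = f0_t[i] + extra
        m6a_score[ctrl][i] = f0_t[i]
        n_rrach_set = n_rrach + (1 if planted is not None else 0)
        m6a_score[treat][i] = (
            f0_t[i] + (config.f1 - f0_t[i]) / n_rrach_set
            if planted is not None
            else f0_t[i]
        )
        cov = rng.negative_binomial(nb_n, nb_p, size=(n_pos, len(samples)))
        f = np.full((n_pos, len(samples)), f0_t[i])
        if planted is not None:
            f[np.ix_(positions == planted, is_treat)] = config.f1
        mod = rng.binomial(cov, f)
        seq = sequences[tid]
        modcall_frames.append(
            pd.DataFrame(
                {
                    "transcript_id": tid,
                    "position": np.repeat(positions, len(samples)),
                    "ref_base": np.repeat([seq[p] for p in positions],
                                          len(samples)),
                    "sample_id": np.tile(samples, n_pos),
                    "coverage": cov.ravel(),
                    "modified_count": mod.ravel(),
                }
            )
        )
    modcalls = ModCallTable(
        pd.concat(modcall_frames, ignore_index=True),
        condition_map,
        condition_order=config.conditions,
        annotations=annotations,
    )

    # standardized scores per condition drive the couplings: abundance is
    # tied to the global modification ratio, poly(A) and protein to the
    # RRACH methylation score (the quantity their measured pairs estimate)
    def _standardize(values: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for cond, x in values.items():
            sd = x.std()
            out[cond] = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        return out

    z = _standardize(ratio_true)
    z_m6a = _standardize(m6a_score)

    # --- poly(A) records ----------------------------------------------------
    base_theta = _theta_for_mean(
        np.array([config.polya_mean]), config.polya_shape,
        config.polya_min, config.polya_max,
    )[0]
    _, var_trunc = _trunc_gamma_moments(
        np.array([base_theta]), config.polya_shape,
        config.polya_min, config.polya_max,
    )
    var_of_mean = float(var_trunc[0]) / (config.reads_per_transcript
                                         * config.replicates)
    r_pa = config.polya_mod_target_r
    delta = np.sqrt(var_of_mean * r_pa**2 / (1.0 - r_pa**2)) if r_pa else 0.0
    log.info("poly(A) coupling calibration: per-transcript shift sd %.3f nt", delta)

    polya_target = {cond: config.polya_mean + delta * z_m6a[cond]
                    for cond in (ctrl, treat)}
    theta_by_cond = {
        cond: _theta_for_mean(polya_target[cond], config.polya_shape,
                              config.polya_min, config.polya_max)
        for cond in (ctrl, treat)
    }
    n_reads = config.reads_per_transcript
    polya_frames = []
    for sample in samples:
        cond = condition_map[sample]
        theta = np.repeat(theta_by_cond[cond], n_reads)
        lengths_pa = _sample_trunc_gamma(
            rng, theta, config.polya_shape, config.polya_min, config.polya_max
        )
        tags = np.where(rng.random(theta.size) < config.polya_qc_fail_prob,
                        "ADAPTER", "PASS")
        polya_frames.append(
            pd.DataFrame(
                {
                    "read_id": [
                        f"read_{tid}_{sample}_{j}"
                        for tid in tids for j in range(n_reads)
                    ],
                    "transcript_id": np.repeat(tids, n_reads),
                    "polya_length": lengths_pa,
                    "qc_tag": tags,
                    "sample_id": sample,
                }
            )
        )
    polya = pd.concat(polya_frames, ignore_index=True)

    # --- transcript counts (log-normal, negative coupling) ------------------
    r_ab = config.abundance_target_r
    sd_ab = config.abundance_log2_sd
    eps = rng.standard_normal(config.n_transcripts)
    log2_abund = {}
    for cond in (ctrl, treat):
        log2_abund[cond] = (
            config.abundance_base_log2
            + r_ab * sd_ab * z[cond]
            + np.sqrt(1.0 - r_ab**2) * sd_ab * eps
        )
    count_cols = {}
    for sample in samples:
        cond = condition_map[sample]
        noise = rng.normal(0.0, config.replicate_log2_sd, config.n_transcripts)
        count_cols[sample] = np.rint(2.0 ** (log2_abund[cond] + noise)).astype(
            np.int64
        )
    counts = AbundanceMatrix(
        pd.DataFrame(count_cols, index=pd.Index(tids, name="transcript_id")),
        kind="counts",
    )

    # --- protein abundances (coupling in treatment only) --------------------
    with_protein = np.sort(
        rng.choice(config.n_transcripts,
                   size=int(round(config.protein_fraction * config.n_transcripts)),
                   replace=False)
    )
    prot_tids = [tids[i] for i in with_protein]
    prot_ids = [f"prot_{tid}" for tid in prot_tids]
    r_pr = config.protein_target_r
    sd_pr = config.protein_log2_sd
    eps_p = rng.standard_normal(len(with_protein))
    log2_prot = {
        ctrl: config.protein_base_log2 + sd_pr * eps_p,
        treat: (
            config.protein_base_log2
            + r_pr * sd_pr * z_m6a[treat][with_protein]
            + np.sqrt(1.0 - r_pr**2) * sd_pr * eps_p
        ),
    }
    prot_cols = {}
    for sample in samples:
        cond = condition_map[sample]
        noise = rng.normal(0.0, config.replicate_log2_sd, len(with_protein))
        prot_cols[sample] = 2.0 ** (log2_prot[cond] + noise)
    proteins = AbundanceMatrix(
        pd.DataFrame(prot_cols, index=pd.Index(prot_ids, name="protein_id")),
        kind="protein",
    )
    id_map = pd.DataFrame({"transcript_id": prot_tids, "protein_id": prot_ids})

    truth = TruthLedger(
        sites=pd.DataFrame(
            truth_sites,
            columns=["transcript_id", "position", "region", "kmer", "f0", "f1"],
        ),
        transcripts=pd.DataFrame(
            {
                "transcript_id": tids,
                f"mod_ratio_{ctrl}": ratio_true[ctrl],
                f"mod_ratio_{treat}": ratio_true[treat],
                f"m6a_score_{ctrl}": m6a_score[ctrl],
                f"m6a_score_{treat}": m6a_score[treat],
                f"polya_mean_{ctrl}": polya_target[ctrl],
                f"polya_mean_{treat}": polya_target[treat],
                f"log2_abundance_{ctrl}": log2_abund[ctrl],
                f"log2_abundance_{treat}": log2_abund[treat],
            }
        ),
        seed=config.seed,
    )
    return SimBundle(
        config=config,
        sequences=sequences,
        annotations=annotations,
        condition_map=condition_map,
        modcalls=modcalls,
        polya=polya,
        counts=counts,
        proteins=proteins,
        id_map=id_map,
        truth=truth,
    )


def simulate_null_positions(
    n: int,
    coverage: int = 50,
    f0: float = 0.2,
    seed: int = 0,
    replicates: int = 1,
    conditions: tuple[str, str] = ("control", "treated"),
) -> ModCallTable:
    """Positions where both conditions share the same modification rate.

    Type-I-error harness: ``n`` independent positions, fixed ``coverage`` per
    replicate, modified counts Binomial(coverage, f0) in every sample.
    """
    return simulate_planted_positions(
        n, coverage, f0, f0, seed=seed, replicates=replicates,
        conditions=conditions,
    )


def simulate_planted_positions(
    n: int,
    coverage: int = 50,
    f0: float = 0.1,
    f1: float = 0.4,
    seed: int = 0,
    replicates: int = 1,
    conditions: tuple[str, str] = ("control", "treated"),
) -> ModCallTable:
    """Positions modified at rate f0 in control and f1 in treatment.

    Power harness; with ``f1 == f0`` this is the null generator.
    """
    if n < 1:
        raise ValidationError("need n >= 1 positions")
    if not (0.0 <= f0 <= 1.0 and 0.0 <= f1 <= 1.0):
        raise ValidationError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ctrl, treat = conditions
    rows = []
    condition_map = {}
    for cond in conditions:
        rate = f0 if cond == ctrl else f1
        for r in range(1, replicates + 1):
            sample = f"{cond}_{r}"
            condition_map[sample] = cond
            mods = rng.binomial(coverage, rate, size=n)
            rows.append(
                pd.DataFrame(
                    {
                        "transcript_id": [f"pos{i:06d}" for i in range(n)],
                        "position": 0,
                        "ref_base": "A",
                        "sample_id": sample,
                        "coverage": coverage,
                        "modified_count": mods,
                    }
                )
            )
    return ModCallTable(pd.concat(rows, ignore_index=True), condition_map,
                        condition_order=conditions)


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "sequences": "sequences.fasta",
    "annotations": "annotations.tsv",
    "conditions": "conditions.tsv",
    "modcalls": "modcalls.tsv",
    "polya": "polya.tsv",
    "counts": "counts.tsv",
    "proteins": "proteins.tsv",
    "id_map": "id_map.tsv",
    "truth_sites": "truth_sites.tsv",
    "truth_transcripts": "truth_transcripts.tsv",
    "config": "sim_config.yaml",
}


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle component in the canonical dialects; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in BUNDLE_FILES.items()}
    io_tables.write_fasta(bundle.sequences, paths["sequences"])
    io_tables.write_annotations(bundle.annotations, paths["annotations"])
    io_tables.write_condition_map(bundle.condition_map, paths["conditions"])
    io_tables.write_modcalls(bundle.modcalls, paths["modcalls"])
    io_tables.write_polya(bundle.polya, paths["polya"])
    io_tables.write_matrix(bundle.counts, paths["counts"])
    io_tables.write_matrix(bundle.proteins, paths["proteins"])
    bundle.id_map.to_csv(paths["id_map"], sep="\t", index=False)
    sites = bundle.truth.sites.copy()
    if len(sites):
        sites["position"] = sites["position"] + 1  # 1-based on disk
    sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    bundle.truth.transcripts.to_csv(paths["truth_transcripts"], sep="\t",
                                    index=False)
    bundle.config.to_file(paths["config"])
    return paths


def load_bundle_inputs(indir: str | Path) -> dict:
    """Read a written bundle back as pipeline inputs (truth files excluded)."""
    indir = Path(indir)
    condition_map = io_tables.read_condition_map(indir / BUNDLE_FILES["conditions"])
    annotations = io_tables.read_annotations(indir / BUNDLE_FILES["annotations"])
    return {
        "sequences": io_tables.read_fasta(indir / BUNDLE_FILES["sequences"]),
        "annotations": annotations,
        "condition_map": condition_map,
        "modcalls": io_tables.read_modcalls(
            indir / BUNDLE_FILES["modcalls"], condition_map,
            annotations=annotations,
        ),
        "polya": io_tables.read_polya(indir / BUNDLE_FILES["polya"]),
        "counts": io_tables.read_matrix(indir / BUNDLE_FILES["counts"], "counts"),
        "proteins": io_tables.read_matrix(indir / BUNDLE_FILES["proteins"],
                                          "protein"),
        "id_map": io_tables.read_id_map(indir / BUNDLE_FILES["id_map"]),
    }
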