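"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the data structure of a four-arm epigenetic
drug study: a microarray-like log2 expression matrix over DMSO /
EZH2i / HDACi / Combo arms with planted gene classes, per-condition
H3K27me3 peak landscapes with planted promoter peak loss at the
cooperative targets, a three-class tumor cohort with an
EZH2-high/ATF3-low gradient and ATF3-dependent survival, and a
dose-response matrix with a known excess over the
highest-single-agent surface.

Planted gene classes
--------------------
cooperative_prc2   induced by effect_log2fc in Combo only; its promoter
                   H3K27me3 peak is present in DMSO/HDACi and absent in
                   EZH2i/Combo.  The true positives of the discovery run.
additive           induced in Combo only, but with no peak loss — passes
                   the expression selection and must be removed by the
                   peak-loss intersection.
ezh2i_only /       induced equally in their single-agent arm AND Combo,
hdaci_only         so they fail the Combo-vs-single-agent contrast.
null               no planted effect.

Determinism: a single master seed is split into named substreams
(annotation, truth, peaks, expression, cohort, dose), so regenerating
one input never perturbs the others, and identical configs produce
byte-identical outputs.

Expression noise is Gaussian on the log2 scale (array-like, matching
the Welch-t contrast model); noise_sd = 0 is accepted to exercise the
noiseless limit in tests.  Survival is exponential with proportional
hazards — the simplest model with a closed-form median (ln 2 / rate).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .diffexpr import CONDITIONS, ExpressionMatrix
from .errors import SizingError, ValidationError
from .io import GeneSet, GenomicInterval
from .peakloss import PROTEIN_CODING, PeakSet, TranscriptAnnotation
from .synergy import DoseResponseMatrix

GENE_CLASSES = ("cooperative_prc2", "ezh2i_only", "hdaci_only", "additive", "null")

_STREAMS = {
    "annotation": 0,
    "truth": 1,
    "peaks": 2,
    "expression": 3,
    "cohort": 4,
    "dose": 5,
}

_TSS_JITTER = 1000  # bp of per-slot jitter on top of the minimum spacing


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study, with the study's defaults."""

    seed: int = 0
    # expression
    n_genes: int = 1000
    n_planted_cooperative: int = 30
    n_planted_ezh2i_only: int = 20
    n_planted_hdaci_only: int = 20
    n_planted_additive: int = 20
    n_replicates_per_condition: int = 3
    effect_log2fc: float = 2.0
    noise_sd: float = 0.25
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    # genome / peaks
    genome_n_chroms: int = 4
    chrom_length: int = 10_000_000
    tss_window_halfwidth: int = 10_000
    peak_halfwidth: int = 500
    second_transcript_fraction: float = 0.2
    noncoding_fraction: float = 0.1
    stable_peak_fraction: float = 0.3
    n_background_peaks: int = 200
    # cohort
    cohort_n_normal: int = 50
    cohort_n_primary: int = 150
    cohort_n_metastatic: int = 200
    primary_ezh2_shift: float = 2.0
    metastatic_ezh2_shift: float = 4.0
    primary_atf3_shift: float = -1.0
    metastatic_atf3_shift: float = -2.0
    atf3_low_shift: float = 1.5
    signature_coupling: float = 0.7
    n_signature_genes: int = 40
    n_cohort_null_genes: int = 400
    signature_gene_noise_sd: float = 0.5
    hazard_ratio_atf3_low: float = 3.0
    baseline_median_survival: float = 60.0
    censor_rate: float = 0.2
    # dose response
    dose_grid_a: tuple[float, ...] = (0.0, 1.25, 2.5, 5.0, 10.0)
    dose_grid_b: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)
    planted_hsa_excess: float = 15.0

    def __post_init__(self):
        counts = {
            "n_genes": self.n_genes,
            "n_planted_cooperative": self.n_planted_cooperative,
            "n_planted_ezh2i_only": self.n_planted_ezh2i_only,
            "n_planted_hdaci_only": self.n_planted_hdaci_only,
            "n_planted_additive": self.n_planted_additive,
            "n_replicates_per_condition": self.n_replicates_per_condition,
            "genome_n_chroms": self.genome_n_chroms,
            "cohort_n_normal": self.cohort_n_normal,
            "cohort_n_primary": self.cohort_n_primary,
            "cohort_n_metastatic": self.cohort_n_metastatic,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValidationError(f"{name} must be >= 0 (got {value})")
        if self.n_planted_total > self.n_genes:
            raise ValidationError(
                f"planted classes ({self.n_planted_total}) exceed n_genes "
                f"({self.n_genes})"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 <= self.censor_rate < 1:
            raise ValidationError("censor_rate must lie in [0, 1)")
        if self.hazard_ratio_atf3_low <= 0:
            raise ValidationError("hazard_ratio_atf3_low must be positive")
        if not -1 < self.signature_coupling < 1:
            raise ValidationError("signature_coupling must lie in (-1, 1)")
        for name, grid in (("dose_grid_a", self.dose_grid_a), ("dose_grid_b", self.dose_grid_b)):
            arr = np.asarray(grid, float)
            if arr.size < 2 or arr[0] != 0 or np.any(np.diff(arr) <= 0):
                raise ValidationError(
                    f"{name} must start at 0 and strictly increase"
                )

    @property
    def n_planted_total(self) -> int:
        return (
            self.n_planted_cooperative
            + self.n_planted_ezh2i_only
            + self.n_planted_hdaci_only
            + self.n_planted_additive
        )

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],))
        )


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators, for recovery tests."""

    gene_classes: dict[str, str]
    lost_transcripts: frozenset[str]
    cohort: pd.DataFrame | None = None  # sample, atf3_low, derepression, atf3_activity
    hsa_excess: float = 0.0

    def genes_of_class(self, cls: str) -> set[str]:
        if cls not in GENE_CLASSES:
            raise ValidationError(f"unknown gene class {cls!r}")
        return {g for g, c in self.gene_classes.items() if c == cls}

    def to_json(self, path) -> None:
        payload = {
            "gene_classes": dict(sorted(self.gene_classes.items())),
            "lost_transcripts": sorted(self.lost_transcripts),
            "hsa_excess": self.hsa_excess,
            "cohort": (
                self.cohort.to_dict(orient="records") if self.cohort is not None else None
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cohort = payload.get("cohort")
        return cls(
            gene_classes=payload["gene_classes"],
            lost_transcripts=frozenset(payload["lost_transcripts"]),
            cohort=pd.DataFrame(cohort) if cohort is not None else None,
            hsa_excess=payload.get("hsa_excess", 0.0),
        )


# ---------------------------------------------------------------------------
# annotation

def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def generate_annotation(config: SyntheticConfig) -> TranscriptAnnotation:
    """Place TSSs spaced >= 3x the window halfwidth so windows never
    capture a neighbor's planted peaks; ~10% of genes are noncoding to
    exercise the protein-coding filter."""
    if config.n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    rng = config.rng("annotation")
    genes = _gene_ids(config.n_genes)

    extra = rng.random(config.n_genes) < config.second_transcript_fraction
    n_transcripts = (1 + extra.astype(int)).tolist()
    total = int(sum(n_transcripts))

    hw = config.tss_window_halfwidth
    step = 3 * hw + _TSS_JITTER
    usable = config.chrom_length - 2 * hw - _TSS_JITTER
    slots_per_chrom = 0 if usable < 0 else usable // step + 1
    capacity = config.genome_n_chroms * slots_per_chrom
    if total > capacity:
        per_chrom = math.ceil(total / max(config.genome_n_chroms, 1))
        required = 2 * hw + _TSS_JITTER + (per_chrom - 1) * step
        raise SizingError(
            f"genome too small: {total} transcripts need chrom_length >= "
            f"{required} bp over {config.genome_n_chroms} chromosome(s), "
            f"got {config.chrom_length}"
        )

    jitter = rng.integers(0, _TSS_JITTER, size=total)
    strands = rng.choice(["+", "-"], size=total)
    n_noncoding = int(math.floor(config.noncoding_fraction * config.n_genes))
    noncoding = set(rng.choice(genes, size=n_noncoding, replace=False)) if n_noncoding else set()

    rows = []
    slot = 0
    for gid, k in zip(genes, n_transcripts):
        biotype = "noncoding" if gid in noncoding else PROTEIN_CODING
        for j in range(k):
            chrom_idx, chrom_slot = divmod(slot, slots_per_chrom)
            tss = hw + chrom_slot * step + int(jitter[slot])
            rows.append(
                {
                    "transcript_id": f"{gid}.t{j + 1}",
                    "gene_id": gid,
                    "gene_name": gid,
                    "chrom": f"chr{chrom_idx + 1}",
                    "strand": strands[slot],
                    "tss": tss,
                    "biotype": biotype,
                }
            )
            slot += 1
    return TranscriptAnnotation(pd.DataFrame(rows))


def plant_truth(config: SyntheticConfig, ann: TranscriptAnnotation) -> PlantedTruth:
    """Assign planted classes to protein-coding genes; every cooperative
    gene gets planted peak loss at all of its transcripts."""
    rng = config.rng("truth")
    coding = sorted(
        set(ann.df.loc[ann.df["biotype"] == PROTEIN_CODING, "gene_id"])
    )
    if config.n_planted_total > len(coding):
        raise ValidationError(
            f"cannot plant {config.n_planted_total} classes among "
            f"{len(coding)} protein-coding genes"
        )
    picked = list(rng.choice(coding, size=config.n_planted_total, replace=False))
    classes: dict[str, str] = {g: "null" for g in ann.gene_ids}
    cursor = 0
    for cls, count in (
        ("cooperative_prc2", config.n_planted_cooperative),
        ("ezh2i_only", config.n_planted_ezh2i_only),
        ("hdaci_only", config.n_planted_hdaci_only),
        ("additive", config.n_planted_additive),
    ):
        for g in picked[cursor : cursor + count]:
            classes[g] = cls
        cursor += count
    coop = {g for g, c in classes.items() if c == "cooperative_prc2"}
    lost = frozenset(
        ann.df.loc[ann.df["gene_id"].isin(coop), "transcript_id"]
    )
    return PlantedTruth(
        gene_classes=classes, lost_transcripts=lost, hsa_excess=config.planted_hsa_excess
    )


# ---------------------------------------------------------------------------
# peaks

def generate_peaksets(
    config: SyntheticConfig, ann: TranscriptAnnotation, truth: PlantedTruth
) -> dict[str, PeakSet]:
    """Per-condition H3K27me3 peak landscapes.

    DMSO and HDACi carry a promoter peak at every planted-loss
    transcript; EZH2i and Combo omit exactly those.  A fraction of the
    remaining transcripts carries a stable promoter peak present in all
    conditions, and background peaks away from any planted TSS appear
    everywhere.
    """
    missing = truth.lost_transcripts - set(ann.df["transcript_id"])
    if missing:
        raise ValidationError(
            f"truth references unknown transcript(s): {sorted(missing)[:5]}"
        )
    rng = config.rng("peaks")
    phw = config.peak_halfwidth
    by_tid = ann.df.set_index("transcript_id")

    planted: list[GenomicInterval] = []
    planted_tss: dict[str, list[int]] = {}
    for tid in sorted(truth.lost_transcripts):
        row = by_tid.loc[tid]
        tss = int(row["tss"])
        planted.append(
            GenomicInterval(
                row["chrom"], max(0, tss - phw), tss + phw, name=f"loss_{tid}"
            )
        )
        planted_tss.setdefault(row["chrom"], []).append(tss)

    other = sorted(set(ann.df["transcript_id"]) - set(truth.lost_transcripts))
    n_stable = int(round(config.stable_peak_fraction * len(other)))
    stable_tids = sorted(rng.choice(other, size=n_stable, replace=False)) if n_stable else []
    stable = []
    for tid in stable_tids:
        row = by_tid.loc[tid]
        tss = int(row["tss"])
        stable.append(
            GenomicInterval(
                row["chrom"], max(0, tss - phw), tss + phw, name=f"stable_{tid}"
            )
        )

    # background peaks kept clear of planted-loss windows
    exclusion = config.tss_window_halfwidth + 2 * phw
    background: list[GenomicInterval] = []
    attempts = 0
    while len(background) < config.n_background_peaks and attempts < 50 * max(
        config.n_background_peaks, 1
    ):
        attempts += 1
        chrom = f"chr{int(rng.integers(1, config.genome_n_chroms + 1))}"
        start = int(rng.integers(0, max(config.chrom_length - 2 * phw, 1)))
        center = start + phw
        if any(abs(center - t) < exclusion for t in planted_tss.get(chrom, [])):
            continue
        background.append(
            GenomicInterval(chrom, start, start + 2 * phw, name=f"bg_{len(background)}")
        )

    common = stable + background
    return {
        "DMSO": PeakSet(planted + common),
        "EZH2i": PeakSet(common),
        "HDACi": PeakSet(planted + common),
        "Combo": PeakSet(common),
    }


# ---------------------------------------------------------------------------
# expression

_CLASS_EFFECTS = {
    # per-condition planted mean shifts, in units of effect_log2fc
    "cooperative_prc2": {"Combo": 1.0},
    "additive": {"Combo": 1.0},
    "ezh2i_only": {"EZH2i": 1.0, "Combo": 1.0},
    "hdaci_only": {"HDACi": 1.0, "Combo": 1.0},
    "null": {},
}


def generate_expression(config: SyntheticConfig, truth: PlantedTruth) -> ExpressionMatrix:
    """Four-arm replicate log2 expression with planted class effects."""
    if config.n_replicates_per_condition < 2:
        raise ValidationError(
            "need >=2 replicates per condition for contrast tests"
        )
    rng = config.rng("expression")
    genes = sorted(truth.gene_classes)
    n = len(genes)
    reps = config.n_replicates_per_condition
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    samples, conditions = [], []
    for cond in CONDITIONS:
        for r in range(1, reps + 1):
            samples.append(f"{cond}_{r}")
            conditions.append(cond)

    mean = np.tile(baseline[:, None], (1, len(samples)))
    for i, g in enumerate(genes):
        effects = _CLASS_EFFECTS[truth.gene_classes[g]]
        for j, cond in enumerate(conditions):
            mean[i, j] += config.effect_log2fc * effects.get(cond, 0.0)
    noise = (
        rng.normal(0.0, config.noise_sd, size=mean.shape)
        if config.noise_sd > 0
        else np.zeros_like(mean)
    )
    values = pd.DataFrame(mean + noise, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(
        values=values, conditions=pd.Series(conditions, index=samples)
    )


# ---------------------------------------------------------------------------
# cohort

_CLASS_PREFIX = {"normal": "N", "primary": "P", "metastatic": "M"}


def signature_gene_sets(config: SyntheticConfig) -> tuple[GeneSet, GeneSet]:
    """The two synthetic signatures scored on the cohort.

    EZH2_TARGETS_SYNTH tracks the PRC2-derepression latent (analogous
    to an EZH2-target up-signature); ATF3_TARGETS_SYNTH tracks the ATF3
    activity latent.  Synthetic stand-ins: member genes exist only in
    the generated cohort.
    """
    k = config.n_signature_genes
    ezh2 = GeneSet(
        name="EZH2_TARGETS_SYNTH",
        description="synthetic PRC2-derepression signature",
        members=tuple(f"EZT{i + 1:03d}" for i in range(k)),
    )
    atf3 = GeneSet(
        name="ATF3_TARGETS_SYNTH",
        description="synthetic ATF3 activity signature",
        members=tuple(f"ATT{i + 1:03d}" for i in range(k)),
    )
    return ezh2, atf3


def generate_cohort(config: SyntheticConfig) -> tuple[CohortTable, pd.DataFrame]:
    """Three-class cohort with an EZH2-up / ATF3-down gradient, coupled
    signature latents, and ATF3-dependent exponential survival.

    Returns (cohort, per-sample latent truth).  EZH2 class means rise
    normal < primary < metastatic (unit within-class SD); ATF3 falls
    along the same order, and tumor samples flagged ATF3-low (fair
    coin) are shifted further down and have their hazard multiplied by
    ``hazard_ratio_atf3_low``.  Censoring: with probability
    ``censor_rate`` a sample is censored uniformly before its event.
    """
    rng = config.rng("cohort")
    n_by_class = {
        "normal": config.cohort_n_normal,
        "primary": config.cohort_n_primary,
        "metastatic": config.cohort_n_metastatic,
    }
    ezh2_shift = {
        "normal": 0.0,
        "primary": config.primary_ezh2_shift,
        "metastatic": config.metastatic_ezh2_shift,
    }
    atf3_shift = {
        "normal": 0.0,
        "primary": config.primary_atf3_shift,
        "metastatic": config.metastatic_atf3_shift,
    }

    samples, tissues = [], []
    for tissue, n in n_by_class.items():
        samples += [f"{_CLASS_PREFIX[tissue]}{i + 1:03d}" for i in range(n)]
        tissues += [tissue] * n
    n = len(samples)
    tissues = np.array(tissues)
    is_tumor = tissues != "normal"

    rho = config.signature_coupling
    lam0 = math.log(2.0) / config.baseline_median_survival
    ezh2_set, atf3_set = signature_gene_sets(config)

    atf3_low = is_tumor & (rng.random(n) < 0.5)
    # coupled signature latents (bivariate standard normal, corr rho)
    u = rng.normal(size=n)
    v = rho * u + math.sqrt(1 - rho**2) * rng.normal(size=n)
    ezh2_expr = np.array([ezh2_shift[t] for t in tissues]) + rng.normal(size=n)
    atf3_expr = (
        np.array([atf3_shift[t] for t in tissues])
        - np.where(atf3_low, config.atf3_low_shift, 0.0)
        + rng.normal(size=n)
    )
    lam = lam0 * np.where(atf3_low, config.hazard_ratio_atf3_low, 1.0)
    t_event = rng.exponential(1.0 / lam)
    censored = (
        rng.random(n) < config.censor_rate
        if config.censor_rate > 0
        else np.zeros(n, dtype=bool)
    )
    time = np.where(censored, rng.uniform(0.0, 1.0, n) * t_event, t_event)
    event = (~censored).astype(int)

    sig_noise = config.signature_gene_noise_sd
    data = {
        "sample": samples,
        "tissue": tissues,
        "time": time,
        "event": event,
        "EZH2": ezh2_expr,
        "ATF3": atf3_expr,
    }
    for j, g in enumerate(ezh2_set.members):
        data[g] = u + rng.normal(0.0, sig_noise, n)
    for j, g in enumerate(atf3_set.members):
        data[g] = v + rng.normal(0.0, sig_noise, n)
    for j in range(config.n_cohort_null_genes):
        data[f"NUL{j + 1:03d}"] = rng.normal(size=n)

    cohort = CohortTable(pd.DataFrame(data))
    truth = pd.DataFrame(
        {
            "sample": samples,
            "atf3_low": atf3_low,
            "derepression": u,
            "atf3_activity": v,
        }
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# dose response

def _hill(d: np.ndarray, emax: float, ec50: float) -> np.ndarray:
    return emax * d / (d + ec50)


def generate_dose_matrix(config: SyntheticConfig) -> DoseResponseMatrix:
    """Monotone saturating single-agent curves; every both-positive well
    equals the HSA reference plus the planted excess (deterministic, so
    the recovered score equals the planted excess exactly)."""
    a = np.asarray(config.dose_grid_a, float)
    b = np.asarray(config.dose_grid_b, float)
    fa = _hill(a, emax=40.0, ec50=5.0)  # modest single agent (EZH2i-like)
    fb = _hill(b, emax=65.0, ec50=2.0)  # stronger single agent (HDACi-like)
    resp = np.maximum.outer(fa, fb)
    resp[1:, 1:] += config.planted_hsa_excess
    resp[0, 0] = 0.0
    return DoseResponseMatrix(doses_a=a, doses_b=b, response=resp)


# ---------------------------------------------------------------------------
# bundle

@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    annotation: TranscriptAnnotation
    truth: PlantedTruth
    peaksets: dict[str, PeakSet]
    expression: ExpressionMatrix
    cohort: CohortTable
    dose: DoseResponseMatrix
    gene_sets: tuple[GeneSet, GeneSet]


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate every pipeline input from one config."""
    ann = generate_annotation(config)
    truth = plant_truth(config, ann)
    peaksets = generate_peaksets(config, ann, truth)
    expr = generate_expression(config, truth)
    cohort, cohort_truth = generate_cohort(config)
    truth.cohort = cohort_truth
    dose = generate_dose_matrix(config)
    return SyntheticBundle(
        config=config,
        annotation=ann,
        truth=truth,
        peaksets=peaksets,
        expression=expr,
        cohort=cohort,
        dose=dose,
        gene_sets=signature_gene_sets(config),
    )
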