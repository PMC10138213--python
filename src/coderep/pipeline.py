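"""End-to-end orchestration: simulate a study bundle, run discovery.

``run_discovery`` chains the three discovery stages — cooperative
induction selection on the expression matrix, peak-loss calling on the
control/treated peak sets, and candidate intersection — and writes all
intermediate tables plus a provenance block (input digests, thresholds,
config hash) so every output is traceable to its exact settings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import diffexpr, integrate, io, peakloss
from .errors import ValidationError
from .integrate import CandidateReport
from .synthdata import SyntheticConfig, generate_bundle

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and the documented defaults of the discovery run."""

    matrix: str
    samples: str
    control_bed: str
    treated_bed: str
    annotation: str
    out_dir: str
    fc_threshold: float = 1.0
    q_threshold: float = 0.05
    halfwidth: int = 10_000
    protein_coding_only: bool = True
    exclusions: str | None = None  # YAML: gene symbol -> reason
    seed: int = 0

    def __post_init__(self):
        for name in ("fc_threshold", "q_threshold", "halfwidth"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def settings(self) -> dict:
        d = asdict(self)
        d.pop("out_dir")
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(settings: dict) -> str:
    return hashlib.sha256(
        json.dumps(settings, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_discovery(config: RunConfig) -> CandidateReport:
    """Execute the full candidate-discovery pipeline and write outputs."""
    inputs = {
        "matrix": config.matrix,
        "samples": config.samples,
        "control_bed": config.control_bed,
        "treated_bed": config.treated_bed,
        "annotation": config.annotation,
    }
    for stage, path in inputs.items():
        if not Path(path).is_file():
            raise ValidationError(f"[{stage}] input file not found: {path}")

    settings = config.settings()
    cfg_hash = _config_hash(settings)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    expr = io.read_expression(config.matrix, config.samples)
    logger.info(
        "[diffexpr] %d genes x %d samples", len(expr.genes), len(expr.values.columns)
    )
    cooperative = diffexpr.select_cooperative(
        expr, fc_threshold=config.fc_threshold, q_threshold=config.q_threshold
    )
    logger.info(
        "[diffexpr] %d cooperatively induced genes (%.2fs)",
        len(cooperative),
        time.perf_counter() - t0,
    )

    t1 = time.perf_counter()
    ann = io.read_annotation(config.annotation)
    control = peakloss.PeakSet(io.read_bed(config.control_bed))
    treated = peakloss.PeakSet(io.read_bed(config.treated_bed))
    windows = peakloss.build_windows(
        ann,
        halfwidth=config.halfwidth,
        protein_coding_only=config.protein_coding_only,
    )
    report_pl = peakloss.call_lost(control, treated, windows)
    prc2_targets = peakloss.prc2_target_genes(report_pl)
    logger.info(
        "[peakloss] %d windows, %d lost genes (%.2fs)",
        len(windows),
        len(prc2_targets),
        time.perf_counter() - t1,
    )

    exclusions = None
    if config.exclusions:
        with open(config.exclusions) as fh:
            exclusions = yaml.safe_load(fh) or {}

    provenance = {
        "config_hash": cfg_hash,
        "settings": settings,
        "input_digests": {k: _sha256(v) for k, v in inputs.items()},
        "n_cooperative": len(cooperative),
        "n_prc2_targets": len(prc2_targets),
    }
    report = integrate.intersect_candidates(
        cooperative, prc2_targets, exclusions=exclusions, provenance=provenance
    )
    logger.info("[integrate] %d candidate gene(s)", len(report.candidates))

    def _with_hash(path, write_fn):
        with open(path, "w") as fh:
            fh.write(f"# config_hash={cfg_hash}\n")
            write_fn(fh)

    _with_hash(
        out_dir / "cooperative_genes.txt",
        lambda fh: fh.writelines(g + "\n" for g in sorted(cooperative)),
    )
    _with_hash(
        out_dir / "prc2_target_genes.txt",
        lambda fh: fh.writelines(g + "\n" for g in sorted(prc2_targets)),
    )
    report_pl.to_tsv(out_dir / "peakloss_report.tsv")
    integrate.write_report(report, out_dir)
    return report


SIMULATED_FILES = (
    "annotation.tsv",
    "expression.tsv",
    "samples.tsv",
    "dmso.bed",
    "ezh2i.bed",
    "hdaci.bed",
    "combo.bed",
    "cohort.tsv",
    "dose_matrix.csv",
    "signatures.gmt",
    "truth.json",
)


def run_simulate(config: SyntheticConfig, out_dir) -> dict:
    """Write the complete synthetic bundle + truth; return the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(config)

    io.write_annotation(bundle.annotation, out_dir / "annotation.tsv")
    io.write_expression(
        bundle.expression, out_dir / "expression.tsv", out_dir / "samples.tsv"
    )
    for cond, fname in (
        ("DMSO", "dmso.bed"),
        ("EZH2i", "ezh2i.bed"),
        ("HDACi", "hdaci.bed"),
        ("Combo", "combo.bed"),
    ):
        io.write_bed(bundle.peaksets[cond], out_dir / fname)
    io.write_cohort(bundle.cohort, out_dir / "cohort.tsv")
    io.write_dose_csv(bundle.dose, out_dir / "dose_matrix.csv")
    io.write_gmt(bundle.gene_sets, out_dir / "signatures.gmt")
    bundle.truth.to_json(out_dir / "truth.json")

    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "files": {name: _sha256(out_dir / name) for name in SIMULATED_FILES},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
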