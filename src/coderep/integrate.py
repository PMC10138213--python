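"""Candidate nomination: intersect cooperatively induced genes with
peak-loss-defined PRC2 targets.

A candidate must be BOTH transcriptionally induced only by the drug
combination AND have lost a repressive promoter peak under EZH2
inhibition; the intersection is what removes combination-induced genes
with no promoter demethylation.  An optional, user-supplied exclusion
list (symbol -> reason) mirrors downstream manual deprioritization as
declarative configuration rather than code.

Every report carries a provenance block (input digests, thresholds,
seed) so its headline counts are always reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .errors import ValidationError


@dataclass
class CandidateReport:
    cooperative: frozenset[str]
    prc2_targets: frozenset[str]
    intersection: frozenset[str]
    candidates: frozenset[str]
    excluded: tuple[tuple[str, str], ...] = ()
    provenance: dict = field(default_factory=dict)

    @property
    def venn(self) -> dict[str, int]:
        both = len(self.intersection)
        return {
            "only_cooperative": len(self.cooperative) - both,
            "only_prc2_targets": len(self.prc2_targets) - both,
            "both": both,
        }


def intersect_candidates(
    cooperative: set[str],
    prc2_targets: set[str],
    exclusions: Mapping[str, str] | None = None,
    provenance: dict | None = None,
) -> CandidateReport:
    """Exact set intersection with optional post-hoc exclusions.

    ``exclusions`` maps gene symbol -> reason; only symbols actually in
    the intersection are recorded as excluded.
    """
    cooperative = frozenset(cooperative)
    prc2_targets = frozenset(prc2_targets)
    intersection = cooperative & prc2_targets
    excluded: list[tuple[str, str]] = []
    candidates = set(intersection)
    if exclusions:
        for symbol in sorted(exclusions):
            if symbol in intersection:
                candidates.discard(symbol)
                excluded.append((symbol, exclusions[symbol]))
    return CandidateReport(
        cooperative=cooperative,
        prc2_targets=prc2_targets,
        intersection=intersection,
        candidates=frozenset(candidates),
        excluded=tuple(excluded),
        provenance=dict(provenance or {}),
    )


def write_report(report: CandidateReport, out_dir) -> dict[str, str]:
    """Write candidates TSV + venn/provenance JSON; byte-deterministic.

    Returns the mapping of logical name -> written path.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    candidates_path = out_dir / "candidates.tsv"
    with open(candidates_path, "w") as fh:
        fh.write("gene\tcooperative\tprc2_target\tcandidate\texcluded_reason\n")
        reasons = dict(report.excluded)
        for gene in sorted(report.cooperative | report.prc2_targets):
            fh.write(
                "\t".join(
                    [
                        gene,
                        str(int(gene in report.cooperative)),
                        str(int(gene in report.prc2_targets)),
                        str(int(gene in report.candidates)),
                        reasons.get(gene, ""),
                    ]
                )
                + "\n"
            )

    venn_path = out_dir / "venn.json"
    with open(venn_path, "w") as fh:
        json.dump(
            {
                "venn": report.venn,
                "n_candidates": len(report.candidates),
                "candidates": sorted(report.candidates),
                "excluded": [
                    {"gene": g, "reason": r} for g, r in report.excluded
                ],
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")

    prov_path = out_dir / "provenance.json"
    with open(prov_path, "w") as fh:
        json.dump(report.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "candidates": str(candidates_path),
        "venn": str(venn_path),
        "provenance": str(prov_path),
    }
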