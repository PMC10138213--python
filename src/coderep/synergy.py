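"""Dose-matrix normalization and HSA (highest single agent) synergy.

The HSA / Gaddum non-interaction reference for a combination well
(a > 0, b > 0) is the better of the two single-agent responses at the
same doses: max(response(a, 0), response(0, b)).  The synergy score is
the mean excess of observed combination response over that reference,
in percentage points, averaged over the both-positive-dose wells only
(the margins have zero excess by definition and would dilute the
score).  A score above 10 flags synergy (strict inequality).

Responses are % inhibition relative to the vehicle well and are not
clipped to [0, 100]; growth stimulation shows up as negative
inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

SYNERGY_THRESHOLD = 10.0


@dataclass
class DoseResponseMatrix:
    """% inhibition on a complete (doses_a x doses_b) grid including 0."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    response: np.ndarray

    def __post_init__(self):
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.response.shape != (self.doses_a.size, self.doses_b.size):
            raise ValidationError(
                f"response shape {self.response.shape} does not match dose grids "
                f"({self.doses_a.size} x {self.doses_b.size})"
            )
        if not np.isfinite(self.response).all():
            raise ValidationError("response matrix contains non-finite wells")
        # canonical dose ordering
        ia, ib = np.argsort(self.doses_a), np.argsort(self.doses_b)
        self.doses_a = self.doses_a[ia]
        self.doses_b = self.doses_b[ib]
        self.response = self.response[np.ix_(ia, ib)]
        for name, grid in (("a", self.doses_a), ("b", self.doses_b)):
            if grid[0] != 0:
                raise ValidationError(f"dose grid {name} must include 0")
            if np.any(np.diff(grid) <= 0):
                raise ValidationError(f"dose grid {name} must strictly increase")


@dataclass
class SynergyResult:
    reference: np.ndarray  # HSA reference over both-positive wells
    excess: np.ndarray  # response - reference, percentage points
    score: float  # mean excess

    @property
    def synergistic(self) -> bool:
        return classify_synergy(self)


def normalize_viability(
    raw: np.ndarray, doses_a, doses_b, vehicle: float | None = None
) -> DoseResponseMatrix:
    """Convert raw viability signal to % inhibition vs the vehicle well.

    % inhibition = 100 * (1 - raw / vehicle); the vehicle defaults to
    the (0, 0) well.  Negative inhibition is preserved, not clipped.
    """
    raw = np.asarray(raw, dtype=float)
    if vehicle is None:
        ia = int(np.argsort(np.asarray(doses_a, float))[0])
        ib = int(np.argsort(np.asarray(doses_b, float))[0])
        vehicle = raw[ia, ib]
    if vehicle <= 0:
        raise ValidationError(f"vehicle signal must be positive (got {vehicle})")
    return DoseResponseMatrix(
        doses_a=doses_a, doses_b=doses_b, response=100.0 * (1.0 - raw / vehicle)
    )


def average_matrices(matrices) -> DoseResponseMatrix:
    """Well-wise mean of replicate dose matrices (same grids required)."""
    matrices = list(matrices)
    if not matrices:
        raise ValidationError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if not (
            np.array_equal(m.doses_a, first.doses_a)
            and np.array_equal(m.doses_b, first.doses_b)
        ):
            raise ValidationError("replicate matrices have mismatched dose grids")
    mean = np.mean([m.response for m in matrices], axis=0)
    return DoseResponseMatrix(first.doses_a, first.doses_b, mean)


def hsa_score(matrix: DoseResponseMatrix) -> SynergyResult:
    """HSA synergy: mean excess over the best single agent, both-positive wells."""
    if matrix.doses_a.size < 2 or matrix.doses_b.size < 2:
        raise ValidationError("need single-agent margins plus >=1 positive dose each")
    resp = matrix.response
    a_margin = resp[1:, 0]  # response(a, 0) for a > 0
    b_margin = resp[0, 1:]  # response(0, b) for b > 0
    reference = np.maximum.outer(a_margin, b_margin)
    excess = resp[1:, 1:] - reference
    return SynergyResult(
        reference=reference, excess=excess, score=float(excess.mean())
    )


def classify_synergy(result: SynergyResult, threshold: float = SYNERGY_THRESHOLD) -> bool:
    """True iff score > threshold, strictly."""
    return bool(result.score > threshold)
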