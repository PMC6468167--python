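"""DSBs per genome from circular-chromosome gel band intensities.

A circular chromosome reporter stays in the well of a pulsed-field gel;
any double-strand break linearizes it and the molecule enters the gel as a
linear band.  With breaks Poisson-distributed along the molecule at rate
``lambda`` per kb, the linearized fraction of a circle of length ``L`` is
``f = 1 - exp(-lambda * L)``, so ``lambda = -ln(1 - f) / L`` and the
genome-wide DSB count is ``lambda * genome_kb``.  Background breakage in
untreated samples is subtracted on the lambda scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["GelLaneQuant", "fraction_broken", "dsbs_per_genome",
           "DEFAULT_CIRCLE_KB", "DEFAULT_GENOME_KB"]

DEFAULT_CIRCLE_KB = 320.0   # linear band position of the circular chromosome III derivative
DEFAULT_GENOME_KB = 12_070.0  # haploid genome assayed by the reporter strain

_SATURATION_TOL = 1e-9


class SaturationError(ValueError):
    """Breakage fraction at or above 1; the Poisson estimate diverges."""


@dataclass(frozen=True)
class GelLaneQuant:
    """Quantified band signals for one gel lane.

    ``signal_well`` — intact circular molecules retained in the well;
    ``signal_linear`` — the linearized-circle band; ``signal_control`` —
    a linear chromosome carrying the same probe, used as loading control.
    """

    signal_well: float
    signal_linear: float
    signal_control: float
    label: str = ""
    dose_mM: float = 0.0

    def __post_init__(self) -> None:
        if min(self.signal_well, self.signal_linear) < 0 or self.signal_control <= 0:
            raise ValueError("signals must be >= 0 with a positive loading control")


def fraction_broken(
    lane: GelLaneQuant, lane_full_linear: GelLaneQuant | None = None
) -> float:
    """Fraction of circular molecules linearized in one lane.

    The linear-band/loading-control ratio is divided by the same ratio at
    complete linearization ``c`` — taken from a calibration lane if given,
    otherwise from the lane itself as ``(linear + well) / control`` (all
    probe signal either still circular or already linear).
    """
    r = lane.signal_linear / lane.signal_control
    if lane_full_linear is not None:
        c = lane_full_linear.signal_linear / lane_full_linear.signal_control
    else:
        total = lane.signal_linear + lane.signal_well
        if total == 0:
            return 0.0
        c = total / lane.signal_control
    if c <= 0:
        return 0.0
    f = min(max(r / c, 0.0), 1.0)
    if f >= 1.0 - _SATURATION_TOL:
        if lane_full_linear is None:
            # self-calibrated: well signal exactly zero -> fully linear
            raise SaturationError("lane fully linearized; DSB estimate unbounded")
        raise SaturationError("lane signal exceeds full-linearization calibration")
    return f


def dsbs_per_genome(
    f: float,
    circle_kb: float = DEFAULT_CIRCLE_KB,
    genome_kb: float = DEFAULT_GENOME_KB,
    f_background: float = 0.0,
) -> float:
    """Convert a linearized fraction into genome-wide DSBs.

    ``lambda = [-ln(1-f) + ln(1-f_background)] / circle_kb`` and the
    result is ``lambda * genome_kb``; the background term removes breaks
    present in untreated samples (handling of DNA during preparation).
    """
    if circle_kb <= 0 or genome_kb <= 0:
        raise ValueError("lengths must be positive")
    if not (0 <= f_background <= f):
        raise ValueError("need 0 <= f_background <= f")
    if f >= 1:
        raise SaturationError("f = 1 gives an infinite estimate")
    lam = (-math.log1p(-f) + math.log1p(-f_background)) / circle_kb
    return lam * genome_kb
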