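"""Ideal-chain polymer arithmetic and acquisition time base.

Long dsDNA in solution is well described as an ideal (Gaussian) coil on
length scales far above the Kuhn length.  The coil's radius of gyration

    Rg = sqrt(L * b / 6)

with contour length ``L = n_bp * rise`` and Kuhn length ``b`` sets the
lateral footprint over which the interferometric signal of a single
molecule is spread, and therefore the blob size the detector must expect.
With the B-DNA rise of 0.34 nm/bp and a Kuhn length of 100 nm (twice the
~50 nm persistence length) this gives ~238 nm for 10 kbp, ~337 nm for
20 kbp and ~522 nm for 48 kbp dsDNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = ["PolymerParams", "radius_of_gyration", "frame_period_ms"]

#: B-form DNA rise per base pair (nm).
DNA_RISE_NM_PER_BP = 0.34
#: Kuhn length of dsDNA at physiological ionic strength (nm).
DNA_KUHN_NM = 100.0


@dataclass(frozen=True)
class PolymerParams:
    """Ideal-chain description of a dsDNA molecule.

    Parameters
    ----------
    n_bp:
        Number of base pairs (``>= 0``).
    rise_nm_per_bp:
        Contour length contributed per base pair, in nm (``> 0``).
    kuhn_nm:
        Kuhn length in nm (``> 0``); twice the persistence length.
    """

    n_bp: int
    rise_nm_per_bp: float = DNA_RISE_NM_PER_BP
    kuhn_nm: float = DNA_KUHN_NM

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.n_bp)
            and math.isfinite(self.rise_nm_per_bp)
            and math.isfinite(self.kuhn_nm)
        ):
            raise InvalidParameterError("polymer parameters must be finite")
        if self.n_bp < 0:
            raise InvalidParameterError(f"n_bp must be >= 0, got {self.n_bp}")
        if self.rise_nm_per_bp <= 0:
            raise InvalidParameterError(
                f"rise_nm_per_bp must be > 0, got {self.rise_nm_per_bp}"
            )
        if self.kuhn_nm <= 0:
            raise InvalidParameterError(f"kuhn_nm must be > 0, got {self.kuhn_nm}")

    @property
    def contour_length_nm(self) -> float:
        """Contour length L = n_bp * rise (nm)."""
        return self.n_bp * self.rise_nm_per_bp


def radius_of_gyration(params: PolymerParams) -> float:
    """Ideal-chain radius of gyration ``sqrt(L * b / 6)`` in nm.

    A zero-length chain has Rg = 0.
    """
    return math.sqrt(params.contour_length_nm * params.kuhn_nm / 6.0)


def frame_period_ms(frame_rate_hz: float) -> float:
    """Frame period in milliseconds for an acquisition rate in Hz.

    At the 90.5 Hz used throughout, this is ~11 ms — the temporal
    resolution of the dwell-time measurements.
    """
    if not math.isfinite(frame_rate_hz) or frame_rate_hz <= 0:
        raise InvalidParameterError(
            f"frame_rate_hz must be a positive finite number, got {frame_rate_hz}"
        )
    return 1000.0 / frame_rate_hz
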