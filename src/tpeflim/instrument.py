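"""Instrument description for TCSPC acquisition under periodic excitation.

A two-photon tomograph excites the sample with a pulsed femtosecond laser
(80 MHz repetition rate) and records photon arrival times into a fixed
number of ADC channels spanning one excitation period.  The instrument
response function (IRF) is modelled as a Gaussian whose full width at half
maximum is below 100 ps, as typical for fast hybrid detectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

#: FWHM of a Gaussian divided by its standard deviation.
_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class InstrumentModel:
    """Acquisition parameters of the TCSPC system.

    Parameters
    ----------
    repetition_rate:
        Laser pulse repetition rate in Hz.  The recorded time window is one
        excitation period, ``1 / repetition_rate`` (12.5 ns at 80 MHz).
    n_channels:
        Number of ADC time channels spanning the window.
    irf_fwhm:
        Full width at half maximum of the Gaussian IRF in ps; must stay
        below 100 ps.
    irf_shift:
        Temporal offset of the IRF peak relative to the nominal time origin,
        in ps.
    background_rate:
        Uncorrelated background, expected counts per channel.
    """

    repetition_rate: float = 8.0e7
    n_channels: int = 256
    irf_fwhm: float = 80.0
    irf_shift: float = 0.0
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.repetition_rate <= 0:
            raise ValueError("repetition_rate must be positive")
        if self.n_channels < 2:
            raise ValueError("n_channels must be at least 2")
        if not 0 < self.irf_fwhm < 100.0:
            raise ValueError(
                f"irf_fwhm must lie in (0, 100) ps, got {self.irf_fwhm}"
            )
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")

    @property
    def window(self) -> float:
        """Measurement window in ps (one excitation period)."""
        return 1.0e12 / self.repetition_rate

    @property
    def channel_width(self) -> float:
        """Width of one ADC channel in ps."""
        return self.window / self.n_channels

    @property
    def irf_sigma(self) -> float:
        """Standard deviation of the Gaussian IRF in ps."""
        return self.irf_fwhm / _FWHM_PER_SIGMA

    @property
    def channel_centers(self):
        """Channel-center times in ps as a numpy array."""
        import numpy as np

        w = self.channel_width
        return (np.arange(self.n_channels) + 0.5) * w

    def with_(self, **kwargs) -> "InstrumentModel":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
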