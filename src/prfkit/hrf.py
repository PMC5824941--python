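"""Hemodynamic response function (HRF) kernels.

The BOLD signal is modeled as neural drive convolved with a slow temporal
kernel. The canonical choice is a double-gamma: a positive gamma density
peaking ~6 s after stimulation minus a scaled, later gamma capturing the
post-stimulus undershoot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma_dist


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma HRF parameters, all in seconds except the ratio.

    The kernel is sampled at the acquisition TR and normalized to unit
    peak, so absolute response scale is carried entirely by the pRF gain.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    peak_undershoot_ratio: float = 6.0
    duration: float = 32.0

    def kernel(self, tr: float) -> np.ndarray:
        """Sample the kernel at resolution ``tr``; peak-normalized."""
        if tr <= 0:
            raise ValueError("tr must be positive")
        t = np.arange(0.0, self.duration, tr)
        peak = _gamma_dist.pdf(t, self.peak_delay / self.peak_disp,
                               scale=self.peak_disp)
        under = _gamma_dist.pdf(t, self.undershoot_delay / self.undershoot_disp,
                                scale=self.undershoot_disp)
        h = peak - under / self.peak_undershoot_ratio
        m = h.max()
        if not np.isfinite(m) or m <= 0:
            raise ValueError("degenerate HRF kernel")
        return h / m
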