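"""Bi-exponential NAD(P)H decay model.

The measured fluorescence decay of NAD(P)H is modelled as a mixture of a
short-lifetime component (free NAD(P)H, ~300-500 ps) and a long-lifetime
component (protein-bound NAD(P)H, ~1.5-2 ns):

    d(t) = alpha1 * exp(-t / tau1) + (1 - alpha1) * exp(-t / tau2)

convolved with the instrument response function and scaled so the expected
total number of signal photons in the window equals ``amplitude``.  The
amplitude-weighted mean lifetime is

    tau_m = alpha1 * tau1 + (1 - alpha1) * tau2.

This module holds the shared forward model; both the simulator and the
fitter call the same function, so the fitted model is by construction
identical to the generating one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .timebase import TimeAxis

__all__ = ["DecayParams", "forward_model", "decay_shape"]


@dataclass(frozen=True)
class DecayParams:
    """Parameters of an IRF-convolved bi-exponential decay.

    Attributes
    ----------
    tau1_ps, tau2_ps : float
        Short (free) and long (protein-bound) lifetimes in ps; tau1 < tau2.
    alpha1 : float
        Fractional amplitude of the short-lifetime component, in [0, 1].
    amplitude : float
        Expected total signal photons over the measurement window.
    offset : float
        Expected background photons per bin.
    """

    tau1_ps: float
    tau2_ps: float
    alpha1: float
    amplitude: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.tau1_ps < self.tau2_ps:
            raise ValueError(
                f"tau1 must be < tau2, got {self.tau1_ps} >= {self.tau2_ps}"
            )
        if self.tau1_ps <= 0:
            raise ValueError("lifetimes must be positive")
        if not 0.0 <= self.alpha1 <= 1.0:
            raise ValueError(f"alpha1 must be in [0, 1], got {self.alpha1}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.offset < 0:
            raise ValueError(f"offset must be >= 0, got {self.offset}")

    @property
    def alpha2(self) -> float:
        return 1.0 - self.alpha1

    @property
    def tau_m_ps(self) -> float:
        """Amplitude-weighted mean lifetime alpha1*tau1 + alpha2*tau2."""
        return self.alpha1 * self.tau1_ps + self.alpha2 * self.tau2_ps

    def with_(self, **kwargs) -> "DecayParams":
        return replace(self, **kwargs)


def decay_shape(
    tau1_ps: float, tau2_ps: float, alpha1: float, axis: TimeAxis
) -> np.ndarray:
    """Un-convolved, un-normalized bi-exponential sampled at the bin times."""
    t = axis.times_ps
    return alpha1 * np.exp(-t / tau1_ps) + (1.0 - alpha1) * np.exp(-t / tau2_ps)


def forward_model(
    params: DecayParams, irf_kernel: np.ndarray, axis: TimeAxis
) -> np.ndarray:
    """Expected photon counts per bin for an IRF-convolved bi-exponential.

    Discrete causal convolution with zero padding (no incomplete-decay
    wrap-around), normalized so the signal integrates to ``amplitude``,
    plus ``offset`` background photons per bin.
    """
    irf_kernel = np.asarray(irf_kernel, dtype=float)
    if irf_kernel.shape != (axis.n_bins,):
        raise ValueError(
            f"irf kernel length {irf_kernel.shape} does not match axis "
            f"n_bins {axis.n_bins}"
        )
    d = decay_shape(params.tau1_ps, params.tau2_ps, params.alpha1, axis)
    curve = np.convolve(irf_kernel, d)[: axis.n_bins]
    total = curve.sum()
    if total > 0:
        curve = curve * (params.amplitude / total)
    return curve + params.offset
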