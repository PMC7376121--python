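"""Forward simulators for 4-pulse DEER and 3-pulse ESEEM time traces.

These generate synthetic data with the statistical structure the analysis
pipelines assume — dipolar oscillations on an exponential intermolecular
background for DEER, nuclear modulations on a stretched-exponential echo
decay for ESEEM — so that every downstream stage can be exercised against a
known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DistanceDistribution, PipelineError, TimeTrace
from .kernel import build_kernel

__all__ = [
    "DeerParameters",
    "EseemParameters",
    "NuclearCoupling",
    "simulate_deer",
    "simulate_3peseem",
    "deer_background",
]


@dataclass
class DeerParameters:
    """Acquisition/sample parameters of a simulated 4-pulse DEER trace.

    mod_depth
        Modulation depth lambda, the intramolecular fraction of the echo
        (0–1); grows with the number of coupled spins and pump efficiency.
    bg_rate
        Intermolecular background decay constant k, per µs.
    bg_dimension
        Background dimensionality d; 3 for a homogeneous 3-D spin bath,
        giving B(t) = exp(-k t^(d/3)).
    noise_sd
        Gaussian noise standard deviation as a fraction of V(0).
    time_axis
        Uniform time axis in µs starting at 0.
    """

    mod_depth: float = 0.3
    bg_rate: float = 0.15
    bg_dimension: float = 3.0
    noise_sd: float = 0.01
    time_axis: np.ndarray = field(default_factory=lambda: np.arange(0, 3.0, 0.008))
    freq_GHz: float = 34.0
    g_value: float = 2.006

    def __post_init__(self) -> None:
        if not 0.0 <= self.mod_depth <= 1.0:
            raise PipelineError(f"mod_depth must lie in [0, 1], got {self.mod_depth}")
        if self.noise_sd < 0:
            raise PipelineError("noise_sd must be non-negative")
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if np.any(np.diff(self.time_axis) <= 0):
            raise PipelineError("time axis must be strictly increasing")


@dataclass
class NuclearCoupling:
    """One weakly coupled nuclear species: id, modulation amplitude k (0–1),
    nuclear (Larmor) frequency in MHz."""

    nucleus: str
    k: float
    freq_mhz: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.k <= 1.0:
            raise PipelineError(f"modulation amplitude must lie in [0, 1], got {self.k}")


@dataclass
class EseemParameters:
    """Parameters of a simulated 3-pulse ESEEM trace.

    tau
        First interpulse delay, ns; set near 2/nu_H (~140 ns at X-band) to
        blind-spot the proton modulation.
    T_axis
        Incremented delay T, ns; 12 ns steps by default.
    couplings
        Weakly coupled nuclei contributing product modulations.
    decay
        (amplitude A, time constant tau_d ns, stretch exponent beta) of the
        stretched-exponential echo decay.
    noise_sd
        Gaussian noise sd as a fraction of A, added independently to the
        real and imaginary channels.
    """

    tau: float = 140.0
    T_axis: np.ndarray = field(default_factory=lambda: np.arange(0.0, 4800.0, 12.0))
    couplings: list[NuclearCoupling] = field(default_factory=list)
    decay: tuple[float, float, float] = (1.0, 1500.0, 0.8)
    noise_sd: float = 0.01
    freq_GHz: float = 9.5
    g_value: float = 2.006

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise PipelineError("tau must be positive")
        a, tau_d, beta = self.decay
        if a <= 0 or tau_d <= 0:
            raise PipelineError("decay amplitude and time constant must be positive")
        if not 0.0 < beta <= 2.0:
            raise PipelineError(f"stretch exponent must lie in (0, 2], got {beta}")
        if self.noise_sd < 0:
            raise PipelineError("noise_sd must be non-negative")
        self.T_axis = np.asarray(self.T_axis, dtype=float)


def deer_background(t_us: np.ndarray, rate: float, dimension: float = 3.0, scale: float = 1.0) -> np.ndarray:
    """Intermolecular background B(t) = scale * exp(-k t^(d/3))."""
    t = np.asarray(t_us, dtype=float)
    return scale * np.exp(-rate * np.abs(t) ** (dimension / 3.0))


def simulate_deer(
    pr: DistanceDistribution,
    params: DeerParameters,
    seed: int | None = None,
) -> TimeTrace:
    """Forward-simulate a DEER trace from a distance distribution.

    V(t) = B(t) [ (1 - lambda) + lambda * integral K(t, r) P(r) dr ] + noise,
    normalised so V(0) = 1 before noise. Deterministic given ``seed``.
    """
    t = params.time_axis
    kern = build_kernel(t, pr.r)
    # trapezoid weights so the kernel integral matches P(r)'s normalisation
    w = np.full_like(pr.r, pr.dr)
    w[0] = w[-1] = 0.5 * pr.dr
    form = (1.0 - params.mod_depth) + params.mod_depth * (kern.matrix @ (pr.density * w))
    signal = deer_background(t, params.bg_rate, params.bg_dimension) * form
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, params.noise_sd, size=signal.shape)
    meta = {
        "freq_GHz": params.freq_GHz,
        "g_value": params.g_value,
        "time_unit": "us",
        "label": "simulated DEER",
    }
    return TimeTrace(axis=t, real=signal, meta=meta)


def _modulation(T: np.ndarray, tau: float, k: float, freq_mhz: float) -> np.ndarray:
    """Weak-coupling 3pESEEM modulation factor of one nucleus.

    1 - (k/4) * 2 * (1 - cos w*tau)(1 - cos w*(tau+T)) with w = 2 pi nu;
    identically 1 at the blind spots w*tau = 2 pi n.
    """
    omega = 2.0 * np.pi * freq_mhz * 1e-3  # rad/ns
    return 1.0 - 0.5 * k * (1.0 - np.cos(omega * tau)) * (1.0 - np.cos(omega * (tau + T)))


def simulate_3peseem(params: EseemParameters, seed: int | None = None) -> TimeTrace:
    """Forward-simulate a 3-pulse ESEEM trace (real + imaginary channels).

    The echo envelope is the product of per-nucleus weak-coupling modulation
    factors times a stretched-exponential decay A exp(-(T/tau_d)^beta);
    independent Gaussian noise of the same sd goes on each channel.
    """
    T = params.T_axis
    a, tau_d, beta = params.decay
    env = a * np.exp(-((T / tau_d) ** beta))
    for c in params.couplings:
        env = env * _modulation(T, params.tau, c.k, c.freq_mhz)
    imag = np.zeros_like(env)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        env = env + rng.normal(0.0, params.noise_sd * a, size=env.shape)
        imag = imag + rng.normal(0.0, params.noise_sd * a, size=imag.shape)
    meta = {
        "freq_GHz": params.freq_GHz,
        "g_value": params.g_value,
        "tau_ns": params.tau,
        "time_unit": "ns",
        "label": "simulated 3pESEEM",
    }
    return TimeTrace(axis=T, real=env, imag=imag, meta=meta)
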