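"""Simulation of positron-lifetime spectra.

A PALS spectrum is a histogram of positron annihilation times: each decay
channel of the material (p-Ps self-annihilation, free-positron annihilation,
o-Ps pick-off) contributes a normalized exponential with its own lifetime
``tau_i`` and relative intensity ``I_i``, broadened by the Gaussian timing
resolution of the coincidence spectrometer (the instrument response function,
IRF) and sitting on a flat random-coincidence background.  This module builds
the noiseless expectation of such a histogram analytically — each component is
an exponentially modified Gaussian (EMG) integrated over the channel edges —
and draws Poisson counts from it, so that every downstream stage of the
analysis can be exercised against a known ground truth.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import erfc, erfcx

__all__ = [
    "AcquisitionSettings",
    "GroundTruth",
    "ChannelSpectrum",
    "expected_spectrum",
    "simulate_spectrum",
    "truth_from_sample",
    "write_spectrum",
    "read_spectrum",
    "P_PS_VACUUM_LIFETIME_NS",
    "FREE_POSITRON_LIFETIME_NS",
]

#: Vacuum lifetime of para-positronium, used as the default tau_1 (ns).
P_PS_VACUUM_LIFETIME_NS = 0.125
#: Conventional free-positron annihilation lifetime in soft matter (ns).
FREE_POSITRON_LIFETIME_NS = 0.40

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class AcquisitionSettings:
    """Spectrometer acquisition parameters.

    Defaults follow a fast-fast coincidence setup with BaF2 scintillators:
    6.5 ps channels, 8192 channels, 1e6 counts under the curve, a Gaussian
    IRF of 250 ps FWHM, and the time-zero centroid placed at channel 1000 so
    a pre-peak region is available for background estimation.
    """

    channel_width: float = 6.5        # ps per channel
    n_channels: int = 8192
    total_counts: float = 1.0e6
    t0_channel: float = 1000.0        # real channel position of time zero
    irf_fwhm: float = 250.0           # ps, Gaussian FWHM; 0 disables the IRF
    background_fraction: float = 0.0  # fraction of counts in a flat background

    def __post_init__(self) -> None:
        if self.channel_width <= 0:
            raise ValueError("channel_width must be positive")
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.total_counts <= 0:
            raise ValueError("total_counts must be positive")
        if not 0 <= self.t0_channel < self.n_channels:
            raise ValueError("t0_channel must lie within [0, n_channels)")
        if self.irf_fwhm < 0:
            raise ValueError("irf_fwhm must be non-negative")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must lie in [0, 1)")

    @property
    def irf_sigma(self) -> float:
        """Gaussian IRF standard deviation in ps."""
        return self.irf_fwhm * _FWHM_TO_SIGMA


@dataclass(frozen=True)
class GroundTruth:
    """Simulator parameter set: decay components plus an optional source term.

    ``components`` is an ordered tuple of ``(lifetime_ns, intensity)`` pairs
    with strictly increasing lifetimes and intensities summing to one.  The
    optional ``source_term`` models annihilation in the Kapton foil wrapping
    the positron source as one extra exponential carrying the given fraction
    of all counts; sample components are scaled down accordingly.
    """

    components: tuple[tuple[float, float], ...]
    source_term: Optional[tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        comps = tuple((float(t), float(i)) for t, i in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError("at least one decay component is required")
        taus = [t for t, _ in comps]
        if any(t2 <= t1 for t1, t2 in zip(taus, taus[1:])):
            raise ValueError("component lifetimes must be strictly increasing")
        if any(i <= 0 for _, i in comps):
            raise ValueError("component intensities must be positive")
        total = sum(i for _, i in comps)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(
                f"component intensities must sum to 1 (got {total!r})"
            )
        if self.source_term is not None:
            s_tau, s_frac = self.source_term
            if s_tau <= 0:
                raise ValueError("source lifetime must be positive")
            if not 0 <= s_frac <= 0.25:
                raise ValueError("source intensity must lie in [0, 0.25]")

    def digest(self) -> str:
        """Short stable hash of the truth parameters (not the seed)."""
        payload = repr((self.components, self.source_term)).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass(frozen=True)
class ChannelSpectrum:
    """A lifetime histogram: integer counts per channel plus acquisition
    metadata.  ``metadata`` carries provenance (seed, truth digest) when the
    spectrum was simulated."""

    counts: np.ndarray
    settings: AcquisitionSettings
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if len(counts) != self.settings.n_channels:
            raise ValueError("counts length must equal n_channels")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    def times_ns(self) -> np.ndarray:
        """Channel-center times relative to t0, in ns."""
        s = self.settings
        idx = np.arange(s.n_channels, dtype=float)
        return (idx - s.t0_channel) * s.channel_width * 1e-3


# ---------------------------------------------------------------------------
# Analytic model: channel-integrated exponentially modified Gaussian
# ---------------------------------------------------------------------------

def _emg_sf(t: np.ndarray, tau: float, sigma: float) -> np.ndarray:
    """Survival function at time ``t`` (relative to the decay start) of an
    exponential with mean ``tau`` convolved with a centered Gaussian of
    width ``sigma``.

    The survival form is used instead of the CDF because channel masses are
    edge differences: far in the tail the CDF saturates at 1 and differencing
    it loses all relative accuracy, while the survival function stays
    magnitude-accurate (the dominant tail term is an explicit exponential,
    with an erfcx-stabilized branch before the peak).
    """
    t = np.asarray(t, dtype=float)
    if sigma <= 0:
        return np.where(t > 0, np.exp(-np.clip(t, 0.0, None) / tau), 1.0)
    z = t / sigma
    k = sigma / tau
    b = (k - z) / _SQRT2
    tail = np.empty_like(z)
    m = b >= 0
    # exp(k^2/2 - k z) * Phi(z - k) == exp(-z^2/2) * erfcx(b) / 2 for b >= 0
    tail[m] = 0.5 * np.exp(-0.5 * z[m] ** 2) * erfcx(b[m])
    tail[~m] = 0.5 * np.exp(0.5 * k * k - k * z[~m]) * erfc(b[~m])
    return 0.5 * erfc(z / _SQRT2) + tail


def component_channel_probs(
    edges_ps: np.ndarray, tau_ps: float, sigma_ps: float
) -> np.ndarray:
    """Per-channel probability mass of one decay component, renormalized over
    the finite acquisition window so long-lived components still sum to one.

    ``edges_ps`` are the n_channels + 1 channel-edge times relative to t0.
    """
    sf = _emg_sf(edges_ps, tau_ps, sigma_ps)
    span = sf[0] - sf[-1]
    if span <= 0:
        raise ValueError("component has no probability mass in the window")
    return np.clip(-np.diff(sf) / span, 0.0, None)


def channel_edges_ps(settings: AcquisitionSettings, t0_channel: float | None = None) -> np.ndarray:
    """Channel-edge times in ps relative to t0 (channel centers at integer
    indices; channel j spans (j - 1/2, j + 1/2))."""
    t0 = settings.t0_channel if t0_channel is None else t0_channel
    idx = np.arange(settings.n_channels + 1, dtype=float) - 0.5
    return (idx - t0) * settings.channel_width


def _effective_components(truth: GroundTruth) -> list[tuple[float, float]]:
    """Fold the source term in as one extra component; fractions sum to 1."""
    comps = [(t, i) for t, i in truth.components]
    if truth.source_term is not None:
        s_tau, s_frac = truth.source_term
        comps = [(t, i * (1.0 - s_frac)) for t, i in comps]
        comps.append((s_tau, s_frac))
    return comps


def expected_spectrum(
    settings: AcquisitionSettings, truth: GroundTruth
) -> np.ndarray:
    """Noiseless expected counts per channel.

    Each component contributes ``total_counts * (1 - b) * f_i`` counts spread
    over the window according to its channel-integrated EMG; a flat background
    carries the remaining fraction ``b``.  The sum over channels equals
    ``total_counts`` exactly because components are renormalized over the
    finite window.
    """
    for tau_ns, _ in truth.components:
        if tau_ns * 1e3 < 0.1 * settings.channel_width:
            raise ValueError(
                f"lifetime {tau_ns} ns is shorter than one-tenth of a channel "
                "width and cannot be resolved"
            )
    edges = channel_edges_ps(settings)
    sigma = settings.irf_sigma
    signal = np.zeros(settings.n_channels)
    for tau_ns, frac in _effective_components(truth):
        signal += frac * component_channel_probs(edges, tau_ns * 1e3, sigma)
    b = settings.background_fraction
    return settings.total_counts * (
        (1.0 - b) * signal + b / settings.n_channels
    )


def simulate_spectrum(
    settings: AcquisitionSettings, truth: GroundTruth
) -> ChannelSpectrum:
    """Draw one Poisson realization of the expected spectrum.

    Deterministic for fixed ``(settings, truth)`` — the generator is seeded
    from ``truth.seed`` alone, so the same inputs give bit-identical spectra.
    """
    mu = expected_spectrum(settings, truth)
    rng = np.random.default_rng(truth.seed)
    counts = rng.poisson(mu)
    meta = {"seed": truth.seed, "truth_digest": truth.digest()}
    return ChannelSpectrum(counts=counts, settings=settings, metadata=meta)


def truth_from_sample(
    tau3_ns: float,
    i3_percent: float,
    *,
    tau1_ns: float = P_PS_VACUUM_LIFETIME_NS,
    tau2_ns: float = FREE_POSITRON_LIFETIME_NS,
    seed: int = 0,
    source_term: Optional[tuple[float, float]] = None,
) -> GroundTruth:
    """Build a three-component ground truth from a reported (tau3, I3) pair.

    The p-Ps intensity follows the 1:3 spin-statistics split of positronium
    formation (I1 = I3 / 3), tau1 defaults to the vacuum p-Ps lifetime and
    tau2 to a conventional free-positron value; the free-positron channel
    absorbs the remainder (I2 = 1 - I1 - I3).  With I3 = 0 no positronium
    forms at all and the truth degenerates to the free-positron component
    alone (zero-intensity components are dropped).
    """
    i3 = i3_percent / 100.0
    if i3 < 0:
        raise ValueError("I3 must be non-negative")
    if i3_percent >= 75.0:
        raise ValueError(
            "I3 >= 75% would make the free-positron intensity negative "
            "under the 1:3 p-Ps:o-Ps split"
        )
    i1 = i3 / 3.0
    i2 = 1.0 - i1 - i3
    comps = [(tau1_ns, i1), (tau2_ns, i2), (tau3_ns, i3)]
    comps = [(t, i) for t, i in comps if i > 0]
    return GroundTruth(
        components=tuple(comps), source_term=source_term, seed=seed
    )


# ---------------------------------------------------------------------------
# Plain-text spectrum files
# ---------------------------------------------------------------------------

_META_FIELDS = (
    "channel_width_ps",
    "n_channels",
    "total_counts",
    "t0_channel",
    "irf_fwhm_ps",
    "background_fraction",
)


def write_spectrum(spectrum: ChannelSpectrum, path: str | Path) -> None:
    """Write a spectrum as '#'-prefixed metadata lines followed by two
    whitespace-separated columns: 0-based channel index and integer counts.

    Channel times are channel-center based: t = (index - t0_channel) *
    channel_width.
    """
    s = spectrum.settings
    path = Path(path)
    lines = [
        f"# channel_width_ps {s.channel_width!r}",
        f"# n_channels {s.n_channels}",
        f"# total_counts {s.total_counts!r}",
        f"# t0_channel {s.t0_channel!r}",
        f"# irf_fwhm_ps {s.irf_fwhm!r}",
        f"# background_fraction {s.background_fraction!r}",
    ]
    for key, value in sorted(spectrum.metadata.items()):
        lines.append(f"# {key} {value}")
    body = "\n".join(
        f"{j} {int(c)}" for j, c in enumerate(spectrum.counts)
    )
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_spectrum(path: str | Path) -> ChannelSpectrum:
    """Read a spectrum written by :func:`write_spectrum` (lossless round
    trip for counts and acquisition metadata)."""
    path = Path(path)
    meta: dict[str, str] = {}
    channels: list[int] = []
    counts: list[int] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split(None, 1)
            if len(parts) == 2:
                meta[parts[0]] = parts[1]
            continue
        j, c = line.split()
        channels.append(int(j))
        counts.append(int(c))
    missing = [f for f in _META_FIELDS if f not in meta]
    if missing:
        raise ValueError(f"spectrum file {path} lacks metadata: {missing}")
    settings = AcquisitionSettings(
        channel_width=float(meta["channel_width_ps"]),
        n_channels=int(meta["n_channels"]),
        total_counts=float(meta["total_counts"]),
        t0_channel=float(meta["t0_channel"]),
        irf_fwhm=float(meta["irf_fwhm_ps"]),
        background_fraction=float(meta["background_fraction"]),
    )
    if channels != list(range(settings.n_channels)):
        raise ValueError(f"spectrum file {path} has non-contiguous channels")
    extra = {
        k: v for k, v in meta.items() if k not in _META_FIELDS
    }
    return ChannelSpectrum(
        counts=np.asarray(counts, dtype=np.int64),
        settings=settings,
        metadata=extra,
    )
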