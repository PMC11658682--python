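"""Wake descriptors: spectra, Strouhal relations, L-moments, periodicity, TKE.

The periodicity score is the L-kurtosis (fourth L-moment ratio,
``tau4 = l4 / l2``) of the one-sided FFT amplitude spectrum of the
cross-stream velocity ``u_y`` at a probe.  A spectrum dominated by a
single shedding peak is a heavy-tailed sample of amplitude values and
scores high; broadband noise scores low.  L-moments are used instead of
conventional moments because their ratios are bounded and robust.

Spectral conventions: the signal is mean-subtracted, no window is
applied, the spectrum is one-sided amplitude, and the zero-frequency bin
is excluded both from the peak search and from the L-kurtosis sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from .field import VelocityField
from .geometry import NU_WATER_15C, ArrayGeometry


class NoDominantFrequencyError(ValueError):
    """Raised when a signal has no spectral content above numerical noise."""


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectrumResult:
    """One-sided amplitude spectrum with its dominant component.

    ``frequencies`` are in Hz for temporal input or cycles/m for spatial
    input; the zero-frequency bin is excluded.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    dominant_frequency: float
    dominant_amplitude: float
    resolution: float


def compute_spectrum(signal: np.ndarray, dt: float) -> SpectrumResult:
    """One-sided amplitude spectrum of a uniformly sampled series.

    The mean is subtracted before the FFT and the zero bin is dropped.
    The dominant frequency is the bin of maximal amplitude; ties break
    toward the lower frequency.

    Raises
    ------
    NoDominantFrequencyError
        If all spectral amplitudes are below 1e-12 of the signal scale
        (e.g. a constant series).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if signal.size < 64:
        raise ValueError(f"need >= 64 samples for a spectrum, got {signal.size}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")

    n = signal.size
    centered = signal - signal.mean()
    spec = np.fft.rfft(centered)
    freqs = np.fft.rfftfreq(n, d=dt)
    amps = np.abs(spec) / n
    amps[1:] *= 2.0
    if n % 2 == 0:
        amps[-1] /= 2.0  # Nyquist bin is not doubled
    freqs, amps = freqs[1:], amps[1:]

    scale = max(float(np.max(np.abs(centered))), np.finfo(float).tiny)
    if np.all(amps < 1e-12 * scale) or scale <= np.finfo(float).tiny:
        raise NoDominantFrequencyError(
            "signal has no spectral content above numerical noise"
        )
    k = int(np.argmax(amps))  # argmax returns the first (lowest-frequency) max
    return SpectrumResult(
        frequencies=freqs,
        amplitudes=amps,
        dominant_frequency=float(freqs[k]),
        dominant_amplitude=float(amps[k]),
        resolution=float(freqs[0]),
    )


# ---------------------------------------------------------------------------
# Strouhal relations
# ---------------------------------------------------------------------------

def strouhal_number(f: float, D: float, U: float) -> float:
    """St = f*D/U for shedding frequency f, diameter D, local speed U."""
    if D <= 0:
        raise ValueError(f"diameter must be positive, got {D}")
    if U <= 0:
        raise ValueError(f"Strouhal number undefined for U={U}")
    return f * D / U


def blockage_corrected_velocity(Uf: float, W: float, D: float) -> float:
    """Solid-blockage correction U = W*Uf/(W - D).

    Continuity across the tank section blocked by one cylinder diameter:
    the nominal speed ``Uf`` is increased to the effective speed in the
    constricted region of the cylinders.
    """
    if D < 0:
        raise ValueError(f"diameter must be non-negative, got {D}")
    if W <= D:
        raise ValueError(f"tank width W={W} must exceed diameter D={D}")
    return W * Uf / (W - D)


def predict_shedding_frequency(St: float, D: float, Uf: float, W: float) -> float:
    """Shedding frequency f = St*U/D with U blockage-corrected from Uf."""
    if St < 0 or Uf < 0:
        raise ValueError("St and Uf must be non-negative")
    if D <= 0:
        raise ValueError(f"diameter must be positive, got {D}")
    return St * blockage_corrected_velocity(Uf, W, D) / D


def reynolds_number(U: float, D: float, nu: float = NU_WATER_15C) -> float:
    """Re = U*D/nu."""
    if U <= 0 or D <= 0:
        raise ValueError("U and D must be positive")
    if nu <= 0:
        raise ValueError(f"kinematic viscosity must be positive, got {nu}")
    return U * D / nu


# ---------------------------------------------------------------------------
# L-moments
# ---------------------------------------------------------------------------

def sample_l_moments(values, order: int = 4) -> tuple[float, ...]:
    """Unbiased sample L-moments l1..l_order (Hosking's PWM estimators).

    With order statistics ``x_(1) <= ... <= x_(n)`` the probability-
    weighted moments are ``b_r = n^-1 sum_i C(i-1, r)/C(n-1, r) x_(i)``
    and

        l1 = b0
        l2 = 2 b1 - b0
        l3 = 6 b2 - 6 b1 + b0
        l4 = 20 b3 - 30 b2 + 12 b1 - b0
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if not 1 <= order <= 4:
        raise ValueError("order must be between 1 and 4")
    if n < order:
        raise ValueError(f"need at least {order} values for order {order}, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values contain non-finite entries")

    i = np.arange(1, n + 1)
    b = [x.mean()]
    for r in range(1, order):
        w = comb(i - 1, r) / comb(n - 1, r)
        b.append(float(np.mean(w * x)))
    coeffs = [
        (1.0,),
        (-1.0, 2.0),
        (1.0, -6.0, 6.0),
        (-1.0, 12.0, -30.0, 20.0),
    ]
    return tuple(
        float(sum(c * br for c, br in zip(coeffs[k], b)))
        for k in range(order)
    )


@dataclass
class PeriodicityScore:
    """L-kurtosis periodicity of a probe spectrum.

    ``l_kurtosis`` is NaN when the spectrum has no dispersion
    (``l2`` below 1e-12 of the amplitude scale).
    """

    l_kurtosis: float
    l_moments: tuple[float, float, float, float]
    n_bins: int

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.l_kurtosis))


def l_kurtosis(values) -> PeriodicityScore:
    """tau4 = l4/l2 of a sample of (spectrum amplitude) values."""
    lm = sample_l_moments(values, order=4)
    scale = max(float(np.max(np.abs(values))), np.finfo(float).tiny)
    tau4 = lm[3] / lm[1] if lm[1] > 1e-12 * scale else float("nan")
    return PeriodicityScore(l_kurtosis=tau4, l_moments=lm, n_bins=len(values))


def periodicity_score(field: VelocityField, probe: tuple[float, float]) -> PeriodicityScore:
    """L-kurtosis of the u_y amplitude spectrum at a probe location.

    The probe snaps to the nearest grid node.  All retained spectrum
    bins (zero bin excluded) form the L-moment sample, unweighted.
    """
    series = field.probe_series(probe[0], probe[1], "u_y")
    if series.size < 64:
        raise ValueError(f"probe series too short ({series.size} < 64 samples)")
    try:
        spec = compute_spectrum(series, field.dt)
    except NoDominantFrequencyError:
        # flat spectrum: score is undefined by the same rule as l2 ~ 0
        nan = float("nan")
        return PeriodicityScore(nan, (nan, nan, nan, nan), 0)
    return l_kurtosis(spec.amplitudes)


def default_probe(geometry: ArrayGeometry) -> tuple[float, float]:
    """Centerline probe two array pitches downstream of the last column."""
    return (2.0 * geometry.streamwise_pitch, 0.0)


# ---------------------------------------------------------------------------
# wavelength and TKE
# ---------------------------------------------------------------------------

def wake_wavelength(field: VelocityField, t: float, y_line: float = 0.0) -> float:
    """Instantaneous wake wavelength from the spatial FFT of u_y.

    Takes u_y along the streamwise line at height ``y_line`` at the time
    sample nearest ``t`` and returns one over the dominant spatial
    frequency, in meters.
    """
    it = int(np.argmin(np.abs(field.t - t)))
    iy = int(np.argmin(np.abs(field.y - y_line)))
    line = field.u_y[it, iy, :]
    if line.size < 64:
        raise ValueError(f"streamwise line too short ({line.size} < 64 samples)")
    try:
        spec = compute_spectrum(line, field.dx)
    except NoDominantFrequencyError as err:
        raise NoDominantFrequencyError("no dominant wavelength: " + str(err)) from err
    return 1.0 / spec.dominant_frequency


def turbulent_kinetic_energy(
    field: VelocityField,
    region: tuple[float, float, float, float] | None = None,
) -> float:
    """Region-averaged TKE, m^2/s^2.

    Per grid node the fluctuations are taken about that node's time
    mean; TKE is the time mean of ``0.5*(ux'^2 + uy'^2)``, then averaged
    over the region (``(x_min, x_max, y_min, y_max)``; whole grid when
    omitted).
    """
    if field.t.size < 2:
        raise ValueError("need at least 2 time samples for TKE")
    ux = field.u_x - field.u_x.mean(axis=0, keepdims=True)
    uy = field.u_y - field.u_y.mean(axis=0, keepdims=True)
    tke = 0.5 * (ux**2 + uy**2).mean(axis=0)
    if region is not None:
        x0, x1, y0, y1 = region
        mx = (field.x >= x0) & (field.x <= x1)
        my = (field.y >= y0) & (field.y <= y1)
        if not (mx.any() and my.any()):
            raise ValueError(f"region {region} contains no grid nodes")
        tke = tke[np.ix_(my, mx)]
    return float(tke.mean())
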