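"""Parametric target spectra for the synthetic sedated-ICU EEG generator.

A :class:`SpectralProfile` is a piecewise power-law power spectrum over
0.5–40 Hz described by clinical band fractions (delta/theta/alpha/beta)
over a normalization range, plus two reconciliation parameters:

``subdelta_mass``
    the share of total power lying *below* the normalization range.
    Published group tables report band fractions normalized over the
    band union together with SEF95 values that are impossible under
    that normalization alone (cumulative power at the printed SEF95 is
    far from 95%); heavy sub-delta slow activity, ubiquitous in sedated
    patients but excluded from the band fractions, reconciles the two.
``in_band_tilt``
    a power-law exponent shaping the spectrum *within* each band,
    which tunes ratio features (RAV) that cut across band boundaries
    without moving the band fractions themselves.

Calibration (:func:`calibrate_profile`) solves one of these free
parameters — or the amplitude scale, for aEEG targets — so the profile's
theoretical feature value equals a published group value; the synthetic
generator then produces recordings whose extracted features recover it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .features import DEFAULT_CONFIG, FeatureConfig
from .preprocessing import bandpass_power_weight

#: Hard spectral support of every profile (Hz): the analysis band-pass.
SUPPORT = (0.5, 40.0)

_GRID_DF = 0.002  # Hz; fine-grid step for theoretical feature integrals


@dataclass(frozen=True)
class SpectralProfile:
    """Piecewise power-law target spectrum for one subject group.

    Parameters
    ----------
    band_edges
        Strictly increasing frequency breakpoints (Hz) of the clinical
        bands, e.g. ``(1, 4, 8, 13, 30)`` for delta/theta/alpha/beta.
    band_fractions
        Power share of each band over ``normalization_range``; must sum
        to 1.
    normalization_range
        ``(lo, hi)`` Hz over which the fractions are defined.
    subdelta_mass
        Share of *total* 0.5–40 Hz power lying in ``[0.5, lo)``,
        excluded from the fraction normalization but included in
        SEF/entropy/aEEG physics.
    in_band_tilt
        Exponent ``t`` of the within-band shape ``S(f) ∝ f**t``.
    amplitude_scale
        Target RMS amplitude of the synthesized signal, µV.
    """

    band_edges: tuple[float, ...]
    band_fractions: tuple[float, ...]
    normalization_range: tuple[float, float]
    subdelta_mass: float = 0.0
    in_band_tilt: float = 0.0
    amplitude_scale: float = 10.0

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.band_edges)
        fracs = tuple(float(f) for f in self.band_fractions)
        if len(fracs) != len(edges) - 1:
            raise ValueError("need exactly one fraction per band")
        if any(np.diff(edges) <= 0):
            raise ValueError("band edges must be strictly increasing")
        if any(f < 0 for f in fracs):
            raise ValueError("band fractions must be nonnegative")
        # printed clinical tables round each fraction to ~4 significant
        # digits, so sums off by up to 1e-3 are accepted and renormalized
        if abs(sum(fracs) - 1.0) > 1e-3:
            raise ValueError(
                f"band fractions must sum to 1 (got {sum(fracs):.8f}); "
                "renormalize before building the profile"
            )
        lo, hi = self.normalization_range
        if not (SUPPORT[0] <= lo < hi <= SUPPORT[1]):
            raise ValueError(
                f"normalization range must lie within {SUPPORT} Hz"
            )
        if edges[0] < lo - 1e-9 or edges[-1] > hi + 1e-9:
            raise ValueError("bands must lie inside the normalization range")
        if not 0.0 <= self.subdelta_mass < 1.0:
            raise ValueError("subdelta_mass must be in [0, 1)")
        if self.subdelta_mass > 0 and lo <= SUPPORT[0]:
            raise ValueError(
                "subdelta_mass requires headroom below the normalization range"
            )
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        # exact renormalization (fractions may carry rounding error <= 1e-6)
        total = sum(fracs)
        object.__setattr__(self, "band_fractions", tuple(f / total for f in fracs))
        object.__setattr__(self, "band_edges", edges)
        object.__setattr__(
            self, "normalization_range", (float(lo), float(hi))
        )

    # -- piecewise segments -------------------------------------------------
    def segments(self) -> list[tuple[float, float, float, float]]:
        """``(f_lo, f_hi, mass, tilt)`` per spectral piece; masses sum to 1.

        The sub-delta piece spans ``[0.5, normalization_lo)`` with a
        flat shape; band pieces carry ``(1 - subdelta_mass) * fraction``
        shaped as ``f**tilt``.
        """
        m = self.subdelta_mass
        segs: list[tuple[float, float, float, float]] = []
        if m > 0:
            segs.append((SUPPORT[0], self.normalization_range[0], m, 0.0))
        for lo, hi, frac in zip(
            self.band_edges[:-1], self.band_edges[1:], self.band_fractions
        ):
            segs.append((lo, hi, (1.0 - m) * frac, self.in_band_tilt))
        return segs

    def density(self, freqs: np.ndarray) -> np.ndarray:
        """Unit-mass spectral density (per Hz) evaluated at ``freqs``."""
        freqs = np.asarray(freqs, dtype=float)
        out = np.zeros_like(freqs)
        segs = self.segments()
        top = max(hi for _, hi, _, _ in segs)
        for lo, hi, mass, tilt in segs:
            if mass == 0.0:
                continue
            norm = _powlaw_integral(lo, hi, tilt)
            # half-open pieces, but the global top edge is closed so the
            # spectrum's last grid point carries its density
            sel = (freqs >= lo) & ((freqs < hi) | (hi == top) & (freqs == hi))
            out[sel] += mass * freqs[sel] ** tilt / norm
        return out


def _powlaw_integral(lo: float, hi: float, tilt: float) -> float:
    if abs(tilt + 1.0) < 1e-12:
        return float(np.log(hi / lo))
    return float((hi ** (tilt + 1) - lo ** (tilt + 1)) / (tilt + 1))


def make_band_profile(
    band_fractions,
    band_edges=(1.0, 4.0, 8.0, 13.0, 30.0),
    normalization_range: tuple[float, float] | None = None,
    amplitude_scale: float = 10.0,
) -> SpectralProfile:
    """Profile from clinical band fractions alone.

    ``normalization_range`` defaults to the band union; the returned
    profile has no sub-delta mass and a flat within-band shape, so its
    theoretical spectrum integrates to exactly the requested fraction
    over each band.
    """
    if normalization_range is None:
        normalization_range = (float(band_edges[0]), float(band_edges[-1]))
    return SpectralProfile(
        band_edges=tuple(band_edges),
        band_fractions=tuple(band_fractions),
        normalization_range=normalization_range,
        amplitude_scale=amplitude_scale,
    )


# ---------------------------------------------------------------------------
# theoretical (closed-form / fine-grid) features of a profile
# ---------------------------------------------------------------------------

def _segment_grid(profile: SpectralProfile, extra: tuple[float, ...] = ()) -> np.ndarray:
    """Fine frequency grid aligned to every segment breakpoint."""
    points = {SUPPORT[0], SUPPORT[1], *extra}
    for lo, hi, _, _ in profile.segments():
        points.update((lo, hi))
    knots = sorted(p for p in points if SUPPORT[0] <= p <= SUPPORT[1])
    pieces = []
    for a, b in zip(knots[:-1], knots[1:]):
        n = max(2, int(np.ceil((b - a) / _GRID_DF)) + 1)
        pieces.append(np.linspace(a, b, n)[:-1])
    pieces.append(np.array([knots[-1]]))
    return np.concatenate(pieces)


def _weighted_density(
    profile: SpectralProfile,
    freqs: np.ndarray,
    power_weight=None,
) -> np.ndarray:
    dens = profile.density(freqs)
    if power_weight is not None:
        dens = dens * power_weight(freqs)
    return dens


def analysis_power_weight(config: FeatureConfig = DEFAULT_CONFIG, fs: float = 256.0):
    """PSD weight function of the analysis band-pass, for calibration."""

    def weight(freqs: np.ndarray) -> np.ndarray:
        return bandpass_power_weight(
            freqs, config.filter_low_hz, config.filter_high_hz, fs, config.filter_order
        )

    return weight


def theoretical_band_fractions(
    profile: SpectralProfile,
    band_edges: tuple[float, ...] | None = None,
    normalization_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Exact band-power fractions of the profile spectrum (closed form)."""
    edges = profile.band_edges if band_edges is None else band_edges
    norm = profile.normalization_range if normalization_range is None else normalization_range

    def mass(a: float, b: float) -> float:
        tot = 0.0
        for lo, hi, m, tilt in profile.segments():
            aa, bb = max(a, lo), min(b, hi)
            if bb > aa and m > 0:
                tot += m * _powlaw_integral(aa, bb, tilt) / _powlaw_integral(lo, hi, tilt)
        return tot

    denom = mass(*norm)
    return np.array([mass(a, b) / denom for a, b in zip(edges[:-1], edges[1:])])


def theoretical_sef(
    profile: SpectralProfile,
    quantile: float = 0.95,
    sef_range: tuple[float, float] = DEFAULT_CONFIG.sef_range,
    power_weight=None,
) -> float:
    """Spectral edge frequency of the theoretical spectrum.

    With ``power_weight`` (e.g. :func:`analysis_power_weight`) the
    spectrum is first multiplied by the analysis chain's PSD transfer,
    modelling what the extractor actually sees.
    """
    grid = _segment_grid(profile, extra=sef_range)
    sel = (grid >= sef_range[0]) & (grid <= sef_range[1])
    f = grid[sel]
    dens = _weighted_density(profile, f, power_weight)
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(f))))
    if cum[-1] <= 0:
        raise ValueError("profile has no power in the SEF range")
    return float(np.interp(quantile * cum[-1], cum, f))


def theoretical_rav(
    profile: SpectralProfile,
    numerator: tuple[float, float] = DEFAULT_CONFIG.rav_numerator,
    denominator: tuple[float, float] = DEFAULT_CONFIG.rav_denominator,
    power_weight=None,
) -> float:
    """Theoretical RAV (%): 6–14 Hz power over 1–20 Hz power."""
    grid = _segment_grid(profile, extra=numerator + denominator)

    def integral(a: float, b: float) -> float:
        sel = (grid >= a) & (grid <= b)
        f = grid[sel]
        dens = _weighted_density(profile, f, power_weight)
        return float(np.trapezoid(dens, f))

    den = integral(*denominator)
    if den <= 0:
        raise ValueError("profile has no power in the RAV denominator range")
    return 100.0 * integral(*numerator) / den


# ---------------------------------------------------------------------------
# expected extractor PSD: analysis-filter transfer + taper-kernel smearing
# ---------------------------------------------------------------------------

def taper_kernel(
    epoch_length_s: float, fs: float, df: float = 0.01, halfwidth_hz: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Expected-periodogram smearing kernel of the Hann-tapered epoch.

    Returns offsets (Hz) and unit-integral weights of the spectral
    window ``|W(f)|²``: the expectation of the tapered periodogram is
    the true PSD convolved with this kernel, which is what smears
    power across band edges.
    """
    n = int(round(epoch_length_s * fs))
    w = np.hanning(n)
    offsets = np.arange(-halfwidth_hz, halfwidth_hz + df / 2, df)
    phase = np.exp(-2j * np.pi * np.outer(offsets / fs, np.arange(n)))
    kernel = np.abs(phase @ w) ** 2
    return offsets, kernel / np.trapezoid(kernel, offsets)


def expected_psd(
    profile: SpectralProfile,
    config: FeatureConfig = DEFAULT_CONFIG,
    fs: float = 256.0,
    df: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected epoch-averaged PSD seen by the extraction chain.

    The profile spectrum is multiplied by the zero-phase band-pass
    power transfer and convolved with the Hann taper kernel (with the
    negative-frequency image folded in), giving the expectation of
    :func:`qeegpod.features.power_spectrum` up to estimation noise.
    Used by :func:`calibrate_profile` so calibrated targets are
    centered on what the extractor reports, not on the ideal spectrum.
    """
    f_hi = SUPPORT[1] + 6.0
    freqs = np.arange(0.0, f_hi + df / 2, df)
    dens = profile.density(freqs) * analysis_power_weight(config, fs)(freqs)
    offsets, kernel = taper_kernel(config.epoch_length_s, fs, df=df)
    # fold in the negative-frequency image before convolving
    full_f = np.concatenate((-freqs[:0:-1], freqs))
    full_d = np.concatenate((dens[:0:-1], dens))
    smeared = np.convolve(full_d, kernel, mode="same") * df
    return freqs, smeared[len(freqs) - 1 :]


def _sef_of_grid(
    freqs: np.ndarray,
    dens: np.ndarray,
    quantile: float,
    sef_range: tuple[float, float],
    resample_hz: float | None = None,
) -> float:
    if resample_hz is not None:
        # evaluate on the extractor's own periodogram grid so that its
        # coarse-grid trapezoid integration is modelled too
        grid = np.arange(0.0, freqs[-1] + resample_hz / 2, resample_hz)
        dens = np.interp(grid, freqs, dens)
        freqs = grid
    sel = (freqs >= sef_range[0]) & (freqs <= sef_range[1])
    f, d = freqs[sel], dens[sel]
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (d[1:] + d[:-1]) * np.diff(f))))
    if cum[-1] <= 0:
        raise ValueError("no power in the SEF range")
    return float(np.interp(quantile * cum[-1], cum, f))


def _ratio_of_grid(
    freqs: np.ndarray,
    dens: np.ndarray,
    numerator: tuple[float, float],
    denominator: tuple[float, float],
) -> float:
    def integral(a: float, b: float) -> float:
        sel = (freqs >= a) & (freqs <= b)
        return float(np.trapezoid(dens[sel], freqs[sel]))

    return 100.0 * integral(*numerator) / integral(*denominator)


_AEEG_CAL_SEED = 20220101  # fixed internal seed of the deterministic aEEG reference
_AEEG_CAL_DURATION_S = 120.0
_AEEG_CAL_N_AVG = 3


def theoretical_aeeg_upper(
    profile: SpectralProfile,
    config: FeatureConfig = DEFAULT_CONFIG,
    fs: float = 256.0,
) -> float:
    """Expected aEEG upper limit (µV) of recordings from this profile.

    The aEEG envelope percentile of band-weighted Gaussian noise has no
    closed form, but it is exactly linear in the amplitude scale, so the
    reference value is computed once per spectral shape by running the
    full aEEG chain on fixed-seed unit-amplitude reference syntheses
    (three 120 s realizations, channel- and realization-averaged) and
    rescaled analytically.
    """
    from .simulate import synthesize_recording  # local import: avoids cycle
    from .features import aeeg_limits

    unit = replace(profile, amplitude_scale=1.0)
    uppers = []
    for k in range(_AEEG_CAL_N_AVG):
        rec = synthesize_recording(
            unit, duration_s=_AEEG_CAL_DURATION_S, fs=fs, seed=_AEEG_CAL_SEED + k
        )
        from .features import preprocess

        filtered, _ = preprocess(rec, config)
        _, upper = aeeg_limits(filtered, config)
        uppers.append(float(upper.loc["mean"]))
    return float(np.mean(uppers)) * profile.amplitude_scale


class CalibrationError(ValueError):
    """Requested feature target is unattainable for this profile."""


def calibrate_profile(
    profile: SpectralProfile,
    target_feature_name: str,
    target_value: float,
    config: FeatureConfig = DEFAULT_CONFIG,
    fs: float = 256.0,
    model_extraction_chain: bool = True,
) -> SpectralProfile:
    """Solve one free parameter so a theoretical feature hits a target.

    ``sef95`` targets are met by adding sub-delta mass (monotone
    decreasing in SEF95), ``rav`` targets by tilting the within-band
    shape, and ``aeeg_upper`` targets by rescaling the amplitude; band
    fractions over the normalization range are preserved in every mode.
    With ``model_extraction_chain`` (default) the theoretical spectral
    features are computed on the :func:`expected_psd` — the profile
    spectrum as the extraction chain sees it, band-pass transfer and
    taper smearing included — so the calibrated target is centered on
    what :func:`~qeegpod.features.extract_features` recovers.  With the
    flag off, calibration uses the ideal (unfiltered) spectrum.

    Raises
    ------
    CalibrationError
        When no parameter value can reach the target; the message names
        the attainable range.
    """

    if target_feature_name == "sef95":
        def sef_of(m: float) -> float:
            prof = replace(profile, subdelta_mass=m)
            if model_extraction_chain:
                return _sef_of_grid(
                    *expected_psd(prof, config, fs),
                    config.sef_quantile,
                    config.sef_range,
                    resample_hz=1.0 / config.epoch_length_s,
                )
            return theoretical_sef(prof, config.sef_quantile, config.sef_range)

        current = sef_of(profile.subdelta_mass)
        if abs(current - target_value) <= 1e-9 * max(1.0, abs(target_value)):
            return profile
        m_hi = 1.0 - 1e-9
        lo_val, hi_val = sef_of(m_hi), sef_of(0.0)
        if not lo_val <= target_value <= hi_val:
            raise CalibrationError(
                f"SEF95 target {target_value:.4g} Hz unattainable; attainable "
                f"range for this profile is [{lo_val:.4g}, {hi_val:.4g}] Hz"
            )
        m = optimize.brentq(
            lambda m: sef_of(m) - target_value, 0.0, m_hi, xtol=1e-12, rtol=1e-14
        )
        return replace(profile, subdelta_mass=float(m))

    if target_feature_name == "rav":
        def rav_of(t: float) -> float:
            prof = replace(profile, in_band_tilt=t)
            if model_extraction_chain:
                return _ratio_of_grid(
                    *expected_psd(prof, config, fs),
                    config.rav_numerator,
                    config.rav_denominator,
                )
            return theoretical_rav(prof, config.rav_numerator, config.rav_denominator)

        current = rav_of(profile.in_band_tilt)
        if abs(current - target_value) <= 1e-9 * max(1.0, abs(target_value)):
            return profile
        tilts = np.linspace(-12.0, 12.0, 49)
        vals = np.array([rav_of(t) - target_value for t in tilts])
        sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        if sign_change.size == 0:
            raise CalibrationError(
                f"RAV target {target_value:.4g}% unattainable; attainable range "
                f"under tilt in [-12, 12] is "
                f"[{min(vals) + target_value:.4g}, {max(vals) + target_value:.4g}]%"
            )
        i = int(sign_change[0])
        t = optimize.brentq(
            lambda t: rav_of(t) - target_value, tilts[i], tilts[i + 1],
            xtol=1e-12, rtol=1e-14,
        )
        return replace(profile, in_band_tilt=float(t))

    if target_feature_name == "aeeg_upper":
        if target_value <= 0:
            raise CalibrationError("aEEG upper-limit target must be positive")
        current = theoretical_aeeg_upper(profile, config, fs)
        if abs(current - target_value) <= 1e-9 * max(1.0, abs(target_value)):
            return profile
        scale = target_value / current
        return replace(profile, amplitude_scale=profile.amplitude_scale * scale)

    raise ValueError(
        f"unknown calibration target {target_feature_name!r}; "
        "expected one of 'sef95', 'rav', 'aeeg_upper'"
    )
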