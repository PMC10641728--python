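"""Reference group profiles of the motivating delirium study.

A prospective observational study of 46 sedated postoperative ICU
patients (24 after cardiopulmonary-bypass cardiac surgery, 22 after
major non-cardiac surgery; within the cardiac arm, 10 delirious vs 14
non-delirious by CAM-ICU) published group-level qEEG summaries
(mean ± SEM of 8-channel averages).  This module encodes those printed
group values and turns them into calibrated
:class:`~qeegpod.profiles.SpectralProfile` / cohort specifications, so
synthetic cohorts with the published group structure can be generated
and re-analyzed end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .features import DEFAULT_CONFIG, FeatureConfig
from .profiles import SpectralProfile, calibrate_profile, make_band_profile
from .simulate import CohortSpec, GroupSpec


@dataclass(frozen=True)
class GroupTarget:
    """Printed qEEG summary of one study arm (means with SEMs)."""

    label: str
    n: int
    band_percents: tuple[float, float, float, float]  # delta/theta/alpha/beta
    band_sems: tuple[float, float, float, float]
    sef95_hz: float
    sef95_sem: float
    rav_percent: float
    rav_sem: float
    aeeg_upper_uv: float
    aeeg_upper_sem: float
    aeeg_lower_uv: float
    aeeg_lower_sem: float
    spectral_entropy: float
    spectral_entropy_sem: float


#: Published group summaries; band fractions are delta/theta/alpha/beta in %.
CARDIAC = GroupTarget(
    label="cardiac", n=24,
    band_percents=(74.95, 9.85, 10.23, 4.97),
    band_sems=(2.32, 0.76, 1.49, 0.77),
    sef95_hz=9.46, sef95_sem=0.75,
    rav_percent=24.92, rav_sem=2.431,
    aeeg_upper_uv=15.01, aeeg_upper_sem=1.09,
    aeeg_lower_uv=9.92, aeeg_lower_sem=0.66,
    spectral_entropy=39.29, spectral_entropy_sem=1.32,
)

NON_CARDIAC = GroupTarget(
    label="non_cardiac", n=22,
    band_percents=(58.49, 11.64, 17.27, 12.61),
    band_sems=(4.15, 0.78, 1.90, 2.35),
    sef95_hz=14.31, sef95_sem=1.01,
    rav_percent=33.38, rav_sem=2.772,
    aeeg_upper_uv=16.38, aeeg_upper_sem=1.54,
    aeeg_lower_uv=11.11, aeeg_lower_sem=1.01,
    spectral_entropy=42.89, spectral_entropy_sem=1.57,
)

DELIRIUM = GroupTarget(
    label="delirium", n=10,
    band_percents=(80.29, 9.85, 6.42, 3.447),
    band_sems=(1.62, 0.56, 1.26, 0.51),
    sef95_hz=7.58, sef95_sem=0.81,
    rav_percent=22.24, rav_sem=3.57,
    aeeg_upper_uv=12.16, aeeg_upper_sem=1.321,
    aeeg_lower_uv=8.23, aeeg_lower_sem=0.84,
    spectral_entropy=38.14, spectral_entropy_sem=1.33,
)

NON_DELIRIUM = GroupTarget(
    label="non_delirium", n=14,
    band_percents=(71.02, 10.87, 11.88, 6.24),
    band_sems=(3.342, 1.12, 2.15, 1.26),
    sef95_hz=10.81, sef95_sem=1.03,
    rav_percent=26.77, rav_sem=3.31,
    aeeg_upper_uv=16.66, aeeg_upper_sem=1.531,
    aeeg_lower_uv=10.84, aeeg_lower_sem=0.92,
    spectral_entropy=39.94, spectral_entropy_sem=1.91,
)

GROUPS: dict[str, GroupTarget] = {
    g.label: g for g in (CARDIAC, NON_CARDIAC, DELIRIUM, NON_DELIRIUM)
}

#: The two published comparisons: surgery type, and delirium within cardiac.
COMPARISONS: dict[str, tuple[GroupTarget, GroupTarget]] = {
    "surgery": (CARDIAC, NON_CARDIAC),
    "delirium": (DELIRIUM, NON_DELIRIUM),
}

#: 2x2 delirium incidence of the study: (events, n) per arm.
DELIRIUM_INCIDENCE = {"cardiac": (10, 24), "non_cardiac": (1, 22)}

#: Clinical band edges of the published fractions (band-union normalized).
TABLE_BAND_EDGES = (1.0, 4.0, 8.0, 13.0, 30.0)


def band_profile(target: GroupTarget, amplitude_scale: float = 10.0) -> SpectralProfile:
    """Band-fraction profile of a study arm (fractions renormalized to 1)."""
    fr = np.asarray(target.band_percents, dtype=float)
    return make_band_profile(
        fr / fr.sum(), TABLE_BAND_EDGES, amplitude_scale=amplitude_scale
    )


def calibrated_profile(
    target: GroupTarget,
    calibrate: tuple[str, ...] = ("sef95", "aeeg_upper"),
    config: FeatureConfig = DEFAULT_CONFIG,
    fs: float = 256.0,
) -> SpectralProfile:
    """Profile matching a study arm's printed values.

    Starts from the arm's band fractions and sequentially calibrates
    the requested features: ``sef95`` (sub-delta mass), ``rav``
    (within-band tilt) and ``aeeg_upper`` (amplitude scale).  Spectral
    calibrations are applied before the amplitude calibration since the
    aEEG reference depends on the spectral shape.
    """
    prof = band_profile(target)
    targets = {
        "sef95": target.sef95_hz,
        "rav": target.rav_percent,
        "aeeg_upper": target.aeeg_upper_uv,
    }
    order = [name for name in ("sef95", "rav", "aeeg_upper") if name in calibrate]
    for name in order:
        prof = calibrate_profile(prof, name, targets[name], config=config, fs=fs)
    return prof


def fraction_dispersion(target: GroupTarget) -> float:
    """Log-jitter SD reproducing the printed delta-band SEM.

    Delta-method inversion of the logistic-normal jitter: for fractions
    ``f`` with common log-SD σ, the delta fraction's SD is approximately
    ``σ f_δ sqrt(1 - 2 f_δ + Σ f_j²)``.  The printed SEM times √n gives
    the between-subject SD to match.
    """
    fr = np.asarray(target.band_percents, dtype=float)
    fr = fr / fr.sum()
    sd_target = target.band_sems[0] * math.sqrt(target.n) / 100.0
    f_d = fr[0]
    factor = f_d * math.sqrt(max(1e-9, 1.0 - 2.0 * f_d + float((fr**2).sum())))
    return sd_target / factor


def amplitude_dispersion(target: GroupTarget) -> float:
    """Log-normal sigma reproducing the printed aEEG-upper SEM."""
    cv = target.aeeg_upper_sem * math.sqrt(target.n) / target.aeeg_upper_uv
    return math.sqrt(math.log(1.0 + cv**2))


def study_cohort_spec(
    comparison: str = "surgery",
    seed: int = 0,
    duration_s: float = 120.0,
    fs: float = 256.0,
    dispersion: str = "matched",
    calibrate: tuple[str, ...] = ("sef95", "aeeg_upper"),
    config: FeatureConfig = DEFAULT_CONFIG,
    n_override: "dict[str, int] | None" = None,
) -> CohortSpec:
    """Cohort specification emulating one of the published comparisons.

    ``comparison`` is ``"surgery"`` (cardiac n=24 vs non-cardiac n=22)
    or ``"delirium"`` (delirious n=10 vs non-delirious n=14 within the
    cardiac arm).  ``dispersion="matched"`` sets between-subject spread
    from the printed SEMs; ``"none"`` gives every subject the group
    mean profile.
    """
    if comparison not in COMPARISONS:
        raise KeyError(
            f"unknown comparison {comparison!r}; expected one of {list(COMPARISONS)}"
        )
    if dispersion not in ("matched", "none"):
        raise ValueError("dispersion must be 'matched' or 'none'")
    groups = []
    for target in COMPARISONS[comparison]:
        n = (n_override or {}).get(target.label, target.n)
        groups.append(
            GroupSpec(
                label=target.label,
                n_subjects=n,
                profile=calibrated_profile(target, calibrate, config, fs),
                fraction_sigma=fraction_dispersion(target) if dispersion == "matched" else 0.0,
                amplitude_sigma=amplitude_dispersion(target) if dispersion == "matched" else 0.0,
            )
        )
    return CohortSpec(
        groups=tuple(groups), duration_s=duration_s, fs=fs, seed=seed
    )
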