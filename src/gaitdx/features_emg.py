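"""19-dimensional time-domain EMG feature bank.

Per muscle segment the canonical vector is, in order: LMAV, NSV, WL, WAMP, SSC,
ZC, MOB, COM, SKW, AR1-AR4, m0, m2, m4, m6, AC1, AC2. Each formula is registered
once here; `emg_feature_vector` is a thin composition of the standalone ops so
every slot can be cross-checked against its scalar function.

Formula conventions (centrally documented, swappable without touching callers):

* LMAV uses the natural log of the mean absolute value.
* NSV is the v-order statistic ``((1/N) sum |x|^v)^(1/v)`` with default v = 3.
* The even "spectral" moments m0/m2/m4/m6 are Parseval time-domain surrogates:
  sums of squared 0th/1st/2nd/3rd differences.
* AC1/AC2 are mean absolute first/second differences.
* Skewness is the biased (population) third standardized moment.
* AR coefficients follow the Yule-Walker sign convention
  ``x_t ≈ sum_k AR_k x_{t-k}`` (Levinson-Durbin via a Toeplitz solve).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_toeplitz

from .errors import ConfigurationError, SegmentTooShortError, UndefinedFeatureError
from .feature_vector import FeatureVector

EMG_FEATURE_NAMES = (
    "LMAV", "NSV", "WL", "WAMP", "SSC", "ZC", "MOB", "COM", "SKW",
    "AR1", "AR2", "AR3", "AR4", "m0", "m2", "m4", "m6", "AC1", "AC2",
)


@dataclass(frozen=True)
class EmgFeatureConfig:
    """Thresholds and orders for the time-domain bank.

    The default thresholds are calibrated for mean-normalized signals:
    theta_wamp = 0.05 amplitude units, theta_zc = theta_ssc = 0.
    """

    theta_wamp: float = 0.05
    theta_zc: float = 0.0
    theta_ssc: float = 0.0
    nsv_order: int = 3
    ar_order: int = 4


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise SegmentTooShortError("empty segment")
    return a


def lmav(x) -> float:
    """Log of the mean absolute value, ln((1/N) sum |x_i|)."""
    a = _as_array(x)
    m = np.abs(a).mean()
    if m == 0.0:
        raise UndefinedFeatureError("LMAV undefined on an all-zero segment")
    return float(np.log(m))


def nsv(x, v: int = 3) -> float:
    """Nonlinear scaled value: the v-order statistic ((1/N) sum |x|^v)^(1/v)."""
    a = _as_array(x)
    return float(np.mean(np.abs(a) ** v) ** (1.0 / v))


def waveform_length(x) -> float:
    """Total path length sum |x_{i+1} - x_i|."""
    a = _as_array(x)
    if a.size < 2:
        raise SegmentTooShortError("waveform length needs >= 2 samples")
    return float(np.abs(np.diff(a)).sum())


def threshold_counts(
    x, theta_wamp: float = 0.05, theta_zc: float = 0.0, theta_ssc: float = 0.0
) -> tuple[int, int, int]:
    """Wilson amplitude, zero-crossing, and slope-sign-change counts.

    WAMP counts first differences with magnitude >= theta_wamp; ZC counts strict
    sign flips whose jump exceeds theta_zc; SSC counts slope reversals whose larger
    adjacent step exceeds theta_ssc.
    """
    if min(theta_wamp, theta_zc, theta_ssc) < 0:
        raise ConfigurationError("thresholds must be non-negative")
    a = _as_array(x)
    if a.size < 3:
        raise SegmentTooShortError("threshold counts need >= 3 samples")
    d = np.diff(a)
    wamp = int(np.count_nonzero(np.abs(d) >= theta_wamp))
    zc = int(np.count_nonzero((a[:-1] * a[1:] < 0) & (np.abs(d) >= theta_zc)))
    left = a[1:-1] - a[:-2]
    right = a[1:-1] - a[2:]
    ssc = int(
        np.count_nonzero(
            (left * right > 0) & (np.maximum(np.abs(left), np.abs(right)) >= theta_ssc)
        )
    )
    return wamp, zc, ssc


def _mobility(a: np.ndarray) -> float:
    v = a.var()
    if v <= 0.0:
        return 0.0
    vd = np.diff(a).var()
    return float(np.sqrt(vd / v))


def hjorth_params(x) -> tuple[float, float]:
    """Hjorth mobility and complexity; degenerate variances map to 0."""
    a = _as_array(x)
    if a.size < 3:
        raise SegmentTooShortError("Hjorth parameters need >= 3 samples")
    mob = _mobility(a)
    if mob == 0.0:
        return 0.0, 0.0
    mob_d = _mobility(np.diff(a))
    return mob, float(mob_d / mob)


def ar_coefficients(x, order: int = 4) -> np.ndarray:
    """Yule-Walker AR coefficients (sign convention x_t ≈ sum_k AR_k x_{t-k})."""
    a = _as_array(x)
    if a.size <= 4 * order:
        raise SegmentTooShortError(f"AR({order}) needs > {4 * order} samples")
    if a.var() == 0.0:
        raise UndefinedFeatureError("AR coefficients undefined on a zero-variance segment")
    n = a.size
    # biased autocorrelation estimates r_0..r_order (no demeaning, MATLAB aryule-style)
    r = np.array([np.dot(a[: n - k], a[k:]) / n for k in range(order + 1)])
    return solve_toeplitz((r[:-1], r[:-1]), r[1:])


def td_spectral_moments(x) -> tuple[float, float, float, float]:
    """m0/m2/m4/m6: sums of squared 0th-3rd differences (Parseval surrogates of
    the even spectral moments)."""
    a = _as_array(x)
    if a.size < 4:
        raise SegmentTooShortError("spectral moments need >= 4 samples")
    m0 = float(np.sum(a**2))
    d1 = np.diff(a)
    d2 = np.diff(d1)
    d3 = np.diff(d2)
    return m0, float(np.sum(d1**2)), float(np.sum(d2**2)), float(np.sum(d3**2))


def amplitude_changes(x) -> tuple[float, float]:
    """AC1 = mean |Δx|, AC2 = mean |Δ²x|."""
    a = _as_array(x)
    if a.size < 3:
        raise SegmentTooShortError("amplitude changes need >= 3 samples")
    d1 = np.abs(np.diff(a))
    d2 = np.abs(np.diff(a, n=2))
    return float(d1.mean()), float(d2.mean())


def skewness(x) -> float:
    """Biased (population) sample skewness; 0 on zero-variance segments."""
    a = _as_array(x)
    s = a.std()
    if s == 0.0:
        return 0.0
    return float(np.mean(((a - a.mean()) / s) ** 3))


def emg_feature_vector(
    x, channel: str, config: EmgFeatureConfig | None = None
) -> FeatureVector:
    """The canonical 19-feature time-domain vector for one muscle segment."""
    cfg = config or EmgFeatureConfig()
    a = _as_array(x)
    try:
        wamp, zc, ssc = threshold_counts(a, cfg.theta_wamp, cfg.theta_zc, cfg.theta_ssc)
        mob, com = hjorth_params(a)
        ar = ar_coefficients(a, cfg.ar_order)
        m0, m2, m4, m6 = td_spectral_moments(a)
        ac1, ac2 = amplitude_changes(a)
        values = [
            lmav(a), nsv(a, cfg.nsv_order), waveform_length(a),
            float(wamp), float(ssc), float(zc), mob, com, skewness(a),
            *ar.tolist(), m0, m2, m4, m6, ac1, ac2,
        ]
    except (UndefinedFeatureError, SegmentTooShortError) as exc:
        raise type(exc)(f"{channel}: {exc}") from exc
    names = [f"{channel}__{n}" for n in EMG_FEATURE_NAMES]
    return FeatureVector(names, np.array(values))
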