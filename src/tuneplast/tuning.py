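"""Constrained Gaussian tuning-curve fitting on the octave axis.

The tuning model is a four-parameter Gaussian

    r(x) = offset + gain * exp(-0.5 * ((x - mu) / sigma)**2)

with ``x`` in octaves re 1 kHz, ``mu`` the best frequency (BF), ``gain``
the peak height above the offset (Rmax) and ``offset`` the curve's
frequency-independent floor.  The reported tuning width is the full
width at half maximum, FWHM = 2*sqrt(2*ln 2)*sigma, in octaves.

Fits minimise squared error over the intensity-averaged frequency
profile, subject to

A.  the BF lies within the tested frequency range;
B.  the tuning width (FWHM, in octaves) exceeds a floor of 0.0235;
C.  the curve's peak (offset + gain) is at most 1.5x the measured
    maximum of the profile;
D.  for non-negative scales (normalized, rate) the offset is >= 0;
    for z-scored profiles, which may be negative, the offset may not
    deviate from the profile minimum by more than 50% of |minimum|.

The optimiser is a multi-start Nelder-Mead simplex run in a smoothly
reparameterised space (logistic squashing for the bounded BF and offset,
an exponential-plus-floor map for the width, and a logistic share of the
remaining peak headroom for the gain), so every iterate is feasible and
the returned parameters satisfy A-D by construction.  Seven restarts are
seeded from the empirical peak and quarter-octave offsets around it; the
best variance-accounted-for (VAF) wins, ties going to the narrower fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = [
    "FWHM_FACTOR",
    "WIDTH_FLOOR_OCT",
    "FitProfile",
    "TuningFitResult",
    "GaussianTuningModel",
    "gaussian_model",
    "fwhm_from_sigma",
    "sigma_from_fwhm",
    "fit_tuning",
    "variance_accounted_for",
    "include_unit",
]

#: FWHM of a unit-SD Gaussian: 2*sqrt(2*ln 2).
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Lower bound on the fitted tuning width (FWHM, octaves), constraint B.
WIDTH_FLOOR_OCT = 0.0235

#: Peak cap multiplier, constraint C.
PEAK_CAP_FACTOR = 1.5

#: Default VAF inclusion threshold for population analysis.
VAF_THRESHOLD = 0.70


def gaussian_model(params, x_oct):
    """Evaluate offset + gain * exp(-((x-mu)/sigma)^2 / 2).

    ``params`` is (offset, gain, mu, sigma) with sigma > 0.  The peak
    value offset + gain is attained at x = mu; the curve decays to the
    offset in the tails and passes offset + gain/2 at mu +/- sigma*sqrt(2 ln 2).
    """
    offset, gain, mu, sigma = (float(p) for p in params)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x_oct, dtype=float)
    return offset + gain * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fwhm_from_sigma(sigma_oct: float) -> float:
    """Full width at half maximum of a Gaussian: 2*sqrt(2 ln 2) * sigma."""
    if sigma_oct <= 0:
        raise ValueError("sigma must be positive")
    return FWHM_FACTOR * float(sigma_oct)


def sigma_from_fwhm(fwhm_oct: float) -> float:
    if fwhm_oct <= 0:
        raise ValueError("fwhm must be positive")
    return float(fwhm_oct) / FWHM_FACTOR


def variance_accounted_for(observed, predicted) -> float:
    """VAF = 1 - SS_residual / SS_total, clipped below at 0 for reporting.

    Invariant under a common affine rescaling of observed and predicted.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must share a length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("observed profile has zero variance; VAF undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return max(0.0, 1.0 - ss_res / ss_tot)


def include_unit(vaf_pre: float, vaf_post: float, threshold: float = VAF_THRESHOLD) -> bool:
    """Population inclusion rule: both phases' fits must reach the VAF threshold."""
    for v in (vaf_pre, vaf_post):
        if not 0.0 <= v <= 1.0:
            raise ValueError("VAF values must lie in [0, 1]")
    return vaf_pre >= threshold and vaf_post >= threshold


@dataclass(frozen=True)
class FitProfile:
    """An intensity-averaged frequency profile ready for tuning fits."""

    x_oct: np.ndarray
    y: np.ndarray
    scale: str = "zscore"

    def __post_init__(self):
        x = np.asarray(self.x_oct, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x_oct and y must be 1-D arrays of equal length")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x_oct must be strictly increasing")
        object.__setattr__(self, "x_oct", x)
        object.__setattr__(self, "y", y)


@dataclass
class TuningFitResult:
    """Fitted tuning parameters plus fit quality for one unit x phase.

    ``bf_oct`` and widths are in octaves re 1 kHz; ``bf_hz`` is the peak
    location back on the frequency axis for display.
    """

    offset: float
    gain: float
    bf_oct: float
    sigma_oct: float
    vaf: float
    converged: bool
    n_restarts: int
    scale: str
    profile: FitProfile = field(repr=False)

    @property
    def fwhm_oct(self) -> float:
        return fwhm_from_sigma(self.sigma_oct)

    @property
    def bf_hz(self) -> float:
        return 1000.0 * 2.0 ** self.bf_oct

    @property
    def params(self) -> tuple:
        return (self.offset, self.gain, self.bf_oct, self.sigma_oct)

    def predict(self, x_oct=None) -> np.ndarray:
        if x_oct is None:
            x_oct = self.profile.x_oct
        return gaussian_model(self.params, x_oct)

    def summary(self) -> str:
        lines = [
            "Gaussian tuning fit"
            f" (scale={self.scale}, restarts={self.n_restarts},"
            f" converged={self.converged})",
            f"  BF        {self.bf_hz:10.1f} Hz  ({self.bf_oct:+.3f} oct re 1 kHz)",
            f"  FWHM      {self.fwhm_oct:10.3f} oct (sigma {self.sigma_oct:.3f})",
            f"  gain      {self.gain:10.3f}",
            f"  offset    {self.offset:10.3f}",
            f"  VAF       {self.vaf:10.3f}",
        ]
        return "\n".join(lines)


class GaussianTuningModel:
    """Constrained Gaussian tuning model for one frequency profile.

    Parameters
    ----------
    y : array-like
        Intensity-averaged responses per frequency.
    x_oct : array-like
        Frequency axis in octaves re 1 kHz, strictly increasing.
    scale : {"zscore", "normalized", "rate"}
        Determines the offset constraint (D): non-negative scales force
        offset >= 0; z-scored profiles bound the offset to within 50% of
        the profile minimum.
    width_floor : float
        Constraint-B floor, by default on the FWHM (0.0235 octaves).
    floor_on : {"fwhm", "sigma"}
        Whether the floor applies to the FWHM (default) or to sigma.
    """

    def __init__(self, y, x_oct, scale: str = "zscore",
                 width_floor: float = WIDTH_FLOOR_OCT, floor_on: str = "fwhm"):
        self.profile = FitProfile(x_oct=x_oct, y=y, scale=scale)
        if scale not in ("zscore", "normalized", "rate"):
            raise ValueError(f"unknown scale {scale!r}")
        if floor_on not in ("fwhm", "sigma"):
            raise ValueError("floor_on must be 'fwhm' or 'sigma'")
        y = self.profile.y
        if y.size < 5:
            raise ValueError("need at least 5 frequency points to fit")
        if not np.all(np.isfinite(y)):
            raise ValueError("profile contains non-finite values")
        if np.ptp(y) == 0:
            raise ValueError("constant profile is unfittable (VAF undefined)")
        self.scale = scale
        self.sigma_min = (sigma_from_fwhm(width_floor) if floor_on == "fwhm"
                          else float(width_floor))
        x = self.profile.x_oct
        self._x_lo, self._x_hi = float(x[0]), float(x[-1])
        y_max, y_min = float(np.max(y)), float(np.min(y))
        # Constraint C presumes a positive measured maximum (activity above
        # baseline); an all-negative z-score profile leaves the cap vacuous.
        self._peak_cap = PEAK_CAP_FACTOR * y_max if y_max > 0 else np.inf
        if scale == "zscore":
            lo = y_min - 0.5 * abs(y_min)
            hi = y_min + 0.5 * abs(y_min)
        else:
            lo, hi = 0.0, max(y_max, 1e-9)
        hi = min(hi, self._peak_cap)
        if hi < lo:
            hi = lo
        self._off_lo, self._off_hi = lo, hi

    # -- parameter transforms: theta (unconstrained) <-> feasible params ----

    def _from_theta(self, theta):
        t_off, t_gain, t_mu, t_sig = theta
        off_span = self._off_hi - self._off_lo
        offset = self._off_lo + off_span * expit(t_off) if off_span > 0 else self._off_lo
        mu = self._x_lo + (self._x_hi - self._x_lo) * expit(t_mu)
        sigma = self.sigma_min + np.exp(np.clip(t_sig, -30.0, 4.0))
        headroom = self._peak_cap - offset
        if not np.isfinite(headroom):
            gain = np.exp(np.clip(t_gain, -30.0, 30.0))
        else:
            gain = max(headroom, 0.0) * expit(t_gain)
        return offset, gain, mu, sigma

    def _to_theta(self, offset, gain, mu, sigma):
        def _logit_frac(v, lo, hi):
            if hi <= lo:
                return 0.0
            f = np.clip((v - lo) / (hi - lo), 1e-6, 1 - 1e-6)
            return float(logit(f))

        t_off = _logit_frac(offset, self._off_lo, self._off_hi)
        t_mu = _logit_frac(mu, self._x_lo, self._x_hi)
        t_sig = float(np.log(max(sigma - self.sigma_min, 1e-6)))
        offset_eff, _, _, _ = self._from_theta((t_off, 0.0, t_mu, t_sig))
        headroom = self._peak_cap - offset_eff
        if not np.isfinite(headroom):
            t_gain = float(np.log(max(gain, 1e-6)))
        else:
            t_gain = _logit_frac(gain, 0.0, max(headroom, 1e-9))
        return np.array([t_off, t_gain, t_mu, t_sig])

    def _sse(self, theta):
        offset, gain, mu, sigma = self._from_theta(theta)
        resid = self.profile.y - (
            offset + gain * np.exp(-0.5 * ((self.profile.x_oct - mu) / sigma) ** 2)
        )
        return float(resid @ resid)

    def _starts(self):
        x, y = self.profile.x_oct, self.profile.y
        peak_x = float(x[int(np.argmax(y))])
        y_min, y_max = float(np.min(y)), float(np.max(y))
        for d_mu in (0.0, 0.25, -0.25, 0.5, -0.5, 0.75, -0.75):
            mu0 = float(np.clip(peak_x + d_mu, self._x_lo, self._x_hi))
            yield (np.clip(y_min, self._off_lo, self._off_hi),
                   max(y_max - y_min, 1e-3), mu0, max(0.5, self.sigma_min * 2))

    def fit(self, n_restarts: int = 7, maxiter: int = 300) -> TuningFitResult:
        """Multi-start Nelder-Mead fit; returns the best-VAF solution."""
        starts = list(self._starts())[:n_restarts]
        best = None
        any_converged = False
        for start in starts:
            theta0 = self._to_theta(*start)
            res = minimize(self._sse, theta0, method="Nelder-Mead",
                           options={"maxiter": maxiter, "xatol": 3e-4,
                                    "fatol": 1e-6})
            params = self._from_theta(res.x)
            sse = self._sse(res.x)
            any_converged = any_converged or bool(res.success)
            cand = (sse, params[3], params, bool(res.success))
            if best is None:
                best = cand
            else:
                # best VAF (lowest SSE) wins; near-ties go to the narrower fit
                if sse < best[0] * (1 - 1e-10):
                    best = cand
                elif abs(sse - best[0]) <= 1e-10 * max(best[0], 1e-30) and cand[1] < best[1]:
                    best = cand
        offset, gain, mu, sigma = best[2]
        pred = gaussian_model((offset, gain, mu, sigma), self.profile.x_oct)
        vaf = variance_accounted_for(self.profile.y, pred)
        return TuningFitResult(
            offset=float(offset), gain=float(gain), bf_oct=float(mu),
            sigma_oct=float(sigma), vaf=vaf, converged=any_converged,
            n_restarts=len(starts), scale=self.scale, profile=self.profile,
        )

    @classmethod
    def from_map(cls, response_map, **kwargs) -> "GaussianTuningModel":
        """Build a model from a :class:`~tuneplast.responses.ResponseMap`."""
        profile = response_map.frequency_profile()
        x = response_map.grid.octaves
        kwargs.setdefault("scale", response_map.scale)
        return cls(profile, x, **kwargs)


def fit_tuning(profile: FitProfile, **kwargs) -> TuningFitResult:
    """Functional wrapper: fit the constrained Gaussian to a profile."""
    model = GaussianTuningModel(profile.y, profile.x_oct, scale=profile.scale, **kwargs)
    return model.fit()
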