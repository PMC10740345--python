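"""Random-walk state-space smoothing of filtered Argos tracks.

Argos error at auxiliary classes (10-30 km, 68th percentile) is of the same
order as the 25 km site radius, so position error is reduced before stop
detection by fitting a continuous-time random walk to each track:

* state: true position ``(x, y)`` in a local azimuthal-equidistant plane
  centred on the track's median position;
* process model: ``x_t ~ N(x_{t-1}, sigma^2 * dt * I)`` with ``sigma`` in
  km/sqrt(h) -- irregular sampling is handled by the ``dt`` scaling, not by
  interpolating to a regular grid;
* observation model: the reported fix with a per-fix 2x2 error covariance,
  from the Argos error ellipse when present, otherwise a class-default
  isotropic covariance calibrated so the implied 68th radial error
  percentile matches the nominal class accuracy.

``sigma`` is estimated by maximising the innovations (prediction-error)
log-likelihood of the Kalman filter with a bounded 1-D search; fitted
positions come from the Rauch-Tung-Striebel smoother.  This is a
position-only model (no velocity states): at the 25-50 km scale of site
assignment the extra complexity of a correlated random walk buys nothing,
and smoothing is optional throughout the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .core import Fix, PipelineConfig, Track, logger
from .geo import from_local_plane, to_local_plane

__all__ = ["ObsCovariance", "SmoothedTrack", "obs_covariance", "fit_rw_ssm", "RAYLEIGH_68"]

#: For an isotropic bivariate normal with per-axis sd s, the radial error is
#: Rayleigh(s); its 68th percentile is s * sqrt(-2 ln 0.32).
RAYLEIGH_68 = math.sqrt(-2.0 * math.log(1.0 - 0.68))


@dataclass(frozen=True)
class ObsCovariance:
    """2x2 observation covariance (km^2) in local east/north coordinates."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 2):
            raise ValueError("observation covariance must be 2x2")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("observation covariance must be symmetric")
        if np.linalg.eigvalsh(m).min() < -1e-9:
            raise ValueError("observation covariance must be positive semi-definite")
        object.__setattr__(self, "matrix", m)


@dataclass
class SmoothedTrack:
    """Fitted positions and variances for each retained fix of one track."""

    individual_id: str
    times: list
    fitted_lat: np.ndarray
    fitted_lon: np.ndarray
    fitted_var_km2: np.ndarray     # trace of the smoothed position covariance
    sigma_km_sqrt_h: float
    log_likelihood: float
    smoothed: bool = True          # False when the model was skipped (short track)


def obs_covariance(fix: Fix, cfg: PipelineConfig | None = None) -> ObsCovariance:
    """Per-fix observation covariance from the error ellipse or class defaults.

    Ellipse semi-axes are treated as 1-sigma extents in metres; the
    orientation is degrees clockwise from north of the semi-major axis.
    Without an ellipse, the class default radial 68th percentiles
    (3/2/1 -> 0.25/0.5/1.5 km; 0/A/B/Z -> 5/8/15/15 km) are converted to an
    isotropic covariance.
    """
    cfg = cfg or PipelineConfig()
    if fix.ellipse_semi_major_m is not None:
        a_km = fix.ellipse_semi_major_m / 1000.0
        b_km = fix.ellipse_semi_minor_m / 1000.0
        theta = math.radians(fix.ellipse_orientation_deg or 0.0)
        # orientation clockwise from north -> major-axis unit vector (east, north)
        u = np.array([math.sin(theta), math.cos(theta)])
        v = np.array([math.cos(theta), -math.sin(theta)])
        m = a_km**2 * np.outer(u, u) + b_km**2 * np.outer(v, v)
        return ObsCovariance(m)
    r68 = cfg.class_r68_km[fix.loc_class]
    s = r68 / RAYLEIGH_68
    return ObsCovariance(np.eye(2) * s**2)


def _kalman_pass(xy, dts, covs, sigma, with_smooth: bool):
    """Forward filter (innovations log-likelihood); optional RTS smoother.

    Exploits that F = H = I and all covariances stay symmetric 2x2.
    """
    n = len(xy)
    eye = np.eye(2)
    m_f = np.empty((n, 2))      # filtered means
    p_f = np.empty((n, 2, 2))   # filtered covariances
    m_p = np.empty((n, 2))      # predicted means
    p_p = np.empty((n, 2, 2))
    loglik = 0.0
    # diffuse-ish start: first observation initializes the state
    m_p[0] = xy[0]
    p_p[0] = covs[0] * 0.0 + eye * 1e6
    for t in range(n):
        if t > 0:
            m_p[t] = m_f[t - 1]
            p_p[t] = p_f[t - 1] + sigma**2 * dts[t] * eye
        s_mat = p_p[t] + covs[t]
        try:
            s_inv = np.linalg.inv(s_mat)
        except np.linalg.LinAlgError:
            logger.debug("singular innovation covariance; jittering by 1e-9 km^2")
            s_mat = s_mat + eye * 1e-9
            s_inv = np.linalg.inv(s_mat)
        innov = xy[t] - m_p[t]
        if t > 0:  # first step is diffuse; exclude it from the likelihood
            sign, logdet = np.linalg.slogdet(s_mat)
            loglik += -0.5 * (logdet + innov @ s_inv @ innov + 2.0 * math.log(2.0 * math.pi))
        gain = p_p[t] @ s_inv
        m_f[t] = m_p[t] + gain @ innov
        p_f[t] = (eye - gain) @ p_p[t]
        p_f[t] = 0.5 * (p_f[t] + p_f[t].T)
    if not with_smooth:
        return loglik, None, None
    m_s = m_f.copy()
    p_s = p_f.copy()
    for t in range(n - 2, -1, -1):
        j = p_f[t] @ np.linalg.inv(p_p[t + 1] + np.eye(2) * 1e-12)
        m_s[t] = m_f[t] + j @ (m_s[t + 1] - m_p[t + 1])
        p_s[t] = p_f[t] + j @ (p_s[t + 1] - p_p[t + 1]) @ j.T
        p_s[t] = 0.5 * (p_s[t] + p_s[t].T)
    return loglik, m_s, p_s


def fit_rw_ssm(track: Track, cfg: PipelineConfig | None = None) -> SmoothedTrack:
    """Fit the random-walk model to a filtered track and smooth its positions.

    Tracks with fewer than 4 fixes are passed through unchanged (with a
    warning): too little data to separate process from observation noise.
    """
    cfg = cfg or PipelineConfig()
    fixes = track.fixes
    times = [f.timestamp for f in fixes]
    if len(fixes) < 4:
        logger.warning("track %s has < 4 fixes; smoothing skipped", track.individual_id)
        return SmoothedTrack(
            individual_id=track.individual_id, times=times,
            fitted_lat=np.array([f.lat for f in fixes]),
            fitted_lon=np.array([f.lon for f in fixes]),
            fitted_var_km2=np.array([np.trace(obs_covariance(f, cfg).matrix) for f in fixes]),
            sigma_km_sqrt_h=float("nan"), log_likelihood=float("nan"), smoothed=False,
        )

    lat0 = float(np.median([f.lat for f in fixes]))
    lon0 = float(np.median([f.lon for f in fixes]))
    x, y = to_local_plane(np.array([f.lat for f in fixes]),
                          np.array([f.lon for f in fixes]), lat0, lon0)
    xy = np.column_stack([x, y])
    dts = np.zeros(len(fixes))
    for t in range(1, len(fixes)):
        dts[t] = (times[t] - times[t - 1]).total_seconds() / 3600.0
    covs = np.array([obs_covariance(f, cfg).matrix for f in fixes])

    lo, hi = cfg.smooth_sigma_bounds

    def neg_loglik(log_sigma: float) -> float:
        ll, _, _ = _kalman_pass(xy, dts, covs, math.exp(log_sigma), with_smooth=False)
        return -ll

    res = minimize_scalar(
        neg_loglik, bounds=(math.log(lo), math.log(hi)), method="bounded",
        options={"xatol": 1e-4},
    )
    sigma = math.exp(res.x)
    loglik, m_s, p_s = _kalman_pass(xy, dts, covs, sigma, with_smooth=True)
    lats, lons = from_local_plane(m_s[:, 0], m_s[:, 1], lat0, lon0)
    return SmoothedTrack(
        individual_id=track.individual_id, times=times,
        fitted_lat=np.asarray(lats), fitted_lon=np.asarray(lons),
        fitted_var_km2=np.einsum("tii->t", p_s),
        sigma_km_sqrt_h=sigma, log_likelihood=loglik,
    )
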