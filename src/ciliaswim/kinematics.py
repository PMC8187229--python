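"""Trajectory observables of the swimming microswimmer.

A trajectory is the time series of the body center, the unit main body axis
n(t) and a body-fixed equatorial marker m(t).  From it this module computes
the propulsion velocity <v_n> along the axis and its fluctuations, the
spinning rate Omega_n of the body about its own axis, the orientation
autocorrelation <n(t).n(t+tau)> and its fit by the helix-plus-noise model

    C(tau) = (cos^2 alpha + sin^2 alpha cos(Omega_c tau)) e^(-kappa tau),

where alpha is the angle between the body axis and the helix axis, Omega_c
the circling frequency and kappa the rotational decorrelation rate.  The
helix radius and pitch follow as R_h = v sin(alpha)/(2 pi Omega_c),
P_h = v cos(alpha)/Omega_c with Omega_c in cycles per unit time (frequencies
are stored in radians internally and converted at this reporting boundary;
the metadata of every result records the convention).

Passive reference scales: rotational diffusion D_rot = kBT/(8 pi eta R^3) of
a no-slip sphere, tau_rot = 1/(2 D_rot), and the hydrodynamic radius implied
by a measured kappa through D proportional to R^-3.  The swimming efficiency
is eta = 6 pi eta_f R <v_n>^2 / <P> with <P> the dissipated power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Trajectory",
    "HelixFit",
    "HelixGeometry",
    "PropulsionSummary",
    "propulsion_stats",
    "spin_rate",
    "orientation_autocorr",
    "fit_helix_correlation",
    "fit_trajectory_helix",
    "helix_geometry",
    "rotational_diffusion_scale",
    "hydrodynamic_radius",
    "efficiency",
    "reynolds",
    "n_scaling_exponent",
    "orientation_matrices",
    "angular_displacement",
    "msd",
    "diffusion_coefficient",
]


@dataclass
class Trajectory:
    """Uniformly sampled body trajectory with energy ledgers."""

    times: np.ndarray
    center: np.ndarray           # (n, 3)
    axis: np.ndarray             # (n, 3) unit main body axis n(t)
    marker: np.ndarray           # (n, 3) unit equatorial marker, m.n = 0
    work_in: np.ndarray | None = None       # cumulative injected work
    energy_removed: np.ndarray | None = None  # cumulative thermostat removal
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


# --------------------------------------------------------------------------
# propulsion statistics
# --------------------------------------------------------------------------

def _whole_period_slice(traj: Trajectory, tau_b: float | None) -> slice:
    if not tau_b:
        return slice(None)
    n_per = int(np.floor(traj.duration / tau_b))
    if n_per < 1:
        return slice(None)
    n_samp = int(round(n_per * tau_b / traj.dt))
    return slice(0, min(n_samp + 1, len(traj)))

def axial_velocity(traj: Trajectory) -> np.ndarray:
    """v_n(t) = dr/dt . n by centered differences (endpoints one-sided)."""
    v = np.gradient(traj.center, traj.times, axis=0)
    return (v * traj.axis).sum(axis=1)


def propulsion_stats(traj: Trajectory, tau_b: float | None = None
                     ) -> tuple[float, float]:
    """Mean axial velocity <v_n> and its root-variance.

    When the beat period tau_b is known (trajectory metadata or argument) the
    average is taken over the largest whole number of beat periods so the
    periodic velocity modulation does not bias the moments.
    """
    if len(traj) < 3:
        raise ValueError("trajectory too short for velocity statistics")
    tau_b = tau_b if tau_b is not None else traj.meta.get("tau_b")
    if tau_b and traj.duration < 2 * tau_b:
        raise ValueError("need at least two beat periods of data")
    vn = axial_velocity(traj)[_whole_period_slice(traj, tau_b)]
    mean = float(vn.mean())
    return mean, float(np.sqrt(np.mean((vn - mean) ** 2)))


def spin_rate(traj: Trajectory) -> float:
    """Signed body spin Omega_n (rad/time) about the main axis.

    The marker angle is unwrapped in a parallel-transported frame: the
    minimal rotation taking n(t) to n(t+dt) transports m(t), and the signed
    in-plane angle to m(t+dt) is accumulated.  This removes the apparent
    rotation caused by axis wobble.
    """
    n = traj.axis
    m = traj.marker
    total = 0.0
    for i in range(len(traj) - 1):
        m_t = _transport(m[i], n[i], n[i + 1])
        m_t -= (m_t @ n[i + 1]) * n[i + 1]
        nm = np.linalg.norm(m_t)
        if nm < 1e-12:
            raise ValueError("degenerate marker frame")
        m_t /= nm
        s = np.cross(m_t, m[i + 1]) @ n[i + 1]
        c = m_t @ m[i + 1]
        total += np.arctan2(s, c)
    return total / traj.duration


def _transport(v: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotate v by the minimal rotation taking unit vector a to unit vector b."""
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    c = np.clip(a @ b, -1.0, 1.0)
    if s < 1e-15:
        return v.copy() if c > 0 else -v
    axis = axis / s
    ang = np.arctan2(s, c)
    return (v * np.cos(ang) + np.cross(axis, v) * np.sin(ang)
            + axis * (axis @ v) * (1.0 - np.cos(ang)))


# --------------------------------------------------------------------------
# orientation autocorrelation and helix fit
# --------------------------------------------------------------------------

def orientation_autocorr(traj: Trajectory, max_lag: float | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged C(tau) = <n(t).n(t+tau)> on the sampling lag grid."""
    n = len(traj)
    if max_lag is None:
        max_lag = traj.duration / 2.0
    k_max = min(int(max_lag / traj.dt), n - 2)
    if k_max < 1:
        raise ValueError("max_lag must allow at least one lag bin")
    corr = np.zeros(n)
    for comp in range(3):
        x = traj.axis[:, comp]
        f = np.fft.rfft(x, 2 * n)
        corr += np.fft.irfft(f * np.conj(f), 2 * n)[:n]
    corr /= np.arange(n, 0, -1)
    lags = np.arange(k_max + 1) * traj.dt
    return lags, corr[:k_max + 1]


@dataclass
class HelixFit:
    """Parameters of the helix-plus-noise orientation correlation model."""

    alpha_deg: float             # helix (alignment) angle, 0..90
    omega_c: float               # circling frequency, rad/time
    kappa: float                 # decorrelation rate, 1/time
    residual: float = 0.0
    cov: np.ndarray | None = None
    kappa_reliable: bool = True  # False when 1/kappa exceeds the data span
    omega_reliable: bool = True  # False when alpha ~ 0 (Omega_c unidentifiable)
    convention: str = "omega_c in rad/time; reported helix uses cycles/time"

    @property
    def omega_c_cyc(self) -> float:
        """Circling frequency in cycles per unit time (reporting convention)."""
        return self.omega_c / (2.0 * np.pi)


def _helix_model(params: np.ndarray, tau: np.ndarray) -> np.ndarray:
    a, om, ka = params
    return (a + (1.0 - a) * np.cos(om * tau)) * np.exp(-ka * tau)


def fit_helix_correlation(lags: np.ndarray, corr: np.ndarray,
                          span: float | None = None) -> HelixFit:
    """Weighted nonlinear least-squares fit of the orientation correlation.

    Parameters are cos^2(alpha) in [0,1], Omega_c >= 0 and kappa >= 0.
    Multi-start over Omega_c seeded by the spectral peak of C (and the
    zero-frequency candidate).  Lag weights are proportional to the square
    root of the number of contributing pairs.  Fits with 1/kappa beyond the
    trajectory span, or with vanishing oscillatory amplitude, are flagged.
    """
    lags = np.asarray(lags, dtype=float)
    corr = np.asarray(corr, dtype=float)
    if span is None:
        span = 2.0 * lags[-1]
    n_pairs = np.maximum(span / max(lags[1], 1e-12) - lags / max(lags[1], 1e-12), 1.0)
    w = np.sqrt(n_pairs / n_pairs[0])

    # multi-start candidates for Omega_c: spectral peaks plus a coarse grid
    c = corr - corr.mean()
    spec = np.abs(np.fft.rfft(c * np.hanning(len(c))))
    freqs = 2.0 * np.pi * np.fft.rfftfreq(len(c), d=lags[1] - lags[0])
    order = np.argsort(spec[1:])[::-1] + 1
    peaks = [float(freqs[i]) for i in order[:3]]
    nyq = np.pi / (lags[1] - lags[0])
    candidates = set(np.round(
        [0.0, *peaks, *(0.5 * np.array(peaks)), *np.linspace(0, 0.25 * nyq, 6)],
        10))

    # crude kappa from the decay of |C|
    tail = np.abs(corr) > 0.05
    ka0 = 0.0
    if corr[-1] < 0.9 * corr[0]:
        with np.errstate(divide="ignore"):
            y = np.log(np.clip(np.abs(corr[tail]), 1e-12, None))
        ka0 = max(-np.polyfit(lags[tail], y, 1)[0], 0.0)

    best = None
    for om0 in sorted(candidates):
        for a0 in (0.2, 0.8, 0.97):
            res = least_squares(
                lambda p: (_helix_model(p, lags) - corr) * w,
                x0=[a0, om0, ka0],
                bounds=([0.0, 0.0, 0.0], [1.0, np.inf, np.inf]))
            if best is None or res.cost < best.cost:
                best = res
    a, om, ka = best.x
    a = float(np.clip(a, 0.0, 1.0))
    alpha = float(np.degrees(np.arccos(np.sqrt(a))))
    jac = best.jac
    cov = None
    try:
        dof = max(len(lags) - 3, 1)
        cov = np.linalg.inv(jac.T @ jac) * 2.0 * best.cost / dof
    except np.linalg.LinAlgError:
        pass
    return HelixFit(
        alpha_deg=alpha, omega_c=float(om), kappa=float(ka),
        residual=float(np.sqrt(2.0 * best.cost / len(lags))), cov=cov,
        kappa_reliable=bool(ka > 0 and 1.0 / ka < span),
        omega_reliable=bool(1.0 - a > 1e-3 and om * lags[-1] > 0.5))


def fit_trajectory_helix(traj: Trajectory, max_lag: float | None = None
                         ) -> HelixFit:
    """Orientation autocorrelation + helix fit with an adaptive lag window.

    Unless ``max_lag`` is given, the fit window ends where the correlation
    envelope (running maximum of |C|, which bridges the oscillation dips)
    has decayed to 1/e.  Longer windows are dominated by the strongly
    correlated noise of the correlation estimator and favor a degenerate
    slow-cosine solution when the oscillation amplitude is small.
    """
    if max_lag is not None:
        lags, corr = orientation_autocorr(traj, max_lag)
        return fit_helix_correlation(lags, corr, span=traj.duration)
    from scipy.ndimage import maximum_filter1d

    lags, corr = orientation_autocorr(traj, traj.duration / 2.0)
    size = max(len(corr) // 20, 3)
    env = maximum_filter1d(np.abs(corr), size=size)
    below = np.nonzero(env < np.exp(-1.0))[0]
    if len(below):
        k = max(int(below[0]), 20)
        lags, corr = lags[:k + 1], corr[:k + 1]
    return fit_helix_correlation(lags, corr, span=traj.duration)


# --------------------------------------------------------------------------
# helix geometry
# --------------------------------------------------------------------------

@dataclass
class HelixGeometry:
    """Helix radius, pitch and angle of the swimming trajectory."""

    R_h: float
    P_h: float
    alpha_h_deg: float
    flagged: bool = False        # straight-line/degenerate case

    @property
    def pitch_radius_ratio(self) -> float:
        """P_h / (2 pi R_h) = cot(alpha)."""
        return self.P_h / (2.0 * np.pi * self.R_h)


def helix_geometry(v_n: float, fit: HelixFit) -> HelixGeometry:
    """Helix radius and pitch from the fitted (alpha, Omega_c) and <v_n>.

    Uses the cycles-per-time frequency convention:
    P_h = v cos(alpha)/Omega_c, R_h = v sin(alpha)/(2 pi Omega_c).
    For alpha = 0 the motion is a straight line (R_h = 0, pitch undefined);
    Omega_c = 0 with alpha > 0 is an inconsistent fit — both are flagged.
    """
    alpha = np.deg2rad(fit.alpha_deg)
    om_cyc = fit.omega_c_cyc
    if om_cyc <= 0.0:
        return HelixGeometry(R_h=0.0, P_h=np.inf, alpha_h_deg=fit.alpha_deg,
                             flagged=True)
    R_h = v_n * np.sin(alpha) / (2.0 * np.pi * om_cyc)
    P_h = v_n * np.cos(alpha) / om_cyc
    if R_h > 0:
        # closure of the geometric identities, exact by construction
        lhs = np.cos(alpha) ** 2
        rhs = P_h**2 / (P_h**2 + 4.0 * np.pi**2 * R_h**2)
        assert abs(lhs - rhs) < 1e-10
        alpha_h = np.degrees(np.arctan2(2.0 * np.pi * R_h, P_h))
    else:
        alpha_h = 0.0
    return HelixGeometry(R_h=float(R_h), P_h=float(P_h),
                         alpha_h_deg=float(alpha_h),
                         flagged=bool(R_h == 0.0 and fit.alpha_deg > 1e-9))


# --------------------------------------------------------------------------
# passive scales, efficiency, Reynolds numbers
# --------------------------------------------------------------------------

def rotational_diffusion_scale(R: float, eta_f: float, kBT: float = 1.0
                               ) -> tuple[float, float]:
    """(D_rot, tau_rot) of a no-slip sphere: kBT/(8 pi eta R^3), 1/(2 D_rot)."""
    if R <= 0 or eta_f <= 0 or kBT <= 0:
        raise ValueError("inputs must be positive")
    d_rot = kBT / (8.0 * np.pi * eta_f * R**3)
    return d_rot, 1.0 / (2.0 * d_rot)


def hydrodynamic_radius(kappa: float, tau_rot: float, R: float
                        ) -> tuple[float, bool]:
    """Hydrodynamic radius implied by a measured decorrelation rate kappa.

    The reduction factor f = 1/(kappa tau_rot) of the rotational diffusion
    maps to R_hydro = R f^(1/3) since D_rot ~ R^-3.  f < 1 (decorrelation
    faster than the passive body) indicates dominant active noise and is
    flagged.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    f = 1.0 / (kappa * tau_rot)
    return float(R * f ** (1.0 / 3.0)), bool(f < 1.0)


def efficiency(v_n: float, power: float, eta_f: float, R: float) -> float:
    """Swimming efficiency eta = 6 pi eta_f R <v_n>^2 / <P> (dimensionless)."""
    if power <= 0:
        raise ValueError("dissipated power must be positive")
    return 6.0 * np.pi * eta_f * R * v_n * v_n / power


def reynolds(rho: float, R: float, L: float, tau_b: float, eta_f: float
             ) -> tuple[float, float]:
    """Body and cilia Reynolds numbers: rho R^2/(tau eta), rho L^2/(tau eta)."""
    if min(rho, R, L, tau_b, eta_f) <= 0:
        raise ValueError("inputs must be positive")
    return rho * R * R / (tau_b * eta_f), rho * L * L / (tau_b * eta_f)


def n_scaling_exponent(gamma: float) -> float:
    """Exponent of v_swim ~ N^x from planar-carpet transport v ~ (d/L)^-gamma.

    The mean cilia spacing on a sphere scales as d ~ N^(-1/2), so the
    transport scaling translates to x = gamma/2 (0.7 for gamma = 1.4).
    """
    return gamma / 2.0


# --------------------------------------------------------------------------
# rigid-body rotation utilities (diffusion measurements)
# --------------------------------------------------------------------------

def orientation_matrices(traj: Trajectory) -> np.ndarray:
    """Body orientation R(t) with columns (m, n x m, n)."""
    e1 = traj.marker
    e3 = traj.axis
    e2 = np.cross(e3, e1)
    return np.stack([e1, e2, e3], axis=-1)


def angular_displacement(rot: np.ndarray) -> np.ndarray:
    """Accumulated angular displacement vector Phi(t) from orientation matrices."""
    n = rot.shape[0]
    phi = np.zeros((n, 3))
    for i in range(n - 1):
        d = rot[i + 1] @ rot[i].T
        angle = np.arccos(np.clip((np.trace(d) - 1.0) / 2.0, -1.0, 1.0))
        vec = np.array([d[2, 1] - d[1, 2], d[0, 2] - d[2, 0], d[1, 0] - d[0, 1]])
        s = np.linalg.norm(vec)
        dphi = angle * vec / s if s > 1e-12 else np.zeros(3)
        phi[i + 1] = phi[i] + dphi
    return phi


def msd(series: np.ndarray, dt: float, max_lag: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean-square displacement over all overlapping windows (FFT-based)."""
    n = series.shape[0]
    k_max = min(int(max_lag / dt), n - 2)
    s2 = (series * series).sum(axis=1)
    out = np.empty(k_max)
    # FFT autocorrelation of each component
    acf = np.zeros(n)
    for comp in range(series.shape[1]):
        f = np.fft.rfft(series[:, comp], 2 * n)
        acf += np.fft.irfft(f * np.conj(f), 2 * n)[:n]
    css = np.concatenate([[0.0], np.cumsum(s2)])
    for k in range(1, k_max + 1):
        tail = css[n] - css[k]          # sum s2[k:]
        head = css[n - k]               # sum s2[:n-k]
        out[k - 1] = (tail + head - 2.0 * acf[k]) / (n - k)
    return np.arange(1, k_max + 1) * dt, out


def diffusion_coefficient(lags: np.ndarray, msd_vals: np.ndarray,
                          n_dim: int = 3) -> float:
    """D from a zero-intercept-free linear fit of MSD = 2 n_dim D t."""
    slope = np.polyfit(lags, msd_vals, 1)[0]
    return float(slope / (2.0 * n_dim))
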