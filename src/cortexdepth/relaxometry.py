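"""Steady-state relaxometry signal models and joint fitting (JSR).

Forward models for spoiled gradient-recalled echo (SPGR, the Ernst
equation) and phase-cycled balanced steady-state free precession (bSSFP,
the Freeman-Hill steady state), plus joint nonlinear least-squares
estimation of (M0, T1, T2) from a combined five-measurement protocol:
two SPGR flip angles and three bSSFP flip/phase-increment combinations.

All times are milliseconds, angles degrees, signals magnitude only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AcquisitionProtocol",
    "TissueParams",
    "JSRFit",
    "spgr_signal",
    "bssfp_signal",
    "forward_signals",
    "fit_jsr",
    "fit_jsr_volume",
]


@dataclass(frozen=True)
class SPGRAcq:
    flip_deg: float
    tr_ms: float


@dataclass(frozen=True)
class BSSFPAcq:
    flip_deg: float
    phase_increment_deg: float
    tr_ms: float


@dataclass(frozen=True)
class AcquisitionProtocol:
    """A set of SPGR and bSSFP acquisitions fitted jointly.

    The default is a pediatric 3-T protocol: SPGR at flips 2.2 deg and 12.5 deg
    (TR 6.2 ms) and bSSFP at (12 deg, 180 deg), (49 deg, 0 deg),
    (49 deg, 180 deg) (TR 6 ms).
    """

    spgr: tuple[SPGRAcq, ...] = (SPGRAcq(2.2, 6.2), SPGRAcq(12.5, 6.2))
    bssfp: tuple[BSSFPAcq, ...] = (
        BSSFPAcq(12.0, 180.0, 6.0),
        BSSFPAcq(49.0, 0.0, 6.0),
        BSSFPAcq(49.0, 180.0, 6.0),
    )

    def __post_init__(self) -> None:
        for acq in list(self.spgr) + list(self.bssfp):
            if not (0.0 < acq.flip_deg <= 90.0):
                raise ValueError(f"flip angle {acq.flip_deg} outside (0, 90] deg")
            if acq.tr_ms <= 0:
                raise ValueError("TR must be positive")

    @property
    def n_measurements(self) -> int:
        return len(self.spgr) + len(self.bssfp)


@dataclass(frozen=True)
class TissueParams:
    """Voxel tissue parameters: equilibrium magnetization and relaxation times."""

    m0: float
    t1_ms: float
    t2_ms: float
    off_resonance_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.t2_ms <= 0 or self.t1_ms <= 0:
            raise ValueError("relaxation times must be positive")
        if self.t1_ms < self.t2_ms:
            raise ValueError("T1 must be >= T2")
        if self.m0 <= 0:
            raise ValueError("M0 must be positive")


def spgr_signal(params: TissueParams, flip_deg: float, tr_ms: float) -> float:
    """SPGR (Ernst) steady-state magnitude.

    S = M0 sin(a) (1 - E1) / (1 - E1 cos(a)), E1 = exp(-TR/T1).
    Ideal spoiling: no T2 dependence.
    """
    if params.t1_ms <= 0:
        raise ValueError("T1 must be positive")
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / params.t1_ms)
    return float(params.m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a)))


def bssfp_signal(
    params: TissueParams,
    flip_deg: float,
    phase_increment_deg: float,
    tr_ms: float,
) -> float:
    """Phase-cycled bSSFP steady-state magnitude (Freeman-Hill form).

    The RF phase increment dphi acts as an extra precession per TR:
    theta = 2 pi * f0 * TR + dphi.  With the conventional 180 deg phase
    cycling, on-resonance spins sit at theta = pi (the passband); a 0 deg
    increment places on-resonance spins at theta = 0, the stopband null.

    Magnitude of the transverse steady state immediately after excitation:

        Mx + iMy = M0 (1 - E1) sin(a) (1 - E2 e^{-i theta}) / D
        D = (1 - E1 cos a)(1 - E2 cos theta) - E2 (E1 - cos a)(E2 - cos theta)
    """
    if params.t2_ms > params.t1_ms:
        raise ValueError("T2 must not exceed T1")
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / params.t1_ms)
    e2 = np.exp(-tr_ms / params.t2_ms)
    theta = 2.0 * np.pi * params.off_resonance_hz * tr_ms * 1e-3 + np.deg2rad(
        phase_increment_deg
    )
    num = params.m0 * (1.0 - e1) * np.sin(a) * (1.0 - e2 * np.exp(-1j * theta))
    den = (1.0 - e1 * np.cos(a)) * (1.0 - e2 * np.cos(theta)) - e2 * (
        e1 - np.cos(a)
    ) * (e2 - np.cos(theta))
    return float(np.abs(num / den))


def forward_signals(params: TissueParams, protocol: AcquisitionProtocol) -> np.ndarray:
    """Noiseless signal vector for a protocol, SPGR entries first."""
    out = [spgr_signal(params, s.flip_deg, s.tr_ms) for s in protocol.spgr]
    out += [
        bssfp_signal(params, b.flip_deg, b.phase_increment_deg, b.tr_ms)
        for b in protocol.bssfp
    ]
    return np.asarray(out, dtype=float)


@dataclass
class JSRFit:
    params: TissueParams
    residual_norm: float
    converged: bool
    degenerate: bool = False


_DEFAULT_BOUNDS = ((1e-6, 100.0, 10.0), (np.inf, 5000.0, 1000.0))  # (M0, T1, T2)


def _residuals(
    x: np.ndarray,
    signals: np.ndarray,
    protocol: AcquisitionProtocol,
    weights: np.ndarray,
) -> np.ndarray:
    m0, t1, t2 = x
    t2 = min(t2, t1)  # keep the model physical inside the solver
    p = TissueParams(m0=m0, t1_ms=t1, t2_ms=t2)
    return weights * (forward_signals(p, protocol) - signals)


def fit_jsr(
    signals: np.ndarray,
    protocol: AcquisitionProtocol | None = None,
    init: TissueParams | None = None,
    bounds: tuple | None = None,
    weights: np.ndarray | None = None,
) -> JSRFit:
    """Joint nonlinear least-squares fit of (M0, T1, T2) to a signal vector.

    Parameters
    ----------
    signals
        One magnitude per protocol entry (SPGR first, then bSSFP).
    protocol
        Acquisition protocol; defaults to the five-measurement pediatric 3-T protocol.
    init
        Starting point; default T1=1000 ms, T2=80 ms, M0 scaled from the
        maximum signal.
    bounds
        ((lo_m0, lo_t1, lo_t2), (hi_m0, hi_t1, hi_t2)); default
        T1 in [100, 5000] ms, T2 in [10, 1000] ms.
    weights
        Optional per-measurement residual weights (e.g. inverse noise SD
        when acquisitions have per-image SNR rather than equal absolute
        noise); default equal weights.

    Returns
    -------
    JSRFit with the estimate, the final residual 2-norm, and flags.
    Degenerate inputs (all-zero signals) are flagged, never fitted silently.
    """
    protocol = protocol or AcquisitionProtocol()
    signals = np.asarray(signals, dtype=float)
    if signals.shape != (protocol.n_measurements,):
        raise ValueError(
            f"expected {protocol.n_measurements} signals, got {signals.shape}"
        )
    if not np.all(np.isfinite(signals)) or np.max(np.abs(signals)) == 0.0:
        return JSRFit(
            params=TissueParams(1e-6, 1000.0, 80.0),
            residual_norm=float(np.linalg.norm(signals)),
            converged=False,
            degenerate=True,
        )
    lo, hi = bounds or _DEFAULT_BOUNDS
    if init is None:
        # rough M0 scale: the largest bSSFP signal is a sizeable fraction of M0
        m0_guess = max(float(np.max(signals)) * 4.0, 1e-6)
        x0 = np.array([m0_guess, 1000.0, 80.0])
    else:
        x0 = np.array([init.m0, init.t1_ms, init.t2_ms])
    x0 = np.clip(x0, lo, np.minimum(hi, np.finfo(float).max))
    if weights is None:
        w = np.ones_like(signals)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != signals.shape or np.any(w <= 0):
            raise ValueError("weights must be positive, one per measurement")
    sol = least_squares(
        _residuals,
        x0,
        bounds=(lo, hi),
        args=(signals, protocol, w),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=400,
    )
    m0, t1, t2 = sol.x
    t2 = min(t2, t1)
    return JSRFit(
        params=TissueParams(m0=float(m0), t1_ms=float(t1), t2_ms=float(t2)),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.status > 0),
    )


def fit_jsr_volume(
    raw_volumes: list[np.ndarray],
    protocol: AcquisitionProtocol | None = None,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
):
    """Voxelwise JSR fit over co-registered raw volumes.

    Parameters
    ----------
    raw_volumes
        One 3D array per protocol entry, all on the same grid.
    mask
        Boolean array; voxels outside are set to 0 in all outputs.

    Returns
    -------
    (qT1, qT2, M0) as ``surfaces.QVolume`` on the shared grid.
    """
    from .surfaces import QVolume

    protocol = protocol or AcquisitionProtocol()
    if len(raw_volumes) != protocol.n_measurements:
        raise ValueError("one volume required per protocol measurement")
    shape = raw_volumes[0].shape
    for v in raw_volumes[1:]:
        if v.shape != shape:
            raise ValueError("raw volumes must share one grid")
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask grid mismatch")
    if affine is None:
        affine = np.eye(4)

    t1 = np.zeros(shape)
    t2 = np.zeros(shape)
    m0 = np.zeros(shape)
    stack = np.stack([v.astype(float) for v in raw_volumes], axis=-1)
    idx = np.argwhere(mask)
    cache: dict[tuple, tuple] = {}
    for i, j, k in idx:
        sig = stack[i, j, k]
        key = tuple(np.round(sig, 12))
        if key not in cache:
            fit = fit_jsr(sig, protocol)
            cache[key] = (fit.params.t1_ms, fit.params.t2_ms, fit.params.m0, fit.degenerate)
        t1v, t2v, m0v, degen = cache[key]
        if not degen:
            t1[i, j, k], t2[i, j, k], m0[i, j, k] = t1v, t2v, m0v
    return (
        QVolume(t1, affine, "qT1"),
        QVolume(t2, affine, "qT2"),
        QVolume(m0, affine, "M0"),
    )
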