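"""Closed-form 1-3-9 DKI estimators for MD and the mean kurtosis tensor (MKT).

Signal model (log domain), with diffusivities carried in units of
10^-3 mm^2/s throughout the package and b-values in s/mm^2:

    ln S(b, n) = ln S0 - b * D(n) + (1/6) * b^2 * MD^2 * W(n)

where D(n) = n^T D n, MD = tr(D)/3, and W(n) = sum_ijlm W_ijlm n_i n_j n_l n_m
is the kurtosis tensor contracted four times with the direction (the
kurtosis tensor is normalized against MD^2, the standard DKI convention).

Along each coordinate axis the log-attenuation h(b) = ln(S/S0) is exactly
quadratic in b, so two shells give the axis diffusivity in closed form;
MD is the mean of the three axis diffusivities.  MKT = tr(W)/5 follows from
the degree-4 quadrature average of the high-shell log-attenuations:

    MKT = 6 * (h_bar + b2 * MD) / (b2 * MD)^2,   h_bar = sum_k w_k h(b2, n_k)

All estimators are pure closed forms: no iterative fitting, no random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scheme import DiffusionScheme

__all__ = [
    "MD_UNIT",
    "KurtosisTissueModel",
    "DWIStudy",
    "ParameterMaps",
    "QCBounds",
    "isotropic_kurtosis_tensor",
    "mkt_from_tensor",
    "forward_signal",
    "axis_diffusivity",
    "mean_diffusivity",
    "mean_kurtosis_tensor",
    "fit_parameter_maps",
]

#: diffusivities are expressed in units of 10^-3 mm^2/s
MD_UNIT = 1e-3

_ISO_DELTA = np.eye(3)


def isotropic_kurtosis_tensor(kurtosis: float) -> np.ndarray:
    """Fully symmetric rank-4 tensor with W(n) = kurtosis for every direction."""
    d = _ISO_DELTA
    sym = (np.einsum("ij,lm->ijlm", d, d)
           + np.einsum("il,jm->ijlm", d, d)
           + np.einsum("im,jl->ijlm", d, d))
    return kurtosis * sym / 3.0


def mkt_from_tensor(w_tensor: np.ndarray) -> float:
    """One fifth of the kurtosis tensor trace, tr(W) = W_iijj."""
    return float(np.einsum("iijj->", np.asarray(w_tensor, float))) / 5.0


@dataclass(frozen=True)
class KurtosisTissueModel:
    """Ground-truth tissue model: diffusion tensor D (10^-3 mm^2/s),
    fully symmetric kurtosis tensor W (dimensionless), signal amplitude S0."""

    D: np.ndarray
    W: np.ndarray
    S0: float = 1.0

    def __post_init__(self):
        D = np.asarray(self.D, float)
        W = np.asarray(self.W, float)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "W", W)
        if D.shape != (3, 3) or not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("D must be a symmetric 3x3 tensor")
        if np.min(np.linalg.eigvalsh(D)) < -1e-12:
            raise ValueError("D must be positive semidefinite")
        if W.shape != (3, 3, 3, 3):
            raise ValueError("W must be a rank-4 tensor")
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")

    @classmethod
    def isotropic(cls, md: float, kurtosis: float, s0: float = 1.0) -> "KurtosisTissueModel":
        """Isotropic model: D = MD * I and W(n) = kurtosis for all n."""
        return cls(D=md * np.eye(3), W=isotropic_kurtosis_tensor(kurtosis), S0=s0)

    @property
    def md(self) -> float:
        return float(np.trace(self.D)) / 3.0

    @property
    def mkt(self) -> float:
        return mkt_from_tensor(self.W)


@dataclass
class DWIStudy:
    """One subject's 4-D diffusion-weighted series in canonical scheme order."""

    data: np.ndarray            # (X, Y, Z, n_volumes)
    affine: np.ndarray          # (4, 4)
    scheme: DiffusionScheme
    sigma: float | None = None  # Rician noise scale, if known
    subject_id: str = ""
    log: list = field(default_factory=list)

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-D (x, y, z, volume)")
        if self.data.shape[3] != self.scheme.n_volumes:
            raise ValueError(
                f"volume count {self.data.shape[3]} does not match scheme "
                f"({self.scheme.n_volumes} volumes)"
            )


@dataclass
class QCBounds:
    """Physical acceptance bounds for voxelwise estimates.

    Estimates outside these bounds (or produced from unusable signals) are
    flagged rather than clipped, so downstream means use valid voxels only.
    """

    md_max: float = 3.0    # 10^-3 mm^2/s
    mkt_min: float = -0.5
    mkt_max: float = 3.0


@dataclass
class ParameterMaps:
    """Voxelwise MD (10^-3 mm^2/s) and MKT maps with a quality-control mask.

    Where ``qc_mask`` is False the maps hold NaN; where True, MD > 0 and MKT
    lies within the configured physical bounds.
    """

    md_map: np.ndarray
    mkt_map: np.ndarray
    qc_mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        if not (self.md_map.shape == self.mkt_map.shape == self.qc_mask.shape):
            raise ValueError("md, mkt and qc grids must share one shape")


def forward_signal(model: KurtosisTissueModel, scheme: DiffusionScheme) -> np.ndarray:
    """Noise-free signal amplitudes in canonical order (b0, axes@b1, shell2@b2)."""
    md = model.md
    out = [model.S0] * scheme.b0_count

    def _ln_atten(b, n):
        dn = float(n @ model.D @ n)
        wn = float(np.einsum("ijlm,i,j,l,m->", model.W, n, n, n, n))
        bd = b * MD_UNIT
        return -bd * dn + (bd * md) ** 2 * wn / 6.0

    for n in scheme.axis_directions:
        out.append(model.S0 * np.exp(_ln_atten(scheme.b1, n)))
    for n in scheme.shell2_directions:
        out.append(model.S0 * np.exp(_ln_atten(scheme.b2, n)))
    return np.array(out)


def axis_diffusivity(h1, h2, b1: float, b2: float, return_v: bool = False):
    """Axis diffusivity from two log-attenuations on the same direction.

    Solves h(b) = -b*D + (1/6)*b^2*V exactly for D (and optionally the
    quadratic coefficient V = MD^2 * W(n), a per-axis diagnostic).  Inputs
    may be scalars or arrays; b in s/mm^2, D returned in 10^-3 mm^2/s.
    Non-finite inputs propagate to NaN so the voxel can be flagged.
    """
    if not (0 < b1 < b2):
        raise ValueError(f"require 0 < b1 < b2, got b1={b1}, b2={b2}")
    h1 = np.asarray(h1, float)
    h2 = np.asarray(h2, float)
    d = (b1 ** 2 * h2 - b2 ** 2 * h1) / (b1 * b2 * (b2 - b1)) / MD_UNIT
    if return_v:
        v = 6.0 * (b2 * h1 - b1 * h2) / (b1 * b2 * (b1 - b2)) / MD_UNIT ** 2
        return d, v
    return d


def mean_diffusivity(dx, dy, dz):
    """MD = (Dxx + Dyy + Dzz) / 3, in 10^-3 mm^2/s."""
    return (np.asarray(dx, float) + np.asarray(dy, float) + np.asarray(dz, float)) / 3.0


def mean_kurtosis_tensor(shell2_log_attenuations, md, scheme: DiffusionScheme):
    """MKT from the weighted high-shell log-attenuations and MD.

    MKT = 6*(h_bar + b2*MD) / (b2*MD)^2 with h_bar the quadrature-weighted
    mean of the nine shell-2 log-attenuations.  Exact (to machine precision)
    for noise-free signals of the quartic model, by degree-4 quadrature
    exactness.  ``shell2_log_attenuations`` has shape (..., 9); ``md`` in
    10^-3 mm^2/s.  Voxels with md <= 0 or non-finite inputs yield NaN.
    """
    h = np.asarray(shell2_log_attenuations, float)
    md = np.asarray(md, float)
    if h.shape[-1] != len(scheme.shell2_weights):
        raise ValueError("expected one log-attenuation per shell-2 direction")
    hbar = h @ scheme.shell2_weights
    bd = scheme.b2 * MD_UNIT * md
    with np.errstate(divide="ignore", invalid="ignore"):
        mkt = 6.0 * (hbar + bd) / bd ** 2
    mkt = np.where(md > 0, mkt, np.nan)
    return mkt if mkt.ndim else float(mkt)


_LOG_MOMENT_TABLE = None


def _log_moment_table():
    """Tabulate phi(lambda) = E[ln X] for X ~ noncentral chi-square(2, lambda).

    X is a chi-square with 2 + 2J degrees of freedom, J ~ Poisson(lambda/2),
    and E[ln chi2_m] = psi(m/2) + ln 2, so phi(lambda) = ln 2 +
    E_J[psi(1 + J)].  The Poisson series is summed exactly for lambda up to
    2000; beyond that a third-order asymptotic expansion in the central
    moments is used (the two agree to < 1e-6 at the splice).
    """
    global _LOG_MOMENT_TABLE
    if _LOG_MOMENT_TABLE is not None:
        return _LOG_MOMENT_TABLE
    from scipy.special import digamma, gammaln

    lam = np.concatenate([[0.0], np.logspace(-4, np.log10(2000.0), 700)])
    kmax = 1000 + int(2000 / 2 + 12 * np.sqrt(2000 / 2))
    k = np.arange(kmax)
    psi1k = digamma(1 + k)
    lgk = gammaln(k + 1.0)
    phi_lo = np.empty(lam.size)
    for i, l in enumerate(lam):
        mu = l / 2.0
        if mu == 0:
            phi_lo[i] = np.log(2.0) + digamma(1.0)
            continue
        logw = -mu + k * np.log(mu) - lgk
        phi_lo[i] = np.log(2.0) + np.exp(logw) @ psi1k
    lam_hi = np.logspace(np.log10(2000.0) + 1e-9, 16, 300)
    m = 2.0 + lam_hi
    var = 4.0 + 4.0 * lam_hi
    mu3 = 8.0 * (2.0 + 3.0 * lam_hi)
    phi_hi = np.log(m) - var / (2.0 * m ** 2) + mu3 / (3.0 * m ** 3)
    lam_all = np.concatenate([lam, lam_hi])
    phi_all = np.concatenate([phi_lo, phi_hi])
    _LOG_MOMENT_TABLE = (phi_all, lam_all)
    return _LOG_MOMENT_TABLE


def _rician_log_amplitude(amplitude: np.ndarray, sigma: float):
    """Noise-compensated log amplitude via exact log-moment inversion.

    Given a floor-corrected Rician amplitude S (so the raw magnitude power
    is M^2 = S^2 + 2*sigma^2, distributed as sigma^2 * X with X a noncentral
    chi-square(2, lambda), lambda = A^2/sigma^2), the true log amplitude is
    estimated by inverting the exact expectation phi(lambda) = E[ln X]:

        lambda_hat = phi^{-1}(ln(M^2 / sigma^2)),   ln A_hat = (1/2) ln(sigma^2 * lambda_hat)

    This remap is monotone and, unlike the naive ln S, carries no
    first-order Jensen bias; it stays finite and well-behaved down to the
    noise floor.  Returns (ln A_hat, 1/lambda_hat); the latter is the
    squared noise-to-signal ratio sigma^2/A^2 used for variance estimates.
    """
    phi, lam = _log_moment_table()
    y = amplitude ** 2 + 2.0 * sigma ** 2
    x = np.log(y / sigma ** 2)
    lam_hat = np.interp(x, phi, lam)
    lam_hat = np.maximum(lam_hat, 1e-12)
    log_a = 0.5 * np.log(sigma ** 2 * lam_hat)
    return log_a, 1.0 / lam_hat


def _noise_compensation(r: np.ndarray, md: np.ndarray, h2_all: np.ndarray,
                        scheme: DiffusionScheme) -> np.ndarray:
    """Delta-method estimate of the second-order noise bias of the MKT.

    The MKT estimator g(h_bar, MD) is nonlinear in the noisy MD that enters
    its denominator, so even with unbiased log-attenuations E[g] differs
    from g(E[.]) at second order.  Both h_bar and MD are linear forms in the
    per-volume log amplitudes, whose variances are approximately
    sigma^2/Y + sigma^4/Y^2 (independent across volumes); the bias

        (1/2) g_uu Var(u) + g_{h u} Cov(h_bar, u),   u = b2 * MD * 1e-3

    is evaluated with plug-in values and subtracted by the caller.
    ``r`` holds the per-volume squared noise-to-signal ratios sigma^2/A^2.
    """
    n0 = scheme.b0_count
    n_ax = len(scheme.axis_directions)
    nv = scheme.n_volumes
    b1, b2 = scheme.b1, scheme.b2
    # md = sum_j a_j * l_j over volumes (axes at b1, their b2 copies, and -S0)
    c1 = -b2 / (b1 * (b2 - b1)) / MD_UNIT / n_ax
    c2 = b1 / (b2 * (b2 - b1)) / MD_UNIT / n_ax
    a = np.zeros(nv)
    a[n0:n0 + n_ax] = c1
    a[n0 + n_ax + scheme.axis_indices_in_shell2] += c2
    a[:n0] = -(n_ax * (c1 + c2)) / n0
    # h_bar = sum_j b_j * l_j
    bb = np.zeros(nv)
    bb[n0 + n_ax:] = scheme.shell2_weights
    bb[:n0] = -1.0 / n0

    rc = np.minimum(r, 1.0)
    v = rc + rc ** 2                    # per-volume log-amplitude variance
    var_md = v @ (a ** 2)
    cov_hm = v @ (a * bb)

    hbar = h2_all @ scheme.shell2_weights
    u = b2 * MD_UNIT * md
    cu = b2 * MD_UNIT
    var_u = cu ** 2 * var_md
    cov_hu = cu * cov_hm
    # the u^-3 / u^-4 factors are evaluated at the noisy plug-in u, which
    # inflates their expectation by (1 + 6q) resp. (1 + 10q), q = Var(u)/u^2;
    # deflate so the compensation matches its oracle value to second order
    q = np.minimum(var_u / u ** 2, 1.0)
    t4 = 36.0 * hbar / (u ** 4 * (1.0 + 10.0 * q))
    t3 = 12.0 / (u ** 3 * (1.0 + 6.0 * q))
    g_hu = -12.0 / (u ** 3 * (1.0 + 6.0 * q))
    comp = 0.5 * (t4 + t3) * var_u + g_hu * cov_hu
    return np.clip(comp, -2.0, 2.0)


def fit_parameter_maps(
    study: DWIStudy,
    brain_mask: np.ndarray,
    bounds: QCBounds | None = None,
) -> ParameterMaps:
    """Voxelwise closed-form 1-3-9 fit inside a brain mask.

    Pipeline per voxel: log-attenuation -> per-axis two-point diffusivity ->
    MD -> quadrature MKT.  Voxels violating sanity rules (any S <= 0, any
    diffusion-weighted S >= S0, MD outside (0, md_max], MKT outside
    [mkt_min, mkt_max]) get qc_mask = False and NaN in the maps.
    Deterministic for fixed input.

    When the study carries a known noise level (sigma > 0, e.g. propagated
    by the Rice-floor preprocessing), the log-attenuations come from the
    exact Rician log-moment inversion (``_rician_log_amplitude``) and the
    MKT is compensated for its second-order noise bias
    (``_noise_compensation``).  With sigma = 0 the fit is the plain closed
    form, exact on noise-free data.
    """
    bounds = bounds or QCBounds()
    scheme = study.scheme
    mask = np.asarray(brain_mask, bool)
    if mask.shape != study.data.shape[:3]:
        raise ValueError("brain mask grid does not match the DWI grid")

    sig = study.data[mask]                       # (N, 13)
    n0 = scheme.b0_count
    n_ax = len(scheme.axis_directions)
    s0 = sig[:, :n0].mean(axis=1)
    dwi = sig[:, n0:]
    sigma = float(study.sigma or 0.0)

    usable = (s0 > 0) & np.all(dwi > 0, axis=1) & np.all(dwi < s0[:, None], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if sigma > 0:
            l_all, r_all = _rician_log_amplitude(sig, sigma)
            l0 = l_all[:, :n0].mean(axis=1)
            h = l_all[:, n0:] - l0[:, None]
        else:
            h = np.log(dwi / s0[:, None])
    h[~usable] = np.nan

    h1_ax = h[:, :n_ax]
    h2_all = h[:, n_ax:]
    h2_ax = h2_all[:, scheme.axis_indices_in_shell2]
    d_ax = axis_diffusivity(h1_ax, h2_ax, scheme.b1, scheme.b2)
    md = mean_diffusivity(d_ax[:, 0], d_ax[:, 1], d_ax[:, 2])
    mkt = mean_kurtosis_tensor(h2_all, md, scheme)
    if sigma > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            mkt = mkt - _noise_compensation(r_all, md, h2_all, scheme)

    ok = (
        usable
        & np.isfinite(md) & np.isfinite(mkt)
        & (md > 0) & (md <= bounds.md_max)
        & (mkt >= bounds.mkt_min) & (mkt <= bounds.mkt_max)
    )
    md = np.where(ok, md, np.nan)
    mkt = np.where(ok, mkt, np.nan)

    shape = study.data.shape[:3]
    md_map = np.full(shape, np.nan)
    mkt_map = np.full(shape, np.nan)
    qc = np.zeros(shape, bool)
    md_map[mask] = md
    mkt_map[mask] = mkt
    qc[mask] = ok
    return ParameterMaps(md_map=md_map, mkt_map=mkt_map, qc_mask=qc, affine=study.affine)
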