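"""Natural cubic spline bases and the exposure-lag cross-basis.

The cross-basis is the design-matrix block of a distributed lag non-linear
model (DLNM): the row-wise tensor product of a spline basis over temperature
(the exposure dimension) and a spline basis over lag days (the lag
dimension).  Both dimensions use natural cubic splines, whose linear tails
beyond the boundary knots double as the extrapolation rule for projected
temperatures outside the historical range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class SplineSpec:
    """Definition of a natural cubic spline basis.

    Parameters
    ----------
    internal_knots : tuple of float
        Knots strictly inside the boundary pair, strictly increasing.
    boundary_knots : (float, float)
        Outside this interval every basis function continues linearly
        (zero second derivative), which is the natural-spline contract.
    with_intercept : bool
        If True the basis spans constants (df = len(internal)+2); if False
        the first column is dropped (df = len(internal)+1) and an external
        intercept is expected in the model.
    """

    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    with_intercept: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError(f"boundary knots must be increasing, got {self.boundary_knots}")
        ik = np.asarray(self.internal_knots, dtype=float)
        if ik.size and (np.any(np.diff(ik) <= 0)):
            raise ValueError(f"internal knots must be strictly increasing, got {self.internal_knots}")
        if ik.size and (ik[0] <= lo or ik[-1] >= hi):
            raise ValueError("internal knots must lie strictly inside the boundary knots")

    @property
    def df(self) -> int:
        return len(self.internal_knots) + 1 + (1 if self.with_intercept else 0)


def _natural_transform(spec: SplineSpec) -> tuple[BSpline, np.ndarray]:
    """Cubic B-spline family on the spec's knots plus the linear map onto
    the natural (second-derivative-free at the boundaries) subspace."""
    lo, hi = spec.boundary_knots
    aknots = np.concatenate([[lo] * 4, np.asarray(spec.internal_knots, float), [hi] * 4])
    nb = len(spec.internal_knots) + 4
    bs = BSpline(aknots, np.eye(nb), 3, extrapolate=False)
    # constraint: second derivative vanishes at both boundary knots
    con = bs.derivative(2)(np.array([lo, hi]))  # 2 x nb
    q, _ = np.linalg.qr(con.T, mode="complete")
    return bs, q[:, 2:]  # nb x (nb-2) null-space map


def ns_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at `x`.

    Returns an ``(n, spec.df)`` matrix.  Points beyond the boundary knots
    are extrapolated linearly (value and slope at the nearest boundary),
    so second differences of every column vanish outside the boundaries.
    """
    x = np.asarray(x, dtype=float)
    shape = x.shape
    x = np.ravel(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("basis evaluation points must be finite")
    if spec.df < 1:
        raise ValueError("spline specification implies fewer than one column")
    lo, hi = spec.boundary_knots
    bs, nmap = _natural_transform(spec)
    out = np.empty((x.size, nmap.shape[1]))

    inside = (x >= lo) & (x <= hi)
    if np.any(inside):
        out[inside] = bs(x[inside]) @ nmap
    d1 = bs.derivative(1)
    for bound, mask in ((lo, x < lo), (hi, x > hi)):
        if np.any(mask):
            b = np.array([bound])
            val = (bs(b) @ nmap)[0]
            slope = (d1(b) @ nmap)[0]
            out[mask] = val + np.outer(x[mask] - bound, slope)

    if not spec.with_intercept:
        out = out[:, 1:]
    return out.reshape(*shape, out.shape[1])


def percentile_knots(values, percentiles) -> tuple[float, ...]:
    """Internal knots at the given percentiles (linear interpolation
    between order statistics) of an observed sample."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    return tuple(float(k) for k in np.percentile(v, list(percentiles)))


def exposure_spec_from_sample(tmean, percentiles=(10, 75, 90)) -> SplineSpec:
    """Exposure-dimension spec with knots at sample percentiles and
    boundary knots at the observed min/max of the fitting period."""
    v = np.asarray(tmean, dtype=float)
    v = v[np.isfinite(v)]
    return SplineSpec(
        internal_knots=percentile_knots(v, percentiles),
        boundary_knots=(float(v.min()), float(v.max())),
        with_intercept=False,
    )


def lag_spec(max_lag: int = 21, n_internal: int = 2) -> SplineSpec:
    """Lag-dimension spec: natural cubic spline over 0..max_lag with
    equally spaced internal knots and an intercept."""
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    internal = tuple(np.linspace(0, max_lag, n_internal + 2)[1:-1]) if n_internal else ()
    return SplineSpec(internal_knots=internal, boundary_knots=(0.0, float(max_lag)), with_intercept=True)


@dataclass(frozen=True)
class CrossBasisSpec:
    """Pair of spline specs defining a DLNM cross-basis."""

    var_spec: SplineSpec
    lag_spec: SplineSpec
    max_lag: int = 21

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.var_spec.with_intercept:
            raise ValueError("exposure basis must not carry an intercept")
        if not self.lag_spec.with_intercept:
            raise ValueError("lag basis must carry an intercept")

    @property
    def vx(self) -> int:
        return self.var_spec.df

    @property
    def vl(self) -> int:
        return self.lag_spec.df

    @property
    def ncol(self) -> int:
        return self.vx * self.vl

    def lag_basis_matrix(self) -> np.ndarray:
        """Lag basis evaluated at integer lags 0..max_lag: (max_lag+1, vl)."""
        return ns_basis(np.arange(self.max_lag + 1, dtype=float), self.lag_spec)

    def column_labels(self) -> list[str]:
        return [f"cb_v{j + 1}_l{k + 1}" for j in range(self.vx) for k in range(self.vl)]


@dataclass
class CrossBasis:
    """Evaluated cross-basis: matrix of shape (n_days, vx*vl).

    Rows before ``valid_from`` lack a complete lag window and must be
    excluded from any fit.
    """

    matrix: np.ndarray
    spec: CrossBasisSpec
    valid_from: int
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = self.spec.column_labels()


def build_crossbasis(tmean, spec: CrossBasisSpec, history=None) -> CrossBasis:
    """Build the cross-basis for a daily temperature series.

    Row t holds sum_{l=0..L} vbasis(T[t-l])_j * lbasis(l)_k over all (j, k)
    pairs, column-ordered exposure-major.  If ``history`` (the max_lag
    temperatures immediately preceding the series) is given, all rows are
    valid; otherwise the first max_lag rows are flagged unusable.
    """
    t = np.asarray(tmean, dtype=float)
    L = spec.max_lag
    if t.size <= L:
        raise ValueError(f"series length {t.size} must exceed max_lag {L}")
    if history is not None:
        h = np.asarray(history, dtype=float)
        if h.size != L:
            raise ValueError(f"history must supply exactly {L} leading temperatures")
        full = np.concatenate([h, t])
        valid_from = 0
    else:
        full = np.concatenate([np.full(L, np.nan), t])
        valid_from = L

    n = t.size
    # lagged[t, l] = temperature at day t, lag l
    idx = np.arange(L, L + n)[:, None] - np.arange(L + 1)[None, :]
    lagged = full[idx]
    filled = np.where(np.isfinite(lagged), lagged, np.nanmean(t))
    vb = ns_basis(filled.ravel(), spec.var_spec).reshape(n, L + 1, spec.vx)
    lb = spec.lag_basis_matrix()  # (L+1, vl)
    # mat[t, j, k] = sum_l vb[t, l, j] * lb[l, k]
    mat = np.einsum("tlj,lk->tjk", vb, lb).reshape(n, spec.ncol)
    mat[:valid_from] = np.nan
    return CrossBasis(matrix=mat, spec=spec, valid_from=valid_from)
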