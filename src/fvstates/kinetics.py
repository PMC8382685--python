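"""Kinetic analysis: tICA, free-energy surfaces, Markov-state models.

The workflow mirrors the standard MSM pipeline for loop dynamics:
sin/cos torsion features -> tICA at a lag time (default 10 ns) -> k-means
discretization into microstates (default 150) -> reversible
maximum-likelihood MSM -> PCCA+ coarse-graining into metastable
macrostates, validated by implied timescales and the Chapman-Kolmogorov
test.  tICA, the reversible estimator, PCCA+ and the CK test are
implemented here; k-means comes from scikit-learn.

Estimators follow the scikit-learn protocol (``fit``, ``transform``,
``get_params``, trailing-underscore fitted attributes).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

from .errors import EstimationError, FeatureError, InputError
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

#: Boltzmann constant in kcal/(mol K).
KB_KCAL = 0.0019872041

DEFAULT_LAG_NS = 10.0
DEFAULT_N_MICROSTATES = 150
DEFAULT_TEMPERATURE = 300.0


def _as_feature_arrays(X):
    """Accept FeatureMatrix, array, or list thereof; return (list, labels)."""
    if isinstance(X, FeatureMatrix):
        return [np.asarray(X.values, float)], list(X.labels)
    if isinstance(X, np.ndarray):
        return [np.asarray(X, float)], None
    if isinstance(X, (list, tuple)):
        arrays, labels = [], None
        for item in X:
            a, lab = _as_feature_arrays(item)
            arrays.extend(a)
            labels = labels or lab
        return arrays, labels
    raise InputError(f"unsupported feature input type {type(X)!r}")


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------

class TICA(BaseEstimator, TransformerMixin):
    """Time-lagged independent component analysis.

    Finds linear combinations of the input features with maximal
    autocorrelation at ``lag`` frames by solving the symmetrized
    generalized eigenproblem ``C_tau v = lambda C_0 v``.  The leading
    components (tIC1, tIC2, ...) approximate the slowest collective
    degrees of freedom and are the coordinate system for free-energy
    surfaces and microstate definition.

    Parameters
    ----------
    lag : int
        Lag time in frames (>= 1).
    n_components : int or None
        Components kept by :meth:`transform` (None = all).
    eig_floor : float
        Relative eigenvalue floor for the C0 regularization: directions of
        C0 with eigenvalue <= ``eig_floor * trace(C0)`` are treated as
        null space and dropped (sin/cos features can be exactly linearly
        dependent).

    Attributes
    ----------
    mean_ : (n_features,) feature mean over all lagged pairs.
    c0_, ctau_ : instantaneous and symmetrized time-lagged covariance.
    eigenvalues_ : descending, real, |lambda| <= 1 (up to round-off).
    eigenvectors_ : columns, C0-orthonormal (v.T @ C0 @ v = I).
    """

    def __init__(self, lag: int = 1, n_components: int | None = None, eig_floor: float = 1e-10):
        self.lag = lag
        self.n_components = n_components
        self.eig_floor = eig_floor

    def fit(self, X, y=None):
        arrays, labels = _as_feature_arrays(X)
        lag = int(self.lag)
        if lag < 1:
            raise InputError("lag must be >= 1 frame")
        pairs0, pairst = [], []
        for a in arrays:
            if a.ndim != 2:
                raise InputError("feature arrays must be 2-D (frames x features)")
            if a.shape[0] <= lag:
                raise InputError(
                    f"trajectory of {a.shape[0]} frames too short for lag {lag}"
                )
            pairs0.append(a[:-lag])
            pairst.append(a[lag:])
        x0 = np.concatenate(pairs0)
        xt = np.concatenate(pairst)
        if x0.shape[1] < 2:
            raise InputError("need at least 2 features")
        mean = (x0.mean(axis=0) + xt.mean(axis=0)) / 2.0
        x0 = x0 - mean
        xt = xt - mean
        n = x0.shape[0]
        c0 = (x0.T @ x0 + xt.T @ xt) / (2.0 * n)
        ct = (x0.T @ xt + xt.T @ x0) / (2.0 * n)

        # regularized whitening of C0
        s, u = scipy.linalg.eigh(c0)
        floor = self.eig_floor * max(np.trace(c0), np.finfo(float).tiny)
        keep = s > floor
        if not np.any(keep):
            raise EstimationError("C0 is rank deficient after regularization")
        if not np.all(keep):
            logger.info("tICA: dropping %d null-space direction(s)", int(np.sum(~keep)))
        w = u[:, keep] / np.sqrt(s[keep])
        m = w.T @ ct @ w
        lam, v = scipy.linalg.eigh(m)
        order = np.argsort(lam)[::-1]
        lam = lam[order]
        vecs = w @ v[:, order]
        # deterministic sign: largest-magnitude loading positive
        for j in range(vecs.shape[1]):
            i = int(np.argmax(np.abs(vecs[:, j])))
            if vecs[i, j] < 0:
                vecs[:, j] = -vecs[:, j]
        self.mean_ = mean
        self.c0_ = c0
        self.ctau_ = ct
        self.eigenvalues_ = lam
        self.eigenvectors_ = vecs
        self.labels_ = labels
        self.n_features_in_ = c0.shape[0]
        return self

    def transform(self, X):
        """Project features into tIC space: (x - mean) @ eigenvectors."""
        if isinstance(X, FeatureMatrix):
            if self.labels_ is not None and list(X.labels) != self.labels_:
                raise FeatureError("feature labels do not match the fitted model")
            x = np.asarray(X.values, float)
        else:
            x = np.asarray(X, float)
        single = x.ndim == 1
        if single:
            x = x[None]
        if x.shape[1] != self.n_features_in_:
            raise FeatureError(
                f"feature count mismatch: {x.shape[1]} vs fitted {self.n_features_in_}"
            )
        k = self.n_components or self.eigenvectors_.shape[1]
        y = (x - self.mean_) @ self.eigenvectors_[:, :k]
        return y[0] if single else y


def fit_tica(features, lag: int, **kwargs) -> TICA:
    return TICA(lag=lag, **kwargs).fit(features)


def project(model: TICA, features):
    return model.transform(features)


# ---------------------------------------------------------------------------
# free-energy surface
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergySurface:
    """2-D free-energy surface over (tIC1, tIC2).

    F = -kB T ln(p / p_max) in kcal/mol; empty bins are +inf; the global
    minimum bin is exactly 0.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    populations: np.ndarray  # (nx, ny) counts fraction
    free_energy: np.ndarray  # (nx, ny) kcal/mol
    temperature: float

    def to_dataframe(self):
        import pandas as pd

        xc = (self.x_edges[:-1] + self.x_edges[1:]) / 2
        yc = (self.y_edges[:-1] + self.y_edges[1:]) / 2
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame(
            {
                "tic1": xx.ravel(),
                "tic2": yy.ravel(),
                "population": self.populations.ravel(),
                "free_energy_kcal_mol": self.free_energy.ravel(),
            }
        )


def free_energy_surface(
    projected: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    bins: int | tuple = 100,
    pad: float = 0.05,
) -> FreeEnergySurface:
    """Histogram the first two projected coordinates into a free-energy map.

    The grid spans the data range padded by ``pad`` (fraction) per side.
    """
    if temperature <= 0:
        raise InputError("temperature must be positive")
    x = np.asarray(projected, float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 1:
        raise InputError("need at least one point")
    a = x[:, 0]
    b = x[:, 1] if x.shape[1] > 1 else np.zeros_like(a)

    def _edges(v, nb):
        lo, hi = float(np.min(v)), float(np.max(v))
        span = hi - lo
        if span == 0:
            lo, hi = lo - 0.5, hi + 0.5
        else:
            lo, hi = lo - pad * span, hi + pad * span
        return np.linspace(lo, hi, nb + 1)

    nx, ny = (bins, bins) if np.isscalar(bins) else bins
    counts, xe, ye = np.histogram2d(a, b, bins=[_edges(a, nx), _edges(b, ny)])
    p = counts / counts.sum()
    with np.errstate(divide="ignore"):
        f = -KB_KCAL * temperature * np.log(p / p.max())
    f[p == 0] = np.inf
    return FreeEnergySurface(
        x_edges=xe, y_edges=ye, populations=p, free_energy=f, temperature=temperature
    )


# ---------------------------------------------------------------------------
# microstates
# ---------------------------------------------------------------------------

def kmeans_microstates(
    projected, k: int = DEFAULT_N_MICROSTATES, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """k-means microstate definition (k-means++ init, Lloyd iterations).

    Returns (centers, discrete trajectory).  ``projected`` may be a single
    (frames, d) array or a list of arrays; in the latter case the discrete
    trajectory is a list matching the input.
    """
    items = projected if isinstance(projected, (list, tuple)) else [np.asarray(projected, float)]
    items = [np.atleast_2d(np.asarray(a, float)) for a in items]
    data = np.concatenate(items)
    if data.shape[0] < k:
        raise InputError(f"k={k} exceeds number of points {data.shape[0]}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=500,
        tol=1e-6,
        random_state=int(seed),
    ).fit(data)
    dtrajs = [km.predict(a) for a in items]
    if isinstance(projected, (list, tuple)):
        return km.cluster_centers_, dtrajs
    return km.cluster_centers_, dtrajs[0]


# ---------------------------------------------------------------------------
# Markov-state model
# ---------------------------------------------------------------------------

def count_matrix(dtrajs, lag: int, n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts at ``lag`` frames."""
    if lag < 1:
        raise InputError("lag must be >= 1")
    dtrajs = [np.asarray(d, int) for d in _as_dtraj_list(dtrajs)]
    n = n_states or (max(int(d.max()) for d in dtrajs if d.size) + 1)
    c = np.zeros((n, n))
    for d in dtrajs:
        if len(d) <= lag:
            raise InputError(f"trajectory of {len(d)} frames too short for lag {lag}")
        np.add.at(c, (d[:-lag], d[lag:]), 1.0)
    return c


def _as_dtraj_list(dtrajs):
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        return [dtrajs]
    if isinstance(dtrajs, (list, tuple)) and dtrajs and np.isscalar(dtrajs[0]):
        return [np.asarray(dtrajs)]
    return list(dtrajs)


def largest_connected_set(c: np.ndarray) -> np.ndarray:
    """States of the largest strongly connected component of the count graph."""
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    n_comp, assign = connected_components(sp.csr_matrix(c > 0), connection="strong")
    sizes = np.bincount(assign, minlength=n_comp)
    # prefer the component with the most counts, ties by size
    weights = np.zeros(n_comp)
    for comp in range(n_comp):
        members = np.nonzero(assign == comp)[0]
        weights[comp] = c[np.ix_(members, members)].sum()
    best = int(np.argmax(weights + 1e-9 * sizes))
    return np.nonzero(assign == best)[0]


def reversible_transition_matrix(
    c: np.ndarray, tol: float = 1e-10, max_iter: int = 100000
) -> tuple[np.ndarray, np.ndarray]:
    """Reversible maximum-likelihood transition matrix from counts.

    Self-consistent fixed-point iteration on the symmetric count surrogate
    ``x_ij``: x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j), which converges
    to the MLE under detailed balance.  Returns (T, pi).
    """
    c = np.asarray(c, float)
    csym = c + c.T
    x = csym.copy()
    crow = c.sum(axis=1)
    if np.any(crow == 0):
        raise EstimationError("count matrix has an empty row; restrict to connected set")
    for _ in range(max_iter):
        xrow = x.sum(axis=1)
        q = crow / xrow
        denom = q[:, None] + q[None, :]
        x_new = np.where(csym > 0, csym / denom, 0.0)
        delta = np.max(np.abs(x_new - x)) / max(np.max(np.abs(x)), 1e-300)
        x = x_new
        if delta < tol:
            break
    xrow = x.sum(axis=1)
    t = x / xrow[:, None]
    pi = xrow / xrow.sum()
    return t, pi


def nonreversible_transition_matrix(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized counts and the stationary left eigenvector."""
    c = np.asarray(c, float)
    t = c / c.sum(axis=1, keepdims=True)
    vals, vecs = scipy.linalg.eig(t.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi) / np.abs(pi).sum()
    return t, pi


class MarkovStateModel(BaseEstimator):
    """Reversible maximum-likelihood Markov-state model.

    Parameters
    ----------
    lag : int
        Lag time in frames for the sliding-window count matrix.
    reversible : bool
        Estimate under detailed balance (default) or by plain row
        normalization.

    Attributes
    ----------
    count_matrix_ : full transition counts at ``lag``.
    active_set_ : states of the largest strongly connected component.
    transition_matrix_ : row-stochastic T over the active set.
    stationary_distribution_ : pi with pi @ T = pi.
    """

    def __init__(self, lag: int = 1, reversible: bool = True):
        self.lag = lag
        self.reversible = reversible

    def fit(self, dtrajs, y=None):
        c_full = count_matrix(dtrajs, int(self.lag))
        active = largest_connected_set(c_full)
        if active.size == 0:
            raise EstimationError("empty connected set")
        dropped = c_full.shape[0] - active.size
        if dropped:
            logger.info("MSM: %d state(s) outside the largest connected set pruned", dropped)
        c = c_full[np.ix_(active, active)]
        if self.reversible:
            t, pi = reversible_transition_matrix(c)
        else:
            t, pi = nonreversible_transition_matrix(c)
        self.count_matrix_ = c_full
        self.active_set_ = active
        self.transition_matrix_ = t
        self.stationary_distribution_ = pi
        return self

    @property
    def n_states_(self) -> int:
        return len(self.active_set_)

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        """Real sorted eigenvalues (descending); reversible T is symmetrized
        with pi^(1/2) so the spectrum is exactly real."""
        t = self.transition_matrix_
        if self.reversible:
            pi = self.stationary_distribution_
            sq = np.sqrt(pi)
            sym = (sq[:, None] * t) / sq[None, :]
            lam = scipy.linalg.eigvalsh((sym + sym.T) / 2.0)[::-1]
        else:
            lam = np.sort(np.real(scipy.linalg.eigvals(t)))[::-1]
        return lam if k is None else lam[:k]

    def right_eigenvectors(self, k: int) -> np.ndarray:
        """First k dominant right eigenvectors (pi-orthonormal, reversible)."""
        pi = self.stationary_distribution_
        sq = np.sqrt(pi)
        t = self.transition_matrix_
        sym = (sq[:, None] * t) / sq[None, :]
        lam, u = scipy.linalg.eigh((sym + sym.T) / 2.0)
        order = np.argsort(lam)[::-1][:k]
        psi = u[:, order] / sq[:, None]
        # normalize the stationary eigenvector to exactly 1
        psi[:, 0] = psi[:, 0] / psi[0, 0] if psi[0, 0] != 0 else psi[:, 0]
        return psi

    def timescales(self, k: int | None = None) -> np.ndarray:
        """Implied timescales -lag / ln|lambda_i| in frames (excluding the
        stationary eigenvalue); non-positive eigenvalues yield NaN."""
        lam = self.eigenvalues()[1:]
        if k is not None:
            lam = lam[:k]
        out = np.full(lam.shape, np.nan)
        ok = lam > 0
        if np.any(lam <= 0):
            logger.warning("non-positive eigenvalue(s); timescale undefined")
        near_one = ok & np.isclose(lam, 1.0)
        if np.any(near_one):
            logger.warning("eigenvalue ~1 beyond the stationary one; timescale undefined")
            ok &= ~near_one
        out[ok] = -float(self.lag) / np.log(lam[ok])
        return out


def estimate_msm(dtrajs, lag: int, reversible: bool = True) -> MarkovStateModel:
    return MarkovStateModel(lag=lag, reversible=reversible).fit(dtrajs)


def implied_timescales(dtrajs, lags, k: int = 5, reversible: bool = True):
    """Implied timescales (frames) for each lag; rows = lags, cols = modes."""
    lags = [int(l) for l in np.atleast_1d(lags)]
    out = np.full((len(lags), k), np.nan)
    for i, lag in enumerate(lags):
        ts = estimate_msm(dtrajs, lag, reversible).timescales(k)
        out[i, : len(ts)] = ts[:k]
    return np.asarray(lags), out


# ---------------------------------------------------------------------------
# PCCA+
# ---------------------------------------------------------------------------

class PCCAPlus(BaseEstimator):
    """PCCA+ fuzzy coarse-graining of microstates into macrostates.

    Uses the inner-simplex construction on the first n dominant right
    eigenvectors of the reversible transition matrix: the rows of the
    eigenvector matrix live (approximately) on an (n-1)-simplex whose
    vertices correspond to the metastable sets; memberships are the
    barycentric coordinates, clipped to [0, 1] and row-normalized.

    Attributes
    ----------
    memberships_ : (microstates, macrostates) chi matrix, rows sum to 1.
    assignments_ : crisp macrostate per microstate (argmax membership).
    populations_ : crisp macrostate stationary populations (sum of pi).
    fuzzy_populations_ : chi-weighted populations (pi @ chi).
    coarse_transition_matrix_ : row-normalized chi^T diag(pi) T chi.
    """

    def __init__(self, n_macrostates: int = 2):
        self.n_macrostates = n_macrostates

    def fit(self, msm: MarkovStateModel, y=None):
        n = int(self.n_macrostates)
        m = msm.n_states_
        if not 2 <= n <= m:
            raise InputError(f"n_macrostates must be in [2, {m}]")
        lam = msm.eigenvalues(n + 1)
        if n < m and lam[n] > 0 and abs(lam[n - 1]) < abs(lam[n]) * 1.05:
            logger.warning(
                "weak spectral gap after %d macrostates (lambda_%d=%.4f, lambda_%d=%.4f)",
                n, n - 1, lam[n - 1], n, lam[n],
            )
        x = msm.right_eigenvectors(n)
        chi = _inner_simplex_memberships(x)
        pi = msm.stationary_distribution_
        t = msm.transition_matrix_
        assign = np.argmax(chi, axis=1)
        pops = np.array([pi[assign == a].sum() for a in range(n)])
        coarse = chi.T @ (pi[:, None] * t) @ chi
        coarse = coarse / coarse.sum(axis=1, keepdims=True)
        self.memberships_ = chi
        self.assignments_ = assign
        self.populations_ = pops
        self.fuzzy_populations_ = pi @ chi
        self.coarse_transition_matrix_ = coarse
        return self


def _inner_simplex_memberships(x: np.ndarray) -> np.ndarray:
    """Inner-simplex algorithm: find n extreme rows of x, invert, clip."""
    m, n = x.shape
    vertices = [int(np.argmax(np.linalg.norm(x - x.mean(axis=0), axis=1)))]
    ortho = x - x[vertices[0]]
    for _ in range(1, n):
        norms = np.linalg.norm(ortho, axis=1)
        nxt = int(np.argmax(norms))
        vertices.append(nxt)
        v = ortho[nxt]
        nv = np.linalg.norm(v)
        if nv > 0:
            v = v / nv
            ortho = ortho - np.outer(ortho @ v, v)
    a = np.linalg.solve(x[vertices], np.eye(n))
    chi = x @ a
    chi = np.clip(chi, 0.0, 1.0)
    rows = chi.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return chi / rows


def pcca(msm: MarkovStateModel, n_macrostates: int) -> PCCAPlus:
    return PCCAPlus(n_macrostates=n_macrostates).fit(msm)


def coarse_mfpt(msm: MarkovStateModel, pcca_model: PCCAPlus) -> np.ndarray:
    """Mean first-passage times (frames) between crisp macrostates."""
    t = msm.transition_matrix_
    assign = pcca_model.assignments_
    n = pcca_model.memberships_.shape[1]
    lag = float(msm.lag)
    out = np.zeros((n, n))
    m = t.shape[0]
    for b in range(n):
        target = assign == b
        # solve (I - T_restricted) h = 1 on the complement of the target set
        free = ~target
        a = np.eye(int(free.sum())) - t[np.ix_(free, free)]
        h = np.linalg.solve(a, np.ones(int(free.sum())))
        full = np.zeros(m)
        full[free] = h
        pi = msm.stationary_distribution_
        for src in range(n):
            if src == b:
                continue
            w = pi * (assign == src)
            out[src, b] = lag * float(w @ full / w.sum())
    return out


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov test
# ---------------------------------------------------------------------------

@dataclass
class CKResult:
    """Predicted vs. re-estimated macrostate self-transition probabilities.

    predicted[f, a]: [T(lag)^factor] coarse-grained, for factor = factors[f]
    estimated[f, a]: MSM re-estimated at lag factor*lag, coarse-grained
    ci_low / ci_high: bootstrap confidence band on the re-estimate
    """

    factors: list[int]
    predicted: np.ndarray
    estimated: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def within_ci(self) -> np.ndarray:
        return (self.predicted >= self.ci_low) & (self.predicted <= self.ci_high)


def _coarse_self_transitions(t, pi, sets) -> np.ndarray:
    out = np.empty(len(sets))
    for a, members in enumerate(sets):
        w = pi[members]
        out[a] = float(w @ t[np.ix_(members, members)].sum(axis=1) / w.sum())
    return out


def ck_test(
    dtrajs,
    msm: MarkovStateModel,
    n_macrostates: int,
    factors=(2, 3, 4, 5),
    n_bootstrap: int = 100,
    seed: int = 0,
    n_blocks: int = 50,
) -> CKResult:
    """Chapman-Kolmogorov test on macrostate self-transition probabilities.

    For each factor k the model prediction ``T(lag)^k``, aggregated onto
    the crisp PCCA+ macrostates, is compared with a fresh MSM estimated at
    lag ``k * lag``.  The confidence band on the re-estimate comes from a
    circular block bootstrap over trajectory segments (``n_blocks`` blocks,
    ``n_bootstrap`` resamples, central 95%).
    """
    dtrajs = [np.asarray(d, int) for d in _as_dtraj_list(dtrajs)]
    lag = int(msm.lag)
    p = pcca(msm, n_macrostates)
    assign = p.assignments_
    active = msm.active_set_
    sets = [np.nonzero(assign == a)[0] for a in range(n_macrostates)]

    # map full-state dtrajs onto the active set (off-set frames -> -1)
    state_map = -np.ones(int(max(d.max() for d in dtrajs)) + 1, dtype=int)
    state_map[active] = np.arange(len(active))

    factors_used, preds, ests, lows, highs = [], [], [], [], []
    rng = np.random.default_rng(seed)
    for k in factors:
        klag = k * lag
        if all(len(d) <= klag for d in dtrajs):
            logger.warning("CK factor %d skipped: trajectories shorter than %d", k, klag)
            continue
        tk = np.linalg.matrix_power(msm.transition_matrix_, k)
        pred = _coarse_self_transitions(tk, msm.stationary_distribution_, sets)
        try:
            msm_k = estimate_msm(dtrajs, klag, reversible=msm.reversible)
        except (EstimationError, InputError) as exc:
            logger.warning("CK factor %d skipped: %s", k, exc)
            continue
        # express macrostate sets in the lag-k model's active set
        map_k = -np.ones_like(state_map)
        map_k[msm_k.active_set_] = np.arange(len(msm_k.active_set_))
        sets_k = []
        for members in sets:
            mk = map_k[active[members]]
            sets_k.append(mk[mk >= 0])
        if any(len(s) == 0 for s in sets_k):
            logger.warning("CK factor %d skipped: macrostate lost from connected set", k)
            continue
        est = _coarse_self_transitions(
            msm_k.transition_matrix_, msm_k.stationary_distribution_, sets_k
        )
        boot = _bootstrap_self_transitions(
            dtrajs, klag, sets_k, msm_k.active_set_, rng, n_bootstrap, n_blocks,
            reversible=msm.reversible,
        )
        factors_used.append(int(k))
        preds.append(pred)
        ests.append(est)
        lows.append(np.nanpercentile(boot, 2.5, axis=0))
        highs.append(np.nanpercentile(boot, 97.5, axis=0))
    return CKResult(
        factors=factors_used,
        predicted=np.asarray(preds),
        estimated=np.asarray(ests),
        ci_low=np.asarray(lows),
        ci_high=np.asarray(highs),
    )


def _bootstrap_self_transitions(dtrajs, lag, sets_k, active_k, rng, n_boot, n_blocks, reversible):
    # circular block bootstrap of transition pairs
    pairs = []
    for d in dtrajs:
        if len(d) > lag:
            pairs.append(np.column_stack([d[:-lag], d[lag:]]))
    pairs = np.concatenate(pairs)
    blocks = np.array_split(np.arange(len(pairs)), min(n_blocks, len(pairs)))
    n_states = int(active_k.max()) + 1
    map_k = -np.ones(n_states, dtype=int)
    map_k[active_k] = np.arange(len(active_k))
    out = np.full((n_boot, len(sets_k)), np.nan)
    for b in range(n_boot):
        chosen = rng.integers(0, len(blocks), size=len(blocks))
        idx = np.concatenate([blocks[c] for c in chosen])
        sub = pairs[idx]
        c = np.zeros((len(active_k), len(active_k)))
        i = map_k[np.clip(sub[:, 0], 0, n_states - 1)]
        j = map_k[np.clip(sub[:, 1], 0, n_states - 1)]
        ok = (i >= 0) & (j >= 0)
        np.add.at(c, (i[ok], j[ok]), 1.0)
        rows = c.sum(axis=1)
        if np.any(rows == 0):
            continue
        try:
            if reversible:
                t, pi = reversible_transition_matrix(c, tol=1e-8, max_iter=10000)
            else:
                t, pi = nonreversible_transition_matrix(c)
        except EstimationError:
            continue
        out[b] = _coarse_self_transitions(t, pi, sets_k)
    return out
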