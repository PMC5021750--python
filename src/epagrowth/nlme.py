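"""Maximum-likelihood estimation of Monod-type nonlinear mixed models.

The observation model for beaker-level juvenile growth is

    y_ij = g0_i + (ginf_i - g0_i) * S_ij / (S_ij + KS_i) + e_ij,
    e_ij ~ N(0, sigma^2),

where clone i's parameters are the fixed (population) values plus
clone-level Gaussian random deviations on a chosen subset of
{g0, ginf, KS} with diagonal covariance.  Two fixed-effect families are
supported: family A estimates a single common half-saturation constant
KS, family B a linear body-size law KS_i = K0 + KL * L_i.  Model names
follow the convention A1..A3 / B1..B3, the digit being the number of
random-effect parameters with the nesting g0 < {g0, ginf} <
{g0, ginf, KS}.

The marginal likelihood integrates the random effects out clone by
clone.  The integral is evaluated with a Laplace approximation around
the per-clone posterior mode (found by an exact damped Newton solve,
vectorised across clones).  Because g0 and ginf enter the Monod mean
linearly, the Laplace approximation is *exact* for models whose random
effects involve only those two parameters (A1, A2, B1, B2); for random
KS it is the usual second-order approximation, cross-checkable against
adaptive Gauss-Hermite quadrature (:func:`marginal_loglik` with
``method="gh"``).

Estimation is ML (not REML), as required for AIC and likelihood-ratio
comparisons across fixed-effect structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .datamodel import CloneInfo, ClutchRecord, GrowthRecord
from .growth import MonodParams, arcsin_sqrt_transform

__all__ = [
    "PARAMS",
    "ModelSpec",
    "MODEL_SERIES",
    "FitResult",
    "PerCloneFit",
    "fit_per_clone_nls",
    "fit_nlme",
    "fit_clutch_series",
    "predict_growth",
    "marginal_loglik",
    "pooled_nls_fit",
]

PARAMS = ("g0", "ginf", "KS")

_TAU_MIN = 1e-6
_SIGMA_MIN = 1e-6


class NonNestedError(ValueError):
    """Raised when a likelihood-ratio test is requested for non-nested fits."""


@dataclass(frozen=True)
class ModelSpec:
    """One member of the model series: fixed-effect family and random set."""

    name: str
    family: str  # "A" (common KS) or "B" (KS = K0 + KL*L)
    random_set: tuple[str, ...]

    def __post_init__(self):
        if self.family not in ("A", "B"):
            raise ValueError(f"family must be 'A' or 'B', got {self.family!r}")
        bad = set(self.random_set) - set(PARAMS)
        if bad:
            raise ValueError(f"unknown random-effect parameter(s) {sorted(bad)}")
        # keep canonical ordering
        ordered = tuple(p for p in PARAMS if p in self.random_set)
        object.__setattr__(self, "random_set", ordered)

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        """Canonical specs A1..A3, B1..B3 (digit = number of random effects,
        nested as g0, {g0, ginf}, {g0, ginf, KS})."""
        name = name.upper()
        if len(name) != 2 or name[0] not in "AB" or name[1] not in "123":
            raise ValueError(f"unknown model name {name!r}; expected A1..B3")
        k = int(name[1])
        return cls(name=name, family=name[0], random_set=PARAMS[:k])

    @property
    def n_fixed(self) -> int:
        return 3 if self.family == "A" else 4

    @property
    def fixed_names(self) -> tuple[str, ...]:
        return ("g0", "ginf", "KS") if self.family == "A" else ("g0", "ginf", "K0", "KL")


MODEL_SERIES = tuple(
    ModelSpec.from_name(n) for n in ("A1", "A2", "A3", "B1", "B2", "B3")
)


@dataclass
class FitResult:
    """A converged (or flagged) maximum-likelihood fit of one ModelSpec."""

    spec: ModelSpec
    fixed_estimates: dict[str, float]
    random_sd: dict[str, float]
    residual_sd: float
    clone_deviations: dict[str, dict[str, float]]
    logLik: float
    Df: int
    AIC: float
    converged: bool
    residuals: np.ndarray
    clone_ids: tuple[str, ...]
    clone_L: dict[str, float]
    n_obs: int
    meta: dict = field(default_factory=dict)

    def ks_for_clone(self, clone_id: str) -> float:
        """Clone-specific half-saturation constant: family fixed structure
        plus the clone's predicted random deviation, where present."""
        if self.spec.family == "A":
            base = self.fixed_estimates["KS"]
        else:
            base = (
                self.fixed_estimates["K0"]
                + self.fixed_estimates["KL"] * self.clone_L[clone_id]
            )
        dev = self.clone_deviations.get(clone_id, {}).get("KS", 0.0)
        return base + dev

    def params_for_clone(self, clone_id: str) -> MonodParams:
        dev = self.clone_deviations.get(clone_id, {})
        return MonodParams(
            g0=self.fixed_estimates["g0"] + dev.get("g0", 0.0),
            ginf=self.fixed_estimates["ginf"] + dev.get("ginf", 0.0),
            KS=self.ks_for_clone(clone_id),
        )

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "family": self.spec.family,
            "random_set": list(self.spec.random_set),
            "fixed_estimates": dict(self.fixed_estimates),
            "random_sd": dict(self.random_sd),
            "residual_sd": float(self.residual_sd),
            "clone_deviations": {
                c: dict(d) for c, d in self.clone_deviations.items()
            },
            "logLik": float(self.logLik),
            "Df": int(self.Df),
            "AIC": float(self.AIC),
            "converged": bool(self.converged),
            "residuals": [float(r) for r in np.asarray(self.residuals).ravel()],
            "clone_ids": list(self.clone_ids),
            "clone_L": {c: float(v) for c, v in self.clone_L.items()},
            "n_obs": int(self.n_obs),
            "meta": dict(self.meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        spec = ModelSpec(
            name=d["model"], family=d["family"], random_set=tuple(d["random_set"])
        )
        return cls(
            spec=spec,
            fixed_estimates=dict(d["fixed_estimates"]),
            random_sd=dict(d["random_sd"]),
            residual_sd=float(d["residual_sd"]),
            clone_deviations={c: dict(v) for c, v in d["clone_deviations"].items()},
            logLik=float(d["logLik"]),
            Df=int(d["Df"]),
            AIC=float(d["AIC"]),
            converged=bool(d["converged"]),
            residuals=np.asarray(d["residuals"], dtype=float),
            clone_ids=tuple(d["clone_ids"]),
            clone_L={c: float(v) for c, v in d["clone_L"].items()},
            n_obs=int(d["n_obs"]),
            meta=dict(d.get("meta", {})),
        )


# ---------------------------------------------------------------------------
# data marshalling
# ---------------------------------------------------------------------------

class _Data:
    """Growth observations padded into clone x observation matrices."""

    def __init__(self, records: Sequence[GrowthRecord], clones: Sequence[CloneInfo]):
        by_clone: dict[str, list[tuple[float, float]]] = {}
        for r in records:
            by_clone.setdefault(r.clone_id, []).append(
                (float(r.epa_conc_S), r.growth_rate())
            )
        self.clone_ids = tuple(c.clone_id for c in clones if c.clone_id in by_clone)
        if not self.clone_ids:
            raise ValueError("no observations for any listed clone")
        self.L = np.array(
            [
                next(c.body_size_L for c in clones if c.clone_id == cid)
                for cid in self.clone_ids
            ]
        )
        self.m = len(self.clone_ids)
        nmax = max(len(by_clone[c]) for c in self.clone_ids)
        self.S = np.zeros((self.m, nmax))
        self.Y = np.zeros((self.m, nmax))
        self.mask = np.zeros((self.m, nmax))
        for i, cid in enumerate(self.clone_ids):
            obs = by_clone[cid]
            self.S[i, : len(obs)] = [o[0] for o in obs]
            self.Y[i, : len(obs)] = [o[1] for o in obs]
            self.mask[i, : len(obs)] = 1.0
        self.n_i = self.mask.sum(axis=1)
        self.n_total = int(self.n_i.sum())


# ---------------------------------------------------------------------------
# Laplace marginal likelihood
# ---------------------------------------------------------------------------

class _Laplace:
    """Evaluates the Laplace-approximated marginal log-likelihood for one
    spec on one dataset, with warm-started inner Newton solves."""

    def __init__(self, data: _Data, spec: ModelSpec):
        self.d = data
        self.spec = spec
        self.rs = spec.random_set
        self._b = {}  # warm starts keyed by active-set tuple

    # -- model pieces -------------------------------------------------------

    def _clone_params(self, fixed: Mapping[str, float], B, active):
        d = self.d
        g0 = np.full(d.m, fixed["g0"])
        ginf = np.full(d.m, fixed["ginf"])
        if self.spec.family == "A":
            K = np.full(d.m, fixed["KS"])
        else:
            K = fixed["K0"] + fixed["KL"] * d.L
        for j, p in enumerate(active):
            if p == "g0":
                g0 = g0 + B[:, j]
            elif p == "ginf":
                ginf = ginf + B[:, j]
            else:
                K = K + B[:, j]
        return g0, ginf, K

    def _mu_resid(self, g0, ginf, K):
        d = self.d
        M = d.S / (d.S + K[:, None])
        mu = g0[:, None] * (1.0 - M) + ginf[:, None] * M
        r = (d.Y - mu) * d.mask
        return M, r

    # -- inner Newton solve over the random deviations ----------------------

    def _inner_f(self, fixed, B, active, tau, sigma):
        g0, ginf, K = self._clone_params(fixed, B, active)
        if np.any(K <= 0):
            return None, None
        _, r = self._mu_resid(g0, ginf, K)
        ssr = (r * r).sum(axis=1)
        f = ssr / (2.0 * sigma**2)
        for j, p in enumerate(active):
            f = f + B[:, j] ** 2 / (2.0 * tau[p] ** 2)
        return f, r

    def _grad_hess(self, fixed, B, active, tau, sigma):
        d = self.d
        q = len(active)
        g0, ginf, K = self._clone_params(fixed, B, active)
        M, r = self._mu_resid(g0, ginf, K)
        inv_sp = 1.0 / (d.S + K[:, None])
        dK = -(ginf - g0)[:, None] * d.S * inv_sp**2  # d mu / d K
        J = np.empty((d.m, d.S.shape[1], q))
        for j, p in enumerate(active):
            if p == "g0":
                J[:, :, j] = (1.0 - M) * d.mask
            elif p == "ginf":
                J[:, :, j] = M * d.mask
            else:
                J[:, :, j] = dK * d.mask
        G = -np.einsum("inj,in->ij", J, r) / sigma**2
        H = np.einsum("inj,ink->ijk", J, J) / sigma**2
        if "KS" in active:
            kj = active.index("KS")
            d2KK = (ginf - g0)[:, None] * 2.0 * d.S * inv_sp**3
            H[:, kj, kj] -= (r * d2KK * d.mask).sum(axis=1) / sigma**2
            for j, p in enumerate(active):
                if p == "g0":
                    cross = -(r * (d.S * inv_sp**2) * d.mask).sum(axis=1) / sigma**2
                elif p == "ginf":
                    cross = (r * (d.S * inv_sp**2) * d.mask).sum(axis=1) / sigma**2
                else:
                    continue
                H[:, kj, j] += cross
                H[:, j, kj] += cross
        for j, p in enumerate(active):
            G[:, j] += B[:, j] / tau[p] ** 2
            H[:, j, j] += 1.0 / tau[p] ** 2
        return G, H

    def _solve_modes(self, fixed, active, tau, sigma):
        d = self.d
        q = len(active)
        B = self._b.get(active)
        if B is None or B.shape != (d.m, q):
            B = np.zeros((d.m, q))
        f, _ = self._inner_f(fixed, B, active, tau, sigma)
        if f is None and B.any():
            # stale warm start invalid at these parameters: restart at zero
            B = np.zeros((d.m, q))
            f, _ = self._inner_f(fixed, B, active, tau, sigma)
        if f is None:
            return None, None
        lam = np.zeros(d.m)
        eye = np.eye(q)
        for _ in range(80):
            G, H = self._grad_hess(fixed, B, active, tau, sigma)
            gnorm = np.abs(G).max(axis=1)
            scale = 1.0 + np.abs(f)
            if np.all(gnorm <= 1e-9 * scale):
                break
            Heff = H + lam[:, None, None] * eye
            try:
                step = np.linalg.solve(Heff, G[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                lam = np.maximum(lam * 10.0, 1e-4)
                continue
            accepted = np.zeros(d.m, dtype=bool)
            t = np.ones(d.m)
            for _ls in range(25):
                Bn = B - t[:, None] * step
                fn, _ = self._inner_f(fixed, Bn, active, tau, sigma)
                if fn is None:
                    # KS random pushed K negative somewhere: shrink all
                    t *= 0.5
                    continue
                better = fn <= f + 1e-14 * (1.0 + np.abs(f))
                newly = better & ~accepted
                B = np.where(newly[:, None], Bn, B)
                f = np.where(newly, fn, f)
                accepted |= better
                if accepted.all():
                    break
                t = np.where(accepted, t, t * 0.5)
            lam = np.where(accepted, lam / 3.0, np.maximum(lam * 10.0, 1e-4))
        self._b[active] = B.copy()
        return B, f

    # -- the marginal log-likelihood ----------------------------------------

    def loglik(self, fixed, tau: Mapping[str, float], sigma: float) -> float:
        d = self.d
        active = tuple(p for p in self.rs if tau.get(p, 0.0) > 0.0)
        if not active:
            g0 = np.full(d.m, fixed["g0"])
            ginf = np.full(d.m, fixed["ginf"])
            if self.spec.family == "A":
                K = np.full(d.m, fixed["KS"])
            else:
                K = fixed["K0"] + fixed["KL"] * d.L
            if np.any(K <= 0):
                return -np.inf
            _, r = self._mu_resid(g0, ginf, K)
            ssr = float((r * r).sum())
            return -0.5 * d.n_total * np.log(2.0 * np.pi * sigma**2) - ssr / (
                2.0 * sigma**2
            )
        B, f = self._solve_modes(fixed, active, tau, sigma)
        if B is None:
            return -np.inf
        _, H = self._grad_hess(fixed, B, active, tau, sigma)
        sign, logdet = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            return -np.inf
        ll = (
            -0.5 * d.n_i * np.log(2.0 * np.pi * sigma**2)
            - f
            - sum(np.log(tau[p]) for p in active)
            - 0.5 * logdet
        )
        return float(ll.sum())

    def modes(self, fixed, tau, sigma):
        active = tuple(p for p in self.rs if tau.get(p, 0.0) > 0.0)
        if not active:
            return active, np.zeros((self.d.m, 0))
        B, _ = self._solve_modes(fixed, active, tau, sigma)
        return active, B

    def loglik_profiled(self, fixed, ratios: Mapping[str, float]):
        """Marginal logLik with the residual SD profiled out.

        Random-effect SDs are parameterised as ratios to the residual SD
        (tau_p = r_p * sigma); the per-clone modes and unscaled curvature
        are then independent of sigma, every log(sigma) term cancels
        between the prior normaliser and the Laplace determinant, and the
        ML residual variance is the penalised SSR over N in closed form.
        Returns (logLik, sigma_hat).
        """
        d = self.d
        active = tuple(p for p in self.rs if ratios.get(p, 0.0) > 0.0)
        if not active:
            g0 = np.full(d.m, fixed["g0"])
            ginf = np.full(d.m, fixed["ginf"])
            if self.spec.family == "A":
                K = np.full(d.m, fixed["KS"])
            else:
                K = fixed["K0"] + fixed["KL"] * d.L
            if np.any(K <= 0):
                return -np.inf, float("nan")
            _, r = self._mu_resid(g0, ginf, K)
            pss = float((r * r).sum())
            sum_logdet = 0.0
        else:
            B, f = self._solve_modes(fixed, active, ratios, 1.0)
            if B is None:
                return -np.inf, float("nan")
            _, H = self._grad_hess(fixed, B, active, ratios, 1.0)
            sign, logdet = np.linalg.slogdet(H)
            if np.any(sign <= 0):
                return -np.inf, float("nan")
            pss = float(2.0 * f.sum())
            sum_logdet = float(logdet.sum())
        sigma2 = max(pss / d.n_total, _SIGMA_MIN**2)
        ll = (
            -0.5 * d.n_total * (np.log(2.0 * np.pi * sigma2) + pss / (d.n_total * sigma2))
            - d.m * sum(np.log(ratios[p]) for p in active)
            - 0.5 * sum_logdet
        )
        return float(ll), float(np.sqrt(sigma2))


def _gauss_hermite_loglik(
    data: _Data, spec: ModelSpec, fixed, tau, sigma, n_nodes: int
) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood (one random effect).

    Independent integration route used as an oracle for the Laplace
    approximation: nodes are centred at each clone's posterior mode and
    scaled by the local curvature.
    """
    lap = _Laplace(data, spec)
    active = tuple(p for p in spec.random_set if tau.get(p, 0.0) > 0.0)
    if len(active) != 1:
        raise NotImplementedError(
            "Gauss-Hermite oracle supports exactly one active random effect"
        )
    B, f0 = lap._solve_modes(fixed, active, tau, sigma)
    _, H = lap._grad_hess(fixed, B, active, tau, sigma)
    h = H[:, 0, 0]
    s = 1.0 / np.sqrt(h)
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    ll_total = 0.0
    p = active[0]
    for i in range(data.m):
        b_nodes = B[i, 0] + np.sqrt(2.0) * s[i] * x
        fvals = np.empty(n_nodes)
        for j, b in enumerate(b_nodes):
            Bj = B.copy()
            Bj[i, 0] = b
            fall, _ = lap._inner_f(fixed, Bj, active, tau, sigma)
            fvals[j] = np.inf if fall is None else fall[i]
        # integral of exp(-f(b)) db, stabilised at the mode
        log_int = (
            np.log(np.sqrt(2.0) * s[i])
            + np.log(np.sum(w * np.exp(-(fvals - f0[i]) + x**2)))
            - f0[i]
        )
        ll_total += (
            -0.5 * data.n_i[i] * np.log(2.0 * np.pi * sigma**2)
            - 0.5 * np.log(2.0 * np.pi)
            - np.log(tau[p])
            + log_int
        )
    return float(ll_total)


def marginal_loglik(
    records: Sequence[GrowthRecord],
    clones: Sequence[CloneInfo],
    spec: ModelSpec,
    fixed: Mapping[str, float],
    random_sd: Mapping[str, float],
    residual_sd: float,
    method: str = "laplace",
    gh_nodes: int = 20,
) -> float:
    """Marginal log-likelihood at given parameter values.

    ``method="laplace"`` uses the estimation route; ``method="gh"`` uses
    adaptive Gauss-Hermite quadrature (only for a single active random
    effect) and serves as an independent cross-check.
    """
    data = _Data(records, clones)
    tau = {p: float(random_sd.get(p, 0.0)) for p in spec.random_set}
    if method == "laplace":
        return _Laplace(data, spec).loglik(dict(fixed), tau, float(residual_sd))
    if method == "gh":
        return _gauss_hermite_loglik(
            data, spec, dict(fixed), tau, float(residual_sd), gh_nodes
        )
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# per-clone and pooled nonlinear least squares (initialisers / oracles)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerCloneFit:
    params: MonodParams
    rss: float
    identifiable: bool


def _profile_ssr(S: np.ndarray, y: np.ndarray, K: float):
    """Least-squares (g0, ginf) given KS: the Monod mean is linear in them."""
    m = S / (S + K)
    X = np.column_stack([1.0 - m, m])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), float(coef[0]), float(coef[1])


_K_GRID = np.geomspace(1e-3, 1e3, 85)


def fit_per_clone_nls(records: Sequence[GrowthRecord]) -> PerCloneFit:
    """Deterministic least-squares Monod fit for a single clone.

    Profiles (g0, ginf) analytically and searches KS on a fixed log grid
    followed by bounded scalar refinement.  Degenerate data (growth flat
    in S) leave KS unidentifiable: the fit is flagged and KS is reported
    at the grid boundary.
    """
    ids = {r.clone_id for r in records}
    if len(ids) != 1:
        raise ValueError(f"records must belong to one clone, got {sorted(ids)}")
    S = np.array([r.epa_conc_S for r in records], dtype=float)
    y = np.array([r.growth_rate() for r in records], dtype=float)
    if len(np.unique(S)) < 4:
        raise ValueError("need >= 4 distinct EPA levels for a per-clone fit")
    ssr_grid = np.array([_profile_ssr(S, y, k)[0] for k in _K_GRID])
    i = int(np.argmin(ssr_grid))
    lo = _K_GRID[max(i - 1, 0)]
    hi = _K_GRID[min(i + 1, len(_K_GRID) - 1)]
    res = minimize_scalar(
        lambda lk: _profile_ssr(S, y, np.exp(lk))[0],
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-13},
    )
    K = float(np.exp(res.x))
    rss, g0, ginf = _profile_ssr(S, y, K)
    tot = float(np.sum((y - y.mean()) ** 2))
    # flat likelihood in K: boundary optimum or no explainable variation
    identifiable = not (
        i in (0, len(_K_GRID) - 1)
        or tot < 1e-20
        or (ssr_grid.max() - ssr_grid.min()) < 1e-12 * (1.0 + tot)
    )
    if not identifiable:
        warnings.warn(
            "flat Monod likelihood: KS not identifiable for this clone",
            RuntimeWarning,
            stacklevel=2,
        )
    return PerCloneFit(MonodParams(g0=g0, ginf=ginf, KS=K), rss, identifiable)


def pooled_nls_fit(records: Sequence[GrowthRecord]):
    """Pooled single-curve Monod least squares over all records, with the
    Gaussian ML log-likelihood (sigma^2 = SSR/n).  Oracle for the mixed
    fit in the limit of zero random-effect variance."""
    S = np.array([r.epa_conc_S for r in records], dtype=float)
    y = np.array([r.growth_rate() for r in records], dtype=float)
    ssr_grid = np.array([_profile_ssr(S, y, k)[0] for k in _K_GRID])
    i = int(np.argmin(ssr_grid))
    lo = _K_GRID[max(i - 1, 0)]
    hi = _K_GRID[min(i + 1, len(_K_GRID) - 1)]
    res = minimize_scalar(
        lambda lk: _profile_ssr(S, y, np.exp(lk))[0],
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-13},
    )
    K = float(np.exp(res.x))
    rss, g0, ginf = _profile_ssr(S, y, K)
    n = len(y)
    sigma2 = max(rss / n, _SIGMA_MIN**2)
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + rss / (n * sigma2))
    return MonodParams(g0=g0, ginf=ginf, KS=K), rss, float(ll)


# ---------------------------------------------------------------------------
# the mixed-model fitter
# ---------------------------------------------------------------------------

def _starting_values(data: _Data, spec: ModelSpec):
    """Per-clone NLS estimates pooled into starting values."""
    g0s, ginfs, ks, rss_tot = [], [], [], 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, cid in enumerate(data.clone_ids):
            sel = data.mask[i] > 0
            recs = [
                GrowthRecord(cid, float(s), 1, growth_rate_g=float(y))
                for s, y in zip(data.S[i, sel], data.Y[i, sel])
            ]
            try:
                pf = fit_per_clone_nls(recs)
                g0s.append(pf.params.g0)
                ginfs.append(pf.params.ginf)
                ks.append(float(np.clip(pf.params.KS, 1e-3, 50.0)))
                rss_tot += pf.rss
            except ValueError:
                g0s.append(float(data.Y[i, sel].mean()))
                ginfs.append(float(data.Y[i, sel].mean()))
                ks.append(1.0)
    g0s, ginfs, ks = map(np.array, (g0s, ginfs, ks))
    fixed = {"g0": float(g0s.mean()), "ginf": float(ginfs.mean())}
    if spec.family == "A":
        fixed["KS"] = float(np.exp(np.log(ks).mean()))
    else:
        X = np.column_stack([np.ones(data.m), data.L])
        (k0, kl), *_ = np.linalg.lstsq(X, ks, rcond=None)
        fixed["K0"], fixed["KL"] = float(k0), float(kl)
    per_clone_sd = {
        "g0": float(max(g0s.std(), 1e-3)),
        "ginf": float(max(ginfs.std(), 1e-3)),
        "KS": float(max(ks.std(), 1e-3)),
    }
    sigma0 = float(max(np.sqrt(rss_tot / max(data.n_total, 1)), 1e-4))
    return fixed, per_clone_sd, sigma0


def _fix_positive_ks(fixed, L):
    """Raise K0 just enough that the size law stays positive over the data."""
    kmin = fixed["K0"] + fixed["KL"] * (L.min() if fixed["KL"] >= 0 else L.max())
    if kmin <= 1e-3:
        fixed = dict(fixed)
        fixed["K0"] += 1e-3 - kmin
    return fixed


_RATIO_MIN = 1e-5
_RATIO_MAX = 1e6


def _pack(spec, fixed, ratio_start, free_ratios):
    x = [fixed["g0"], fixed["ginf"]]
    if spec.family == "A":
        x.append(np.log(fixed["KS"]))
    else:
        x += [fixed["K0"], fixed["KL"]]
    x += [
        np.log(np.clip(ratio_start[p], _RATIO_MIN, _RATIO_MAX)) for p in free_ratios
    ]
    return np.array(x, dtype=float)


def _unpack(spec, x, free_ratios, ratio_fixed):
    fixed = {"g0": x[0], "ginf": x[1]}
    if spec.family == "A":
        fixed["KS"] = float(np.exp(x[2]))
        k = 3
    else:
        fixed["K0"], fixed["KL"] = float(x[2]), float(x[3])
        k = 4
    ratios = dict(ratio_fixed)
    for p in free_ratios:
        ratios[p] = float(np.exp(x[k]))
        k += 1
    return fixed, ratios


def _bounds(spec, n_free_ratios):
    b = [(-5.0, 5.0), (-5.0, 5.0)]
    if spec.family == "A":
        b.append((np.log(1e-4), np.log(1e3)))
    else:
        b += [(-20.0, 20.0), (-20.0, 20.0)]
    b += [(np.log(_RATIO_MIN), np.log(_RATIO_MAX))] * n_free_ratios
    return b


def _fit_fixed_only(data: _Data, spec: ModelSpec, random_sd_fixed) -> FitResult:
    """No free random effects with positive SD: profile (g0, ginf) and sigma
    analytically and minimise SSR over the remaining 1-2 parameters."""
    S = data.S[data.mask > 0].ravel()
    y = data.Y[data.mask > 0].ravel()
    if spec.family == "A":
        params, rss, ll = pooled_nls_fit(
            [GrowthRecord("all", float(s), 1, growth_rate_g=float(v))
             for s, v in zip(S, y)]
        )
        fixed = {"g0": params.g0, "ginf": params.ginf, "KS": params.KS}
        converged = True
    else:
        idx = np.repeat(np.arange(data.m), data.mask.sum(axis=1).astype(int))
        Lobs = data.L[idx]

        def ssr_of(k0kl):
            k0, kl = k0kl
            K = k0 + kl * Lobs
            if np.any(K <= 1e-8):
                return 1e12
            mfrac = S / (S + K)
            X = np.column_stack([1.0 - mfrac, mfrac])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            return float(resid @ resid)

        start_fixed, _, _ = _starting_values(data, spec)
        start_fixed = _fix_positive_ks(start_fixed, data.L)
        res = minimize(
            ssr_of,
            np.array([start_fixed["K0"], start_fixed["KL"]]),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 2000},
        )
        k0, kl = res.x
        K = k0 + kl * Lobs
        mfrac = S / (S + K)
        X = np.column_stack([1.0 - mfrac, mfrac])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
        fixed = {"g0": float(coef[0]), "ginf": float(coef[1]),
                 "K0": float(k0), "KL": float(kl)}
        n = len(y)
        sigma2 = max(rss / n, _SIGMA_MIN**2)
        ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + rss / (n * sigma2))
        converged = bool(res.success)
    n = len(y)
    sigma = float(np.sqrt(max(rss / n, _SIGMA_MIN**2)))
    n_free_tau = sum(1 for p in spec.random_set if p not in random_sd_fixed)
    df = spec.n_fixed + n_free_tau + 1
    lap = _Laplace(data, spec)
    tau = {p: 0.0 for p in spec.random_set}
    g0v, ginfv, Kv = lap._clone_params(fixed, np.zeros((data.m, 0)), ())
    _, r = lap._mu_resid(g0v, ginfv, Kv)
    return FitResult(
        spec=spec,
        fixed_estimates=fixed,
        random_sd={p: float(random_sd_fixed.get(p, 0.0)) for p in spec.random_set},
        residual_sd=sigma,
        clone_deviations={cid: {} for cid in data.clone_ids},
        logLik=float(ll),
        Df=df,
        AIC=2.0 * df - 2.0 * float(ll),
        converged=converged,
        residuals=r[data.mask > 0].ravel(),
        clone_ids=data.clone_ids,
        clone_L={cid: float(L) for cid, L in zip(data.clone_ids, data.L)},
        n_obs=data.n_total,
        meta={},
    )


def fit_nlme(
    records: Sequence[GrowthRecord],
    clones: Sequence[CloneInfo],
    spec: ModelSpec,
    random_sd_fixed: Mapping[str, float] | None = None,
    ratio_fixed: Mapping[str, float] | None = None,
    start: FitResult | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one model spec.

    Parameters
    ----------
    records, clones
        Growth observations and the clone table (body sizes are required
        for family B).
    spec
        The model to fit.
    random_sd_fixed
        Optional mapping pinning random-effect SDs at zero
        (e.g. ``{"g0": 0.0}``); pinned components do not count towards Df.
    ratio_fixed
        Optional mapping pinning random-effect SDs at a fixed *ratio* to
        the residual SD (the natural pinning under the profiled
        likelihood; used by the bootstrap's fixed-variance mode).
    start
        Optional previous fit of the same spec used as starting point
        (skips the per-clone initialisation; used by the bootstrap).

    Returns
    -------
    FitResult with ML estimates, Laplace logLik, Df (fixed effects +
    estimated variance components + residual variance) and AIC.
    Non-convergence is reported via ``converged=False``, never raised.

    Notes
    -----
    Internally the random-effect SDs are parameterised as ratios to the
    residual SD and the residual SD is profiled out analytically, so the
    outer quasi-Newton optimisation runs over the fixed effects and the
    log variance ratios only.
    """
    if len(clones) < 2:
        raise ValueError("need at least 2 clones for a mixed fit")
    random_sd_fixed = dict(random_sd_fixed or {})
    if any(v != 0.0 for v in random_sd_fixed.values()):
        raise ValueError(
            "random_sd_fixed pins SDs at zero only; use ratio_fixed to pin "
            "a non-zero variance component"
        )
    ratio_fixed = dict(ratio_fixed or {})
    data = _Data(records, clones)
    pinned = set(random_sd_fixed) | set(ratio_fixed)
    free_ratios = tuple(p for p in spec.random_set if p not in pinned)
    if not free_ratios and not ratio_fixed:
        return _fit_fixed_only(data, spec, random_sd_fixed)

    lap = _Laplace(data, spec)
    base_ratios = {p: 0.0 for p in random_sd_fixed} | {
        p: float(v) for p, v in ratio_fixed.items()
    }

    def objective(x):
        fixed, ratios = _unpack(spec, x, free_ratios, base_ratios)
        ll, _ = lap.loglik_profiled(fixed, ratios)
        return 1e12 if not np.isfinite(ll) else -ll

    # starting candidates: per-clone NLS pool plus a log-grid multi-start
    # on the half-saturation structure (ridge-prone direction)
    if start is not None and start.spec.name == spec.name:
        fixed0 = dict(start.fixed_estimates)
        sigma0 = max(start.residual_sd, 1e-6)
        ratio0 = {
            p: max(start.random_sd.get(p, 0.0), 1e-3) / sigma0 for p in free_ratios
        }
        candidates = [fixed0]
    else:
        fixed0, per_sd, sigma0 = _starting_values(data, spec)
        ratio0 = {p: per_sd[p] / sigma0 for p in free_ratios}
        candidates = []
        for scale in (0.25, 0.5, 1.0, 2.0, 4.0):
            c = dict(fixed0)
            if spec.family == "A":
                c["KS"] = fixed0["KS"] * scale
            else:
                c["KL"] = fixed0["KL"] * scale
                c = _fix_positive_ks(c, data.L)
            candidates.append(c)
    best_x, best_f = None, np.inf
    for c in candidates:
        if spec.family == "B":
            c = _fix_positive_ks(c, data.L)
        x = _pack(spec, c, ratio0, free_ratios)
        f = objective(x)
        if f < best_f:
            best_x, best_f = x, f
    bounds = _bounds(spec, len(free_ratios))
    best_x = np.clip(best_x, [b[0] for b in bounds], [b[1] for b in bounds])
    opts = {"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9}
    res = minimize(objective, best_x, method="L-BFGS-B", bounds=bounds, options=opts)
    if not res.success:
        # documented restart schedule: a derivative-free polish (immune to
        # finite-difference line-search stalls), then one more quasi-Newton
        # pass from the polished point
        res_nm = minimize(
            objective,
            res.x,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if res_nm.fun <= res.fun:
            res = res_nm
        if not res.success:
            res2 = minimize(
                objective, res.x, method="L-BFGS-B", bounds=bounds, options=opts
            )
            if res2.fun <= res.fun:
                res = res2
    converged = bool(np.isfinite(res.fun)) and (
        res.success or res.status == 1  # maxiter with a finite optimum
    )
    fixed, ratios = _unpack(spec, res.x, free_ratios, base_ratios)
    ll, sigma = lap.loglik_profiled(fixed, ratios)
    tau = {p: r * sigma for p, r in ratios.items()}
    active, B = lap.modes(fixed, tau, sigma)
    if B is None:
        active, B = (), np.zeros((data.m, 0))
        converged = False
    clone_dev = {
        cid: {p: float(B[i, j]) for j, p in enumerate(active)}
        for i, cid in enumerate(data.clone_ids)
    }
    g0v, ginfv, Kv = lap._clone_params(fixed, B, active)
    _, r = lap._mu_resid(g0v, ginfv, Kv)
    df = spec.n_fixed + len(free_ratios) + 1
    # ratios at the lower optimisation bound have collapsed to zero
    random_sd = {}
    for p in spec.random_set:
        rr = ratios.get(p, 0.0)
        random_sd[p] = 0.0 if rr <= _RATIO_MIN * 1.01 else float(tau[p])
    return FitResult(
        spec=spec,
        fixed_estimates={k: float(v) for k, v in fixed.items()},
        random_sd=random_sd,
        residual_sd=float(sigma),
        clone_deviations=clone_dev,
        logLik=ll,
        Df=df,
        AIC=2.0 * df - 2.0 * ll,
        converged=converged,
        residuals=r[data.mask > 0].ravel(),
        clone_ids=data.clone_ids,
        clone_L={cid: float(L) for cid, L in zip(data.clone_ids, data.L)},
        n_obs=data.n_total,
        meta={},
    )


def predict_growth(fit: FitResult, clone_id: str, S, L: float | None = None):
    """Clone-specific growth prediction from a converged fit.

    Combines the fixed effects, the size law (family B) and the clone's
    predicted random deviations.  For a clone absent from the fit, family
    B gives a population-level prediction from the body size ``L``
    (flagged by a warning) and family A the fixed-effects prediction.
    """
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    from .growth import monod_growth

    if clone_id in fit.clone_ids:
        p = fit.params_for_clone(clone_id)
    else:
        warnings.warn(
            f"clone {clone_id!r} not in fit: population-level prediction",
            RuntimeWarning,
            stacklevel=2,
        )
        if fit.spec.family == "B":
            if L is None:
                raise ValueError(
                    "family B prediction for an unknown clone needs its body size L"
                )
            ks = fit.fixed_estimates["K0"] + fit.fixed_estimates["KL"] * L
        else:
            ks = fit.fixed_estimates["KS"]
        p = MonodParams(
            g0=fit.fixed_estimates["g0"], ginf=fit.fixed_estimates["ginf"], KS=ks
        )
    return monod_growth(S, p)


def fit_clutch_series(
    records: Sequence[ClutchRecord],
    clones: Sequence[CloneInfo],
    spec: ModelSpec,
    scale: float | None = None,
) -> FitResult:
    """Fit the same saturation mixed model to clutch-size data.

    Preprocessing mirrors the growth analysis of reproduction: clones
    that never develop eggs are removed, treatment cells (clone x EPA
    level) without any eggs are omitted, and clutch counts are rescaled
    into [0, 1] and arcsin-square-root transformed to stabilise the
    mean-variance relationship.  The rescaling constant is the dataset
    maximum clutch unless ``scale`` supplies a known ceiling; either way
    it is reported in ``meta["clutch_scale"]``.
    """
    by_clone: dict[str, list[ClutchRecord]] = {}
    for r in records:
        by_clone.setdefault(r.clone_id, []).append(r)
    keep_clones = [
        cid for cid, rs in by_clone.items() if any(r.clutch_size_c > 0 for r in rs)
    ]
    if not keep_clones:
        raise ValueError("all clones are eggless: no clutch data to fit")
    cmax = float(scale) if scale is not None else max(r.clutch_size_c for r in records)
    if any(r.clutch_size_c > cmax for r in records):
        raise ValueError(f"clutch sizes exceed the supplied scale {cmax}")
    growth_like: list[GrowthRecord] = []
    for cid in keep_clones:
        cells: dict[float, list[ClutchRecord]] = {}
        for r in by_clone[cid]:
            cells.setdefault(r.epa_conc_S, []).append(r)
        for s_level, cell in cells.items():
            if all(r.clutch_size_c == 0 for r in cell):
                continue  # treatment without eggs
            for r in cell:
                growth_like.append(
                    GrowthRecord(
                        clone_id=cid,
                        epa_conc_S=s_level,
                        replicate=r.replicate,
                        growth_rate_g=arcsin_sqrt_transform(r.clutch_size_c / cmax),
                    )
                )
    clones_kept = [c for c in clones if c.clone_id in keep_clones]
    fit = fit_nlme(growth_like, clones_kept, spec)
    fit.meta["response"] = "clutch_arcsin_sqrt"
    fit.meta["clutch_scale"] = float(cmax)
    return fit
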