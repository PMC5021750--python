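"""Model selection and uncertainty for the Monod mixed-model series.

AIC ranking across the six-model series (A1..A3, B1..B3), pairwise
likelihood-ratio tests between the size-law family B and its common-KS
counterpart A (B nests A via KL = 0, so each pair differs by one degree
of freedom), and residual-bootstrap standard errors for the per-clone
half-saturation constants and the derived 75%-saturation thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .datamodel import CloneInfo, GrowthRecord, logger
from .growth import saturation_threshold
from .nlme import (
    MODEL_SERIES,
    FitResult,
    ModelSpec,
    NonNestedError,
    fit_nlme,
)

__all__ = [
    "aic",
    "lr_test",
    "SelectionTable",
    "run_model_series",
    "BootstrapSummary",
    "residual_bootstrap",
]


def aic(logLik: float, Df: int) -> float:
    """Akaike information criterion, AIC = 2*Df - 2*logLik."""
    return 2.0 * Df - 2.0 * logLik


def lr_test(fit_null: FitResult, fit_alt: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a family-A fit against its family-B pair.

    The null (common KS) is nested in the alternative (KS = K0 + KL*L)
    via KL = 0 with an identical random-effect set.  Returns
    (chisq, chi_df, p) with chisq = 2*(logLik_alt - logLik_null) floored
    at zero and p from the chi-square upper tail.
    """
    ok = (
        fit_null.spec.family == "A"
        and fit_alt.spec.family == "B"
        and fit_null.spec.random_set == fit_alt.spec.random_set
    )
    if not ok:
        raise NonNestedError(
            f"{fit_null.spec.name} is not nested in {fit_alt.spec.name}: "
            "need a family-A null and family-B alternative with the same "
            "random-effect set"
        )
    if not (fit_null.converged and fit_alt.converged):
        raise ValueError("both fits must have converged for a LR test")
    chisq = max(0.0, 2.0 * (fit_alt.logLik - fit_null.logLik))
    chi_df = fit_alt.Df - fit_null.Df
    p = float(chi2.sf(chisq, chi_df))
    return chisq, chi_df, p


@dataclass
class SelectionTable:
    """Six-model comparison: one row per spec plus the pairwise A-vs-B
    likelihood-ratio tests and the minimum-AIC winner."""

    rows: list[dict]
    pairwise_tests: dict[str, dict]
    best_model: str
    fits: dict[str, FitResult] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)


def run_model_series(
    records: Sequence[GrowthRecord],
    clones: Sequence[CloneInfo],
    specs: Sequence[ModelSpec] = MODEL_SERIES,
) -> SelectionTable:
    """Fit every spec in the series and rank by AIC.

    Selection is restricted to converged fits; AIC ties break toward the
    model with fewer parameters.  Pairwise tests are computed for each
    (A_k, B_k) pair present.
    """
    fits: dict[str, FitResult] = {}
    rows = []
    for spec in specs:
        fit = fit_nlme(records, clones, spec)
        fits[spec.name] = fit
        if not fit.converged:
            logger.warning("model %s did not converge", spec.name)
        rows.append(
            {
                "model": spec.name,
                "fixed_effects": ", ".join(spec.fixed_names),
                "random_effects": ", ".join(spec.random_set),
                "Df": fit.Df,
                "AIC": fit.AIC,
                "logLik": fit.logLik,
                "converged": fit.converged,
            }
        )
    tests = {}
    for k in "123":
        a, b = fits.get(f"A{k}"), fits.get(f"B{k}")
        if a is None or b is None or not (a.converged and b.converged):
            continue
        chisq, chi_df, p = lr_test(a, b)
        tests[f"A{k}-vs-B{k}"] = {"chisq": chisq, "chi_df": chi_df, "p_value": p}
    converged = [(r["AIC"], r["Df"], r["model"]) for r in rows if r["converged"]]
    if not converged:
        raise RuntimeError("no model in the series converged")
    best_model = min(converged)[2]
    return SelectionTable(rows=rows, pairwise_tests=tests, best_model=best_model,
                          fits=fits)


@dataclass
class BootstrapSummary:
    """Residual-bootstrap uncertainty for per-clone KS and the derived
    75%-saturation threshold S75 = 3*KS."""

    n_boot: int
    seed: int
    n_dropped: int
    ks_point: dict[str, float]
    s75_point: dict[str, float]
    ks_se: dict[str, float]
    s75_se: dict[str, float]
    ks_ci: dict[str, tuple[float, float]]
    s75_ci: dict[str, tuple[float, float]]
    replicates: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def _clone_ks_vector(fit: FitResult) -> dict[str, float]:
    return {cid: fit.ks_for_clone(cid) for cid in fit.clone_ids}


def residual_bootstrap(
    fit: FitResult,
    records: Sequence[GrowthRecord],
    clones: Sequence[CloneInfo],
    n_boot: int = 1000,
    seed: int = 0,
    refit_variances: bool = True,
) -> BootstrapSummary:
    """Residual bootstrap of a converged mixed fit.

    Residuals about the conditional (clone-specific) fitted values are
    centred, rescaled by sqrt(n/(n - p)) with p the number of fixed
    effects, resampled with replacement at the observation level pooled
    across clones, added back onto the fitted values, and the same spec
    is refit.  With ``refit_variances=False`` the variance components are
    pinned at the point estimates during the refits.  Replicates that
    fail to converge are dropped; more than 20% dropped is an error.
    Deterministic for a given seed.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not fit.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    recs = list(records)
    keep = [r for r in recs if r.clone_id in set(fit.clone_ids)]
    resid = np.asarray(fit.residuals, dtype=float)
    n = len(resid)
    if n != len(keep):
        raise ValueError("fit residuals do not match the record collection")
    fitted = np.array([r.growth_rate() for r in keep]) - resid
    centred = resid - resid.mean()
    centred *= np.sqrt(n / max(n - fit.spec.n_fixed, 1))
    ratio_fixed = None
    if not refit_variances:
        # pin variance components at the point estimates via their ratio
        # to the residual SD (the profiled likelihood's natural pinning)
        sigma = max(fit.residual_sd, 1e-12)
        ratio_fixed = {p: sd / sigma for p, sd in fit.random_sd.items()}
    ks_reps: dict[str, list[float]] = {cid: [] for cid in fit.clone_ids}
    dropped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ystar = fitted + centred[idx]
        boot_records = [
            GrowthRecord(
                clone_id=r.clone_id,
                epa_conc_S=r.epa_conc_S,
                replicate=r.replicate,
                growth_rate_g=float(y),
                duration_t=r.duration_t,
            )
            for r, y in zip(keep, ystar)
        ]
        refit = fit_nlme(
            boot_records,
            clones,
            fit.spec,
            ratio_fixed=ratio_fixed,
            start=fit,
        )
        if not refit.converged:
            dropped += 1
            continue
        for cid, k in _clone_ks_vector(refit).items():
            ks_reps[cid].append(k)
    if dropped > 0.2 * n_boot:
        raise RuntimeError(
            f"{dropped}/{n_boot} bootstrap replicates failed to converge"
        )
    ks_point = _clone_ks_vector(fit)
    reps = {cid: np.asarray(v) for cid, v in ks_reps.items()}
    ks_se, s75_se, ks_ci, s75_ci = {}, {}, {}, {}
    for cid, arr in reps.items():
        ks_se[cid] = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        s75 = 3.0 * arr
        s75_se[cid] = float(s75.std(ddof=1)) if len(s75) > 1 else 0.0
        ks_ci[cid] = (
            float(np.percentile(arr, 2.5)),
            float(np.percentile(arr, 97.5)),
        )
        s75_ci[cid] = (
            float(np.percentile(s75, 2.5)),
            float(np.percentile(s75, 97.5)),
        )
    s75_point = {
        cid: saturation_threshold(k, 0.75) if k > 0 else float("nan")
        for cid, k in ks_point.items()
    }
    return BootstrapSummary(
        n_boot=n_boot,
        seed=seed,
        n_dropped=dropped,
        ks_point=ks_point,
        s75_point=s75_point,
        ks_se=ks_se,
        s75_se=s75_se,
        ks_ci=ks_ci,
        s75_ci=s75_ci,
        replicates=reps,
    )
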