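"""Fatty-acid statistics: totals, tissue quotas and species comparisons.

Totals follow the FAME bookkeeping of the growth study design:
total PUFA = LIN (18:2w6) + ALA (18:3w3) + ETE (20:3w3) + EPA (20:5w3);
total w-3 = ALA + ETE + EPA (so total w-3 = total PUFA - LIN); total FA
additionally includes the pooled non-PUFA fraction.  The "newly built
biomass" tissue quota divides the analyte mass gained between the
neonate and day-6 samples by the dry mass gained — a resource-use
efficiency measure (minimum tissue quota).

Species-level tables average clone means without replicate weighting;
SEs are the SD of clone means over sqrt(number of clones).  Species
effects are tested with Kruskal-Wallis rank ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kruskal

from .datamodel import FattyAcidProfile, logger

__all__ = [
    "ANALYTES",
    "TissueQuota",
    "fa_totals",
    "newly_built_biomass_content",
    "clone_mean_totals",
    "clone_quotas",
    "species_mean_table",
    "kruskal_wallis",
]

ANALYTES = ("total_FA", "total_PUFA", "total_w3", "EPA")

_PUFA_KEYS = ("18:2w6", "18:3w3", "20:3w3", "20:5w3")
_W3_KEYS = ("18:3w3", "20:3w3", "20:5w3")


@dataclass(frozen=True)
class TissueQuota:
    """Analyte content of newly built biomass for one clone (ng ug^-1 dwt).

    Negative contents indicate net depletion of the analyte during
    growth; they are reported with ``depletion=True``, never clamped.
    """

    clone_id: str
    analyte: str
    content_new_biomass: float
    depletion: bool = False


def _get(profile: FattyAcidProfile, key: str) -> float:
    v = profile.fa_content.get(key, float("nan"))
    return float(v)


def fa_totals(profile: FattyAcidProfile) -> dict[str, float]:
    """Derived totals of one sample: total FA, total PUFA, total w-3, EPA.

    Missing FAME entries propagate as NaN into the affected totals.
    """
    pufa = sum(_get(profile, k) for k in _PUFA_KEYS)
    w3 = sum(_get(profile, k) for k in _W3_KEYS)
    total = pufa + _get(profile, "other")
    return {
        "total_FA": float(total),
        "total_PUFA": float(pufa),
        "total_w3": float(w3),
        "EPA": _get(profile, "20:5w3"),
    }


def newly_built_biomass_content(
    neonate: FattyAcidProfile, day6: FattyAcidProfile, analyte: str
) -> TissueQuota:
    """Analyte content of biomass built between the neonate and day-6 stages.

    With per-individual (or per-sample, consistently) dry masses m0, m6
    and per-dwt contents C0, C6:

        quota = (C6*m6 - C0*m0) / (m6 - m0)

    Requires growth (m6 > m0); invariant to rescaling both masses by a
    common factor.  A negative quota (analyte pool shrank) is reported
    with the depletion flag set.
    """
    if neonate.clone_id != day6.clone_id:
        raise ValueError(
            f"profiles belong to different clones "
            f"({neonate.clone_id!r} vs {day6.clone_id!r})"
        )
    if analyte not in ANALYTES:
        raise ValueError(f"unknown analyte {analyte!r}; expected one of {ANALYTES}")
    m0, m6 = neonate.dry_mass_ug, day6.dry_mass_ug
    if m6 <= m0:
        raise ValueError(
            f"no growth for clone {neonate.clone_id!r}: day-6 mass {m6} ug "
            f"does not exceed neonate mass {m0} ug"
        )
    c0 = fa_totals(neonate)[analyte]
    c6 = fa_totals(day6)[analyte]
    q = (c6 * m6 - c0 * m0) / (m6 - m0)
    return TissueQuota(
        clone_id=neonate.clone_id,
        analyte=analyte,
        content_new_biomass=float(q),
        depletion=bool(q < 0),
    )


def _mean_profile(profiles: Sequence[FattyAcidProfile]) -> FattyAcidProfile:
    keys = sorted({k for p in profiles for k in p.fa_content})
    fa = {k: float(np.mean([_get(p, k) for p in profiles])) for k in keys}
    return FattyAcidProfile(
        clone_id=profiles[0].clone_id,
        stage=profiles[0].stage,
        replicate=0,
        dry_mass_ug=float(np.mean([p.dry_mass_ug for p in profiles])),
        fa_content=fa,
    )


def clone_mean_totals(
    profiles: Iterable[FattyAcidProfile], stage: str
) -> pd.DataFrame:
    """Per-clone mean totals for one stage: tidy frame with columns
    clone_id, analyte, value, n_replicates."""
    rows = []
    by_clone: dict[str, list[FattyAcidProfile]] = {}
    for p in profiles:
        if p.stage == stage:
            by_clone.setdefault(p.clone_id, []).append(p)
    for cid, ps in by_clone.items():
        totals = [fa_totals(p) for p in ps]
        for a in ANALYTES:
            vals = np.array([t[a] for t in totals])
            rows.append(
                {
                    "clone_id": cid,
                    "analyte": a,
                    "value": float(np.nanmean(vals)) if not np.all(np.isnan(vals))
                    else float("nan"),
                    "n_replicates": int(np.sum(~np.isnan(vals))),
                }
            )
    return pd.DataFrame(rows)


def clone_quotas(profiles: Iterable[FattyAcidProfile]) -> pd.DataFrame:
    """Newly-built-biomass quotas per clone from clone-mean neonate and
    day-6 profiles; tidy frame (clone_id, analyte, value, depletion)."""
    by: dict[str, dict[str, list[FattyAcidProfile]]] = {}
    for p in profiles:
        by.setdefault(p.clone_id, {}).setdefault(p.stage, []).append(p)
    rows = []
    for cid, stages in by.items():
        if "neonate" not in stages or "day6" not in stages:
            logger.warning("clone %s lacks a neonate/day6 pair; skipped", cid)
            continue
        neo = _mean_profile(stages["neonate"])
        d6 = _mean_profile(stages["day6"])
        for a in ANALYTES:
            q = newly_built_biomass_content(neo, d6, a)
            rows.append(
                {
                    "clone_id": cid,
                    "analyte": a,
                    "value": q.content_new_biomass,
                    "depletion": q.depletion,
                }
            )
    return pd.DataFrame(rows)


def species_mean_table(
    clone_values: pd.DataFrame, species_of: Mapping[str, str]
) -> pd.DataFrame:
    """Species-level table of unweighted means of clone means.

    ``clone_values`` is tidy (clone_id, analyte, value) — clone-level
    means, e.g. from :func:`clone_mean_totals` or :func:`clone_quotas`.
    Missing clone values (NaN) are excluded with the divisor reduced.
    Returns a frame with species, analyte, mean, se, n_clones; the SE is
    the SD of clone means / sqrt(n_clones), blank (NaN) for a single
    clone.  Species without any clone value for an analyte are omitted
    with a warning.
    """
    df = clone_values.copy()
    unknown = set(df["clone_id"]) - set(species_of)
    if unknown:
        raise ValueError(f"clones without species mapping: {sorted(unknown)}")
    df["species"] = df["clone_id"].map(species_of)
    rows = []
    for (sp, a), grp in df.groupby(["species", "analyte"], sort=False):
        vals = grp["value"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            logger.warning("species %s has no data for %s; omitted", sp, a)
            continue
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        rows.append(
            {"species": sp, "analyte": a, "mean": mean, "se": se,
             "n_clones": len(vals)}
        )
    return pd.DataFrame(rows)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis rank one-way ANOVA across >= 2 groups.

    Returns the tie-corrected H statistic and the chi-square upper-tail
    p-value with k-1 degrees of freedom.  All-identical data yield
    (H=0, p=1) by convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = kruskal(*arrays)
    return float(h), float(p)
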