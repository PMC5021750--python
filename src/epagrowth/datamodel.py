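"""Domain types and tidy-CSV interchange for the EPA-growth analysis.

All tables are plain UTF-8 CSV with one header row and "." as the decimal
separator.  Units are fixed throughout the package and never converted:
growth rates in day^-1, dietary EPA in ug EPA mg C^-1, body size in mm,
dry masses in ug, fatty-acid contents in ng ug^-1 dwt.

Schemas
-------
clones.csv      clone_id, species, body_size_L, body_size_se
growth.csv      clone_id, epa_conc_S, replicate, growth_rate_g,
                mass_initial_W0, mass_final_Wt, duration_t
clutch.csv      clone_id, epa_conc_S, replicate, clutch_size_c
fattyacids.csv  clone_id, stage, replicate, dry_mass_ug,
                fa_18_2w6, fa_18_3w3, fa_20_3w3, fa_20_5w3, fa_other
"""

from __future__ import annotations

import json
import logging
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("epagrowth")

SPECIES = ("longispina_complex", "pulicaria", "magna")

#: canonical FAME keys -> CSV column names
FAME_COLUMNS = {
    "18:2w6": "fa_18_2w6",  # linoleic acid (LIN)
    "18:3w3": "fa_18_3w3",  # alpha-linolenic acid (ALA)
    "20:3w3": "fa_20_3w3",  # eicosatrienoic acid (ETE)
    "20:5w3": "fa_20_5w3",  # eicosapentaenoic acid (EPA)
    "other": "fa_other",    # pooled non-PUFA fatty acids
}

STAGES = ("neonate", "day6")


class SchemaError(ValueError):
    """A CSV is missing a required column or has an unusable header."""


class ValidationError(ValueError):
    """A row violates a domain-type invariant; the message names the row."""


def configure_logging(verbose: bool = False) -> None:
    """Route package logging to stderr; DEBUG level when verbose."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CloneInfo:
    """A clonal *Daphnia* lineage with its body size at first reproduction."""

    clone_id: str
    species: str
    body_size_L: float  # mm
    body_size_se: float = 0.0  # mm

    def validate(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(
                f"clone {self.clone_id!r}: unknown species {self.species!r} "
                f"(expected one of {SPECIES})"
            )
        if not self.body_size_L > 0:
            raise ValidationError(
                f"clone {self.clone_id!r}: body_size_L must be positive, "
                f"got {self.body_size_L}"
            )


@dataclass(frozen=True)
class GrowthRecord:
    """One beaker-level growth observation.

    Either ``growth_rate_g`` or the dry-mass pair (``mass_initial_W0``,
    ``mass_final_Wt``) must be present; :meth:`growth_rate` resolves the
    rate either way.
    """

    clone_id: str
    epa_conc_S: float  # ug EPA mg C^-1
    replicate: int
    growth_rate_g: float | None = None  # day^-1
    mass_initial_W0: float | None = None  # ug dwt
    mass_final_Wt: float | None = None  # ug dwt
    duration_t: float = 6.0  # days

    def validate(self) -> None:
        if self.epa_conc_S < 0:
            raise ValidationError(
                f"clone {self.clone_id!r}: epa_conc_S must be >= 0, "
                f"got {self.epa_conc_S}"
            )
        if not self.duration_t > 0:
            raise ValidationError(
                f"clone {self.clone_id!r}: duration_t must be positive"
            )
        has_masses = self.mass_initial_W0 is not None and self.mass_final_Wt is not None
        if self.growth_rate_g is None and not has_masses:
            raise ValidationError(
                f"clone {self.clone_id!r}: need growth_rate_g or both masses"
            )
        for name in ("mass_initial_W0", "mass_final_Wt"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(
                    f"clone {self.clone_id!r}: {name} must be positive, got {v}"
                )

    def growth_rate(self) -> float:
        from .growth import juvenile_growth_rate

        if self.growth_rate_g is not None:
            return float(self.growth_rate_g)
        return juvenile_growth_rate(
            self.mass_initial_W0, self.mass_final_Wt, self.duration_t
        )


@dataclass(frozen=True)
class ClutchRecord:
    """Clutch size (eggs per female) of one beaker at one EPA level."""

    clone_id: str
    epa_conc_S: float
    replicate: int
    clutch_size_c: float

    def validate(self) -> None:
        if self.epa_conc_S < 0:
            raise ValidationError(
                f"clone {self.clone_id!r}: epa_conc_S must be >= 0"
            )
        if self.clutch_size_c < 0:
            raise ValidationError(
                f"clone {self.clone_id!r}: clutch_size_c must be >= 0, "
                f"got {self.clutch_size_c}"
            )


@dataclass(frozen=True)
class FattyAcidProfile:
    """Per-sample fatty-acid contents (ng ug^-1 dwt) of one pooled sample.

    ``fa_content`` maps FAME names (keys of :data:`FAME_COLUMNS`) to
    contents; missing analytes may be absent or NaN and propagate as
    missing through downstream statistics.
    """

    clone_id: str
    stage: str  # "neonate" or "day6"
    replicate: int
    dry_mass_ug: float
    fa_content: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(
                f"clone {self.clone_id!r}: stage must be one of {STAGES}, "
                f"got {self.stage!r}"
            )
        if not self.dry_mass_ug > 0:
            raise ValidationError(
                f"clone {self.clone_id!r}: dry_mass_ug must be positive"
            )
        for name, v in self.fa_content.items():
            if v is not None and not math.isnan(v) and v < 0:
                raise ValidationError(
                    f"clone {self.clone_id!r}: content of {name} must be >= 0, "
                    f"got {v}"
                )


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _opt_float(value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_clone_table(path) -> list[CloneInfo]:
    df = pd.read_csv(path)
    _require_columns(df, ["clone_id", "species", "body_size_L"], path)
    clones = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        c = CloneInfo(
            clone_id=str(row.clone_id),
            species=str(row.species),
            body_size_L=float(row.body_size_L),
            body_size_se=float(getattr(row, "body_size_se", 0.0) or 0.0),
        )
        try:
            c.validate()
        except ValidationError as e:
            raise ValidationError(f"{path} row {i}: {e}") from None
        if c.clone_id in seen:
            raise ValidationError(f"{path} row {i}: duplicate clone_id {c.clone_id!r}")
        seen.add(c.clone_id)
        clones.append(c)
    return clones


def write_clone_table(clones: Iterable[CloneInfo], path) -> None:
    pd.DataFrame(
        [
            dict(
                clone_id=c.clone_id,
                species=c.species,
                body_size_L=c.body_size_L,
                body_size_se=c.body_size_se,
            )
            for c in clones
        ]
    ).to_csv(path, index=False)


def read_growth_table(path, clone_table) -> tuple[list[GrowthRecord], list[CloneInfo]]:
    """Read growth observations and the clone table, validating every row.

    Records referencing a clone_id absent from the clone table are
    rejected with the offending row number.
    """
    clones = read_clone_table(clone_table)
    known = {c.clone_id for c in clones}
    df = pd.read_csv(path)
    _require_columns(df, ["clone_id", "epa_conc_S", "replicate"], path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = GrowthRecord(
            clone_id=str(row.clone_id),
            epa_conc_S=float(row.epa_conc_S),
            replicate=int(row.replicate),
            growth_rate_g=_opt_float(getattr(row, "growth_rate_g", None)),
            mass_initial_W0=_opt_float(getattr(row, "mass_initial_W0", None)),
            mass_final_Wt=_opt_float(getattr(row, "mass_final_Wt", None)),
            duration_t=float(getattr(row, "duration_t", 6.0) or 6.0),
        )
        if rec.clone_id not in known:
            raise ValidationError(
                f"{path} row {i}: unknown clone_id {rec.clone_id!r}"
            )
        try:
            rec.validate()
        except ValidationError as e:
            raise ValidationError(f"{path} row {i}: {e}") from None
        records.append(rec)
    return records, clones


def write_growth_table(records: Iterable[GrowthRecord], path) -> None:
    pd.DataFrame(
        [
            dict(
                clone_id=r.clone_id,
                epa_conc_S=r.epa_conc_S,
                replicate=r.replicate,
                growth_rate_g=r.growth_rate_g,
                mass_initial_W0=r.mass_initial_W0,
                mass_final_Wt=r.mass_final_Wt,
                duration_t=r.duration_t,
            )
            for r in records
        ]
    ).to_csv(path, index=False)


def read_clutch_table(path, clone_table=None) -> list[ClutchRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["clone_id", "epa_conc_S", "replicate", "clutch_size_c"], path)
    known = None
    if clone_table is not None:
        known = {c.clone_id for c in read_clone_table(clone_table)}
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = ClutchRecord(
            clone_id=str(row.clone_id),
            epa_conc_S=float(row.epa_conc_S),
            replicate=int(row.replicate),
            clutch_size_c=float(row.clutch_size_c),
        )
        if known is not None and rec.clone_id not in known:
            raise ValidationError(f"{path} row {i}: unknown clone_id {rec.clone_id!r}")
        try:
            rec.validate()
        except ValidationError as e:
            raise ValidationError(f"{path} row {i}: {e}") from None
        records.append(rec)
    return records


def write_clutch_table(records: Iterable[ClutchRecord], path) -> None:
    pd.DataFrame(
        [
            dict(
                clone_id=r.clone_id,
                epa_conc_S=r.epa_conc_S,
                replicate=r.replicate,
                clutch_size_c=r.clutch_size_c,
            )
            for r in records
        ]
    ).to_csv(path, index=False)


def read_fattyacid_table(path, clone_table=None) -> list[FattyAcidProfile]:
    df = pd.read_csv(path)
    _require_columns(df, ["clone_id", "stage", "replicate", "dry_mass_ug"], path)
    known = None
    if clone_table is not None:
        known = {c.clone_id for c in read_clone_table(clone_table)}
    profiles = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        fa = {}
        for key, col in FAME_COLUMNS.items():
            if col in df.columns:
                v = _opt_float(getattr(row, col))
                fa[key] = float("nan") if v is None else v
        prof = FattyAcidProfile(
            clone_id=str(row.clone_id),
            stage=str(row.stage),
            replicate=int(row.replicate),
            dry_mass_ug=float(row.dry_mass_ug),
            fa_content=fa,
        )
        if known is not None and prof.clone_id not in known:
            raise ValidationError(f"{path} row {i}: unknown clone_id {prof.clone_id!r}")
        try:
            prof.validate()
        except ValidationError as e:
            raise ValidationError(f"{path} row {i}: {e}") from None
        profiles.append(prof)
    return profiles


def write_fattyacid_table(profiles: Iterable[FattyAcidProfile], path) -> None:
    rows = []
    for p in profiles:
        row = dict(
            clone_id=p.clone_id,
            stage=p.stage,
            replicate=p.replicate,
            dry_mass_ug=p.dry_mass_ug,
        )
        for key, col in FAME_COLUMNS.items():
            row[col] = p.fa_content.get(key, float("nan"))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fit reports
# ---------------------------------------------------------------------------

def write_fit_report(fit, path) -> None:
    """Serialise a :class:`~epagrowth.nlme.FitResult` to JSON.

    The report carries estimates, variance components, logLik, Df, AIC and
    the convergence flag in machine-readable form and can be read back with
    :func:`read_fit_report`.
    """
    payload = fit.to_dict()
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_fit_report(path):
    from .nlme import FitResult

    return FitResult.from_dict(json.loads(Path(path).read_text()))
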