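"""Trait-table data model, I/O, transformation, standardization and pairing.

The analysis unit is a *population*: all sampled individuals of one species at
one site, observed at one ontogenetic stage (seedling or adult).  Eight
functional traits are carried per population; five of them (LA, SLA, d_h, VD,
DA_pit) are log-normal-ish and registered for natural-log transformation
before z-scoring, the remaining three (LDMC, WSG, TFW) are treated as
approximately normal on their natural scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TRAIT_NAMES: tuple[str, ...] = ("LA", "LDMC", "SLA", "WSG", "TFW", "d_h", "VD", "DA_pit")

#: traits measured on a multiplicative scale; natural log applied before z-scoring
LOG_TRAITS: frozenset[str] = frozenset({"LA", "SLA", "d_h", "VD", "DA_pit"})

TRAIT_UNITS: dict[str, str] = {
    "LA": "cm^2",
    "LDMC": "g g^-1",
    "SLA": "cm^2 g^-1",
    "WSG": "unitless",
    "TFW": "um",
    "d_h": "um",
    "VD": "vessels mm^-2",
    "DA_pit": "um",
}

STAGES = ("seedling", "adult")
PHENOLOGIES = ("deciduous", "evergreen", "unknown")
GROWTH_FORMS = ("liana", "free_standing", "unknown")

SCOPES = ("pooled_stages", "adults_only", "seedlings_only")

CANONICAL_COLUMNS = ("species_id", "site_id", "stage", "phenology", "growth_form") + TRAIT_NAMES


@dataclass(frozen=True)
class TraitMeta:
    """Per-trait metadata: units and whether the trait is log-registered."""

    name: str
    units: str
    log_transform: bool


def default_trait_meta() -> list[TraitMeta]:
    return [TraitMeta(t, TRAIT_UNITS[t], t in LOG_TRAITS) for t in TRAIT_NAMES]


@dataclass
class PopulationTraits:
    """One population x stage record with covariates and trait values.

    ``traits`` maps trait name to a float, with ``None`` for missing cells.
    """

    species_id: str
    site_id: int
    stage: str
    phenology: str = "unknown"
    growth_form: str = "unknown"
    traits: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.site_id = int(self.site_id)
        if self.site_id not in (1, 2, 3, 4):
            raise ValueError(f"site_id must be in {{1,2,3,4}}, got {self.site_id!r}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.phenology not in PHENOLOGIES:
            raise ValueError(f"phenology must be one of {PHENOLOGIES}, got {self.phenology!r}")
        if self.growth_form not in GROWTH_FORMS:
            raise ValueError(
                f"growth_form must be one of {GROWTH_FORMS}, got {self.growth_form!r}"
            )
        for name, value in self.traits.items():
            if value is None:
                continue
            if not math.isfinite(value):
                raise ValueError(f"trait {name} is non-finite for {self.species_id}")
            if name in LOG_TRAITS and value <= 0:
                raise ValueError(
                    f"log-registered trait {name} must be > 0, got {value} "
                    f"({self.species_id}, site {self.site_id}, {self.stage})"
                )
            if name == "LDMC" and not (0 < value <= 1):
                raise ValueError(f"LDMC must be in (0, 1], got {value} ({self.species_id})")
            if name == "WSG" and not (0 < value < 2):
                raise ValueError(f"WSG must be in (0, 2), got {value} ({self.species_id})")

    @property
    def population(self) -> tuple[str, int]:
        return (self.species_id, self.site_id)


def _fold_category(raw: object, allowed: Sequence[str], *, default: str, what: str, row: int) -> str:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return default
    text = str(raw).strip().lower().replace("-", "_").replace(" ", "_")
    if text in ("", "na", "nan", "unknown"):
        return default
    if text in allowed:
        return text
    raise ValueError(f"unknown {what} label {raw!r} in row {row}")


def read_trait_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[PopulationTraits]:
    """Read a CSV/TSV trait table into a list of :class:`PopulationTraits`.

    ``schema`` optionally maps canonical column names to the names actually
    used in the file.  Empty cells and the sentinel ``NA`` become missing.
    Stage, phenology and growth-form labels are matched case-insensitively.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str}, float_precision="round_trip")
    if schema:
        df = df.rename(columns={actual: canon for canon, actual in schema.items()})
    missing_cols = [c for c in ("species_id", "site_id", "stage") if c not in df.columns]
    if missing_cols:
        raise ValueError(f"trait table is missing required columns: {missing_cols}")

    records: list[PopulationTraits] = []
    seen: set[tuple[str, int, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        stage = _fold_category(row_d["stage"], STAGES, default="", what="stage", row=i)
        if stage not in STAGES:
            raise ValueError(f"unknown stage label {row_d['stage']!r} in row {i}")
        phen = _fold_category(
            row_d.get("phenology"), PHENOLOGIES, default="unknown", what="phenology", row=i
        )
        gform = _fold_category(
            row_d.get("growth_form"), GROWTH_FORMS, default="unknown", what="growth_form", row=i
        )
        traits: dict[str, float | None] = {}
        for t in TRAIT_NAMES:
            if t not in row_d:
                continue
            v = row_d[t]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                traits[t] = None
            else:
                v = float(v)
                if t in LOG_TRAITS and v <= 0:
                    raise ValueError(
                        f"non-positive value {v} for log-registered trait {t} in row {i}"
                    )
                traits[t] = v
        try:
            rec = PopulationTraits(
                species_id=str(row_d["species_id"]),
                site_id=int(row_d["site_id"]),
                stage=stage,
                phenology=phen,
                growth_form=gform,
                traits=traits,
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
        key = (rec.species_id, rec.site_id, rec.stage)
        if key in seen:
            raise ValueError(f"duplicate (species, site, stage) = {key} in row {i}")
        seen.add(key)
        records.append(rec)
    return records


def write_trait_table(table: Iterable[PopulationTraits], path: str | Path) -> None:
    """Write records to CSV with full float precision (repr round-trip)."""
    rows = []
    for rec in table:
        row: dict[str, object] = {
            "species_id": rec.species_id,
            "site_id": rec.site_id,
            "stage": rec.stage,
            "phenology": rec.phenology,
            "growth_form": rec.growth_form,
        }
        for t in TRAIT_NAMES:
            v = rec.traits.get(t)
            row[t] = "" if v is None else repr(float(v))
        rows.append(row)
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(Path(path), index=False)


@dataclass
class StandardizedMatrix:
    """Populations x traits matrix after log-transform and z-scoring.

    ``values`` uses NaN for missing cells.  ``center``/``scale`` record the
    per-trait mean/SD used (on the transformed scale), so the transform is
    invertible via :meth:`destandardize`.  ``covariates`` carries each row's
    (phenology, growth_form) so pairing can copy them.
    """

    row_index: list[tuple[str, int, str]]
    trait_names: tuple[str, ...]
    values: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    scope: str
    covariates: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, trait: str) -> np.ndarray:
        return self.values[:, self.trait_names.index(trait)]

    def destandardize(self) -> np.ndarray:
        """Invert z-scoring and the log transform, returning natural units."""
        raw = self.values * self.scale + self.center
        out = raw.copy()
        for j, t in enumerate(self.trait_names):
            if t in LOG_TRAITS:
                out[:, j] = np.exp(raw[:, j])
        return out

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.trait_names))
        df.insert(0, "stage", [r[2] for r in self.row_index])
        df.insert(0, "site_id", [r[1] for r in self.row_index])
        df.insert(0, "species_id", [r[0] for r in self.row_index])
        return df


def _scope_mask(stages: Sequence[str], scope: str) -> np.ndarray:
    if scope == "pooled_stages":
        return np.ones(len(stages), dtype=bool)
    if scope == "adults_only":
        return np.array([s == "adult" for s in stages])
    if scope == "seedlings_only":
        return np.array([s == "seedling" for s in stages])
    raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")


def transform_and_standardize(
    table: Sequence[PopulationTraits],
    meta: Sequence[TraitMeta] | None = None,
    scope: str = "pooled_stages",
    center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
) -> StandardizedMatrix:
    """Log-transform registered traits and z-score each trait within ``scope``.

    Means/SDs are computed over non-missing cells of rows within the scope
    (sample SD, ddof=1).  Pass explicit ``center``/``scale`` (on the
    transformed scale) to standardize against a fixed external reference
    instead of the empirical moments.
    """
    if meta is None:
        meta = default_trait_meta()
    trait_names = tuple(m.name for m in meta)
    stages = [rec.stage for rec in table]
    keep = _scope_mask(stages, scope)
    rows = [rec for rec, k in zip(table, keep) if k]
    if not rows:
        raise ValueError(f"no rows in scope {scope!r}")

    raw = np.full((len(rows), len(trait_names)), np.nan)
    for i, rec in enumerate(rows):
        for j, m in enumerate(meta):
            v = rec.traits.get(m.name)
            if v is None:
                continue
            raw[i, j] = math.log(v) if m.log_transform else v

    if center is None or scale is None:
        mu = np.empty(len(trait_names))
        sd = np.empty(len(trait_names))
        for j, m in enumerate(meta):
            col = raw[:, j]
            obs = col[~np.isnan(col)]
            if obs.size < 2:
                raise ValueError(f"trait {m.name}: need >= 2 non-missing values in scope {scope}")
            mu[j] = obs.mean()
            sd[j] = obs.std(ddof=1)
            if sd[j] <= 1e-12 * max(1.0, abs(mu[j])):
                raise ValueError(f"trait {m.name} has zero SD within scope {scope}")
    else:
        mu = np.asarray(center, dtype=float).copy()
        sd = np.asarray(scale, dtype=float).copy()
        if mu.shape != (len(trait_names),) or sd.shape != (len(trait_names),):
            raise ValueError("center/scale must have one entry per trait")
        if np.any(sd <= 0):
            bad = trait_names[int(np.argmax(sd <= 0))]
            raise ValueError(f"trait {bad} has non-positive scale")

    z = (raw - mu) / sd
    return StandardizedMatrix(
        row_index=[(r.species_id, r.site_id, r.stage) for r in rows],
        trait_names=trait_names,
        values=z,
        center=mu,
        scale=sd,
        scope=scope,
        covariates=[(r.phenology, r.growth_form) for r in rows],
    )


@dataclass
class ShiftDataset:
    """Paired per-population standardized trait differences (adult - seedling).

    ``deciduous``/``liana`` are 0/1 indicators (``unknown`` maps to the
    evergreen / free-standing reference class, 0).
    """

    trait: str
    population_index: list[tuple[str, int]]
    delta: np.ndarray
    site: np.ndarray
    deciduous: np.ndarray
    liana: np.ndarray

    @property
    def n(self) -> int:
        return self.delta.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": [p[0] for p in self.population_index],
                "site_id": self.site,
                "delta": self.delta,
                "deciduous": self.deciduous,
                "liana": self.liana,
            }
        )


def pair_stages(std: StandardizedMatrix, trait: str) -> ShiftDataset:
    """Build adult-minus-seedling deltas for populations observed at both stages."""
    if std.scope != "pooled_stages":
        raise ValueError("pair_stages requires a pooled_stages standardization")
    if trait not in std.trait_names:
        raise ValueError(f"unknown trait {trait!r}")
    col = std.column(trait)
    by_pop: dict[tuple[str, int], dict[str, tuple[float, tuple[str, str]]]] = {}
    for i, (sp, site, stage) in enumerate(std.row_index):
        if np.isnan(col[i]):
            continue
        by_pop.setdefault((sp, site), {})[stage] = (float(col[i]), std.covariates[i])

    pops, deltas, sites, dec, liana = [], [], [], [], []
    for pop in sorted(by_pop):
        rec = by_pop[pop]
        if "adult" not in rec or "seedling" not in rec:
            continue
        (a, cov_a), (s, cov_s) = rec["adult"], rec["seedling"]
        for x, y in zip(cov_a, cov_s):
            # same population must not change phenology or growth form
            if x != y and "unknown" not in (x, y):
                raise ValueError(
                    f"conflicting covariates for population {pop}: {cov_a} vs {cov_s}"
                )
        phen = cov_a[0] if cov_a[0] != "unknown" else cov_s[0]
        gform = cov_a[1] if cov_a[1] != "unknown" else cov_s[1]
        pops.append(pop)
        deltas.append(a - s)
        sites.append(pop[1])
        dec.append(1 if phen == "deciduous" else 0)
        liana.append(1 if gform == "liana" else 0)
    if not pops:
        raise ValueError(f"no populations with both stages for trait {trait}")
    return ShiftDataset(
        trait=trait,
        population_index=pops,
        delta=np.array(deltas),
        site=np.array(sites, dtype=int),
        deciduous=np.array(dec, dtype=int),
        liana=np.array(liana, dtype=int),
    )


def complete_cases(
    std: StandardizedMatrix, traits: Sequence[str], stage_filter: str = "pooled_stages"
) -> StandardizedMatrix:
    """Restrict to rows with all listed traits observed (and matching stage)."""
    unknown = [t for t in traits if t not in std.trait_names]
    if unknown:
        raise ValueError(f"traits not in matrix: {unknown}")
    cols = [std.trait_names.index(t) for t in traits]
    stage_keep = _scope_mask([r[2] for r in std.row_index], stage_filter)
    sub = std.values[:, cols]
    full = ~np.isnan(sub).any(axis=1)
    keep = stage_keep & full
    if not keep.any():
        tallies = {
            t: int(np.isnan(std.values[stage_keep, j]).sum()) for t, j in zip(traits, cols)
        }
        raise ValueError(
            f"no complete cases for traits {list(traits)} under {stage_filter}; "
            f"missing-cell tallies within stage filter: {tallies}"
        )
    idx = np.where(keep)[0]
    return StandardizedMatrix(
        row_index=[std.row_index[i] for i in idx],
        trait_names=tuple(traits),
        values=std.values[np.ix_(idx, cols)].copy(),
        center=std.center[cols].copy(),
        scale=std.scale[cols].copy(),
        scope=std.scope,
        covariates=[std.covariates[i] for i in idx],
    )
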