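"""Synthetic cohort generation.

Real HRS genotype-linked survey data are access-restricted, so this module
generates cohorts with the statistical structure the downstream analysis
assumes: a standard-normal polygenic score (the published scores are
standardized within ancestry group, so no genotype layer is simulated),
binary adverse early-psychosocial exposures at stated prevalences, a
logistic ever-smoking outcome with G, E, G×E and covariate effects, and
missing-completely-at-random survey fields.

Two generation modes exist:

* :func:`simulate_cohort` — draw a cohort from :class:`SimulationParams`;
  raw survey fields are generated consistently with the latent binary
  exposures so the harmonization layer can re-derive them.
* :func:`cohort_from_cell_counts` — build a cohort whose G×E×outcome
  cross-tabulation reproduces a printed cell-count table exactly, for
  worked-example and oracle tests against published numbers.

Determinism: every operation takes one seed; per-field substreams are
spawned from it in a fixed, documented order, so identical parameters and
seed give byte-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .cohort import (
    EPFS,
    EPF_RAW_FIELDS,
    PC_COLUMNS,
    CellCounts,
    Cohort,
    exposure_column,
)


class SimulationParamsError(ValueError):
    """Invalid simulation parameter; the message names the field."""


# EPF prevalences back-calculated from the published EA cell totals
# (adverse-cell totals / block N), e.g. low maternal warmth
# (1120 + 385) / 5572 ~= 0.27.  Not ground truth; see docs/methods.md.
DEFAULT_PREV_E: dict[str, float] = {
    "maternal_warmth": 0.2701,
    "financial_burden": 0.0877,
    "childhood_stress": 0.2523,
    "father_education": 0.1699,
    "mother_education": 0.1088,
}

# Per-EPF MCAR rates back-calculated as 1 - block N / 6969 genotyped EA
# participants; all inside the reported 1%-40% range.
DEFAULT_MISSING_RATES: dict[str, float] = {
    "maternal_warmth": 0.200,
    "financial_burden": 0.014,
    "childhood_stress": 0.112,
    "father_education": 0.117,
    "mother_education": 0.070,
}

# Fixed spawn order of per-field random substreams.
_STREAMS = (
    "age",
    "gender",
    "pc",
    "pgs",
    "epf",
    "outcome",
    "raw",
    "missing",
)


@dataclass
class SimulationParams:
    """Generating model for a synthetic cohort.

    Log-odds coefficients default to the published EA maternal-warmth
    block (OR_G 1.10, OR_E 1.21, multiplicative ratio 1.30); the intercept
    is calibrated so the default cohort smokes at roughly the reported 55%
    EA prevalence; ``beta_age`` encodes the reported 5.6% lower odds per
    10 years of age.  ``driver_epf`` names the single EPF that enters the
    outcome model; the remaining four are independent noise exposures.
    """

    n_participants: int = 6969
    prev_E: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREV_E))
    pgs_mean: float = 0.0
    pgs_sd: float = 1.0
    beta0: float = 0.28
    beta_G: float = math.log(1.10)
    beta_E: float = math.log(1.21)
    beta_GxE: float = math.log(1.30)
    beta_age: float = math.log(0.944) / 10.0
    beta_gender: float = -0.3
    beta_pc: tuple[float, float, float, float, float] = (0.0, 0.0, 0.0, 0.0, 0.0)
    age_mean: float = 74.3
    age_sd: float = 14.3
    prop_female: float = 0.572
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    driver_epf: str = "maternal_warmth"
    group: str = "EA"
    n_waves: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_participants, (int, np.integer)) and self.n_participants >= 1):
            raise SimulationParamsError("n_participants must be a positive integer")
        if self.pgs_sd <= 0:
            raise SimulationParamsError("pgs_sd must be > 0")
        if not 0.0 <= self.prop_female <= 1.0:
            raise SimulationParamsError("prop_female must be in [0, 1]")
        if self.age_sd < 0:
            raise SimulationParamsError("age_sd must be >= 0")
        if self.driver_epf not in EPFS:
            raise SimulationParamsError(
                f"driver_epf must be one of {EPFS}, got {self.driver_epf!r}"
            )
        if len(self.beta_pc) != 5:
            raise SimulationParamsError("beta_pc must have length 5")
        if self.n_waves < 1:
            raise SimulationParamsError("n_waves must be >= 1")
        for epf, p in self.prev_E.items():
            if epf not in EPFS:
                raise SimulationParamsError(f"prev_E: unknown EPF {epf!r}")
            if not 0.0 <= p <= 1.0:
                raise SimulationParamsError(f"prev_E[{epf!r}] must be in [0, 1]")
        for epf in EPFS:
            if epf not in self.prev_E:
                raise SimulationParamsError(f"prev_E missing EPF {epf!r}")
        for epf, r in self.missing_rates.items():
            if epf not in EPFS:
                raise SimulationParamsError(f"missing_rates: unknown EPF {epf!r}")
            if not 0.0 <= r <= 1.0:
                raise SimulationParamsError(f"missing_rates[{epf!r}] must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParams":
        """Load parameters from a YAML mapping keyed exactly by field name."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise SimulationParamsError(f"unknown config keys: {sorted(unknown)}")
        if "beta_pc" in raw:
            raw["beta_pc"] = tuple(raw["beta_pc"])
        params = cls(**raw)
        params.validate()
        return params

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["beta_pc"] = list(self.beta_pc)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def simulate_cohort(params: SimulationParams) -> Cohort:
    """Draw a synthetic cohort from the generating model.

    The high-genetic-risk flag G marks scores above the within-cohort 75th
    percentile (linear-interpolation quantile, strict inequality).  The
    outcome is Bernoulli(logistic(beta0 + beta_G·G + beta_E·E +
    beta_GxE·G·E + beta_age·(age − age_mean) + beta_gender·female +
    Σ beta_pc·pc)), with E the driver EPF.  Raw survey fields are filled
    so that harmonization recovers the categorical exposures exactly and
    the maternal-warmth score separates adverse from normal records;
    MCAR missingness is then injected per EPF at ``missing_rates``.
    """
    params.validate()
    n = params.n_participants
    rng = _substreams(params.seed)

    age = rng["age"].normal(params.age_mean, params.age_sd, n)
    female = (rng["gender"].random(n) < params.prop_female).astype(int)
    pcs = rng["pc"].standard_normal((n, 5))
    pgs = rng["pgs"].normal(params.pgs_mean, params.pgs_sd, n)
    g = (pgs > np.quantile(pgs, 0.75)).astype(int)

    adverse = {
        epf: (rng["epf"].random(n) < params.prev_E[epf]).astype(int) for epf in EPFS
    }
    e = adverse[params.driver_epf]

    eta = (
        params.beta0
        + params.beta_G * g
        + params.beta_E * e
        + params.beta_GxE * g * e
        + params.beta_age * (age - params.age_mean)
        + params.beta_gender * female
        + pcs @ np.asarray(params.beta_pc)
    )
    y = (rng["outcome"].random(n) < expit(eta)).astype(int)

    raw = rng["raw"]
    df = pd.DataFrame(
        {
            "id": [f"{params.group}-{i:06d}" for i in range(n)],
            "group": params.group,
            "age": np.round(age, 1),
            "gender": np.where(female == 1, "female", "male"),
        }
    )
    for j, c in enumerate(PC_COLUMNS):
        df[c] = pcs[:, j]
    df["pgs"] = pgs

    # Maternal warmth: adverse records score in [1, 2], normal in [3, 5]
    # item units, so the within-cohort bottom-quartile cut falls between
    # the two clusters whenever the adverse fraction is near 25%.
    warm = adverse["maternal_warmth"].astype(bool)
    df["warmth_item1"] = np.where(warm, raw.integers(1, 3, n), raw.integers(3, 5, n)).astype(float)
    df["warmth_item2"] = np.where(warm, raw.integers(1, 3, n), raw.integers(3, 5, n)).astype(float)
    df["warmth_item3"] = np.where(warm, raw.integers(1, 3, n), raw.integers(4, 6, n)).astype(float)

    fin = adverse["financial_burden"].astype(bool)
    normal_fin = np.where(
        raw.random(n) < 0.112, "pretty_well_off", "about_average"
    )
    df["child_finance"] = np.where(fin, "poor", normal_fin)

    stress = adverse["childhood_stress"].astype(bool)
    which = raw.integers(0, 3, n)  # at least one event for exposed records
    extra = raw.random((n, 3)) < 0.25
    for k, col in enumerate(EPF_RAW_FIELDS["childhood_stress"]):
        flag = stress & ((which == k) | extra[:, k])
        df[col] = np.where(flag, "yes", "no")

    df["father_ed_gt8"] = np.where(adverse["father_education"] == 1, "no", "yes")
    df["mother_ed_gt8"] = np.where(adverse["mother_education"] == 1, "no", "yes")

    # Ever-smokers endorse the 100-cigarette item at one random wave and
    # may repeat at later interviews; never-smokers answer no throughout.
    first = raw.integers(0, params.n_waves, n)
    repeat = raw.random((n, params.n_waves)) < 0.5
    for w in range(params.n_waves):
        yes = (y == 1) & ((first == w) | repeat[:, w])
        df[f"ever_smoked_wave{w + 1}"] = np.where(yes, "yes", "no")
    df["ever_smoked"] = y

    truth = pd.DataFrame({"id": df["id"], "G": g})
    for epf in EPFS:
        truth[exposure_column(epf)] = adverse[epf]
    truth["ever_smoked"] = y

    cohort = Cohort(
        df=df,
        provenance={"mode": "simulated", "seed": params.seed, "params": asdict(params)},
        truth=truth,
    )
    if any(r > 0 for r in params.missing_rates.values()):
        cohort = inject_missingness(
            cohort, params.missing_rates, seed=_missing_seed(params.seed)
        )
    return cohort


def _missing_seed(seed: int) -> int:
    # stable sub-seed below 2**31 for the missingness pass
    return int(np.random.SeedSequence(seed).spawn(len(_STREAMS))[-1].generate_state(1)[0] % (2**31))


def inject_missingness(
    cohort: Cohort, rates: Mapping[str, float], seed: int
) -> Cohort:
    """Set fields missing completely at random, per-EPF or per-column.

    Keys of ``rates`` may be EPF names (all backing survey fields of a
    record go missing together) or individual column names.  Other
    columns are untouched; a new cohort is returned.
    """
    df = cohort.df.copy()
    rng = np.random.default_rng(seed)
    for name, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {name!r} must be in [0, 1], got {rate}")
        if name in EPF_RAW_FIELDS:
            cols = [c for c in EPF_RAW_FIELDS[name] if c in df.columns]
            if not cols:
                raise KeyError(f"cohort has no raw fields for EPF {name!r}")
        elif name in df.columns:
            cols = [name]
        else:
            raise KeyError(f"unknown field {name!r}")
        mask = rng.random(len(df)) < rate
        for c in cols:
            col = df[c]
            if col.dtype.kind in "iu":
                col = col.astype(float)
            df[c] = col.mask(mask)
    prov = dict(cohort.provenance)
    prov["missingness"] = {"rates": dict(rates), "seed": seed}
    return Cohort(df=df, provenance=prov, truth=cohort.truth)


def cohort_from_cell_counts(
    cells: CellCounts,
    seed: int,
    epf: str = "maternal_warmth",
    group: str = "EA",
    with_covariates: bool = False,
) -> Cohort:
    """Build a cohort whose G×E×outcome cross-tab equals ``cells`` exactly.

    Within each of the four exposure cells, ``cases`` records get outcome 1
    and the remainder 0; record order is then shuffled by ``seed``.  By
    default the cohort carries only id/group/G/E/outcome (crude analyses);
    ``with_covariates`` adds independent noise covariates (age, gender,
    PCs, pgs) for pipeline smoke tests only — they carry no signal.
    """
    rows_g, rows_e, rows_y = [], [], []
    for (g, e), (cases, total) in cells:
        rows_g += [g] * total
        rows_e += [e] * total
        rows_y += [1] * cases + [0] * (total - cases)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows_g))
    df = pd.DataFrame(
        {
            "id": [f"cc-{i:06d}" for i in range(len(order))],
            "group": group,
            "G": np.asarray(rows_g)[order],
            exposure_column(epf): np.asarray(rows_e)[order],
            "ever_smoked": np.asarray(rows_y)[order],
        }
    )
    if with_covariates:
        n = len(df)
        df["age"] = np.round(rng.normal(70.0, 10.0, n), 1)
        df["gender"] = np.where(rng.random(n) < 0.55, "female", "male")
        for c in PC_COLUMNS:
            df[c] = rng.standard_normal(n)
        df["pgs"] = rng.standard_normal(n)
    return Cohort(
        df=df,
        provenance={
            "mode": "cell_counts",
            "seed": seed,
            "epf": epf,
            "cells": {str(k): v for k, v in cells},
        },
    )
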