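"""Derivation of analysis variables from raw survey fields.

Turns one row per participant of raw responses into the binary variables
the interaction models consume:

* ``Y`` — ever smoking: endorsed the 100-cigarette item at any wave.
* ``G`` — high genetic risk: polygenic score strictly above the
  within-group 75th percentile (linear-interpolation quantile; boundary
  ties fall in the larger, unexposed group).
* five ``E_*`` adverse early-psychosocial exposures, coded 1 = adverse.

All derivations are pure functions of the record, except the two
quantile cuts (polygenic top quartile, maternal-warmth bottom quartile),
which depend on the observed within-group score distribution.
Missingness propagates as ``NaN``; listwise deletion happens per model
via :func:`complete_cases`, which is why analysis Ns differ across EPFs.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    EPFS,
    EPF_RAW_FIELDS,
    FINANCE_LEVELS,
    Cohort,
    exposure_column,
    wave_columns,
)

_YES_NO = {"yes": 1.0, "no": 0.0}


def _yn(value) -> float:
    """Map yes/no (or 0/1) to float, NaN-preserving; reject anything else."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if isinstance(value, str):
        try:
            return _YES_NO[value]
        except KeyError:
            raise ValueError(f"expected 'yes'/'no', got {value!r}") from None
    if value in (0, 1):
        return float(value)
    raise ValueError(f"expected 'yes'/'no', got {value!r}")


def derive_ever_smoking(responses: Iterable) -> float:
    """Lifetime ever-smoking from per-wave yes/no responses.

    Returns 1 if any wave was endorsed, 0 if at least one wave was
    observed and none endorsed, NaN if no wave was observed.
    """
    vals = [_yn(v) for v in responses]
    if any(v == 1.0 for v in vals):
        return 1.0
    if any(v == 0.0 for v in vals):
        return 0.0
    return np.nan


def derive_ever_smoking_frame(df: pd.DataFrame, waves: Sequence[str] | None = None) -> pd.Series:
    """Vectorized any-wave ever-smoking over a cohort frame."""
    waves = list(waves) if waves is not None else wave_columns(df)
    if not waves:
        raise ValueError("no per-wave ever-smoking columns found")
    coded = pd.DataFrame({c: df[c].map(_yn, na_action="ignore") for c in waves})
    any_yes = (coded == 1.0).any(axis=1)
    any_obs = coded.notna().any(axis=1)
    out = pd.Series(np.nan, index=df.index, name="Y")
    out[any_obs] = 0.0
    out[any_yes] = 1.0
    return out


def rescale_warmth_item3(x):
    """Map the 1–5 relationship item onto the 1–4 scale of the other items."""
    return 1.0 + 3.0 * (np.asarray(x, dtype=float) - 1.0) / 4.0


def warmth_score(item1, item2, item3, rescale: bool = True):
    """Maternal-warmth mean score on the 1–4 scale.

    The third item is asked on a 1–5 scale and is linearly rescaled to
    1–4 before averaging so the mean has range 1–4 (set ``rescale=False``
    to average raw items).  Out-of-range items raise.
    """
    i1 = np.asarray(item1, dtype=float)
    i2 = np.asarray(item2, dtype=float)
    i3 = np.asarray(item3, dtype=float)
    for name, arr, hi in (("warmth_item1", i1, 4), ("warmth_item2", i2, 4), ("warmth_item3", i3, 5)):
        bad = ~np.isnan(arr) & ((arr < 1) | (arr > hi))
        if np.any(bad):
            raise ValueError(f"{name} out of range 1..{hi}")
    i3r = rescale_warmth_item3(i3) if rescale else i3
    return (i1 + i2 + i3r) / 3.0


def _group_quantile_flag(
    values: pd.Series,
    groups: pd.Series | None,
    q: float,
    tail: str,
) -> pd.Series:
    """Flag the strict lower/upper tail of a within-group quantile cut.

    ``tail='upper'`` flags values strictly above the q-quantile;
    ``tail='lower'`` flags values strictly below it.  Ties at the cut go
    to the unflagged (larger) side, keeping the flagged fraction at or
    below the nominal tail mass.  NaN values stay NaN.
    """
    out = pd.Series(np.nan, index=values.index, dtype=float)
    frame = pd.DataFrame({"v": values})
    frame["g"] = groups if groups is not None else "_all"
    for _, sub in frame.groupby("g", sort=False):
        obs = sub["v"].dropna()
        if obs.empty:
            continue
        thr = float(np.quantile(obs.to_numpy(), q))
        if tail == "upper":
            flag = sub["v"] > thr
        else:
            flag = sub["v"] < thr
        out.loc[sub.index] = flag.astype(float).where(sub["v"].notna())
    return out


def dichotomize_pgs(
    df: pd.DataFrame,
    cut: float = 0.75,
    by_group: bool = True,
    pgs_col: str = "pgs",
    group_col: str = "group",
) -> pd.Series:
    """High-genetic-risk flag: score strictly above the within-group cut.

    With the default 0.75 cut this marks the top quartile of the observed
    polygenic-score distribution in each ancestry group, matching the
    within-group standardization of the published scores.
    """
    pgs = df[pgs_col]
    n_obs = int(pgs.notna().sum())
    if n_obs == 0:
        raise ValueError("all polygenic scores are missing")
    if n_obs < 4:
        raise ValueError(f"need >= 4 non-missing polygenic scores, have {n_obs}")
    groups = df[group_col] if by_group and group_col in df.columns else None
    return _group_quantile_flag(pgs, groups, cut, "upper").rename("G")


def derive_maternal_warmth(
    df: pd.DataFrame,
    cut: float = 0.25,
    by_group: bool = True,
    rescale: bool = True,
    group_col: str = "group",
) -> tuple[pd.Series, pd.Series]:
    """Warmth score and low-warmth flag (score strictly below the cut).

    Returns ``(score, flag)``; the flag is 1 for records in the bottom
    quartile of the within-group score distribution, with boundary ties
    going to the normal group.
    """
    score = pd.Series(
        warmth_score(df["warmth_item1"], df["warmth_item2"], df["warmth_item3"], rescale=rescale),
        index=df.index,
        name="warmth_score",
    )
    groups = df[group_col] if by_group and group_col in df.columns else None
    flag = _group_quantile_flag(score, groups, cut, "lower")
    return score, flag.rename(exposure_column("maternal_warmth"))


def derive_financial_burden(value) -> float:
    """1 for a 'poor' perceived childhood financial situation, else 0."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if value == "poor":
        return 1.0
    if value in ("pretty_well_off", "about_average"):
        return 0.0
    raise ValueError(
        f"unknown child_finance category {value!r}; expected one of {FINANCE_LEVELS}"
    )


def derive_stress_events(police, parent_substance, abuse) -> tuple[float, float]:
    """Childhood-stress indicator and event count from the three flags.

    Indicator is 1 if any flag is yes, 0 if none observed is yes, and
    missing only when all three flags are missing; the count is the
    number of endorsed flags among those observed.
    """
    vals = [_yn(police), _yn(parent_substance), _yn(abuse)]
    obs = [v for v in vals if not np.isnan(v)]
    if not obs:
        return np.nan, np.nan
    count = float(sum(obs))
    return (1.0 if count > 0 else 0.0), count


def derive_parent_education(value, parent: str = "father") -> float:
    """Adverse low-education flag: 1 iff education was NOT more than 8 years."""
    if parent not in ("father", "mother"):
        raise ValueError(f"parent must be 'father' or 'mother', got {parent!r}")
    v = _yn(value)
    if np.isnan(v):
        return np.nan
    return 1.0 - v


def complete_cases(df: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Listwise deletion on the named variables, preserving record order."""
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise KeyError(f"unknown variables: {missing}")
    return df.loc[df[list(variables)].notna().all(axis=1)]


def harmonize_cohort(
    cohort: Cohort | pd.DataFrame,
    pgs_cut: float = 0.75,
    warmth_cut: float = 0.25,
    by_group: bool = True,
    rescale_warmth: bool = True,
) -> pd.DataFrame:
    """Derive every analysis variable a cohort's raw fields support.

    Returns a frame with id, group, covariates (when present), ``Y``,
    ``G``, ``warmth_score``, ``stress_count`` and the five ``E_*``
    exposures.  For each variable, raw fields are used when present;
    otherwise a pre-derived column of the same name (as produced by the
    exact-count generator) is passed through unchanged.
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    out = pd.DataFrame(index=df.index)
    passthrough = ["id", "group", "age", "gender", "pgs", *("pc%d" % i for i in range(1, 6))]
    for c in passthrough:
        if c in df.columns:
            out[c] = df[c]

    if wave_columns(df):
        out["Y"] = derive_ever_smoking_frame(df)
    elif "ever_smoked" in df.columns:
        out["Y"] = pd.to_numeric(df["ever_smoked"])
    else:
        raise KeyError("cohort has neither per-wave smoking columns nor 'ever_smoked'")

    if "pgs" in df.columns and df["pgs"].notna().any():
        out["G"] = dichotomize_pgs(df, cut=pgs_cut, by_group=by_group)
    elif "G" in df.columns:
        out["G"] = pd.to_numeric(df["G"])

    if all(c in df.columns for c in EPF_RAW_FIELDS["maternal_warmth"]):
        score, flag = derive_maternal_warmth(
            df, cut=warmth_cut, by_group=by_group, rescale=rescale_warmth
        )
        out["warmth_score"] = score
        out[flag.name] = flag
    if "child_finance" in df.columns:
        out[exposure_column("financial_burden")] = df["child_finance"].map(
            derive_financial_burden, na_action="ignore"
        )
    if all(c in df.columns for c in EPF_RAW_FIELDS["childhood_stress"]):
        pairs = [
            derive_stress_events(p, s, a)
            for p, s, a in zip(
                df["stress_police"], df["stress_parent_substance"], df["stress_abuse"]
            )
        ]
        out[exposure_column("childhood_stress")] = [ind for ind, _ in pairs]
        out["stress_count"] = [cnt for _, cnt in pairs]
    if "father_ed_gt8" in df.columns:
        out[exposure_column("father_education")] = df["father_ed_gt8"].map(
            lambda v: derive_parent_education(v, "father"), na_action="ignore"
        )
    if "mother_ed_gt8" in df.columns:
        out[exposure_column("mother_education")] = df["mother_ed_gt8"].map(
            lambda v: derive_parent_education(v, "mother"), na_action="ignore"
        )

    # exact-count cohorts carry pre-derived exposures; pass them through
    for epf in EPFS:
        col = exposure_column(epf)
        if col not in out.columns and col in df.columns:
            out[col] = pd.to_numeric(df[col])
    return out
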