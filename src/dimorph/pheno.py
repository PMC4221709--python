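"""Phenotype preparation and phenotypic sexual dimorphism.

Normality screening with a log2 rescue for strongly non-normal traits,
derived meat-colour traits (hue angle), least-squares sex-effect models
with batch as a fixed effect, and FDR q-values across the trait family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normality_screen_and_transform",
    "hue_angle",
    "sex_effect_model",
    "qvalues",
    "SexEffectResult",
    "sex_effect_table",
]

#: Shapiro-Wilk p below which a trait is considered strongly non-normal
SHAPIRO_P_TRANSFORM = 1e-8

#: Shapiro-Wilk statistic accuracy degrades above this n; screen subsamples
_SHAPIRO_MAX_N = 5000


class TransformationError(ValueError):
    """log2 requested on non-positive values."""


class DegenerateInputError(ValueError):
    pass


class IdentifiabilityError(ValueError):
    """Design matrix rank-deficient (e.g. sex confounded with batch)."""


def normality_screen_and_transform(
    values: np.ndarray, p_threshold: float = SHAPIRO_P_TRANSFORM,
    offset: float = 0.0,
) -> tuple[np.ndarray, bool, float]:
    """Screen a trait for strong non-normality; log2-transform if it fails.

    Returns (values, transformed, shapiro_p).  Missing entries (NaN) are
    passed through untouched.  The transform is applied only when the
    Shapiro-Wilk p-value of the non-missing values falls below
    ``p_threshold``; it then requires all non-missing values (plus the
    optional ``offset``, default 0) to be strictly positive.
    """
    v = np.asarray(values, dtype=float)
    obs = v[~np.isnan(v)]
    if obs.size < 3:
        raise DegenerateInputError("need >= 3 non-missing values")
    if np.ptp(obs) == 0:
        raise DegenerateInputError("constant trait; normality test undefined")
    if obs.size > _SHAPIRO_MAX_N:
        # deterministic thinning keeps the test inside its accuracy range
        step = int(np.ceil(obs.size / _SHAPIRO_MAX_N))
        test_sample = np.sort(obs)[::step]
    else:
        test_sample = obs
    p = float(stats.shapiro(test_sample).pvalue)
    if p >= p_threshold:
        return v, False, p
    shifted = obs + offset
    n_bad = int((shifted <= 0).sum())
    if n_bad:
        raise TransformationError(
            f"log2 transform requires positive values; {n_bad} non-positive"
        )
    out = v.copy()
    out[~np.isnan(v)] = np.log2(shifted)
    return out, True, p


def hue_angle(a_star, b_star):
    """Meat-colour hue angle H* = arctan(b*/a*) in degrees, in (-90, 90).

    a* is Minolta redness, b* yellowness.  Vectorised; a* = 0 is undefined.
    """
    a = np.asarray(a_star, dtype=float)
    b = np.asarray(b_star, dtype=float)
    if np.any(a == 0):
        raise DegenerateInputError("hue angle undefined at a* = 0")
    out = np.degrees(np.arctan(b / a))
    return float(out) if out.ndim == 0 else out


@dataclass
class SexEffectResult:
    trait: str
    estimate: float  # male minus female, trait units
    se: float
    pvalue: float
    fold: float  # male mean / female mean (raw scale)
    n_male: int
    n_female: int
    qvalue: float = np.nan
    degenerate: bool = False


def sex_effect_model(
    values, sex, batch=None, trait_name: str = "trait"
) -> SexEffectResult:
    """Least-squares fit of trait ~ sex + batch; reports the male-female
    contrast with its standard error and two-sided p-value.

    Batch enters as fixed-effect indicators; with fewer than two batch
    levels the term is dropped.  Rows with missing trait, sex or batch are
    excluded.  A zero-variance trait is flagged degenerate (estimate 0,
    p-value NaN) rather than raising.
    """
    import statsmodels.api as sm

    v = np.asarray(values, dtype=float)
    sex = pd.Series(sex).astype(str).to_numpy()
    ok = ~np.isnan(v) & pd.notna(sex)
    if batch is not None:
        batch = pd.Series(batch).to_numpy()
        ok &= pd.notna(batch)
    v, sex = v[ok], sex[ok]
    males = sex == "M"
    if males.all() or not males.any():
        raise IdentifiabilityError("both sexes must be represented")

    n_m, n_f = int(males.sum()), int((~males).sum())
    mean_m, mean_f = float(v[males].mean()), float(v[~males].mean())
    fold = mean_m / mean_f if mean_f != 0 else np.nan

    if np.ptp(v) == 0:
        return SexEffectResult(trait_name, 0.0, np.nan, np.nan, fold, n_m, n_f,
                               degenerate=True)

    X = [np.ones(v.size), males.astype(float)]
    if batch is not None:
        levels = pd.unique(batch[ok])
        if len(levels) >= 2:
            for lev in levels[1:]:
                X.append((batch[ok] == lev).astype(float))
    X = np.column_stack(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise IdentifiabilityError("rank-deficient design (sex confounded?)")
    fit = sm.OLS(v, X).fit()
    return SexEffectResult(
        trait=trait_name,
        estimate=float(fit.params[1]),
        se=float(fit.bse[1]),
        pvalue=float(fit.pvalues[1]),
        fold=fold,
        n_male=n_m,
        n_female=n_f,
    )


def qvalues(p: np.ndarray, pi0: float | str = 1.0) -> np.ndarray:
    """FDR q-values (monotone step-up), input order preserved.

    pi0=1 gives Benjamini-Hochberg adjusted p-values; pi0='storey'
    estimates the null proportion as pi0 = min(1, #{p > 0.5} / (0.5 m)).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0,1]")
    if pi0 == "storey":
        lam = 0.5
        pi0 = min(1.0, float((p > lam).mean()) / (1.0 - lam))
        pi0 = max(pi0, 1.0 / p.size)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def sex_effect_table(
    traits: pd.DataFrame,
    trait_columns: list[str],
    sex_col: str = "sex",
    batch_col: str = "batch",
    screen_normality: bool = True,
) -> pd.DataFrame:
    """Run the sex-effect model for each trait column and attach q-values.

    Returns a table with one row per trait: estimate (male-female), se, p,
    q, fold (on the raw scale), per-sex n, and whether the trait was
    log2-transformed before modelling.
    """
    rows = []
    for name in trait_columns:
        v = traits[name].to_numpy(dtype=float)
        transformed = False
        if screen_normality:
            try:
                v, transformed, _ = normality_screen_and_transform(v)
            except (TransformationError, DegenerateInputError):
                pass  # model the raw values; decision recorded as False
        res = sex_effect_model(
            v, traits[sex_col], traits.get(batch_col), trait_name=name
        )
        # fold is reported on the raw scale even when modelling used log2
        if transformed:
            raw = traits[name].to_numpy(dtype=float)
            sx = traits[sex_col].astype(str).to_numpy()
            okr = ~np.isnan(raw)
            mm = raw[okr & (sx == "M")].mean()
            ff = raw[okr & (sx == "F")].mean()
            res.fold = mm / ff if ff != 0 else np.nan
        rows.append((name, res.estimate, res.se, res.pvalue, res.fold,
                     res.n_male, res.n_female, transformed, res.degenerate))
    out = pd.DataFrame(
        rows,
        columns=["trait", "estimate", "se", "p", "fold",
                 "n_male", "n_female", "log2_transformed", "degenerate"],
    )
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = qvalues(out.loc[ok, "p"].to_numpy())
    return out
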