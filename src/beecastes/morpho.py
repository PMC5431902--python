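"""Colony-structured morphometric statistics for guard/forager comparisons.

Workers are sampled at nest entrances in two behavioral roles (entrance
guards and returning foragers) from several colonies per species. Because
workers from the same colony are not independent, role contrasts are
fitted as Gaussian random-intercept mixed models with colony (optionally
bee nested within colony) as the grouping factor. The module also provides
the size-corrected coefficient of variation, the guard-forager
differentiation index (DI), colony centring, the melanization level,
model-II (reduced major axis) allometry against the cube root of body
weight, and Benjamini-Hochberg adjustment for table-wide testing.
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

#: strict header for individual-level morphometric CSV tables
MORPH_COLUMNS = ["species", "colony", "bee_id", "role", "head_width_mm",
                 "wet_weight_mg", "gray_level", "reference_gray", "cuticle_um"]

ROLES = ("guard", "forager")


def read_morph_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MORPH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"morphometric CSV missing columns: {missing}")
    bad = set(df["role"].unique()) - set(ROLES)
    if bad:
        raise ValueError(f"unknown roles {sorted(bad)}; expected {ROLES}")
    if (df["head_width_mm"] <= 0).any():
        raise ValueError("head_width_mm must be > 0")
    return df


def write_morph_csv(df: pd.DataFrame, path) -> None:
    df.loc[:, MORPH_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scalar statistics
# ---------------------------------------------------------------------------

def cv_corrected(values: Sequence[float]) -> float:
    """Coefficient of variation with the small-sample correction (1 + 1/(4n)).

    Uses the n-1 standard deviation; scale-invariant. Requires n >= 2 and a
    positive mean.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("cv_corrected requires at least 2 values")
    m = x.mean()
    if m <= 0:
        raise ValueError("cv_corrected requires a positive mean")
    return float((1.0 + 1.0 / (4.0 * n)) * x.std(ddof=1) / m)


def melanization_level(g, r):
    """Melanization m = 1 - g/r (g: mean gray of the clypeus, r: white reference).

    Darker cuticle (smaller g) gives larger m; m = 1 is fully dark,
    m = 0 matches the background.
    """
    g = np.asarray(g, dtype=float)
    r = np.asarray(r, dtype=float)
    if (r <= 0).any():
        raise ValueError("reference gray must be > 0")
    out = 1.0 - g / r
    return float(out) if out.ndim == 0 else out


def _trait_values(records: pd.DataFrame, trait: str) -> pd.Series:
    if trait == "head_width":
        return records["head_width_mm"].astype(float)
    if trait == "melanization":
        sub = records.dropna(subset=["gray_level", "reference_gray"])
        return pd.Series(melanization_level(sub["gray_level"], sub["reference_gray"]),
                         index=sub.index)
    raise ValueError(f"unknown trait {trait!r}")


def differentiation_index(records: pd.DataFrame, trait: str = "head_width") -> float:
    """Guard-forager differentiation index (DI) for one species.

    Per colony: |mean(guard) - mean(forager)| divided by the standard
    deviation of the trait over all workers of that colony (both roles
    pooled); the species DI is the mean over colonies. Colonies lacking at
    least 2 individuals of either role are skipped with a warning.
    """
    vals = _trait_values(records, trait)
    df = records.loc[vals.index].assign(_v=vals)
    per_colony = []
    for colony, grp in df.groupby("colony", sort=True):
        g = grp.loc[grp["role"] == "guard", "_v"]
        f = grp.loc[grp["role"] == "forager", "_v"]
        if len(g) < 2 or len(f) < 2:
            warnings.warn(f"colony {colony!r} lacks >=2 of each role; skipped")
            continue
        sd = grp["_v"].std(ddof=1)
        if sd == 0:
            warnings.warn(f"colony {colony!r} has zero trait variance; skipped")
            continue
        per_colony.append(abs(g.mean() - f.mean()) / sd)
    if not per_colony:
        raise ValueError("no colony with >=2 guards and >=2 foragers")
    return float(np.mean(per_colony))


def centre_by_colony(records: pd.DataFrame, column: str = "head_width_mm") -> pd.Series:
    """Centre a trait so each colony mean and the grand mean are 0."""
    x = records[column].astype(float)
    centred = x - x.groupby(records["colony"]).transform("mean")
    return centred - centred.mean()


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LMEFit:
    """Random-intercept model fit for a role contrast.

    ``fixed_effect_estimate`` is guard minus forager in the units of the
    response; ``df`` follows the containment convention
    N - n_groups - 1 and is always reported with the fit.
    """

    fixed_effect_estimate: float
    standard_error: float
    t_value: float
    df: int
    p_value: float
    variance_components: dict
    fallback_ttest: bool = False


def lme_random_intercept(records: pd.DataFrame, response: str = "head_width",
                         grouping: str = "colony",
                         nested: bool = False) -> LMEFit:
    """REML random-intercept fit of ``response ~ role`` with colony grouping.

    ``nested=True`` adds bee nested within colony as a second variance
    component (for repeated measures per bee, e.g. cuticle thickness).
    With a single colony the model is unidentifiable and the function
    falls back to a two-sample t-test, flagged in the result.
    """
    col_map = {"head_width": "head_width_mm", "cuticle": "cuticle_um",
               "melanization": None}
    if response == "melanization":
        y = _trait_values(records, "melanization")
        df = records.loc[y.index].assign(_y=y)
    else:
        col = col_map.get(response, response)
        df = records.dropna(subset=[col]).assign(_y=lambda d: d[col].astype(float))
    if set(df["role"].unique()) != set(ROLES):
        raise ValueError("both guard and forager records are required")
    role = (df["role"] == "guard").astype(float).to_numpy()
    y = df["_y"].to_numpy(dtype=float)
    groups = df[grouping].to_numpy()
    n_groups = len(np.unique(groups))

    if n_groups < 2:
        g, f = y[role == 1], y[role == 0]
        t, p = stats.ttest_ind(g, f, equal_var=True)
        se = (g.mean() - f.mean()) / t if t != 0 else np.nan
        warnings.warn("single colony: falling back to two-sample t-test")
        return LMEFit(float(g.mean() - f.mean()), float(se), float(t),
                      int(len(y) - 2), float(p),
                      {"colony": np.nan, "residual": float(np.var(y, ddof=1))},
                      fallback_ttest=True)

    resid = df.groupby([grouping, "role"])["_y"].transform(lambda v: v - v.mean())
    if np.allclose(resid, 0):
        raise ValueError("zero residual variance: mixed model is degenerate")

    X = np.column_stack([np.ones_like(role), role])
    if nested:
        bee = df["bee_id"].astype(str).to_numpy()
        vcf = {"bee": "0 + C(bee_id)"}
        model = MixedLM.from_formula("_y ~ role_g", data=df.assign(
            role_g=role, bee_id=bee), groups=groups, vc_formula=vcf,
            re_formula="1")
    else:
        model = MixedLM(y, X, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = est = se = None
        for methods in (["lbfgs", "powell"], ["cg"]):
            try:
                fit = model.fit(reml=True, method=methods)
                est = float(fit.fe_params.iloc[-1] if hasattr(fit.fe_params, "iloc")
                            else fit.fe_params[-1])
                se = float(fit.bse_fe.iloc[-1] if hasattr(fit.bse_fe, "iloc")
                           else fit.bse_fe[-1])
                if np.isfinite(se) and se > 0:
                    break
            except np.linalg.LinAlgError:
                fit = None
    if fit is None or not (np.isfinite(se) and se > 0):
        # REML failed numerically (typically a boundary fit); degrade to a
        # flagged two-sample t-test rather than abort a table-wide run
        g, f = y[role == 1], y[role == 0]
        t, p = stats.ttest_ind(g, f, equal_var=True)
        warnings.warn("mixed model numerically singular: two-sample t-test "
                      "fallback")
        return LMEFit(float(g.mean() - f.mean()),
                      float((g.mean() - f.mean()) / t) if t != 0 else np.nan,
                      float(t), int(len(y) - 2), float(p),
                      {"colony": np.nan, "residual": float(np.var(y, ddof=1))},
                      fallback_ttest=True)
    tval = est / se
    dof = int(len(y) - n_groups - 1)
    p = float(2 * stats.t.sf(abs(tval), dof))
    vc = {"colony": float(np.asarray(fit.cov_re)[0, 0]),
          "residual": float(fit.scale)}
    if nested and fit.vcomp.size:
        vc["bee"] = float(fit.vcomp[0])
    return LMEFit(est, se, tval, dof, p, vc)


# ---------------------------------------------------------------------------
# Allometry (model II / reduced major axis)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RMAFit:
    """Reduced-major-axis fit of log10 head width on log10 cube-root weight.

    ``slope`` is signed by the correlation; the t statistic tests the
    isometry null H0: b = 1 on n - 2 degrees of freedom.
    """

    slope: float
    intercept: float
    r: float
    n: int
    t_value: float
    p_value: float


def rma_allometry(head_width_mm: Sequence[float],
                  wet_weight_mg: Sequence[float]) -> RMAFit:
    """Model-II allometry of head width against the cube root of wet weight.

    x = log10(weight^(1/3)), y = log10(head width); slope
    b = sign(r) * sd_y / sd_x with SE(b) = |b| * sqrt((1-r^2)/(n-2)).
    b = 1 is isometry; b < 1 with p <= alpha is negative allometry (larger
    workers have relatively smaller heads).
    """
    hw = np.asarray(head_width_mm, dtype=float)
    w = np.asarray(wet_weight_mg, dtype=float)
    mask = ~(np.isnan(hw) | np.isnan(w))
    hw, w = hw[mask], w[mask]
    if len(hw) < 3:
        raise ValueError("rma_allometry requires n >= 3 paired values")
    if (hw <= 0).any() or (w <= 0).any():
        raise ValueError("measurements must be positive for log transformation")
    x = np.log10(w) / 3.0
    y = np.log10(hw)
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    b = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    n = len(x)
    se = abs(b) * np.sqrt(max(1.0 - r * r, 0.0) / (n - 2))
    if se > 0:
        t = (b - 1.0) / se
    else:  # perfect correlation: t is 0 at exact isometry, +-inf otherwise
        t = 0.0 if abs(b - 1.0) <= 1e-10 else math.copysign(math.inf, b - 1.0)
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return RMAFit(slope=float(b), intercept=float(y.mean() - b * x.mean()),
                  r=r, n=n, t_value=float(t), p_value=p)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
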