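"""Mixed-effects models for the perilesional spatial-gradient analysis.

Three model families, one per scientific question, each fit separately for
every white matter metric (FA, MD, MWF, GMT2) as outcome:

1. distance x group — does the metric change with distance from the WMH
   (quadratic contrast over the six levels WMH, 2, 4, 6, 8, 10 mm) and does
   the gradient differ between older adults and stroke survivors?
2. distance x hemisphere — within unilateral-stroke subjects, does the
   gradient differ between the ipsilesional and contralesional hemisphere?
3. WMH volume — do metrics inside the WMH track whole-brain lesion burden
   (log-transformed volume)?

All models carry age and MoCA as standardized covariates, a scanner random
intercept, and (for the repeated-measures families) a participant random
intercept nested within scanner.  Estimation is REML via statsmodels
MixedLM; reported p-values are Wald tests on the fixed effects.  Post hoc
pairwise contrasts use the Tukey studentized-range (HSD) adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import studentized_range

from .rois import DISTANCE_LEVELS

__all__ = [
    "FitResult",
    "ContrastResult",
    "ALPHA",
    "standardize_predictors",
    "log_wmh_volume",
    "quadratic_contrast",
    "fit_distance_group",
    "fit_distance_hemisphere",
    "fit_wmh_volume_model",
    "tukey_posthoc",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05

#: continuous predictors standardized within group before modelling
CONTINUOUS_PREDICTORS = ("age", "moca", "log_wmh_volume")


@dataclass
class FitResult:
    """Fixed-effect estimates of one mixed model."""

    outcome: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    converged: bool
    vc: dict = field(default_factory=dict)
    model_result: object = None  # underlying statsmodels result (unit-variance outcome)
    headline_term: str = ""
    y_scale: float = 1.0  # factor mapping the internal outcome scale to physical units

    def term(self, name: str) -> tuple[float, float, float]:
        """(estimate, SE, p) for one fixed-effect term."""
        return float(self.params[name]), float(self.bse[name]), float(self.pvalues[name])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "p": self.pvalues}
        ).rename_axis("term")


@dataclass
class ContrastResult:
    label: str
    estimate: float
    se: float
    p_raw: float
    p_adjusted: float
    family_size: int


def log_wmh_volume(v_ml) -> np.ndarray:
    """Natural log of WMH volume (mL).  Zero-lesion subjects must be
    excluded upstream, mirroring the study's exclusion rule."""
    v = np.asarray(v_ml, dtype=float)
    if np.any(v <= 0):
        raise ValueError("WMH volume must be positive (zero-WMH subjects excluded)")
    return np.log(v)


def standardize_predictors(
    table: pd.DataFrame, by_group: bool = True, predictors=CONTINUOUS_PREDICTORS
) -> pd.DataFrame:
    """Group-mean-center and scale continuous predictors to unit SD.

    Adds ``<name>_z`` columns.  Raises when a predictor is constant within a
    group (zero variance), naming the predictor.
    """
    out = table.copy()
    if "log_wmh_volume" not in out.columns and "wmh_volume_ml" in out.columns:
        out["log_wmh_volume"] = log_wmh_volume(out["wmh_volume_ml"])
    keys = ["group"] if (by_group and "group" in out.columns) else [lambda _: 0]
    for name in predictors:
        if name not in out.columns:
            continue
        grouped = out.groupby(keys[0] if not callable(keys[0]) else np.zeros(len(out)))[name]
        sd = grouped.transform("std")
        if (sd == 0).any() or sd.isna().any():
            raise ValueError(f"zero variance within a group for predictor {name!r}")
        out[f"{name}_z"] = (out[name] - grouped.transform("mean")) / sd
    return out


def quadratic_contrast(levels=DISTANCE_LEVELS) -> pd.DataFrame:
    """Orthogonal polynomial contrast codes (linear, quadratic) for ordered levels.

    Codes are Gram-Schmidt orthogonalized powers of equally spaced scores,
    zero-sum and unit-normalized — the standard ``contr.poly`` coding.
    """
    k = len(levels)
    x = np.arange(1, k + 1, dtype=float)
    raw = np.vander(x, 3, increasing=True)  # 1, x, x^2
    q, _ = np.linalg.qr(raw)
    lin, quad = q[:, 1], q[:, 2]
    lin = lin if lin[-1] > 0 else -lin  # increasing convention
    quad = quad if quad[0] > 0 else -quad  # U-shape positive at the ends
    return pd.DataFrame({"dist_lin": lin, "dist_quad": quad}, index=list(levels))


def _attach_distance_codes(df: pd.DataFrame) -> pd.DataFrame:
    codes = quadratic_contrast()
    missing = set(DISTANCE_LEVELS) - set(df["distance_level"].astype(str))
    if missing:
        raise ValueError(f"missing distance levels: {sorted(missing)}")
    out = df.copy()
    out["distance_level"] = out["distance_level"].astype(str)
    out = out.join(codes, on="distance_level")
    return out


def _fit_mixedlm(formula: str, data: pd.DataFrame, groups: str, vc_formula=None,
                 outcome: str = "", headline: str = "") -> FitResult:
    # fit on a unit-variance outcome for numerical health (MD is ~1e-3 in
    # physical units); estimates and SEs are rescaled afterwards, p-values
    # are scale-invariant
    data = data.copy()
    y_sd = float(data["value"].std()) or 1.0
    data["value"] = data["value"] / y_sd
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula, data=data, groups=data[groups], re_formula="1", vc_formula=vc_formula
        )
        for method in (["lbfgs"], ["powell"], ["cg"]):
            try:
                result = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if getattr(result, "converged", False):
                break
    if result is None:
        # degenerate designs (e.g. very few subjects) can defeat every
        # optimizer; fall back to OLS on the fixed effects, flagged as
        # non-converged so it is never silently reported as a mixed fit
        logger.warning("mixed model failed for all optimizers; OLS fallback: %s", formula)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols(formula, data=data).fit()
        return FitResult(
            outcome=outcome,
            params=ols.params * y_sd,
            bse=ols.bse * y_sd,
            pvalues=ols.pvalues,
            converged=False,
            vc={},
            model_result=None,
            headline_term=headline,
            y_scale=y_sd,
        )
    converged = bool(getattr(result, "converged", True))
    if not converged:
        logger.warning("mixed model did not converge: %s", formula)
    fe = result.fe_params.index
    return FitResult(
        outcome=outcome,
        params=result.params[fe] * y_sd,
        bse=result.bse[fe] * y_sd,
        pvalues=result.pvalues[fe],
        converged=converged,
        vc={"scanner_var": float(result.cov_re.iloc[0, 0]) * y_sd**2,
            "resid_var": float(result.scale) * y_sd**2,
            **({"subject_var": float(result.vcomp[0]) * y_sd**2} if len(result.vcomp) else {})},
        model_result=result,
        headline_term=headline,
        y_scale=y_sd,
    )


def _metric_table(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    df = table[table["metric"] == outcome].copy()
    if df.empty:
        raise ValueError(f"no rows for metric {outcome!r}")
    return df


def fit_distance_group(table: pd.DataFrame, outcome: str) -> FitResult:
    """Distance(quadratic contrast) x group mixed model for one metric.

    Fixed: age_z + moca_z + distance (linear+quadratic orthogonal codes) +
    group + distance x group.  Random: scanner intercept, participant
    intercept nested within scanner.  The stroke group is the reference
    category; the headline "Distance" term is the quadratic column.
    """
    df = _metric_table(table, outcome)
    for g in ("older_adult", "stroke"):
        if (df["group"] == g).sum() < 2 * len(DISTANCE_LEVELS):
            raise ValueError(f"need >= 2 subjects in group {g!r}")
    df = standardize_predictors(df, by_group=True, predictors=("age", "moca"))
    df = _attach_distance_codes(df)
    df["group_oa"] = (df["group"] == "older_adult").astype(float)  # stroke = reference
    formula = (
        "value ~ age_z + moca_z + dist_lin + dist_quad + group_oa"
        " + dist_lin:group_oa + dist_quad:group_oa"
    )
    return _fit_mixedlm(
        formula, df, groups="scanner",
        vc_formula={"subject": "0 + C(subject_id)"},
        outcome=outcome, headline="dist_quad",
    )


def fit_distance_hemisphere(table: pd.DataFrame, outcome: str) -> FitResult:
    """Distance x hemisphere model within unilateral-stroke subjects.

    The input table must carry a ``hemisphere`` column with levels
    ipsilesional/contralesional (one row per subject x hemisphere x level);
    ipsilesional is the reference category.
    """
    df = _metric_table(table, outcome)
    if "hemisphere" not in df.columns:
        raise ValueError("hemisphere column required (split ring sets first)")
    bad = set(df["hemisphere"]) - {"ipsilesional", "contralesional"}
    if bad:
        raise ValueError(f"unexpected hemisphere levels: {sorted(bad)}")
    df = standardize_predictors(df, by_group=False, predictors=("age", "moca"))
    df = _attach_distance_codes(df)
    df["hemi_contra"] = (df["hemisphere"] == "contralesional").astype(float)
    formula = (
        "value ~ age_z + moca_z + dist_lin + dist_quad + hemi_contra"
        " + dist_lin:hemi_contra + dist_quad:hemi_contra"
    )
    return _fit_mixedlm(
        formula, df, groups="scanner",
        vc_formula={"subject": "0 + C(subject_id)"},
        outcome=outcome, headline="dist_quad",
    )


def fit_wmh_volume_model(table: pd.DataFrame, outcome: str) -> FitResult:
    """Lesion-burden model: WMH-ROI metric ~ age + moca + log WMH volume.

    One row per subject (WMH distance level only); random scanner intercept
    only, as there are no repeated measures.
    """
    df = _metric_table(table, outcome)
    df = df[df["distance_level"].astype(str) == "WMH"].copy()
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject rows in the WMH-ROI table")
    df = standardize_predictors(
        df, by_group=True, predictors=("age", "moca", "log_wmh_volume")
    )
    formula = "value ~ age_z + moca_z + log_wmh_volume_z"
    return _fit_mixedlm(
        formula, df, groups="scanner", vc_formula=None,
        outcome=outcome, headline="log_wmh_volume_z",
    )


# ---------------------------------------------------------------------------
# post hoc contrasts


def _cell_l_matrix(result, level: str, group_value: float | None, design_info) -> np.ndarray:
    """Row vector picking the model cell mean for a distance level (and group)."""
    codes = quadratic_contrast()
    names = list(result.fe_params.index)
    l_vec = np.zeros(len(names))

    def set_term(name, value):
        if name in names:
            l_vec[names.index(name)] = value

    set_term("Intercept", 1.0)
    set_term("dist_lin", codes.loc[level, "dist_lin"])
    set_term("dist_quad", codes.loc[level, "dist_quad"])
    factor = design_info  # 'group_oa' or 'hemi_contra'
    g = 0.5 if group_value is None else group_value
    set_term(factor, g)
    set_term(f"dist_lin:{factor}", codes.loc[level, "dist_lin"] * g)
    set_term(f"dist_quad:{factor}", codes.loc[level, "dist_quad"] * g)
    return l_vec


def tukey_posthoc(
    fit: FitResult, family: str = "distance", factor_name: str = "group_oa",
    factor_labels: tuple[str, str] = ("stroke", "older_adult"),
) -> list[ContrastResult]:
    """Tukey-adjusted pairwise contrasts from a distance-model fit.

    ``family='distance'``: the 15 pairwise contrasts between the six
    distance-level means (factor averaged out) — the follow-up to a distance
    main effect.  ``family='interaction'``: contrasts between distance
    levels within each factor level plus between factor levels within each
    distance level (36 contrasts over the 12 cell means) — the follow-up to
    a distance x factor interaction.  Adjusted p-values use the studentized
    range over the family's cell means with residual degrees of freedom.
    """
    result = fit.model_result
    fe = result.fe_params
    cov = np.asarray(result.cov_params())[: len(fe), : len(fe)]
    df_resid = max(int(result.nobs - len(fe)), 2)

    if family == "distance":
        cells = [(lev, None) for lev in DISTANCE_LEVELS]
        pairs = [
            (cells[i], cells[j])
            for i in range(len(cells))
            for j in range(i + 1, len(cells))
        ]
    elif family == "interaction":
        cells = [(lev, g) for g in (0.0, 1.0) for lev in DISTANCE_LEVELS]
        pairs = []
        for g in (0.0, 1.0):
            for i in range(len(DISTANCE_LEVELS)):
                for j in range(i + 1, len(DISTANCE_LEVELS)):
                    pairs.append(((DISTANCE_LEVELS[i], g), (DISTANCE_LEVELS[j], g)))
        for lev in DISTANCE_LEVELS:
            pairs.append(((lev, 0.0), (lev, 1.0)))
    else:
        raise ValueError(f"unknown family {family!r}")

    k = len(cells)
    out = []
    from scipy.stats import t as t_dist

    for (lev_a, g_a), (lev_b, g_b) in pairs:
        l_a = _cell_l_matrix(result, lev_a, g_a, factor_name)
        l_b = _cell_l_matrix(result, lev_b, g_b, factor_name)
        delta = l_a - l_b
        est = float(delta @ np.asarray(fe))
        se = float(np.sqrt(delta @ cov @ delta))
        if se == 0:
            continue
        t_stat = est / se
        p_raw = 2 * float(t_dist.sf(abs(t_stat), df_resid))
        q = abs(t_stat) * np.sqrt(2.0)
        p_adj = float(studentized_range.sf(q, k, df_resid))
        p_adj = min(max(p_adj, p_raw), 1.0)

        def cell_label(lev, g):
            if g is None:
                return lev
            return f"{lev}@{factor_labels[int(g)]}"

        out.append(
            ContrastResult(
                label=f"{cell_label(lev_a, g_a)} - {cell_label(lev_b, g_b)}",
                estimate=est * fit.y_scale,
                se=se * fit.y_scale,
                p_raw=p_raw,
                p_adjusted=p_adj,
                family_size=k,
            )
        )
    return out
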