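"""Group comparisons of callosal measures with EMM-based effect sizes.

The inferential layer runs, per comparison, a two-factor between-subjects
ANOVA (factors: handedness group, sex), optionally with the power-converted
forebrain volume as covariate (ANCOVA).  Sums of squares are Type III under
sum-to-zero factor coding.  Group and sex effect sizes are Cohen's *d*
computed from estimated marginal means (model predictions averaged with
equal weight over the levels of the other factor, at the covariate mean)
standardized by the model residual standard deviation; the 95% CI uses a
normal approximation on the standardized EMM difference.  The sign
convention makes *d* negative when the right-handed group (cRH/dRH) — or,
for the sex effect, the male group — has the larger mean.  The interaction
effect is summarised as eta-squared (its Type III SS over the corrected
total SS).

Four canonical comparisons are supported: A (Witelson cRH vs MH), B (Habib
cRH vs MH), C (dRH vs dLH), D (Witelson cRH vs cLH), plus the cRH-vs-NcRH
variant.  Segment-wise analyses fit the same model at each of the 100
thickness segments and control the false discovery rate across segments at
5% with the Benjamini-Hochberg step-up procedure; segments significant
before correction are flagged separately.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from statsmodels.stats.multitest import multipletests

__all__ = [
    "COMPARISON_SCHEMES",
    "ComparisonDesign",
    "ComparisonResult",
    "ContinuousLQResult",
    "SegmentMap",
    "TermResult",
    "ZeroVarianceError",
    "build_comparison",
    "benjamini_hochberg",
    "continuous_lq_analysis",
    "fit_anova",
    "report",
    "segmentwise_analysis",
    "threshold_sweep",
]

logger = logging.getLogger("callothick")


class ZeroVarianceError(ValueError):
    """Raised when a fit is impossible for lack of variance."""


#: scheme -> (label column, {kept levels}, right-handed level)
COMPARISON_SCHEMES: dict[str, tuple[str, frozenset, str]] = {
    "A": ("witelson", frozenset({"cRH", "MH"}), "cRH"),
    "B": ("habib", frozenset({"cRH", "MH"}), "cRH"),
    "C": ("direction", frozenset({"dRH", "dLH"}), "dRH"),
    "D": ("witelson", frozenset({"cRH", "cLH"}), "cRH"),
    "NcRH": ("witelson", frozenset({"cRH", "NcRH"}), "cRH"),
}


@dataclass
class TermResult:
    """F-test summary for one model term."""

    F: float
    df_num: float
    df_den: float
    p: float


@dataclass
class ComparisonResult:
    """One fitted two-factor (AN)(C)OVA.

    ``emm`` maps group level -> (estimated marginal mean, s.e.); ``d`` is
    negative when the right-handed group's EMM is larger.  ``sex_d`` is the
    (female - male) standardized EMM difference.
    """

    group: TermResult
    sex: TermResult
    interaction: TermResult
    emm: dict
    sex_emm: dict
    d: float
    d_ci95: tuple[float, float]
    sex_d: float
    sex_d_ci95: tuple[float, float]
    eta2_interaction: float
    sigma_resid: float
    nobs: int
    rh_level: str
    other_level: str
    dependent: str = ""
    covariate: str | None = None
    zero_variance: bool = False


@dataclass
class ComparisonDesign:
    """A two-level analysis table plus exclusion accounting."""

    table: pd.DataFrame
    scheme: str
    rh_level: str
    other_level: str
    excluded: dict = field(default_factory=dict)


@dataclass
class SegmentMap:
    """Segment-wise comparison results over a thickness profile."""

    F: np.ndarray
    p: np.ndarray
    df_den: float
    d: np.ndarray
    d_lo: np.ndarray
    d_hi: np.ndarray
    eta2_interaction: np.ndarray
    sex_d: np.ndarray
    sex_p: np.ndarray
    p_fdr: np.ndarray
    fdr_significant: np.ndarray
    uncorrected_significant: np.ndarray
    sex_fdr_significant: np.ndarray
    alpha: float
    fdr_q: float

    def __post_init__(self) -> None:
        if np.any(self.fdr_significant & ~self.uncorrected_significant):
            raise RuntimeError(
                "BH-significant segment with raw p above alpha: FDR flags "
                "must imply uncorrected flags"
            )

    @property
    def n_segments(self) -> int:
        return len(self.p)

    @property
    def min_d(self) -> tuple[float, int]:
        """Most negative d and its 1-based segment index."""
        i = int(np.argmin(self.d))
        return float(self.d[i]), i + 1

    @property
    def max_d(self) -> tuple[float, int]:
        i = int(np.argmax(self.d))
        return float(self.d[i]), i + 1


@dataclass
class ContinuousLQResult:
    """Per-segment linear association of |LQ| with thickness."""

    slope: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    fdr_significant: np.ndarray
    uncorrected_significant: np.ndarray
    alpha: float
    fdr_q: float


# ---------------------------------------------------------------------------
# comparison construction
# ---------------------------------------------------------------------------


def build_comparison(
    table: pd.DataFrame, scheme: str, min_cell: int = 2
) -> ComparisonDesign:
    """Filter a labelled cohort table down to one two-level comparison.

    Rows with labels outside the comparison (e.g. cLH rows for comparison A)
    are dropped and counted in the exclusion record.  For the cRH-vs-NcRH
    variant, MH and cLH are merged into NcRH.  Raises if any group-by-sex
    cell has fewer than ``min_cell`` members (the interaction would be
    unidentifiable).
    """
    if scheme not in COMPARISON_SCHEMES:
        raise ValueError(f"unknown comparison scheme {scheme!r}")
    label_col, levels, rh_level = COMPARISON_SCHEMES[scheme]
    out = table.copy()
    if scheme == "NcRH":
        out["group"] = np.where(out[label_col] == "cRH", "cRH", "NcRH")
    else:
        out["group"] = out[label_col]
    keep = out["group"].isin(levels)
    excluded = (
        out.loc[~keep, label_col].value_counts().to_dict() if (~keep).any() else {}
    )
    out = out.loc[keep].reset_index(drop=True)
    (other_level,) = levels - {rh_level}
    cells = out.groupby(["group", "sex"], observed=True).size()
    for g in (rh_level, other_level):
        for s in ("female", "male"):
            if cells.get((g, s), 0) < min_cell:
                raise ValueError(
                    f"comparison {scheme}: cell ({g}, {s}) has fewer than "
                    f"{min_cell} members; model unidentifiable"
                )
    if excluded:
        logger.info("comparison %s: excluded %s", scheme, excluded)
    return ComparisonDesign(
        table=out,
        scheme=scheme,
        rh_level=rh_level,
        other_level=other_level,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# single-dependent fit (statsmodels route)
# ---------------------------------------------------------------------------


def _zero_variance_result(design, dependent, covariate, nobs) -> ComparisonResult:
    flat = TermResult(F=0.0, df_num=1.0, df_den=float(nobs - 4), p=1.0)
    return ComparisonResult(
        group=flat,
        sex=TermResult(**vars(flat)),
        interaction=TermResult(**vars(flat)),
        emm={design.rh_level: (0.0, 0.0), design.other_level: (0.0, 0.0)},
        sex_emm={"female": (0.0, 0.0), "male": (0.0, 0.0)},
        d=0.0,
        d_ci95=(0.0, 0.0),
        sex_d=0.0,
        sex_d_ci95=(0.0, 0.0),
        eta2_interaction=0.0,
        sigma_resid=0.0,
        nobs=nobs,
        rh_level=design.rh_level,
        other_level=design.other_level,
        dependent=dependent,
        covariate=covariate,
        zero_variance=True,
    )


def fit_anova(
    design: ComparisonDesign,
    dependent: str,
    covariate: str | None = None,
) -> ComparisonResult:
    """Fit ``dependent ~ group * sex (+ covariate)`` with Type III SS.

    The covariate is mean-centred before fitting; EMMs are therefore model
    predictions at the covariate mean, averaged with equal weights over sex.
    A constant dependent yields a flagged zero-variance result (F = 0,
    p = 1) rather than an error.
    """
    df = design.table
    y = df[dependent].to_numpy(float)
    if np.ptp(y) == 0:
        return _zero_variance_result(design, dependent, covariate, len(df))
    work = pd.DataFrame(
        {
            "_y": y,
            "_g": pd.Categorical(df["group"], categories=[design.rh_level, design.other_level]),
            "_s": pd.Categorical(df["sex"], categories=["female", "male"]),
        }
    )
    formula = "_y ~ C(_g, Sum) * C(_s, Sum)"
    if covariate is not None:
        cov = df[covariate].to_numpy(float)
        work["_c"] = cov - cov.mean()
        formula += " + _c"
    fit = smf.ols(formula, data=work).fit()
    if np.any(np.isnan(fit.params)):
        aliased = [n for n, v in fit.params.items() if np.isnan(v)]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    if fit.mse_resid <= 0:
        raise ZeroVarianceError("zero residual variance: effects are not testable")
    anova = sm.stats.anova_lm(fit, typ=3)

    def term(name: str) -> TermResult:
        row = anova.loc[name]
        return TermResult(
            F=float(row["F"]),
            df_num=float(row["df"]),
            df_den=float(fit.df_resid),
            p=float(row["PR(>F)"]),
        )

    g_term = term("C(_g, Sum)")
    s_term = term("C(_s, Sum)")
    i_term = term("C(_g, Sum):C(_s, Sum)")
    ss_total = float(np.sum((y - y.mean()) ** 2))
    eta2 = float(anova.loc["C(_g, Sum):C(_s, Sum)", "sum_sq"]) / ss_total

    # EMMs: predictions over the 2x2 factor grid at the covariate mean
    grid = pd.DataFrame(
        {
            "_g": pd.Categorical(
                [design.rh_level, design.rh_level, design.other_level, design.other_level],
                categories=[design.rh_level, design.other_level],
            ),
            "_s": pd.Categorical(
                ["female", "male", "female", "male"], categories=["female", "male"]
            ),
        }
    )
    if covariate is not None:
        grid["_c"] = 0.0
    (X_grid,) = build_design_matrices(
        [fit.model.data.design_info], grid, return_type="matrix"
    )
    X_grid = np.asarray(X_grid)
    params = fit.params.to_numpy()
    cov_params = fit.cov_params().to_numpy()

    def emm_from(L: np.ndarray) -> tuple[float, float]:
        return float(L @ params), float(np.sqrt(L @ cov_params @ L))

    L_rh = X_grid[:2].mean(axis=0)
    L_other = X_grid[2:].mean(axis=0)
    L_f = X_grid[[0, 2]].mean(axis=0)
    L_m = X_grid[[1, 3]].mean(axis=0)
    emm = {design.rh_level: emm_from(L_rh), design.other_level: emm_from(L_other)}
    sex_emm = {"female": emm_from(L_f), "male": emm_from(L_m)}
    sigma = float(np.sqrt(fit.mse_resid))

    def std_diff(L1, L2) -> tuple[float, tuple[float, float]]:
        L = L1 - L2
        diff, se = emm_from(L)
        d = diff / sigma
        half = 1.959963984540054 * se / sigma
        return d, (d - half, d + half)

    d, d_ci = std_diff(L_other, L_rh)
    sex_d, sex_ci = std_diff(L_f, L_m)
    return ComparisonResult(
        group=g_term,
        sex=s_term,
        interaction=i_term,
        emm=emm,
        sex_emm=sex_emm,
        d=d,
        d_ci95=d_ci,
        sex_d=sex_d,
        sex_d_ci95=sex_ci,
        eta2_interaction=eta2,
        sigma_resid=sigma,
        nobs=int(fit.nobs),
        rh_level=design.rh_level,
        other_level=design.other_level,
        dependent=dependent,
        covariate=covariate,
    )


# ---------------------------------------------------------------------------
# vectorized batch fits (shared design, many dependents)
# ---------------------------------------------------------------------------


def _batch_model(
    g_pm: np.ndarray, s_pm: np.ndarray, Y: np.ndarray, cov: np.ndarray | None
) -> dict:
    """Fit y ~ 1 + g + s + g:s (+ cov) for every column of Y at once.

    Factors are +/-1 coded (g = +1 for the right-handed group, s = +1 for
    female), which makes the partial F from dropping one column the Type III
    F, and makes EMM contrasts plain multiples of single coefficients:
    EMM(RH) - EMM(other) = 2 b_g, EMM(female) - EMM(male) = 2 b_s.
    """
    n = len(g_pm)
    cols = [np.ones(n), g_pm, s_pm, g_pm * s_pm]
    if cov is not None:
        cols.append(cov - cov.mean())
    X = np.column_stack(cols)
    k = X.shape[1]
    df_resid = n - k
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    ssr_full = np.einsum("ij,ij->j", resid, resid)

    def ssr_without(col: int) -> np.ndarray:
        Xr = np.delete(X, col, axis=1)
        br = np.linalg.solve(Xr.T @ Xr, Xr.T @ Y)
        r = Y - Xr @ br
        return np.einsum("ij,ij->j", r, r)

    mse = ssr_full / df_resid
    out = {"beta": beta, "mse": mse, "df_resid": df_resid, "XtX_inv": XtX_inv}
    for name, col in (("g", 1), ("s", 2), ("gs", 3)):
        ss_term = ssr_without(col) - ssr_full
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(mse > 0, ss_term / mse, 0.0)
        out[f"ss_{name}"] = ss_term
        out[f"F_{name}"] = F
        out[f"p_{name}"] = np.where(mse > 0, sps.f.sf(F, 1, df_resid), 1.0)
    out["ss_total"] = np.einsum("ij,ij->j", Y - Y.mean(axis=0), Y - Y.mean(axis=0))
    return out


def _pm_codes(design: ComparisonDesign) -> tuple[np.ndarray, np.ndarray]:
    df = design.table
    g_pm = np.where(df["group"].to_numpy() == design.rh_level, 1.0, -1.0)
    s_pm = np.where(df["sex"].to_numpy() == "female", 1.0, -1.0)
    return g_pm, s_pm


def benjamini_hochberg(p: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up FDR adjustment; returns (reject, adjusted p)."""
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def segmentwise_analysis(
    design: ComparisonDesign,
    profile_cols: Sequence[str],
    covariate: str | None = None,
    alpha: float = 0.05,
    fdr_q: float = 0.05,
) -> SegmentMap:
    """Fit the comparison model at every profile segment and adjust the
    group-effect p-values across segments with BH at ``fdr_q``.

    The multiple-testing family is the segment set of this one analysis
    (one comparison, one dependent-variable variant); families are never
    pooled across analyses.
    """
    df = design.table
    Y = df[list(profile_cols)].to_numpy(float)
    if np.any(~np.isfinite(Y)):
        bad = int(np.nonzero(~np.isfinite(Y).all(axis=0))[0][0])
        raise ValueError(f"non-finite values in segment column {profile_cols[bad]}")
    g_pm, s_pm = _pm_codes(design)
    cov = df[covariate].to_numpy(float) if covariate else None
    m = _batch_model(g_pm, s_pm, Y, cov)
    sigma = np.sqrt(m["mse"])
    if np.any(sigma == 0):
        idx = int(np.nonzero(sigma == 0)[0][0])
        raise ZeroVarianceError(
            f"segment {profile_cols[idx]} has zero residual variance"
        )
    # EMM(other) - EMM(RH) = -2 b_g ; se = 2 se(b_g)
    d = -2.0 * m["beta"][1] / sigma
    se_diff = 2.0 * np.sqrt(m["mse"] * m["XtX_inv"][1, 1])
    half = 1.959963984540054 * se_diff / sigma
    sex_d = 2.0 * m["beta"][2] / sigma
    reject, p_adj = benjamini_hochberg(m["p_g"], fdr_q)
    sex_reject, _ = benjamini_hochberg(m["p_s"], fdr_q)
    return SegmentMap(
        F=m["F_g"],
        p=m["p_g"],
        df_den=float(m["df_resid"]),
        d=d,
        d_lo=d - half,
        d_hi=d + half,
        eta2_interaction=m["ss_gs"] / m["ss_total"],
        sex_d=sex_d,
        sex_p=m["p_s"],
        p_fdr=p_adj,
        fdr_significant=reject,
        uncorrected_significant=m["p_g"] <= alpha,
        sex_fdr_significant=sex_reject,
        alpha=alpha,
        fdr_q=fdr_q,
    )


def continuous_lq_analysis(
    table: pd.DataFrame,
    profile_cols: Sequence[str],
    alpha: float = 0.05,
    fdr_q: float = 0.05,
    abs_lq_col: str = "abs_lq",
) -> ContinuousLQResult:
    """Per-segment linear model ``thickness ~ |LQ| + sex``.

    A negative slope means thicker segments with less consistent hand
    preference.  P-values are BH-adjusted across segments.
    """
    x = table[abs_lq_col].to_numpy(float)
    if np.ptp(x) == 0:
        raise ZeroVarianceError("abs_lq has zero variance")
    s_pm = np.where(table["sex"].to_numpy() == "female", 1.0, -1.0)
    Y = table[list(profile_cols)].to_numpy(float)
    X = np.column_stack([np.ones(len(x)), x - x.mean(), s_pm])
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df_resid = len(x) - X.shape[1]
    mse = np.einsum("ij,ij->j", resid, resid) / df_resid
    se = np.sqrt(mse * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    p = 2 * sps.t.sf(np.abs(t), df_resid)
    reject, p_adj = benjamini_hochberg(p, fdr_q)
    return ContinuousLQResult(
        slope=beta[1],
        se=se,
        t=t,
        p=p,
        p_fdr=p_adj,
        fdr_significant=reject,
        uncorrected_significant=p <= alpha,
        alpha=alpha,
        fdr_q=fdr_q,
    )


def threshold_sweep(
    table: pd.DataFrame,
    thresholds: Sequence[float],
    dependent: str,
    covariate: str | None = None,
    abs_lq_col: str = "abs_lq",
    min_cell: int = 2,
) -> dict[float, ComparisonResult]:
    """Re-run the consistency comparison over a grid of |LQ| cut-offs.

    At each threshold T in [10, 100] the cohort splits into "consistent"
    (|LQ| >= T, taking the right-handed role in the sign convention) versus
    "nonconsistent".  Thresholds that empty a group-by-sex cell are skipped
    with a warning.
    """
    results: dict[float, ComparisonResult] = {}
    for T in thresholds:
        if not 10.0 <= T <= 100.0:
            raise ValueError(f"threshold {T} outside [10, 100]")
        work = table.copy()
        work["group"] = np.where(
            work[abs_lq_col].to_numpy(float) >= T, "consistent", "nonconsistent"
        )
        cells = work.groupby(["group", "sex"], observed=True).size()
        ok = all(
            cells.get((g, s), 0) >= min_cell
            for g in ("consistent", "nonconsistent")
            for s in ("female", "male")
        )
        if not ok:
            logger.warning("threshold sweep: T=%s skipped (empty/small cell)", T)
            continue
        design = ComparisonDesign(
            table=work,
            scheme=f"T{T:g}",
            rh_level="consistent",
            other_level="nonconsistent",
        )
        results[float(T)] = fit_anova(design, dependent, covariate)
    return results


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def _result_row(tag: Mapping, res: ComparisonResult) -> dict:
    emm_rh = res.emm[res.rh_level]
    emm_other = res.emm[res.other_level]
    return {
        **tag,
        "n": res.nobs,
        "rh_level": res.rh_level,
        "other_level": res.other_level,
        "emm_rh": emm_rh[0],
        "se_rh": emm_rh[1],
        "emm_other": emm_other[0],
        "se_other": emm_other[1],
        "F": res.group.F,
        "df_num": res.group.df_num,
        "df_den": res.group.df_den,
        "p": res.group.p,
        "d": res.d,
        "d_ci_lo": res.d_ci95[0],
        "d_ci_hi": res.d_ci95[1],
        "interaction_p": res.interaction.p,
        "eta2_interaction": res.eta2_interaction,
        "sex_F": res.sex.F,
        "sex_p": res.sex.p,
        "sex_d": res.sex_d,
        "sex_d_ci_lo": res.sex_d_ci95[0],
        "sex_d_ci_hi": res.sex_d_ci95[1],
        "zero_variance": res.zero_variance,
    }


def segment_map_frame(segmap: SegmentMap) -> pd.DataFrame:
    """Tabulate a segment map (one row per segment, 1-based index)."""
    n = segmap.n_segments
    return pd.DataFrame(
        {
            "segment": np.arange(1, n + 1),
            "F": segmap.F,
            "p": segmap.p,
            "p_fdr": segmap.p_fdr,
            "d": segmap.d,
            "d_ci_lo": segmap.d_lo,
            "d_ci_hi": segmap.d_hi,
            "eta2_interaction": segmap.eta2_interaction,
            "sex_d": segmap.sex_d,
            "sex_p": segmap.sex_p,
            "fdr_significant": segmap.fdr_significant,
            "uncorrected_significant": segmap.uncorrected_significant,
            "sex_fdr_significant": segmap.sex_fdr_significant,
        }
    )


def report(
    area_results: Sequence[tuple[dict, ComparisonResult]],
    segment_maps: Sequence[tuple[dict, SegmentMap]] = (),
    out_dir: str | Path | None = None,
    float_format: str = "%.10g",
) -> dict:
    """Assemble (and optionally write) the result tables.

    ``area_results``/``segment_maps`` pair a tag dict (e.g. ``{"comparison":
    "A", "variant": "absolute"}``) with a fitted result.  Writes
    ``area_results.csv``, one ``segments_<tags>.csv`` per map and a summary
    JSON; returns the in-memory frames.
    """
    area_rows = [_result_row(tag, res) for tag, res in area_results]
    if area_rows:
        columns = list(area_rows[0].keys())
    else:  # header-only output for an empty result list
        columns = list(
            _result_row(
                {"comparison": None, "variant": None},
                _zero_variance_result(
                    ComparisonDesign(pd.DataFrame(), "A", "cRH", "MH"), "", None, 4
                ),
            ).keys()
        )
    area_frame = pd.DataFrame(area_rows, columns=columns)
    maps = {}
    summaries = []
    for tag, segmap in segment_maps:
        key = "_".join(str(v) for v in tag.values())
        maps[key] = segment_map_frame(segmap)
        min_d, min_seg = segmap.min_d
        max_d, max_seg = segmap.max_d
        summaries.append(
            {
                **tag,
                "min_d": min_d,
                "min_d_segment": min_seg,
                "max_d": max_d,
                "max_d_segment": max_seg,
                "n_fdr_significant": int(segmap.fdr_significant.sum()),
                "n_uncorrected_significant": int(
                    segmap.uncorrected_significant.sum()
                ),
            }
        )
    bundle = {"area": area_frame, "segments": maps, "segment_summaries": summaries}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        area_frame.to_csv(out / "area_results.csv", index=False, float_format=float_format)
        for key, frame in maps.items():
            frame.to_csv(out / f"segments_{key}.csv", index=False, float_format=float_format)
        with open(out / "segment_summaries.json", "w") as fh:
            json.dump(summaries, fh, indent=2, default=float)
    return bundle


def plot_segment_map(segmap: SegmentMap, path: str | Path, title: str = "") -> None:
    """Colour-coded segment map of the group effect (orange: larger in the
    non-right-handed group, blue: larger in the right-handed group), with
    FDR and uncorrected significance marks."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    seg = np.arange(1, segmap.n_segments + 1)
    fig, ax = plt.subplots(figsize=(9, 3))
    colors = np.where(segmap.d >= 0, "tab:orange", "tab:blue")
    ax.bar(seg, segmap.d, color=colors, width=1.0)
    ax.plot(seg[segmap.uncorrected_significant],
            segmap.d[segmap.uncorrected_significant], "k.", ms=4,
            label="p < alpha (uncorrected)")
    if segmap.fdr_significant.any():
        ax.plot(seg[segmap.fdr_significant], segmap.d[segmap.fdr_significant],
                "ks", ms=4, label="FDR significant")
    for val, pos in (segmap.min_d, segmap.max_d):
        ax.annotate(f"d={val:.2f}", (pos, val), fontsize=8)
    ax.set_xlabel("segment (anterior -> posterior)")
    ax.set_ylabel("Cohen's d")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
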