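"""Moderated differential expression for pseudo-bulk and bulk counts.

The model is the voom + limma approach: counts are transformed to
log2 counts-per-million with a 0.5 pseudo-count, a LOWESS curve of
sqrt(residual SD) against mean log-count supplies per-observation
precision weights (predicted SD to the power −4), gene-wise weighted
least squares estimates the contrast, and residual variances are shrunk
toward a common prior by empirical Bayes: the prior degrees of freedom d0
and prior variance s0² are obtained by moment-matching the scaled-F
distribution of the sample variances on the log scale (digamma/trigamma
relations), giving posterior variances

    s~²_g = (d0·s0² + d·s²_g) / (d0 + d)

and moderated t statistics with d0 + d degrees of freedom. Benjamini–
Hochberg adjusted p-values and the strict DEG rule (q < 0.01 and
|log2FC| > 1.5) complete the calling step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .pseudobulk import PseudoBulkMatrix, estimate_size_factors

__all__ = [
    "filter_low_expression",
    "two_group_design",
    "voom_weights",
    "VoomFit",
    "fit_moderated",
    "bh_fdr",
    "call_degs",
    "DEResult",
    "ModeratedDEModel",
    "per_celltype_de",
]


def _frame(B) -> pd.DataFrame:
    return B.counts if isinstance(B, PseudoBulkMatrix) else B


def filter_low_expression(B, min_umi: int = 10, min_columns: int = 3) -> pd.DataFrame:
    """Keep genes with at least ``min_umi`` UMIs in at least ``min_columns``
    of the analyzed columns (both comparisons inclusive)."""
    frame = _frame(B)
    if frame.empty:
        raise ValueError("empty count matrix")
    qualifying = (frame >= min_umi).sum(axis=1)
    keep = qualifying >= min_columns
    if not keep.any():
        raise ValueError("no gene passes the low-expression filter")
    return frame.loc[keep]


def two_group_design(groups: pd.Series, reference: str, treatment: str) -> pd.DataFrame:
    """Intercept + indicator design; the indicator coefficient is the
    log2 fold-change of ``treatment`` over ``reference``."""
    groups = groups.astype(str)
    used = groups[groups.isin([reference, treatment])]
    if used.nunique() != 2:
        raise ValueError(f"need columns from both {reference!r} and {treatment!r}")
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            f"{treatment}_vs_{reference}": (used == treatment).astype(float),
        },
        index=used.index,
    )
    return design


@dataclass
class VoomFit:
    """Log-CPM values, precision weights and the fitted mean-variance trend."""

    log_cpm: pd.DataFrame  # genes x columns
    weights: pd.DataFrame  # genes x columns, positive
    eff_lib: pd.Series
    trend_x: np.ndarray  # mean log2-count grid of the LOWESS curve
    trend_y: np.ndarray  # sqrt residual SD on that grid


def _effective_library_size(frame: pd.DataFrame, size_factors: pd.Series | None) -> pd.Series:
    lib = frame.sum(axis=0).astype(float)
    if size_factors is None:
        return lib
    if not frame.columns.equals(size_factors.index):
        raise ValueError("size factors do not match the count columns")
    s = size_factors.to_numpy(dtype=float)
    # scale factors so the geometric-mean library size is preserved
    geo_lib = np.exp(np.log(lib.to_numpy()).mean())
    geo_s = np.exp(np.log(s).mean())
    return pd.Series(s / geo_s * geo_lib, index=frame.columns)


def _ols(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Gene-wise OLS: coefficients, fitted values, residual df."""
    pinv = np.linalg.pinv(X)
    coef = Y @ pinv.T
    fitted = coef @ X.T
    return coef, fitted, X.shape[0] - np.linalg.matrix_rank(X)


def voom_weights(
    B,
    size_factors: pd.Series | None = None,
    design: pd.DataFrame | None = None,
    span: float = 0.5,
) -> VoomFit:
    """Estimate per-observation precision weights from the mean-variance trend.

    log_cpm = log2((count + 0.5) / (eff_lib + 1) * 1e6); gene-wise linear
    models give residual SDs; LOWESS (span 0.5) of sqrt(SD) on mean
    log2-count is evaluated at each observation's fitted log2-count and
    raised to −4. Effective library sizes incorporate the size factors,
    rescaled to preserve the geometric-mean column total.
    """
    frame = _frame(B)
    n = frame.shape[1]
    if design is None:
        design = pd.DataFrame({"intercept": np.ones(n)}, index=frame.columns)
    X = design.to_numpy(dtype=float)
    df_resid = n - np.linalg.matrix_rank(X)
    if df_resid < 1:
        raise ValueError("design leaves no residual degrees of freedom")

    eff_lib = _effective_library_size(frame, size_factors)
    lib = eff_lib.to_numpy()
    counts = frame.to_numpy(dtype=float)
    y = np.log2((counts + 0.5) / (lib + 1.0) * 1e6)

    coef, fitted, _ = _ols(y, X)
    resid = y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)

    amean = y.mean(axis=1)
    sx = amean + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    delta = 0.01 * (sx.max() - sx.min())
    curve = sm_lowess(sy, sx, frac=span, it=3, delta=delta, return_sorted=True)
    trend_x, trend_y = curve[:, 0], curve[:, 1]

    fitted_count = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred_sqrt_sd = np.interp(fitted_count, trend_x, trend_y)  # clamps at range ends
    pred_sqrt_sd = np.maximum(pred_sqrt_sd, 1e-4)  # keep weights finite and positive
    w = pred_sqrt_sd**-4.0

    return VoomFit(
        log_cpm=pd.DataFrame(y, index=frame.index, columns=frame.columns),
        weights=pd.DataFrame(w, index=frame.index, columns=frame.columns),
        eff_lib=eff_lib,
        trend_x=trend_x,
        trend_y=trend_y,
    )


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < tol * y:
            break
    return float(y)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes variance moderation (moment matching on log s²).

    Returns (d0, s0², posterior variances). d0 = inf when the observed
    variances show no excess spread beyond the chi-square sampling noise.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 0.0, s2.copy()
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread: variances are consistent with one common value,
        # best estimated by their arithmetic mean
        d0 = np.inf
        s0_sq = float(s2[ok].mean())
    if np.isfinite(d0):
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        post = np.full_like(s2, s0_sq)
    return float(d0), s0_sq, post


@dataclass
class DEResult:
    """Per-gene differential-expression estimates and the moderation state."""

    table: pd.DataFrame  # gene index; log2fc, t, p, q, deg
    d0: float
    s0_sq: float
    df_residual: float
    contrast_name: str = "contrast"
    fdr_threshold: float | None = None
    lfc_threshold: float | None = None

    @property
    def df_total(self) -> float:
        return min(self.df_residual + self.d0, len(self.table) * self.df_residual)

    @property
    def n_degs(self) -> int:
        if "deg" not in self.table:
            raise ValueError("call_degs has not been applied")
        return int(self.table["deg"].sum())

    def summary(self, top: int = 10) -> str:
        t = self.table
        lines = [
            f"Moderated DE: {self.contrast_name}",
            f"  genes tested:      {len(t)}",
            f"  residual df:       {self.df_residual:g}",
            f"  prior df d0:       {self.d0:.4g}",
            f"  prior variance s0²: {self.s0_sq:.4g}",
        ]
        if "deg" in t:
            lines.append(
                f"  DEGs (q < {self.fdr_threshold:g}, |log2FC| > {self.lfc_threshold:g}): {self.n_degs}"
            )
        show = t.sort_values("p", kind="stable").head(top)
        lines.append(show.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def fit_moderated(
    fit: VoomFit,
    design: pd.DataFrame,
    contrast=None,
    d0_override: float | None = None,
) -> DEResult:
    """Gene-wise weighted least squares with empirical-Bayes moderation.

    ``contrast`` is a coefficient combination (default: the last design
    column). ``d0_override=0`` disables moderation, reproducing the
    ordinary weighted-least-squares t-test.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    if contrast is None:
        contrast = np.eye(p)[-1]
    c = np.asarray(contrast, dtype=float)

    Y = fit.log_cpm.to_numpy()
    W = fit.weights.to_numpy()

    # batched WLS: per gene solve (X' W X) beta = X' W y
    XtWX = np.einsum("gj,ji,jk->gik", W, X, X)
    XtWy = np.einsum("gj,ji->gi", W * Y, X)
    beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
    fitted = beta @ X.T
    s2 = (W * (Y - fitted) ** 2).sum(axis=1) / df_resid
    cov_unscaled = np.linalg.inv(XtWX)
    se_unscaled = np.sqrt(np.einsum("i,gik,k->g", c, cov_unscaled, c))
    coef = beta @ c

    if d0_override is not None and d0_override == 0:
        d0, s0_sq, post = 0.0, float("nan"), s2.copy()
    else:
        d0, s0_sq, post = _squeeze_var(s2, df_resid)
        if d0_override is not None:
            d0 = d0_override
            post = (
                (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
                if np.isfinite(d0)
                else np.full_like(s2, s0_sq)
            )

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coef / (se_unscaled * np.sqrt(post))
    # total df is capped at the pooled residual df over all genes
    df_total = min(df_resid + d0, len(s2) * df_resid)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    pvals = np.where(np.isnan(tstat), 1.0, pvals)

    table = pd.DataFrame(
        {
            "log2fc": coef,
            "t": tstat,
            "p": pvals,
            "s2": s2,
            "s2_post": post,
        },
        index=fit.log_cpm.index,
    )
    name = design.columns[-1] if contrast is None else "@".join(map(str, np.round(c, 3)))
    return DEResult(
        table=table,
        d0=d0,
        s0_sq=s0_sq,
        df_residual=float(df_resid),
        contrast_name=str(design.columns[-1]) if (c == np.eye(p)[-1]).all() else name,
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    q_(i) = min_{k >= i} p_(k) * m / k, capped at 1; stable in the original
    order, so tied p-values receive identical q.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_degs(res: DEResult, fdr: float = 0.01, lfc: float = 1.5) -> DEResult:
    """Attach BH q-values and the strict DEG flag:
    q < fdr AND |log2FC| > lfc (boundary genes are not DEGs)."""
    t = res.table
    q = bh_fdr(t["p"].to_numpy())
    t = t.assign(q=q, deg=(q < fdr) & (np.abs(t["log2fc"]) > lfc))
    return DEResult(
        table=t,
        d0=res.d0,
        s0_sq=res.s0_sq,
        df_residual=res.df_residual,
        contrast_name=res.contrast_name,
        fdr_threshold=fdr,
        lfc_threshold=lfc,
    )


class ModeratedDEModel:
    """A two-group moderated DE model over a count matrix.

    Parameters
    ----------
    counts : genes x columns integer counts (pseudo-bulk or bulk).
    groups : group label per column.
    reference, treatment : the two groups compared; log2FC is
        treatment over reference.
    size_factors : optional; estimated by median-of-ratios when omitted.
    """

    def __init__(self, counts, groups: pd.Series, reference: str, treatment: str,
                 size_factors: pd.Series | None = None,
                 min_umi: int = 10, min_columns: int = 3):
        frame = _frame(counts)
        groups = pd.Series(groups).reindex(frame.columns)
        used = groups.isin([reference, treatment])
        self.counts = frame.loc[:, used.to_numpy()]
        self.groups = groups[used]
        self.reference = reference
        self.treatment = treatment
        self.design = two_group_design(self.groups, reference, treatment)
        self.filtered = filter_low_expression(self.counts, min_umi, min_columns)
        if size_factors is None:
            size_factors = estimate_size_factors(self.filtered)
        else:
            size_factors = size_factors.reindex(self.counts.columns)
        self.size_factors = size_factors

    def fit(self, fdr: float = 0.01, lfc: float = 1.5, d0_override: float | None = None) -> DEResult:
        vfit = voom_weights(self.filtered, self.size_factors, self.design)
        res = fit_moderated(vfit, self.design, d0_override=d0_override)
        res.contrast_name = f"{self.treatment} vs {self.reference}"
        return call_degs(res, fdr=fdr, lfc=lfc)


def per_celltype_de(
    pb: PseudoBulkMatrix,
    reference: str,
    treatment: str,
    fdr: float = 0.01,
    lfc: float = 1.5,
    min_umi: int = 10,
    min_columns: int = 3,
    min_replicates: int = 2,
) -> tuple[dict, pd.DataFrame]:
    """Run the two-group moderated DE model within each cell type.

    Returns (cell_type -> DEResult, DEG-count summary table). Cell types
    lacking ``min_replicates`` pseudo-bulks per group are skipped and appear
    in the summary with a missing count.
    """
    results: dict = {}
    rows = []
    for ct in sorted(set(pb.counts.columns.get_level_values("cell_type"))):
        sub = pb.for_cell_type(ct)
        flat = sub.counts.copy()
        flat.columns = [f"{s}|{t}" for s, t, g in sub.counts.columns]
        groups = pd.Series(
            sub.counts.columns.get_level_values("group"), index=flat.columns
        )
        n_ref = int((groups == reference).sum())
        n_trt = int((groups == treatment).sum())
        if n_ref < min_replicates or n_trt < min_replicates:
            rows.append({"cell_type": ct, "n_ref": n_ref, "n_trt": n_trt, "n_degs": np.nan})
            continue
        try:
            model = ModeratedDEModel(
                flat, groups, reference, treatment, min_umi=min_umi, min_columns=min_columns
            )
        except ValueError:
            rows.append({"cell_type": ct, "n_ref": n_ref, "n_trt": n_trt, "n_degs": np.nan})
            continue
        res = model.fit(fdr=fdr, lfc=lfc)
        results[ct] = res
        rows.append({"cell_type": ct, "n_ref": n_ref, "n_trt": n_trt, "n_degs": res.n_degs})
    summary = pd.DataFrame(rows, columns=["cell_type", "n_ref", "n_trt", "n_degs"])
    return results, summary
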