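"""Plate-aware mixed-model statistics for compound screens.

Per-subject feature values from a multi-plate screen are modelled as

    y_irpj = mu + beta_r + gamma_p + alpha_i + e_irpj

with a fixed row-location effect beta_r shared across plates, a
plate/day random effect gamma_p ~ N(0, sigma_gamma^2), a compound random
effect alpha_i ~ N(0, sigma_alpha^2) and residuals e ~ N(0, sigma_e^2).
Variance components are estimated by REML; compound effects are returned
as best linear unbiased predictions (BLUPs) with conditional SDs from the
mixed-model equations.  Each compound is compared with the DMSO negative
control through

    z_i = (alpha_i - alpha_DMSO) / sqrt(sigma_i^2 + sigma_DMSO^2)

which under the null is treated as standard normal; two-sided p-values are
Benjamini-Hochberg adjusted within each feature (one family per feature,
and per time point for the cardiomyocyte assay).  Adjusted p-values below
.05 are significant, except ventricular beat rate which uses the stricter
calibrated cutoff .0013; arrhythmic-beat and cardiac-arrest calls
additionally require a positive z-score, because only increases in those
features are pathological.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.stats.multitest import multipletests

from cardioscreen.formats import ONE_SIDED_FEATURES

#: Adjusted-p significance cutoff per feature (default 0.05).
DEFAULT_CUTOFF = 0.05
VENTRICULAR_BPM_CUTOFF = 0.0013

DMSO = "DMSO"


class DegenerateDesignError(ValueError):
    """Design cannot identify the model (e.g. a single plate or row)."""


@dataclass
class LmmFit:
    """REML fit of the screen mixed model for one feature."""

    feature: str
    mu: float
    beta_row: dict[str, float]
    sigma_plate: float
    sigma_compound: float
    sigma_error: float
    alpha: dict[str, float]
    alpha_sd: dict[str, float]
    converged: bool
    #: covariance of the level estimates (order = sorted compounds); the
    #: DMSO contrast SE uses it, since compounds share plate uncertainty
    alpha_cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        if DMSO not in self.alpha:
            raise DegenerateDesignError("fit lacks the DMSO reference group")


def _design(data: pd.DataFrame):
    rows = sorted(data["row"].unique())
    plates = sorted(data["plate"].unique())
    compounds = sorted(data["compound"].unique())
    n = len(data)
    X = np.ones((n, len(rows)))
    row_idx = data["row"].map({r: i for i, r in enumerate(rows)}).to_numpy()
    X = np.zeros((n, len(rows)))
    X[:, 0] = 1.0
    for i in range(1, len(rows)):
        X[row_idx == i, i] = 1.0
    Zp = np.zeros((n, len(plates)))
    Zp[np.arange(n), data["plate"].map(
        {p: i for i, p in enumerate(plates)}).to_numpy()] = 1.0
    Zc = np.zeros((n, len(compounds)))
    Zc[np.arange(n), data["compound"].map(
        {c: i for i, c in enumerate(compounds)}).to_numpy()] = 1.0
    return X, Zp, Zc, rows, plates, compounds


def _neg2_reml(theta, y, X, GammaP, GammaC):
    vg, va, ve = np.exp(theta)
    n = len(y)
    V = ve * np.eye(n) + vg * GammaP + va * GammaC
    try:
        L = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        return 1e12
    logdet_v = 2.0 * np.log(np.diag(L[0])).sum()
    ViX = linalg.cho_solve(L, X)
    Viy = linalg.cho_solve(L, y)
    XtViX = X.T @ ViX
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    ypy = float(y @ Viy - (X.T @ Viy) @ beta)
    return logdet_v + logdet_x + ypy


def fit_lmm(data: pd.DataFrame, feature: str | None = None) -> LmmFit:
    """REML-fit the screen mixed model for one feature.

    Parameters
    ----------
    data
        Long table with columns compound, plate, row, subject, value (and
        optionally feature, filtered by the ``feature`` argument).

    Raises
    ------
    DegenerateDesignError
        With fewer than 2 plates, fewer than 2 compounds, a missing DMSO
        group, or fewer than 3 subjects for some compound.
    """
    df = data
    if feature is not None and "feature" in df.columns:
        df = df[df["feature"] == feature]
    feature = feature or (
        df["feature"].iloc[0] if "feature" in df.columns else "value"
    )
    if df["plate"].nunique() < 2:
        raise DegenerateDesignError("need at least 2 plates")
    if df["compound"].nunique() < 2 or DMSO not in set(df["compound"]):
        raise DegenerateDesignError("need >= 2 compounds including DMSO")
    counts = df.groupby("compound").size()
    if (counts < 3).any():
        low = counts[counts < 3].index.tolist()
        raise DegenerateDesignError(f"fewer than 3 subjects for {low}")

    y = df["value"].to_numpy(dtype=float)
    X, Zp, Zc, rows, plates, compounds = _design(df)
    GammaP, GammaC = Zp @ Zp.T, Zc @ Zc.T

    v_tot = max(y.var(ddof=1), 1e-12)
    ve0 = df.groupby(["compound", "plate"])["value"].var(ddof=1).mean()
    if not np.isfinite(ve0) or ve0 <= 0:  # single observation per cell
        ve0 = 0.5 * v_tot
    start = np.log([max(v_tot - ve0, 0.1 * ve0),
                    max(v_tot - ve0, 0.1 * ve0), ve0])
    lb = np.log(v_tot) - 25.0
    ub = np.log(v_tot) + 6.0
    res = optimize.minimize(
        _neg2_reml, start, args=(y, X, GammaP, GammaC),
        method="L-BFGS-B", bounds=[(lb, ub)] * 3,
    )
    vg, va, ve = np.exp(res.x)

    # Per-compound levels by GLS with compound as a fixed level and the
    # plate effect random (V = vg ZpZp' + ve I).  This yields estimates
    # alpha_i with standard errors sigma_i whose standardised DMSO
    # contrast is null-calibrated standard normal, which the shrunk BLUPs
    # are not; sigma_alpha above still reports the between-compound
    # variance component of the generative model.
    n = len(y)
    nr, nc = X.shape[1], Zc.shape[1]
    Xf = np.hstack([Zc, X[:, 1:]])  # compound levels + non-reference rows
    V = ve * np.eye(n) + vg * GammaP
    L = linalg.cho_factor(V, lower=True)
    ViX = linalg.cho_solve(L, Xf)
    A = Xf.T @ ViX
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError(
            "row and compound effects are confounded in this layout"
        ) from exc
    coef = cov @ (ViX.T @ y)
    levels = coef[:nc]
    level_sd = np.sqrt(np.maximum(np.diag(cov)[:nc], 0.0))
    mu_hat = float(levels.mean())
    beta_rows = {rows[0]: 0.0}
    beta_rows.update({r: float(b) for r, b in zip(rows[1:], coef[nc:nc + nr - 1])})
    return LmmFit(
        feature=feature,
        mu=mu_hat,
        beta_row=beta_rows,
        sigma_plate=float(np.sqrt(vg)),
        sigma_compound=float(np.sqrt(va)),
        sigma_error=float(np.sqrt(ve)),
        alpha={c: float(v - mu_hat) for c, v in zip(compounds, levels)},
        alpha_sd={c: float(s) for c, s in zip(compounds, level_sd)},
        converged=bool(res.success),
        alpha_cov=cov[:nc, :nc],
    )


def zscore_vs_dmso(fit: LmmFit) -> dict[str, float]:
    """Per-compound z of the DMSO contrast, standard normal under the null.

    z_i = (alpha_i - alpha_DMSO) / SE(alpha_i - alpha_DMSO).  The SE is
    sqrt(s_i^2 + s_DMSO^2 - 2 cov_i,DMSO): when the level estimates are
    independent this reduces to the familiar sqrt(s_i^2 + s_DMSO^2), but
    compounds estimated on shared plates have strongly covarying levels and
    dropping the covariance term would misstate the contrast uncertainty.
    DMSO's own z is exactly 0.
    """
    names = sorted(fit.alpha)
    i0 = names.index(DMSO)
    a0 = fit.alpha[DMSO]
    out: dict[str, float] = {}
    for i, c in enumerate(names):
        if c == DMSO:
            out[c] = 0.0
            continue
        var = fit.alpha_sd[c] ** 2 + fit.alpha_sd[DMSO] ** 2
        if fit.alpha_cov is not None:
            var -= 2.0 * fit.alpha_cov[i, i0]
        denom = np.sqrt(var) if var > 0 else 0.0
        out[c] = float((fit.alpha[c] - a0) / denom) if denom > 0 else float("nan")
    return out


def pvalues_from_z(z: dict[str, float]) -> dict[str, float]:
    """Two-sided normal p-values, p = 2 Phi(-|z|)."""
    return {c: float(2 * stats.norm.sf(abs(v))) for c, v in z.items()}


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(list(pvalues), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def feature_cutoff(feature: str) -> float:
    """Significance cutoff: .0013 for ventricular beat rate, else .05."""
    return VENTRICULAR_BPM_CUTOFF if feature == "ventricular_bpm" else DEFAULT_CUTOFF


def classify_numeric_feature(
    z: float, adj_p: float, feature: str, cutoff: float | None = None
) -> bool:
    """Significance call for one compound on one numeric feature.

    Positive iff the adjusted p-value is below the feature's cutoff and,
    for the one-sided features (arrhythmic beats, cardiac arrest), the
    z-score is positive.
    """
    cut = feature_cutoff(feature) if cutoff is None else cutoff
    call = bool(adj_p < cut)
    if feature in ONE_SIDED_FEATURES:
        call = call and z > 0
    return call


def feature_calls(data: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Fit + z + FDR + call for one feature; one row per non-DMSO compound."""
    fit = fit_lmm(data, feature)
    z = zscore_vs_dmso(fit)
    comps = [c for c in z if c != DMSO]
    pvals = pvalues_from_z({c: z[c] for c in comps})
    adj = adjust_fdr([pvals[c] for c in comps])
    return pd.DataFrame({
        "compound": comps,
        "feature": feature,
        "z": [z[c] for c in comps],
        "p": [pvals[c] for c in comps],
        "adj_p": adj,
        "call": [
            classify_numeric_feature(z[c], a, feature)
            for c, a in zip(comps, adj)
        ],
    })


def screen_calls(data: pd.DataFrame) -> pd.DataFrame:
    """Per-feature significance calls for every feature in a long table."""
    out = [feature_calls(data, f) for f in sorted(data["feature"].unique())]
    return pd.concat(out, ignore_index=True)


def zscore_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot call rows into a compounds x features z-score matrix."""
    return calls.pivot(index="compound", columns="feature", values="z")


def order_compounds(zmatrix: pd.DataFrame) -> list[str]:
    """Compounds by descending sum of |z| (masked cells count 0); ties
    broken alphabetically."""
    score = zmatrix.abs().fillna(0.0).sum(axis=1)
    key = pd.DataFrame({"score": -score, "name": zmatrix.index})
    return key.sort_values(["score", "name"], kind="stable")["name"].tolist()


def hipsc_pipeline(data: pd.DataFrame) -> pd.DataFrame:
    """Cardiomyocyte assay: average triplicates, then model per feature x
    time point.

    Expects a long table with columns compound, plate, row, replicate,
    feature, timepoint, value.  Replicates are averaged within compound x
    plate x feature x time point (missing replicates are averaged over
    what is present); each feature x time point is then fit with the
    mixed model and called at the .05 adjusted-p cutoff.
    """
    required = {"compound", "plate", "row", "replicate", "feature",
                "timepoint", "value"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    avg = (
        data.groupby(
            ["compound", "plate", "row", "feature", "timepoint"],
            as_index=False,
        )["value"].mean()
    )
    avg["subject"] = avg["plate"].astype(str)
    out = []
    for (feat, tp), grp in avg.groupby(["feature", "timepoint"]):
        fit = fit_lmm(grp.assign(feature=feat), feat)
        z = zscore_vs_dmso(fit)
        comps = [c for c in z if c != DMSO]
        pvals = pvalues_from_z({c: z[c] for c in comps})
        adj = adjust_fdr([pvals[c] for c in comps])
        out.append(pd.DataFrame({
            "compound": comps,
            "feature": feat,
            "timepoint": tp,
            "z": [z[c] for c in comps],
            "adj_p": adj,
            "call": [a < DEFAULT_CUTOFF for a in adj],
        }))
    return pd.concat(out, ignore_index=True)
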