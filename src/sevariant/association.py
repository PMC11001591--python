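"""Case-control association under four genetic models, FDR, and heterogeneity.

Per variant, case/control status is regressed on a genotype coding —
additive (0/1/2 dosage), dominant (carrier), recessive (hom-alt), or
codominant (het and hom-alt indicators vs hom-ref) — optionally adjusted for
age, BMI, smoking (two dummies: ever, current, vs never) and family history.
Effects are reported as odds ratios with Wald 95% CIs and two-sided Wald
p-values; multiple testing is handled by Benjamini-Hochberg step-up with a
configurable test count m.  Stratified analyses summarise between-stratum
heterogeneity with Cochran's Q and I-squared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .variant_qc import MISSING, GenotypeMatrix

MODELS = ("additive", "dominant", "recessive", "codominant")
Z95 = 1.959963984540054  # Phi^{-1}(0.975)
DEFAULT_COVARIATES = ("age", "bmi", "smoking", "family_history")


def code_genotype(calls: np.ndarray, model: str) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Genotype predictor column(s) for a model, plus names and the used-sample mask.

    Missing calls are masked out (the sample is dropped for that variant).
    Codominant returns two indicator columns (het, hom-alt) vs hom-ref.
    """
    calls = np.asarray(calls)
    mask = calls != MISSING
    g = calls[mask].astype(float)
    if model == "additive":
        X = g[:, None]
        names = ["dosage"]
    elif model == "dominant":
        X = (g >= 1).astype(float)[:, None]
        names = ["carrier"]
    elif model == "recessive":
        X = (g == 2).astype(float)[:, None]
        names = ["hom_alt"]
    elif model == "codominant":
        X = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
        names = ["het", "hom_alt"]
    else:
        raise ValueError(f"unknown genetic model {model!r}; choose from {MODELS}")
    return X, names, mask


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    names: list[str]


def fit_logistic(y: np.ndarray, X: np.ndarray, names: list[str] | None = None) -> LogisticFit:
    """Logistic regression by IRLS/Newton with an observed-information SE.

    Converges on |Delta loglik| < 1e-10 (max 50 iterations).  Quasi-complete
    separation is flagged (converged=False) when any |beta| exceeds 15.  The
    design must include the intercept column explicitly.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    const = X.std(axis=0) == 0
    if const.sum() > 1 or (const.any() and not np.any(X[0, const] != 0)):
        bad = [names[j] for j in np.where(const)[0]]
        raise ValueError(f"constant non-intercept columns in design: {bad}")
    if np.linalg.matrix_rank(X) < k:
        # name the offending columns via rank-revealing QR
        from scipy.linalg import qr

        _, r, piv = qr(X, pivoting=True, mode="economic")
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[j]] for j in range(k) if diag[j] <= tol]
        raise ValueError(f"singular design; collinear columns: {bad}")

    beta = np.zeros(k)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, 51):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        eta_new = X @ beta
        ll = float(np.sum(y * eta_new) - np.sum(np.logaddexp(0.0, eta_new)))
        if abs(ll - ll_old) < 1e-10:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    if np.any(np.abs(beta) > 15):
        converged = False  # separation
    mu = expit(X @ beta)
    info = (X * (mu * (1 - mu))[:, None]).T @ X
    try:
        se = np.sqrt(np.diag(np.linalg.inv(info)))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return LogisticFit(beta=beta, se=se, loglik=ll_old, converged=converged, n_iter=it, names=names)


def or_from_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Closed-form odds ratio and SE of log-OR for a 2x2 table.

    Layout: a = exposed cases, b = unexposed cases, c = exposed controls,
    d = unexposed controls.
    """
    if min(a, b, c, d) <= 0:
        raise ValueError("closed-form OR requires all cells > 0")
    return (a * d) / (b * c), float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))


def counts_to_arrays(case_counts, control_counts) -> tuple[np.ndarray, np.ndarray]:
    """Expand per-genotype (hom-ref, het, hom-alt) counts into y and call arrays."""
    case_counts = [int(x) for x in case_counts]
    control_counts = [int(x) for x in control_counts]
    y = np.concatenate([np.ones(sum(case_counts)), np.zeros(sum(control_counts))])
    g = np.concatenate(
        [np.repeat([0, 1, 2], case_counts), np.repeat([0, 1, 2], control_counts)]
    ).astype(np.int8)
    return y, g


def _status_to_y(status: pd.Series) -> np.ndarray:
    vals = status.astype(str)
    bad = set(vals.unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"status must be 'case'/'control', got {sorted(bad)}")
    return (vals == "case").to_numpy().astype(float)


def covariate_design(phenotypes: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Covariate columns with the field codings used throughout.

    smoking expands to two dummies (ever, current) vs never; family_history is
    0/1.  Returns (matrix, names, complete-case mask over the table's rows).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov == "smoking":
            smk = phenotypes["smoking"].astype(str)
            bad = set(smk.unique()) - {"never", "ever", "current"}
            if bad:
                raise ValueError(f"unknown smoking levels {sorted(bad)}")
            cols.append((smk == "ever").to_numpy(float))
            names.append("smoking_ever")
            cols.append((smk == "current").to_numpy(float))
            names.append("smoking_current")
        else:
            cols.append(pd.to_numeric(phenotypes[cov]).to_numpy(float))
            names.append(cov)
    if not cols:
        return np.empty((len(phenotypes), 0)), [], np.ones(len(phenotypes), bool)
    M = np.column_stack(cols)
    return M, names, np.isfinite(M).all(axis=1)


def _fit_one(y, Xg, gnames, C, cnames, n_cases, n_controls, variant, model, adjusted):
    X = np.column_stack([np.ones(len(y)), Xg, C])
    names = ["intercept"] + gnames + cnames
    fit = fit_logistic(y, X, names)
    rows = []
    for j, gname in enumerate(gnames, start=1):
        beta, se = fit.beta[j], fit.se[j]
        rows.append(
            {
                "variant": variant,
                "model": model if model != "codominant" else f"codominant_{gname}",
                "adjusted": adjusted,
                "term": gname,
                "beta": beta,
                "se": se,
                "or_": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - Z95 * se)),
                "ci_high": float(np.exp(beta + Z95 * se)),
                "p": float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan,
                "converged": fit.converged,
                "n_cases": n_cases,
                "n_controls": n_controls,
            }
        )
    return rows


def association_scan(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    model: str = "additive",
    covariates=(),
    variant_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variant logistic association under one genetic model.

    ``phenotypes`` needs a ``sample`` column matching the genotype matrix and a
    ``status`` column ('case'/'control'); covariate columns as named.  Analysis
    is complete-case per variant.  Codominant contrasts with an empty genotype
    class are reported as undefined (NaN) while the other contrast is still fit.
    """
    if variant_ids is None:
        variant_ids = list(genotypes.variants["id"])
    phen = phenotypes.reset_index(drop=True)
    sidx = genotypes.sample_index(list(phen["sample"]))
    y_all = _status_to_y(phen["status"])
    C_all, cnames, cov_ok = covariate_design(phen, covariates)

    rows: list[dict] = []
    for vid in variant_ids:
        calls = genotypes.variant_calls(vid)[sidx]
        Xg, gnames, gmask = code_genotype(calls, model)
        use = gmask & cov_ok
        y = y_all[use]
        Xg_use, _, _ = code_genotype(calls[use], model)
        C = C_all[use]
        n_cases, n_controls = int(y.sum()), int((1 - y).sum())
        if model == "codominant":
            present = [j for j in range(Xg_use.shape[1]) if Xg_use[:, j].any()]
            missing_contrasts = [gnames[j] for j in range(2) if j not in present]
            try:
                fitted = _fit_one(
                    y, Xg_use[:, present], [gnames[j] for j in present], C, cnames,
                    n_cases, n_controls, vid, model, bool(cnames),
                )
            except ValueError:
                fitted = []
                missing_contrasts = gnames
            rows.extend(fitted)
            for gname in missing_contrasts:
                rows.append(
                    {"variant": vid, "model": f"codominant_{gname}", "adjusted": bool(cnames),
                     "term": gname, "beta": np.nan, "se": np.nan, "or_": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "converged": False,
                     "n_cases": n_cases, "n_controls": n_controls}
                )
        else:
            rows.extend(
                _fit_one(y, Xg_use, gnames, C, cnames, n_cases, n_controls, vid, model, bool(cnames))
            )
    return pd.DataFrame(rows)


def bh_fdr(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the total number of tests (defaults to len(pvalues); may be larger
    when only the smallest p-values of a bigger scan are passed in).  Adjusted
    values are p_(i) * m / i with a cumulative minimum from the largest rank,
    capped at 1; the output is in the input order.  NaNs pass through.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = np.isfinite(p)
    if np.any((p[ok] <= 0) | (p[ok] > 1)):
        raise ValueError("p-values must be in (0, 1]")
    k = int(ok.sum())
    m_eff = k if m is None else int(m)
    if m_eff < k:
        raise ValueError(f"m={m_eff} smaller than the number of p-values ({k})")
    out = np.full(p.shape, np.nan)
    if k:
        order = np.argsort(p[ok], kind="stable")
        ranked = p[ok][order] * m_eff / np.arange(1, k + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        vals = np.minimum(adj, 1.0)
        tmp = np.empty(k)
        tmp[order] = vals
        out[ok] = tmp
    return out


@dataclass
class HeterogeneityStats:
    """Cochran's Q and derived I^2 across stratum-specific log-OR estimates."""

    q: float
    df: int
    i2: float  # percentage in [0, 100]
    p_het: float


def cochran_q(betas, ses) -> HeterogeneityStats:
    """Fixed-effect heterogeneity: Q = sum w_i (b_i - b_w)^2, w_i = 1/se_i^2."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    ok = np.isfinite(b) & np.isfinite(s) & (s > 0)
    b, s = b[ok], s[ok]
    if len(b) < 2:
        raise ValueError("heterogeneity requires >= 2 strata with defined estimates")
    w = 1.0 / s**2
    bw = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - bw) ** 2))
    df = len(b) - 1
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    return HeterogeneityStats(q=q, df=df, i2=i2, p_het=float(stats.chi2.sf(q, df)))


def stratified_analysis(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    variant_id: str,
    strata_var: str,
    model: str = "dominant",
    covariates=(),
    case_only: bool = False,
) -> tuple[pd.DataFrame, HeterogeneityStats]:
    """Per-stratum association for one variant plus heterogeneity statistics.

    Population strata split the whole table by ``strata_var``.  With
    ``case_only=True`` the stratifying variable is defined on cases only
    (clinicopathologic subgroups) and each subgroup's cases are compared
    against the full control set.  Strata whose fit is undefined are excluded
    from Q with a warning column in the output.
    """
    if model == "codominant":
        raise ValueError("stratified analysis expects a single-parameter model")
    phen = phenotypes.reset_index(drop=True)
    frames = []
    if case_only:
        controls = phen[phen["status"] == "control"]
        cases = phen[phen["status"] == "case"]
        levels = [lv for lv in cases[strata_var].dropna().unique()]
        groups = [(lv, pd.concat([cases[cases[strata_var] == lv], controls])) for lv in sorted(map(str, levels))]
    else:
        levels = phen[strata_var].dropna().unique()
        groups = [(lv, phen[phen[strata_var] == lv]) for lv in sorted(map(str, levels))]
    if len(groups) < 2:
        raise ValueError(f"stratified analysis requires >= 2 strata, got {len(groups)}")
    for level, sub in groups:
        try:
            res = association_scan(genotypes, sub, model=model, covariates=covariates,
                                   variant_ids=[variant_id])
            res.insert(0, "stratum", str(level))
            frames.append(res)
        except ValueError:
            frames.append(pd.DataFrame([{"stratum": str(level), "variant": variant_id,
                                         "model": model, "beta": np.nan, "se": np.nan,
                                         "converged": False}]))
    table = pd.concat(frames, ignore_index=True)
    ok = table["converged"].fillna(False).astype(bool)
    het = cochran_q(table.loc[ok, "beta"], table.loc[ok, "se"])
    return table, het
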