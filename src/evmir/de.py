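"""Covariate-adjusted mixed-effects differential abundance and correlations.

Per feature, the repeated-measures model is

    y_ij = β0 + β1·arm_i + β2·visit_j + β3·(arm×visit)_ij + Σ γ·covariates + b_i + ε_ij

with a random intercept b_i per subject.  The treatment effect is the
arm×visit interaction β3 (the difference-in-differences of the PIO vs PLA
week12−baseline changes, in log2 units).  Fixed-effect tests use a t
reference with between-within (containment) denominator degrees of freedom
by default — with two dozen subjects the asymptotic normal reference is
anticonservative; ``df_method="normal"`` restores it.

Fits go through statsmodels MixedLM (REML by default).  A singular fit
(between-subject variance estimated at zero) degenerates to independent
errors, so the fallback is the corresponding OLS fit, reported with a
warning rather than a crash.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleSheet
from .qpcr import NormalizedMatrix, signed_fold_change

__all__ = [
    "ModelSpec",
    "DEResult",
    "FeatureFit",
    "fit_mixed_de",
    "posthoc_contrasts",
    "bh_fdr",
    "directional_test",
    "partial_correlation",
    "PartialCorrResult",
]

DEFAULT_COVARIATES = {
    "plasma_EV": ["weight_kg", "hematocrit_pct"],
    "adipose": ["weight_kg"],
}


@dataclass
class ModelSpec:
    """Fixed/random structure of the per-feature repeated-measures model.

    ``covariates=None`` selects the compartment default (weight + hematocrit
    for circulating measurements, weight only for adipose tissue).  Setting
    ``metformin=True`` refits with metformin use as an additional cofactor
    (the sensitivity analysis).
    """

    compartment: str = "plasma_EV"
    covariates: list[str] | None = None
    metformin: bool = False
    reml: bool = True
    df_method: str = "between_within"  # or "normal"

    def resolved_covariates(self) -> list[str]:
        cov = (list(self.covariates) if self.covariates is not None
               else list(DEFAULT_COVARIATES.get(self.compartment, [])))
        if self.metformin and "metformin" not in cov:
            cov.append("metformin")
        return cov


@dataclass
class FeatureFit:
    """Fitted fixed effects for one feature (needed for post-hoc contrasts)."""

    feature_id: str
    params: pd.Series          # named fixed-effect coefficients
    cov_params: pd.DataFrame   # their covariance
    df_resid: float
    n_subjects: int
    n_obs: int
    converged: bool
    fallback_ols: bool
    term_names: list[str]


@dataclass
class DEResult:
    """Per-feature interaction tests with BH q-values."""

    table: pd.DataFrame  # feature_id, estimate, se, stat, p, q, signed_fc, ...
    spec: ModelSpec
    fits: dict[str, FeatureFit] = field(default_factory=dict)


def _design(meta: pd.DataFrame, covariates: list[str]):
    """Fixed-effect design matrix: intercept, arm(PIO=1), visit(week12=1),
    interaction, then covariates.  Returns (X, names)."""
    arm = (meta["arm"] == "PIO").astype(float).to_numpy()
    vis = (meta["visit"] == "week12").astype(float).to_numpy()
    cols = [np.ones(len(meta)), arm, vis, arm * vis]
    names = ["intercept", "arm[PIO]", "visit[week12]", "arm[PIO]:visit[week12]"]
    for c in covariates:
        if c not in meta.columns:
            raise ValueError(f"covariate {c!r} missing from sample sheet")
        v = meta[c].to_numpy(dtype=float)
        # center/scale for conditioning; leaves the interaction test invariant
        s = v.std()
        cols.append((v - v.mean()) / (s if s > 0 else 1.0))
        names.append(c)
    return np.column_stack(cols), names


def _between_within_df(meta: pd.DataFrame, names: list[str]) -> dict[str, float]:
    """nlme-style containment df: terms varying within subject are tested
    against N − n_subjects − q_within; between-subject terms against
    n_subjects − q_between − 1."""
    n_obs = len(meta)
    n_subj = meta["subject_id"].nunique()
    within, between = [], []
    for nm in names:
        if nm == "intercept":
            continue
        if nm == "arm[PIO]":
            between.append(nm)
            continue
        col = nm if nm in meta.columns else None
        if nm in ("visit[week12]", "arm[PIO]:visit[week12]"):
            within.append(nm)
        elif col is not None:
            varies = meta.groupby("subject_id")[col].nunique().gt(1).any()
            (within if varies else between).append(nm)
        else:
            within.append(nm)
    df_within = max(n_obs - n_subj - len(within), 1)
    df_between = max(n_subj - len(between) - 1, 1)
    out = {"intercept": df_between}
    for nm in names[1:]:
        out[nm] = df_within if nm in within else df_between
    return out


def _fit_one(y: np.ndarray, X: np.ndarray, names: list[str],
             subjects: np.ndarray, reml: bool) -> tuple[pd.Series, pd.DataFrame, bool, bool]:
    """Random-intercept fit; OLS fallback at the zero-variance boundary."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell"):
            try:
                model = sm.MixedLM(y, X, groups=subjects)
                res = model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            re_var = float(np.squeeze(res.cov_re))
            if bool(res.converged) and re_var > 1e-10:
                params = pd.Series(res.fe_params, index=names)
                cov = pd.DataFrame(np.asarray(res.cov_params())[: len(names), : len(names)],
                                   index=names, columns=names)
                return params, cov, True, False
    # GLS limit with zero between-subject variance = ordinary least squares
    ols = sm.OLS(y, X).fit()
    params = pd.Series(ols.params, index=names)
    cov = pd.DataFrame(ols.cov_params(), index=names, columns=names)
    warnings.warn("singular mixed fit: fell back to the zero-variance (OLS) limit",
                  stacklevel=3)
    return params, cov, True, True


def fit_mixed_de(mat: NormalizedMatrix, sheet: SampleSheet, spec: ModelSpec,
                 *, features: list[str] | None = None) -> DEResult:
    """Fit the repeated-measures model per feature and test the interaction.

    Subjects missing a covariate value are excluded from that model only
    (logged via warning); subjects with one missing visit are retained —
    the mixed model uses their remaining observation.
    """
    covs = spec.resolved_covariates()
    meta_all = sheet.resolve(list(mat.values.columns))
    meta_all = meta_all[meta_all["compartment"] == spec.compartment]
    feats = features if features is not None else list(mat.values.index)

    rows = []
    fits: dict[str, FeatureFit] = {}
    for feat in feats:
        y_by_sample = mat.values.loc[feat]
        meta = meta_all.copy()
        meta["y"] = meta["sample_id"].map(y_by_sample)
        meta = meta.dropna(subset=["y"])
        bad_cov = meta[covs].isna().any(axis=1) if covs else pd.Series(False, index=meta.index)
        if bad_cov.any():
            excluded = sorted(meta.loc[bad_cov, "subject_id"].unique())
            warnings.warn(
                f"{feat}: subjects excluded for missing covariates: {excluded}",
                stacklevel=2)
            meta = meta[~meta["subject_id"].isin(excluded)]
        if meta["subject_id"].nunique() < 4 or meta["visit"].nunique() < 2:
            rows.append((feat, np.nan, np.nan, np.nan, np.nan, np.nan,
                         meta["subject_id"].nunique(), False))
            continue
        X, names = _design(meta, covs)
        params, cov, converged, fallback = _fit_one(
            meta["y"].to_numpy(dtype=float), X, names,
            meta["subject_id"].to_numpy(), spec.reml)
        term = "arm[PIO]:visit[week12]"
        est = float(params[term])
        se = float(np.sqrt(cov.loc[term, term]))
        stat = est / se if se > 0 else np.nan
        if spec.df_method == "normal":
            p = 2 * stats.norm.sf(abs(stat))
            dfr = np.inf
        else:
            dfr = _between_within_df(meta, names)[term]
            p = 2 * stats.t.sf(abs(stat), dfr)
        n_subj = int(meta["subject_id"].nunique())
        fits[feat] = FeatureFit(feat, params, cov, dfr, n_subj, len(meta),
                                converged, fallback, names)
        rows.append((feat, est, se, stat, float(p),
                     signed_fold_change(est) if np.isfinite(est) else np.nan,
                     n_subj, fallback))

    table = pd.DataFrame(rows, columns=["feature_id", "estimate", "se", "stat",
                                        "p", "signed_fc", "n_subjects",
                                        "ols_fallback"])
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["sidedness"] = "two-sided"
    table = table[["feature_id", "estimate", "se", "stat", "p", "q",
                   "signed_fc", "sidedness", "n_subjects", "ols_fallback"]]
    return DEResult(table, spec, fits)


# ---------------------------------------------------------------------------
# Post-hoc contrasts
# ---------------------------------------------------------------------------

_CONTRASTS = {
    ("within_arm_change", "PIO"): {"visit[week12]": 1.0, "arm[PIO]:visit[week12]": 1.0},
    ("within_arm_change", "PLA"): {"visit[week12]": 1.0},
    ("between_arm_at_visit", "baseline"): {"arm[PIO]": 1.0},
    ("between_arm_at_visit", "week12"): {"arm[PIO]": 1.0, "arm[PIO]:visit[week12]": 1.0},
}


def posthoc_contrasts(fit: FeatureFit, which: str,
                      levels: list[str] | None = None) -> pd.DataFrame:
    """Linear contrasts on the fitted fixed effects.

    ``within_arm_change``: week12 − baseline change inside each arm.
    ``between_arm_at_visit``: PIO − PLA difference at each visit.
    Wald t tests with the fit's residual df.
    """
    if which == "within_arm_change":
        levels = levels or ["PIO", "PLA"]
    elif which == "between_arm_at_visit":
        levels = levels or ["baseline", "week12"]
    else:
        raise ValueError(f"unknown contrast family {which!r}")
    rows = []
    for lev in levels:
        weights = _CONTRASTS[(which, lev)]
        missing = [t for t in weights if t not in fit.params.index]
        if missing:
            raise ValueError(f"non-estimable contrast: term(s) {missing} aliased "
                             f"or absent from the fit")
        c = pd.Series(0.0, index=fit.params.index)
        for t, w in weights.items():
            c[t] = w
        est = float(c @ fit.params)
        se = float(np.sqrt(c @ fit.cov_params @ c))
        stat = est / se if se > 0 else np.nan
        dfr = fit.df_resid
        p = (2 * stats.norm.sf(abs(stat)) if not np.isfinite(dfr)
             else 2 * stats.t.sf(abs(stat), dfr))
        rows.append((fit.feature_id, which, lev, est, se, stat, float(p)))
    return pd.DataFrame(rows, columns=["feature_id", "contrast", "level",
                                       "estimate", "se", "stat", "p"])


# ---------------------------------------------------------------------------
# Multiple testing and sidedness
# ---------------------------------------------------------------------------

def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    NaN entries yield NaN and are excluded from the family size m.  Output
    is monotone in p, clipped at 1, returned in the input order.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.clip(ranked, 0, 1)
    q[ok] = qv
    return q


def directional_test(p_two_sided: float, estimate_sign: int, expected_sign: int) -> float:
    """One-sided p from a symmetric two-sided test with an a-priori direction.

    Used for overtargeted genes, where upregulated miRNAs are expected to
    *down*regulate their targets: p/2 when the estimate's sign matches the
    expectation, 1 − p/2 otherwise.
    """
    if not 0 <= p_two_sided <= 1:
        raise ValueError("p must lie in [0, 1]")
    if estimate_sign == 0:
        return 0.5
    match = (estimate_sign > 0) == (expected_sign > 0)
    return p_two_sided / 2 if match else 1 - p_two_sided / 2


# ---------------------------------------------------------------------------
# Partial correlation
# ---------------------------------------------------------------------------

@dataclass
class PartialCorrResult:
    x: str
    y: str
    r: float
    p: float
    n: int
    covariates: list[str]
    note: str = ""


def partial_correlation(x, y, covariates=None, *, labels=("x", "y")) -> PartialCorrResult:
    """Pearson partial correlation by two-stage residual regression.

    ``x`` and ``y`` are regressed on the covariates plus an intercept; the
    partial r is the plain Pearson correlation of the two residual vectors.
    Two-sided p from the t transform with df = n − k − 2 (k covariates).
    With no covariates this reduces exactly to the ordinary Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        Z = np.empty((len(x), 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(Z), axis=1)
    x, y, Z = x[ok], y[ok], Z[ok]
    n, k = len(x), Z.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete cases, got {n}")
    design = np.column_stack([np.ones(n), Z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    if sx < 1e-12 * max(1, np.abs(x).max()) or sy < 1e-12 * max(1, np.abs(y).max()):
        return PartialCorrResult(labels[0], labels[1], np.nan, np.nan, n,
                                 list(range(k)) if covariates is not None else [],
                                 note="zero-variance residuals")
    r = float(np.clip(rx @ ry / (sx * sy), -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrResult(labels[0], labels[1], r, p, n,
                             [f"cov{i}" for i in range(k)])


def partial_correlation_table(df: pd.DataFrame, pairs: list[tuple[str, str]],
                              covariates: list[str]) -> pd.DataFrame:
    """Partial correlations for many column pairs of one change-score frame,
    with BH correction across the pairs."""
    rows = []
    for a, b in pairs:
        sub = df[[a, b] + covariates].dropna()
        try:
            res = partial_correlation(sub[a], sub[b],
                                      sub[covariates] if covariates else None,
                                      labels=(a, b))
            rows.append((a, b, res.r, res.p, res.n, ",".join(covariates), res.note))
        except ValueError as exc:
            rows.append((a, b, np.nan, np.nan, len(sub), ",".join(covariates), str(exc)))
    out = pd.DataFrame(rows, columns=["x", "y", "r", "p", "n", "covariates", "note"])
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
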