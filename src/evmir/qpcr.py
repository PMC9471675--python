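"""Ct → normalized log2 relative abundance.

The chain is: spike-in recovery adjustment (cel-miR-39 style), model-based
reference selection (NormFinder-type variance decomposition), normalization
against the geometric mean of the chosen references (arithmetic mean on the
Ct scale), per-subject −ΔΔCt fold changes, and a minimum-fold pre-filter.

Conventions
-----------
Ct is inversely proportional to log2 abundance: one cycle ≈ one log2 unit,
lower Ct = more template.  Normalized abundance is reported as −ΔCt =
−(Ct_feature − mean Ct of normalizers), so larger values mean more abundant
and differences are log2 fold ratios.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CtTable, SampleSheet

__all__ = [
    "NormalizedMatrix",
    "StabilityRanking",
    "FoldChangeTable",
    "spike_adjust",
    "normfinder_stability",
    "normalize",
    "ddct_relative_expression",
    "signed_fold_change",
    "change_scores",
    "fold_filter",
]


class NormalizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Spike-in recovery adjustment
# ---------------------------------------------------------------------------

def spike_adjust(ct: CtTable, spike_id: str) -> CtTable:
    """Remove per-sample technical yield using an exogenous spike-in.

    For each sample ``s`` every target/control Ct is shifted by
    ``-(spikeCt_s - mean_s spikeCt)``: a sample whose spike amplified late
    (poor recovery) has all its Cts pulled down by the same amount.  Spike
    rows are dropped from the output; undetermined wells pass through
    flagged.  Within-sample Ct differences are preserved exactly.
    """
    df = ct.data
    spikes = df[df["feature_id"] == spike_id]
    if spikes.empty:
        raise NormalizationError(f"spike-in {spike_id!r} not present in Ct table")
    bad = spikes.loc[spikes["undetermined"], "sample_id"].tolist()
    missing = sorted(set(df["sample_id"]) - set(spikes["sample_id"]))
    if bad or missing:
        raise NormalizationError(
            f"spike-in {spike_id!r} undetermined or missing in samples: "
            f"{sorted(set(bad) | set(missing))}"
        )
    dev = spikes.set_index("sample_id")["ct"] - spikes["ct"].mean()
    out = df[df["feature_id"] != spike_id].copy()
    out["ct"] = out["ct"] - out["sample_id"].map(dev)
    out.loc[out["undetermined"], "ct"] = np.nan
    fcm = {f: c for f, c in ct.feature_class.items() if f != spike_id}
    return CtTable(out.reset_index(drop=True), fcm)


# ---------------------------------------------------------------------------
# NormFinder-type stability
# ---------------------------------------------------------------------------

@dataclass
class StabilityRanking:
    """Per-feature stability (lower = more stable) plus best single/pair."""

    stability: pd.Series              # indexed by feature_id, ρ values
    best_single: str
    best_pair: tuple[str, str]
    pair_stability: float
    intra_var: pd.DataFrame | None = None   # feature × group σ̂²
    inter_diff: pd.DataFrame | None = None  # feature × group d


def _stability_components(values: np.ndarray, group_idx: list[np.ndarray]):
    """Shared variance decomposition on a feature × sample matrix.

    Returns (d, v, gamma2): feature × group intergroup differences,
    feature × group sampling variances d̂, and the empirical-Bayes
    between-group variance used for shrinkage.

    Model: y_igj = α_ig + β_gj + ε_igj with sample effects β estimated by the
    per-sample mean across features.  The naive within-group mean square of
    the centered values is biased by that centering; with k features,
    E[MS_i] = σ²_i (1 − 2/k) + mean_l σ²_l / k, which inverts to
    σ̂²_i = k/(k−2) · (MS_i − Σ_l MS_l / (k(k−1))), floored at 0.
    """
    k, _ = values.shape
    G = len(group_idx)
    # per-sample centering (removes sample effects)
    z = values - values.mean(axis=0, keepdims=True)
    zbar = np.column_stack([z[:, idx].mean(axis=1) for idx in group_idx])
    n_g = np.array([len(idx) for idx in group_idx])
    ms = np.column_stack([
        z[:, idx].var(axis=1, ddof=1) for idx in group_idx
    ])
    if k > 2:
        sigma2 = (k / (k - 2)) * (ms - ms.sum(axis=0, keepdims=True) / (k * (k - 1)))
        sigma2 = np.clip(sigma2, 0.0, None)
    else:
        sigma2 = ms  # too few features to correct for centering contamination
    d = zbar - zbar.mean(axis=1, keepdims=True)
    v = sigma2 / n_g[np.newaxis, :]
    gamma2 = max((d ** 2).sum() / (k * (G - 1)) - v.mean(), 0.0)
    return d, v, gamma2, sigma2


def _rho(d: np.ndarray, v: np.ndarray, gamma2: float) -> np.ndarray:
    """Stability value: mean over groups of |shrunken d| + sampling sd."""
    if gamma2 > 0:
        shrink = gamma2 / (gamma2 + v)
    else:
        shrink = np.zeros_like(v)
    return (np.abs(d * shrink) + np.sqrt(v)).mean(axis=1)


def normfinder_stability(mat: pd.DataFrame, groups: dict[str, str] | pd.Series,
                         *, search_pairs: bool = True) -> StabilityRanking:
    """Rank candidate reference features by model-based stability.

    ``mat`` is a feature × sample matrix of log2-scale values (e.g. raw or
    spike-adjusted Ct — the decomposition is location-invariant), ``groups``
    maps each sample to its group (typically treatment arm).  Requires ≥2
    groups each with ≥2 samples; with a single group the stability falls
    back to the per-feature variance of sample-centered values.

    Pair stability is evaluated exhaustively for all feature pairs using the
    same model on the pair-average profile (d and sampling variance of the
    average of the two members), with the shared shrinkage variance.  Ties
    break lexicographically for determinism.
    """
    if mat.isna().any().any():
        bad = mat.index[mat.isna().any(axis=1)].tolist()
        raise NormalizationError(f"undetermined/missing values among candidates: {bad}")
    groups = pd.Series(groups)
    samples = list(mat.columns)
    glabels = sorted(groups.loc[samples].unique())
    features = list(mat.index)
    values = mat.to_numpy(dtype=float)
    k = len(features)

    if len(glabels) < 2:
        z = values - values.mean(axis=0, keepdims=True)
        rho = z.var(axis=1, ddof=1)
        order = sorted(range(k), key=lambda i: (rho[i], features[i]))
        stab = pd.Series(rho, index=features).loc[[features[i] for i in order]]
        best = features[order[0]]
        pair, pstab = (best, best), float(stab.iloc[0])
        if search_pairs and k >= 2:
            best_p = None
            for a, b in itertools.combinations(sorted(features), 2):
                w = (mat.loc[a].to_numpy() + mat.loc[b].to_numpy()) / 2.0
                wz = w - values.mean(axis=0)
                s = wz.var(ddof=1)
                if best_p is None or s < best_p[1] - 1e-15:
                    best_p = ((a, b), s)
            pair, pstab = best_p
        return StabilityRanking(stab, best, pair, float(pstab))

    group_idx = []
    for g in glabels:
        idx = np.array([i for i, s in enumerate(samples) if groups[s] == g])
        if len(idx) < 2:
            raise NormalizationError(f"group {g!r} has fewer than 2 samples")
        group_idx.append(idx)

    d, v, gamma2, sigma2 = _stability_components(values, group_idx)
    rho = _rho(d, v, gamma2)
    order = sorted(range(k), key=lambda i: (rho[i], features[i]))
    stab = pd.Series(rho[order], index=[features[i] for i in order], name="stability")
    best_single = features[order[0]]

    best_pair, pair_stab = (best_single, best_single), float(stab.iloc[0])
    if search_pairs and k >= 2:
        fidx = {f: i for i, f in enumerate(features)}
        best = None
        n_g = np.array([len(idx) for idx in group_idx])
        for a, b in itertools.combinations(sorted(features), 2):
            ia, ib = fidx[a], fidx[b]
            d_p = (d[ia] + d[ib]) / 2.0
            v_p = (sigma2[ia] + sigma2[ib]) / 4.0 / n_g
            r = float(_rho(d_p[np.newaxis, :], v_p[np.newaxis, :], gamma2)[0])
            if best is None or r < best[1] - 1e-15:
                best = ((a, b), r)
        best_pair, pair_stab = best
    return StabilityRanking(stab, best_single, best_pair, float(pair_stab),
                            intra_var=pd.DataFrame(sigma2, index=features, columns=glabels),
                            inter_diff=pd.DataFrame(d, index=features, columns=glabels))


# ---------------------------------------------------------------------------
# Reference normalization (−ΔCt)
# ---------------------------------------------------------------------------

@dataclass
class NormalizedMatrix:
    """Feature × sample matrix of −ΔCt values (log2 relative abundance).

    The normalizers' own geometric mean maps to 0 in every sample by
    construction.  ``values`` rows are features, columns samples; NaN marks
    undetermined wells.
    """

    values: pd.DataFrame
    normalizer_ids: list[str]
    spike_adjusted: bool = False
    undetermined_policy: dict = field(default_factory=lambda: {"policy": "propagate_nan"})

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# normalizers: {','.join(self.normalizer_ids)}\n")
            fh.write(f"# spike_adjusted: {self.spike_adjusted}\n")
            fh.write(f"# undetermined_policy: {self.undetermined_policy}\n")
            self.values.to_csv(fh, sep="\t", index_label="feature_id")


def normalize(ct: CtTable, normalizers: list[str], *,
              spike_adjusted: bool = False) -> NormalizedMatrix:
    """Normalize Ct against the geometric mean of reference features.

    On the concentration scale the reference is the geometric mean of the
    normalizers; on the Ct (log2) scale this is exactly their arithmetic
    mean, which is what is computed (no exponentiation round-trip).  Output
    is −ΔCt: a feature one cycle *below* the normalizer mean (more abundant)
    scores +1.  Supports a single normalizer (adipose-tissue mode).
    """
    if not normalizers:
        raise NormalizationError("at least one normalizer feature required")
    wide = ct.data.pivot(index="feature_id", columns="sample_id", values="ct")
    missing = sorted(set(normalizers) - set(wide.index))
    if missing:
        raise NormalizationError(f"normalizers absent from Ct table: {missing}")
    ref = wide.loc[normalizers]
    if ref.isna().any().any():
        bad = ref.columns[ref.isna().any(axis=0)].tolist()
        raise NormalizationError(
            f"normalizer undetermined in samples: {bad}"
        )
    values = -(wide - ref.mean(axis=0))
    return NormalizedMatrix(values, list(normalizers), spike_adjusted=spike_adjusted)


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------

def ddct_relative_expression(delta_delta_ct: float) -> float:
    """Relative expression by the −ΔΔCt method: 2^(−ΔΔCt)."""
    return float(2.0 ** (-delta_delta_ct))


def signed_fold_change(delta_log2: float) -> float:
    """Fold change with sign convention: 2^Δ for Δ≥0, −2^(−Δ) for Δ<0.

    |signed_fc| ≥ 1 always; a halving is −2.0, a doubling +2.0.
    """
    if delta_log2 >= 0:
        return float(2.0 ** delta_log2)
    return float(-(2.0 ** (-delta_log2)))


def delta_from_signed_fc(signed_fc: float) -> float:
    """Inverse of :func:`signed_fold_change`."""
    if abs(signed_fc) < 1:
        raise ValueError("|signed_fc| must be >= 1")
    return math.log2(signed_fc) if signed_fc > 0 else -math.log2(-signed_fc)


@dataclass
class FoldChangeTable:
    """Per (feature, subject) week12 − baseline log2 change (Δ) and signed FC."""

    data: pd.DataFrame  # columns: feature_id, subject_id, arm, compartment, delta, signed_fc


def change_scores(mat: NormalizedMatrix, sheet: SampleSheet, *,
                  compartment: str | None = None,
                  drop_incomplete: bool = True,
                  cap_imputation: float | None = None) -> FoldChangeTable:
    """Per-subject week12 − baseline change of normalized abundance.

    Undetermined wells: by default a subject's pair is dropped for a feature
    if either visit is undetermined; alternatively ``cap_imputation`` imputes
    a Ct-cap-equivalent floor value (on the −ΔCt scale) before differencing.
    """
    meta = sheet.resolve(list(mat.values.columns))
    if compartment is not None:
        meta = meta[meta["compartment"] == compartment]
    rows = []
    vals = mat.values
    for (subj, comp), sub in meta.groupby(["subject_id", "compartment"]):
        visits = sub.set_index("visit")["sample_id"]
        if "baseline" not in visits.index or "week12" not in visits.index:
            continue
        arm = sub["arm"].iloc[0]
        b = vals[visits["baseline"]]
        w = vals[visits["week12"]]
        if cap_imputation is not None:
            b = b.fillna(cap_imputation)
            w = w.fillna(cap_imputation)
        delta = w - b
        for feat, dv in delta.items():
            if pd.isna(dv):
                if drop_incomplete:
                    continue
                dv = np.nan
            rows.append((feat, subj, arm, comp, dv,
                         signed_fold_change(dv) if pd.notna(dv) else np.nan))
    df = pd.DataFrame(rows, columns=["feature_id", "subject_id", "arm",
                                     "compartment", "delta", "signed_fc"])
    return FoldChangeTable(df)


def fold_filter(fc: FoldChangeTable, threshold: float = 1.5, *,
                mode: str = "group_effect") -> tuple[FoldChangeTable, pd.DataFrame]:
    """Drop features whose between-arm effect is below a minimum fold.

    ``group_effect`` (default): a feature is retained iff
    |mean PIO Δ − mean PLA Δ| ≥ log2(threshold); the boundary case is
    retained (sub-threshold features are the ones filtered out).
    ``subject_median``: retained iff the larger |per-arm median Δ| clears
    log2(threshold) — an alternative per-subject-level reading.

    Returns the filtered table and a frame of dropped features with their
    effect sizes.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    cut = math.log2(threshold)
    df = fc.data
    eff = {}
    for feat, sub in df.groupby("feature_id"):
        pio = sub.loc[sub["arm"] == "PIO", "delta"]
        pla = sub.loc[sub["arm"] == "PLA", "delta"]
        if mode == "group_effect":
            e = (pio.mean() if len(pio) else 0.0) - (pla.mean() if len(pla) else 0.0)
        elif mode == "subject_median":
            cands = [m for m in (pio.median() if len(pio) else np.nan,
                                 pla.median() if len(pla) else np.nan)
                     if pd.notna(m)]
            e = max(cands, key=abs) if cands else 0.0
        else:
            raise ValueError(f"unknown fold_filter mode {mode!r}")
        eff[feat] = e
    keep = {f for f, e in eff.items() if abs(e) >= cut - 1e-12}
    dropped = pd.DataFrame(
        [(f, e) for f, e in sorted(eff.items()) if f not in keep],
        columns=["feature_id", "group_effect_log2"],
    )
    return FoldChangeTable(df[df["feature_id"].isin(keep)].reset_index(drop=True)), dropped
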