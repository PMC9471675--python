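import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evmir.io import CtTable
from evmir.qpcr import (FoldChangeTable, NormalizationError, change_scores,
                        ddct_relative_expression, delta_from_signed_fc,
                        fold_filter, normalize, normfinder_stability,
                        signed_fold_change, spike_adjust)

# ---------------------------------------------------------------------------
# spike adjustment
# ---------------------------------------------------------------------------

def _ct(rows, fcm):
    df = pd.DataFrame(rows, columns=["sample_id", "feature_id", "ct", "undetermined"])
    return CtTable(df, fcm)


FCM = {"miR-a": "target", "miR-b": "target", "spike": "spike_in"}


def test_spike_adjust_centering_rule_and_identity():
    # equal spike Cts → identity on targets
    same = _ct([("S1", "miR-a", 25, False), ("S2", "miR-a", 26, False),
                ("S1", "spike", 20, False), ("S2", "spike", 20, False)], FCM)
    out = spike_adjust(same, "spike")
    assert out.data.set_index("sample_id")["ct"].to_dict() == {"S1": 25.0, "S2": 26.0}
    assert "spike" not in out.features

    # spike Cts 20 and 22 (mean 21): S1 shifts +1, S2 shifts −1
    two = _ct([("S1", "miR-a", 25, False), ("S2", "miR-a", 25, False),
               ("S1", "spike", 20, False), ("S2", "spike", 22, False)], FCM)
    got = spike_adjust(two, "spike").data.set_index("sample_id")["ct"]
    assert got["S1"] == pytest.approx(26.0)
    assert got["S2"] == pytest.approx(24.0)

    # single sample: its spike equals the mean → unchanged
    one = _ct([("S1", "miR-a", 25, False), ("S1", "spike", 23, False)], FCM)
    assert spike_adjust(one, "spike").data["ct"].iloc[0] == pytest.approx(25.0)


def test_spike_adjust_errors_name_sample():
    missing = _ct([("S1", "miR-a", 25, False), ("S1", "spike", 20, False),
                   ("S2", "miR-a", 25, False)], FCM)
    with pytest.raises(NormalizationError, match="S2"):
        spike_adjust(missing, "spike")
    undet = _ct([("S1", "miR-a", 25, False), ("S1", "spike", np.nan, True)], FCM)
    with pytest.raises(NormalizationError, match="S1"):
        spike_adjust(undet, "spike")


def test_spike_adjust_preserves_within_sample_differences():
    rng = np.random.default_rng(7)
    rows = []
    for s in ("S1", "S2", "S3", "S4"):
        rows += [(s, "miR-a", rng.uniform(20, 30), False),
                 (s, "miR-b", rng.uniform(20, 30), False),
                 (s, "spike", rng.uniform(18, 24), False)]
    ct = _ct(rows, FCM)
    out = spike_adjust(ct, "spike")
    for s in ("S1", "S2", "S3", "S4"):
        before = ct.data[ct.data.sample_id == s].set_index("feature_id")["ct"]
        after = out.data[out.data.sample_id == s].set_index("feature_id")["ct"]
        assert (before["miR-a"] - before["miR-b"]) == pytest.approx(
            after["miR-a"] - after["miR-b"], abs=1e-12)


# ---------------------------------------------------------------------------
# normalization (−ΔCt)
# ---------------------------------------------------------------------------

def test_normalize_sign_convention_and_reference_mean():
    rows = [("S1", "miR-x", 21.0, False), ("S1", "n1", 20.0, False),
            ("S1", "n2", 24.0, False),
            ("S2", "miR-x", 22.0, False), ("S2", "n1", 22.0, False),
            ("S2", "n2", 22.0, False)]
    ct = _ct(rows, {"miR-x": "target", "n1": "target", "n2": "target"})
    mat = normalize(ct, ["n1", "n2"])
    # S1: normalizer mean 22, feature one cycle below → +1 (more abundant)
    assert mat.values.loc["miR-x", "S1"] == pytest.approx(1.0)
    assert mat.values.loc["miR-x", "S2"] == pytest.approx(0.0)
    # normalizer-pair mean maps to 0 in every sample
    assert np.allclose(mat.values.loc[["n1", "n2"]].mean(axis=0), 0.0, atol=1e-9)


def test_normalize_single_reference_and_errors():
    rows = [("S1", "miR-x", 25.0, False), ("S1", "ctrl", 24.0, False),
            ("S2", "miR-x", 24.0, False), ("S2", "ctrl", np.nan, True)]
    ct = _ct(rows, {"miR-x": "target", "ctrl": "endogenous_control"})
    with pytest.raises(NormalizationError, match="S2"):
        normalize(ct, ["ctrl"])
    ok = _ct(rows[:2] + [("S2", "miR-x", 24.0, False), ("S2", "ctrl", 26.0, False)],
             {"miR-x": "target", "ctrl": "endogenous_control"})
    mat = normalize(ok, ["ctrl"])
    assert mat.values.loc["miR-x", "S1"] == pytest.approx(-1.0)
    assert mat.values.loc["miR-x", "S2"] == pytest.approx(2.0)


def test_pipeline_location_invariance():
    """Adding a global constant to every Ct leaves normalized values unchanged."""
    rng = np.random.default_rng(3)
    rows = []
    for s in ("S1", "S2", "S3"):
        for f in ("miR-a", "miR-b", "spike"):
            rows.append((s, f, rng.uniform(18, 30), False))
    ct = _ct(rows, FCM)
    shifted = _ct([(s, f, c + 3.7, False) for s, f, c, _ in rows], FCM)
    a = normalize(spike_adjust(ct, "spike"), ["miR-b"]).values
    b = normalize(spike_adjust(shifted, "spike"), ["miR-b"]).values
    assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)


# ---------------------------------------------------------------------------
# −ΔΔCt and signed fold change
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ddct,expected", [(0.0, 1.0), (-1.0, 2.0), (1.0, 0.5)])
def test_ddct_relative_expression(ddct, expected):
    assert ddct_relative_expression(ddct) == pytest.approx(expected)


@given(st.floats(-10, 10, allow_nan=False))
@settings(max_examples=200, deadline=None)
def test_signed_fc_round_trip(delta):
    fc = signed_fold_change(delta)
    assert abs(fc) >= 1.0
    assert delta_from_signed_fc(fc) == pytest.approx(delta, abs=1e-9)


# ---------------------------------------------------------------------------
# fold filter
# ---------------------------------------------------------------------------

def _fc_table(effects: dict[str, float], n_per_arm: int = 4) -> FoldChangeTable:
    """Noise-free per-subject change table with the given PIO−PLA effects."""
    rows = []
    for feat, eff in effects.items():
        for i in range(n_per_arm):
            rows.append((feat, f"P{i}", "PIO", "plasma_EV", eff,
                         signed_fold_change(eff)))
            rows.append((feat, f"L{i}", "PLA", "plasma_EV", 0.0, 1.0))
    return FoldChangeTable(pd.DataFrame(
        rows, columns=["feature_id", "subject_id", "arm", "compartment",
                       "delta", "signed_fc"]))


def test_fold_filter_boundary_and_planted_recovery():
    effects = {f"null{i}": 0.0 for i in range(6)}
    effects.update({f"hit{i}": 1.0 for i in range(4)})   # log2(2.0)
    effects["edge"] = math.log2(1.5)                     # exactly at threshold
    kept, dropped = fold_filter(_fc_table(effects), 1.5)
    kept_feats = set(kept.data["feature_id"])
    assert kept_feats == {"hit0", "hit1", "hit2", "hit3", "edge"}
    assert set(dropped["feature_id"]) == {f"null{i}" for i in range(6)}
    with pytest.raises(ValueError):
        fold_filter(_fc_table(effects), 1.0)


# ---------------------------------------------------------------------------
# NormFinder-type stability
# ---------------------------------------------------------------------------

def _normfinder_oracle(mat: pd.DataFrame, groups: dict[str, str]):
    """Plain-loop transcription of the variance-decomposition formulas.

    Independent of the vectorized implementation: explicit Python loops over
    features, groups and samples.
    """
    feats = list(mat.index)
    samples = list(mat.columns)
    k = len(feats)
    glabels = sorted(set(groups[s] for s in samples))
    # sample centering
    z = {}
    for s in samples:
        col_mean = sum(mat.loc[f, s] for f in feats) / k
        for f in feats:
            z[(f, s)] = mat.loc[f, s] - col_mean
    members = {g: [s for s in samples if groups[s] == g] for g in glabels}
    zbar = {(f, g): sum(z[(f, s)] for s in members[g]) / len(members[g])
            for f in feats for g in glabels}
    ms = {}
    for f in feats:
        for g in glabels:
            n = len(members[g])
            ms[(f, g)] = sum((z[(f, s)] - zbar[(f, g)]) ** 2
                             for s in members[g]) / (n - 1)
    sigma2 = {}
    for g in glabels:
        tot = sum(ms[(f, g)] for f in feats)
        for f in feats:
            v = (k / (k - 2)) * (ms[(f, g)] - tot / (k * (k - 1)))
            sigma2[(f, g)] = max(v, 0.0)
    d = {}
    for f in feats:
        overall = sum(zbar[(f, g)] for g in glabels) / len(glabels)
        for g in glabels:
            d[(f, g)] = zbar[(f, g)] - overall
    v = {(f, g): sigma2[(f, g)] / len(members[g]) for f in feats for g in glabels}
    G = len(glabels)
    gamma2 = max(sum(d[fg] ** 2 for fg in d) / (k * (G - 1))
                 - sum(v.values()) / (k * G), 0.0)
    rho = {}
    for f in feats:
        acc = 0.0
        for g in glabels:
            shrink = gamma2 / (gamma2 + v[(f, g)]) if gamma2 > 0 else 0.0
            acc += abs(d[(f, g)] * shrink) + math.sqrt(v[(f, g)])
        rho[f] = acc / G
    # pair stabilities on the pair-average profile
    pair_rho = {}
    for a, b in itertools.combinations(sorted(feats), 2):
        acc = 0.0
        for g in glabels:
            dp = (d[(a, g)] + d[(b, g)]) / 2.0
            vp = (sigma2[(a, g)] + sigma2[(b, g)]) / 4.0 / len(members[g])
            shrink = gamma2 / (gamma2 + vp) if gamma2 > 0 else 0.0
            acc += abs(dp * shrink) + math.sqrt(vp)
        pair_rho[(a, b)] = acc / G
    return rho, pair_rho


@pytest.fixture()
def stability_fixture():
    """4 features × 8 samples × 2 groups with heterogeneous noise/offsets."""
    rng = np.random.default_rng(42)
    samples = [f"S{i}" for i in range(8)]
    groups = {s: ("A" if i < 4 else "B") for i, s in enumerate(samples)}
    data = {
        "f-stable": 20 + rng.normal(0, 0.05, 8),
        "f-noisy": 24 + rng.normal(0, 1.0, 8),
        "f-shifted": np.concatenate([22 + rng.normal(0, 0.2, 4),
                                     23.5 + rng.normal(0, 0.2, 4)]),
        "f-mid": 26 + rng.normal(0, 0.4, 8),
    }
    mat = pd.DataFrame(data).T
    mat.columns = samples
    return mat, groups


def test_normfinder_matches_loop_transcription_oracle(stability_fixture):
    mat, groups = stability_fixture
    rank = normfinder_stability(mat, groups)
    oracle, _ = _normfinder_oracle(mat, groups)
    for f, rho in oracle.items():
        assert rank.stability[f] == pytest.approx(rho, abs=1e-10)
    assert rank.best_single == min(oracle, key=lambda f: (oracle[f], f))
    # group-shifted feature must rank worse than the stable one
    assert rank.stability["f-shifted"] > rank.stability["f-stable"]


def test_normfinder_zero_variation_ranks_first(stability_fixture):
    mat, groups = stability_fixture
    # construct a feature whose sample-centered values are constant:
    # equal to the per-sample mean of the others plus a constant
    const = mat.mean(axis=0) + 1.0
    mat2 = pd.concat([mat, const.to_frame("f-zero").T])
    # adding f-zero changes all sample means equally → still exactly centered
    rank = normfinder_stability(mat2, groups)
    assert rank.best_single == "f-zero"
    assert rank.stability["f-zero"] == pytest.approx(0.0, abs=1e-9)


def test_normfinder_location_invariance_and_permutation(stability_fixture):
    mat, groups = stability_fixture
    base = normfinder_stability(mat, groups)
    shifted = mat.copy()
    shifted.loc["f-noisy"] += 5.0
    s = normfinder_stability(shifted, groups)
    assert np.allclose(s.stability.sort_index(), base.stability.sort_index(),
                       atol=1e-9)
    perm = mat[list(mat.columns[::-1])]
    p = normfinder_stability(perm, groups)
    assert (p.stability.sort_index() - base.stability.sort_index()).abs().max() < 1e-12
    assert p.best_pair == base.best_pair


def test_normfinder_pair_is_minimum_over_pairs(stability_fixture):
    mat, groups = stability_fixture
    rank = normfinder_stability(mat, groups)
    _, pair_oracle = _normfinder_oracle(mat, groups)
    best = min(pair_oracle, key=lambda p: (pair_oracle[p], p))
    assert rank.best_pair == best
    assert rank.pair_stability == pytest.approx(pair_oracle[best], abs=1e-10)
    assert rank.pair_stability == pytest.approx(min(pair_oracle.values()), abs=1e-10)


def test_normfinder_group_size_error(stability_fixture):
    mat, groups = stability_fixture
    bad = dict(groups)
    bad["S7"] = "C"
    with pytest.raises(NormalizationError, match="fewer than 2"):
        normfinder_stability(mat, bad)


def test_normfinder_rejects_missing_values(stability_fixture):
    mat, groups = stability_fixture
    mat = mat.copy()
    mat.iloc[0, 0] = np.nan
    with pytest.raises(NormalizationError):
        normfinder_stability(mat, groups)


# ---------------------------------------------------------------------------
# change scores / undetermined policy
# ---------------------------------------------------------------------------

def test_change_scores_drop_and_cap_policies(paired_sheet):
    import evmir.qpcr as q
    vals = pd.DataFrame(
        {f"{s}_{v}": [1.0 if v == "week12" else 0.0, np.nan if (s == "A" and v == "week12") else 2.0]
         for s in ("A", "B", "C", "D") for v in ("baseline", "week12")},
        index=["m1", "m2"])
    mat = q.NormalizedMatrix(vals, ["n"])
    fc = change_scores(mat, paired_sheet)
    m2 = fc.data[fc.data.feature_id == "m2"]
    assert "A" not in set(m2["subject_id"])          # dropped pair
    assert len(fc.data[fc.data.feature_id == "m1"]) == 4
    capped = change_scores(mat, paired_sheet, cap_imputation=-5.0)
    m2c = capped.data[capped.data.feature_id == "m2"].set_index("subject_id")
    assert m2c.loc["A", "delta"] == pytest.approx(-7.0)  # cap − baseline 2.0
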