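"""Synthetic cohorts, Ct tables, target databases, and clinical series.

Every generator plants known ground truth (``SyntheticTruth``) so each
pipeline stage can be scored for recovery without any external download.
The default cohort emulates the study design the pipeline targets: a
randomized placebo-controlled 2-arm × 2-visit paired design with 12
subjects per arm, a 42-miRNA panel plus spike-in and endogenous controls,
subject random intercepts, a planted treatment×visit effect on five
features, and treated-arm covariate drift (weight gain, hematocrit dilution).

Sign chain (documented prominently because it is the easiest place to err):
a planted ``signed_fc`` of −2.0 means abundance halves, i.e. the log2
abundance effect is −1, i.e. the Ct *increases* by one cycle in the treated
arm at week 12.  The −ΔCt normalization downstream restores the abundance
sign, so the recovered interaction estimate is −1.0 log2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical import FfaSeries
from .io import CtTable, InteractionTable, SampleSheet
from .qpcr import delta_from_signed_fc

__all__ = [
    "CohortConfig",
    "TargetDbConfig",
    "ClinicalConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_target_db",
    "generate_clinical",
    "toy_interaction_db",
    "DEFAULT_QUERY",
]

#: The five differentially expressed EV-miRNAs used as default planted
#: features and default overtargeting query.
DEFAULT_QUERY = [
    "hsa-miR-374b-5p",
    "hsa-miR-195-5p",
    "hsa-miR-20a-5p",
    "hsa-miR-7-5p",
    "hsa-miR-92a-3p",
]

STABLE_PAIR = ["hsa-miR-126-3p", "hsa-miR-30b-5p"]
SPIKE_ID = "cel-miR-39"
ENDOGENOUS_CONTROL = "hsa-miR-191-5p"


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to score recovery without re-reading config."""

    effects: dict[str, float] = field(default_factory=dict)   # feature → log2 abundance effect
    planted_genes: list[str] = field(default_factory=list)
    seed: int = 0
    config: dict = field(default_factory=dict)


@dataclass
class CohortConfig:
    """Study-condition defaults for the paired qPCR cohort generator.

    ``planted`` maps feature → signed fold change (|fc| ≥ 1); defaults to
    the five DE EV-miRNAs at −2.0.  SDs are log2-scale (cycles).
    """

    n_per_arm: int = 12
    n_target_features: int = 42
    planted: dict[str, float] = field(
        default_factory=lambda: {m: -2.0 for m in DEFAULT_QUERY})
    subject_sd: float = 0.5
    residual_sd: float = 0.4
    spike_sd: float = 0.5
    visit_effect: float = 0.0          # common week12 shift, cycles
    weight_gain_pio: float = 3.0       # kg over 12 weeks, treated arm
    hematocrit_drift_pio: float = -1.5 # pct, hemodilution in treated arm
    stable_normalizer_factor: float = 0.3  # noise shrink for miR-126/miR-30b
    covariate_confounding: float = 0.0 # cycles of Ct per kg weight change
    compartment: str = "plasma_EV"
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        for f, fc in self.planted.items():
            if abs(fc) < 1:
                raise ValueError(f"|signed_fc| must be >= 1 (feature {f})")
        for name in ("subject_sd", "residual_sd", "spike_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _feature_panel(cfg: CohortConfig) -> list[str]:
    panel = list(cfg.planted)
    for m in STABLE_PAIR:
        if m not in panel:
            panel.append(m)
    i = 1
    while len(panel) < cfg.n_target_features:
        name = f"hsa-miR-s{i:02d}"
        if name not in panel:
            panel.append(name)
        i += 1
    return panel[: cfg.n_target_features]


def generate_cohort(cfg: CohortConfig | None = None,
                    ) -> tuple[CtTable, SampleSheet, SyntheticTruth]:
    """Generate a paired 2-arm × 2-visit Ct table with planted effects.

    Model per feature f, subject i, visit v:

        Ct = μ_f + b_if + visit_effect·[v=week12] − δ_f·[arm=PIO, v=week12]
             + λ·Δweight + t_s + ε

    with subject intercepts b_if ~ N(0, subject_sd²) drawn independently per
    feature, technical per-sample shift t_s ~ N(0, spike_sd²) shared by all
    features of a sample (and fully captured by the spike-in row, so the
    spike adjustment removes it exactly), and ε ~ N(0, residual_sd²).
    δ_f is the planted log2 *abundance* effect (−1 for signed_fc −2.0); the
    Ct effect has opposite sign.  By default λ=0: covariates drift with the
    arm but do not confound the molecular truth.
    """
    cfg = cfg or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    panel = _feature_panel(cfg)
    features = panel + [ENDOGENOUS_CONTROL, SPIKE_ID]
    fclass = {f: "target" for f in panel}
    fclass[ENDOGENOUS_CONTROL] = "endogenous_control"
    fclass[SPIKE_ID] = "spike_in"

    subjects = [f"PIO{i:02d}" for i in range(1, cfg.n_per_arm + 1)] + \
               [f"PLA{i:02d}" for i in range(1, cfg.n_per_arm + 1)]
    arms = {s: s[:3] for s in subjects}

    mu = {f: rng.uniform(22.0, 30.0) for f in panel}
    mu[ENDOGENOUS_CONTROL] = 24.0
    low_noise = set(STABLE_PAIR) | {ENDOGENOUS_CONTROL}

    # covariates
    weight0 = {s: rng.normal(100.0, 15.0) for s in subjects}
    hct0 = {s: rng.normal(42.0, 3.0) for s in subjects}
    metformin = {s: int(rng.random() < 0.5) for s in subjects}
    weight = {}
    hct = {}
    for s in subjects:
        pio = arms[s] == "PIO"
        weight[(s, "baseline")] = weight0[s]
        hct[(s, "baseline")] = hct0[s]
        weight[(s, "week12")] = weight0[s] + rng.normal(
            cfg.weight_gain_pio if pio else 0.0, 1.0)
        hct[(s, "week12")] = hct0[s] + rng.normal(
            cfg.hematocrit_drift_pio if pio else 0.0, 0.8)

    b = {(s, f): rng.normal(0.0, cfg.subject_sd *
                            (cfg.stable_normalizer_factor if f in low_noise else 1.0))
         for s in subjects for f in panel + [ENDOGENOUS_CONTROL]}
    tshift = {(s, v): rng.normal(0.0, cfg.spike_sd)
              for s in subjects for v in ("baseline", "week12")}

    effects = {f: 0.0 for f in panel}
    for f, fc in cfg.planted.items():
        effects[f] = delta_from_signed_fc(fc)

    ct_rows, sheet_rows = [], []
    for s in subjects:
        for v in ("baseline", "week12"):
            sid = f"{s}_{v}"
            dweight = weight[(s, v)] - weight[(s, "baseline")]
            for f in panel + [ENDOGENOUS_CONTROL]:
                noise_scale = (cfg.stable_normalizer_factor
                               if f in low_noise else 1.0)
                ct = (mu[f] + b[(s, f)]
                      + (cfg.visit_effect if v == "week12" else 0.0)
                      - (effects.get(f, 0.0)
                         if (arms[s] == "PIO" and v == "week12") else 0.0)
                      + cfg.covariate_confounding * dweight
                      + tshift[(s, v)]
                      + rng.normal(0.0, cfg.residual_sd * noise_scale))
                ct_rows.append((sid, f, ct, False))
            ct_rows.append((sid, SPIKE_ID, 20.0 + tshift[(s, v)], False))
            sheet_rows.append((sid, s, arms[s], v, cfg.compartment,
                               weight[(s, v)], hct[(s, v)], metformin[s]))

    ct = CtTable(pd.DataFrame(ct_rows, columns=["sample_id", "feature_id",
                                                "ct", "undetermined"]), fclass)
    sheet = SampleSheet(pd.DataFrame(
        sheet_rows, columns=["sample_id", "subject_id", "arm", "visit",
                             "compartment", "weight_kg", "hematocrit_pct",
                             "metformin"]))
    truth = SyntheticTruth(effects=effects, seed=cfg.seed,
                           config={"n_per_arm": cfg.n_per_arm,
                                   "planted": dict(cfg.planted),
                                   "subject_sd": cfg.subject_sd,
                                   "residual_sd": cfg.residual_sd,
                                   "spike_sd": cfg.spike_sd})
    return ct, sheet, truth


# ---------------------------------------------------------------------------
# Target database generator
# ---------------------------------------------------------------------------

@dataclass
class TargetDbConfig:
    """Synthetic miRNA-target database with planted cooperative targeting."""

    n_mirnas: int = 200
    n_genes: int = 2000
    mean_degree: float = 30.0          # expected targets per miRNA
    n_planted_genes: int = 10
    planted_multiplicity: int = 4      # query miRNAs wired to each planted gene
    seed: int = 0

    def validate(self, query_size: int) -> None:
        if not (self.planted_multiplicity <= query_size <= self.n_mirnas):
            raise ValueError(
                "need planted_multiplicity <= query size <= n_mirnas "
                f"({self.planted_multiplicity} <= {query_size} <= {self.n_mirnas})")
        if self.n_planted_genes > self.n_genes:
            raise ValueError("more planted genes than genes")


def generate_target_db(cfg: TargetDbConfig | None = None,
                       query: list[str] | None = None,
                       ) -> tuple[InteractionTable, SyntheticTruth]:
    """Random bipartite target database with planted overtargeted genes.

    Background edges are drawn independently with probability
    ``mean_degree / n_genes``.  The last ``n_planted_genes`` genes are wired
    to exactly ``planted_multiplicity`` of the query miRNAs (background
    query→planted edges are cleared first, so each planted gene has exactly
    T = multiplicity under the query by construction).  All interactions
    carry reporter-assay/Western-blot evidence so the strong-evidence filter
    keeps them.
    """
    cfg = cfg or TargetDbConfig()
    query = list(query) if query is not None else list(DEFAULT_QUERY)
    cfg.validate(len(query))
    rng = np.random.default_rng(cfg.seed)

    mirnas = list(query) + [f"hsa-miR-b{i:04d}" for i in
                            range(cfg.n_mirnas - len(query))]
    genes = [f"GENE{i:04d}" for i in range(cfg.n_genes)]
    planted = genes[-cfg.n_planted_genes:] if cfg.n_planted_genes else []

    p = cfg.mean_degree / cfg.n_genes
    adj = rng.random((cfg.n_mirnas, cfg.n_genes)) < p
    if planted:
        gidx = np.arange(cfg.n_genes - cfg.n_planted_genes, cfg.n_genes)
        adj[: len(query), gidx.min():] = False  # clear query→planted background
        for g in gidx:
            chosen = rng.choice(len(query), size=cfg.planted_multiplicity,
                                replace=False)
            adj[chosen, g] = True

    mi, gi = np.nonzero(adj)
    data = pd.DataFrame({
        "mirna_id": [mirnas[i] for i in mi],
        "gene_symbol": [genes[j] for j in gi],
        "support_type": "Functional MTI",
        "evidence": [["Luciferase reporter assay", "Western blot"]] * len(mi),
        "pmids": [[]] * len(mi),
    })
    db = InteractionTable(data, strong_only=True, source="synthetic")
    truth = SyntheticTruth(planted_genes=list(planted), seed=cfg.seed,
                           config={"n_mirnas": cfg.n_mirnas,
                                   "n_genes": cfg.n_genes,
                                   "mean_degree": cfg.mean_degree,
                                   "planted_multiplicity": cfg.planted_multiplicity,
                                   "query": query})
    return db, truth


def toy_interaction_db() -> InteractionTable:
    """Deterministic 6-miRNA × 8-gene fixture used by the enumeration oracle."""
    edges = {
        "miR-t1": ["G1", "G2", "G3", "G4"],
        "miR-t2": ["G1", "G2", "G5"],
        "miR-t3": ["G2", "G3", "G6"],
        "miR-t4": ["G4", "G5", "G7"],
        "miR-t5": ["G6", "G7", "G8"],
        "miR-t6": ["G1", "G8"],
    }
    rows = [(m, g, "Functional MTI", ["Luciferase reporter assay"], [])
            for m, targets in edges.items() for g in targets]
    return InteractionTable(
        pd.DataFrame(rows, columns=["mirna_id", "gene_symbol", "support_type",
                                    "evidence", "pmids"]),
        strong_only=True, source="toy")


# ---------------------------------------------------------------------------
# Clinical series generator
# ---------------------------------------------------------------------------

@dataclass
class ClinicalConfig:
    """Exponential-decay FFA curves and fasting FFA/insulin tables."""

    n_per_arm: int = 12
    decay_rate: float = 0.02           # per minute → K_FFA = 2.0 %/min
    rate_improvement_pio: float = 0.005
    noise_sd: float = 0.0              # multiplicative log-scale noise
    ffa0: float = 0.6                  # mmol/L at t=0
    times: tuple[float, ...] = (0, 5, 10, 19, 25, 30, 40, 50, 60)
    seed: int = 0


def generate_clinical(cfg: ClinicalConfig | None = None,
                      ) -> tuple[dict[tuple[str, str], FfaSeries], pd.DataFrame]:
    """FFA time courses and fasting tables per subject-visit.

    Returns ``(curves, fasting)`` where ``curves`` maps (subject, visit) to
    an :class:`FfaSeries` and ``fasting`` has columns subject_id, visit,
    ffa_fasting, insulin_fasting.
    """
    cfg = cfg or ClinicalConfig()
    rng = np.random.default_rng(cfg.seed)
    subjects = [f"PIO{i:02d}" for i in range(1, cfg.n_per_arm + 1)] + \
               [f"PLA{i:02d}" for i in range(1, cfg.n_per_arm + 1)]
    t = np.asarray(cfg.times, dtype=float)
    curves: dict[tuple[str, str], FfaSeries] = {}
    fasting_rows = []
    for s in subjects:
        pio = s.startswith("PIO")
        for v in ("baseline", "week12"):
            rate = cfg.decay_rate + (cfg.rate_improvement_pio
                                     if (pio and v == "week12") else 0.0)
            ffa = cfg.ffa0 * np.exp(-rate * t)
            if cfg.noise_sd > 0:
                ffa = ffa * np.exp(rng.normal(0.0, cfg.noise_sd, size=t.shape))
            curves[(s, v)] = FfaSeries(t, ffa)
            f0 = max(rng.normal(0.55, 0.1), 0.05)
            ins = max(rng.normal(80.0, 20.0), 5.0)
            if pio and v == "week12":
                f0 *= 0.85
                ins *= 0.8
            fasting_rows.append((s, v, f0, ins))
    fasting = pd.DataFrame(fasting_rows, columns=["subject_id", "visit",
                                                  "ffa_fasting",
                                                  "insulin_fasting"])
    return curves, fasting
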