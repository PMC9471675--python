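"""End-to-end orchestration from one YAML config with provenance logging.

Stages: normalize → fold filter → differential abundance → partial
correlations → overtargeting → enrichment.  Every output is TSV; a JSON
manifest records input hashes, the config echo, the seed, and the SHA-256
of every stage output so reruns can be verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de import ModelSpec, fit_mixed_de, partial_correlation_table
from .io import (CtTable, SampleSheet, read_ct_table, read_gmt,
                 read_interactions, read_sample_sheet, write_network)
from .network import enrich, overtarget_test
from .qpcr import change_scores, fold_filter, normalize, normfinder_stability, spike_adjust

log = logging.getLogger("evmir")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Schema-validated run configuration.

    Either ``ct_path``/``sheet_path`` point at input files, or
    ``synthetic: true`` generates the default cohort.  Every default is
    echoed into the manifest.
    """

    out_dir: str = "evmir_out"
    seed: int = 0
    synthetic: bool = False
    ct_path: str | None = None
    sheet_path: str | None = None
    interactions_path: str | None = None
    gmt_path: str | None = None
    compartment: str = "plasma_EV"
    spike_id: str = "cel-miR-39"
    normalizers: list[str] | None = None   # None → NormFinder best pair
    fold_threshold: float = 1.5
    covariates: list[str] | None = None
    metformin_refit: bool = True
    overtarget_B: int = 10_000
    overtarget_k_min: int = 2
    overtarget_null: str = "degree_matched"
    overtarget_alpha: float = 0.05
    query_mirnas: list[str] | None = None  # None → features passing the filter
    stages: list[str] = field(default_factory=lambda: [
        "normalize", "filter", "de", "correlate", "overtarget", "enrich"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.synthetic:
            for name in ("ct_path", "sheet_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"config requires {name} (or synthetic: true)")
                if not Path(p).exists():
                    raise ValueError(f"{name} does not exist: {p}")
        bad = set(self.stages) - {"normalize", "filter", "de", "correlate",
                                  "overtarget", "enrich"}
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if "overtarget" in self.stages and not self.synthetic \
                and self.interactions_path is None:
            raise ValueError("overtarget stage requires interactions_path")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Any stage error aborts with the stage name attached.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "config": {k: v for k, v in vars(cfg).items()},
                      "inputs": {}, "outputs": {}, "stages": []}
    stage = "load"
    try:
        if cfg.synthetic:
            from .simulate import CohortConfig, TargetDbConfig, generate_cohort, generate_target_db
            ct, sheet, truth = generate_cohort(CohortConfig(seed=cfg.seed))
            db = None
            if "overtarget" in cfg.stages:
                planted_mirnas = [f for f, e in truth.effects.items() if e != 0.0]
                db, _ = generate_target_db(
                    TargetDbConfig(seed=cfg.seed),
                    query=planted_mirnas if cfg.query_mirnas is None else cfg.query_mirnas)
        else:
            ct = read_ct_table(cfg.ct_path)
            sheet = read_sample_sheet(cfg.sheet_path)
            manifest["inputs"]["ct"] = _sha256(Path(cfg.ct_path))
            manifest["inputs"]["sheet"] = _sha256(Path(cfg.sheet_path))
            db = (read_interactions(cfg.interactions_path)
                  if cfg.interactions_path else None)
            if cfg.interactions_path:
                manifest["inputs"]["interactions"] = _sha256(Path(cfg.interactions_path))

        mat = None
        if "normalize" in cfg.stages:
            stage = "normalize"
            spikes = ct.features_of_class("spike_in")
            adj = spike_adjust(ct, cfg.spike_id) if cfg.spike_id in spikes else ct
            norms = cfg.normalizers
            if norms is None:
                wide = adj.data.pivot(index="feature_id", columns="sample_id",
                                      values="ct")
                targets = [f for f in adj.features_of_class("target")
                           if f in wide.index and not wide.loc[f].isna().any()]
                groups = sheet.resolve(list(wide.columns)).set_index("sample_id")["arm"]
                rank = normfinder_stability(wide.loc[targets], groups)
                norms = list(rank.best_pair)
                log.info("NormFinder best pair: %s (stability %.4f)",
                         norms, rank.pair_stability)
            mat = normalize(adj, norms, spike_adjusted=cfg.spike_id in spikes)
            mat.values = mat.values.drop(index=norms, errors="ignore")
            path = out / "normalized.tsv"
            mat.to_tsv(path)
            manifest["outputs"]["normalized"] = _sha256(path)
            manifest["stages"].append("normalize")
            manifest["normalizers"] = norms

        fc = None
        if "filter" in cfg.stages and mat is not None:
            stage = "filter"
            fc_all = change_scores(mat, sheet, compartment=cfg.compartment)
            fc, dropped = fold_filter(fc_all, cfg.fold_threshold)
            path = out / "fold_changes.tsv"
            fc.data.to_csv(path, sep="\t", index=False)
            (out / "filtered_out.tsv").write_text(
                dropped.to_csv(sep="\t", index=False))
            manifest["outputs"]["fold_changes"] = _sha256(path)
            manifest["outputs"]["filtered_out"] = _sha256(out / "filtered_out.tsv")
            manifest["stages"].append("filter")

        de = None
        if "de" in cfg.stages and mat is not None:
            stage = "de"
            keep = (sorted(fc.data["feature_id"].unique())
                    if fc is not None else list(mat.values.index))
            spec = ModelSpec(compartment=cfg.compartment,
                             covariates=cfg.covariates)
            de = fit_mixed_de(mat, sheet, spec, features=keep)
            path = out / "de_results.tsv"
            de.table.to_csv(path, sep="\t", index=False)
            manifest["outputs"]["de_results"] = _sha256(path)
            manifest["stages"].append("de")
            if cfg.metformin_refit:
                spec_m = ModelSpec(compartment=cfg.compartment,
                                   covariates=cfg.covariates, metformin=True)
                de_m = fit_mixed_de(mat, sheet, spec_m, features=keep)
                pm = out / "de_results_metformin.tsv"
                de_m.table.to_csv(pm, sep="\t", index=False)
                manifest["outputs"]["de_results_metformin"] = _sha256(pm)

        if "correlate" in cfg.stages and mat is not None:
            stage = "correlate"
            fc_all = change_scores(mat, sheet, compartment=cfg.compartment)
            wide = fc_all.data.pivot(index="subject_id", columns="feature_id",
                                     values="delta")
            meta = sheet.data[sheet.data["compartment"] == cfg.compartment]
            spec = ModelSpec(compartment=cfg.compartment, covariates=cfg.covariates)
            covs = spec.resolved_covariates()
            for c in covs:
                piv = meta.pivot(index="subject_id", columns="visit", values=c)
                wide[c] = piv["week12"] - piv["baseline"]
            feats = (sorted(fc.data["feature_id"].unique()) if fc is not None
                     else [c for c in wide.columns if c not in covs])
            pairs = [(a, b) for i, a in enumerate(feats) for b in feats[i + 1:]]
            pc = partial_correlation_table(wide.reset_index(), pairs, covs)
            path = out / "partial_correlations.tsv"
            pc.to_csv(path, sep="\t", index=False)
            manifest["outputs"]["partial_correlations"] = _sha256(path)
            manifest["stages"].append("correlate")

        ot = None
        if "overtarget" in cfg.stages and db is not None:
            stage = "overtarget"
            query = cfg.query_mirnas
            if query is None:
                query = (sorted(fc.data["feature_id"].unique()) if fc is not None
                         else sorted(set(db.data["mirna_id"])))
            ot = overtarget_test(db, query, B=cfg.overtarget_B,
                                 k_min=cfg.overtarget_k_min,
                                 null_model=cfg.overtarget_null,
                                 alpha=cfg.overtarget_alpha, seed=cfg.seed)
            path = out / "overtarget_result.tsv"
            with open(path, "w") as fh:
                fh.write(f"# null_model: {ot.null_model}\tstatistic: {ot.statistic}"
                         f"\tB: {ot.B}\tk_min: {ot.k_min}\tseed: {ot.seed}\n")
                fh.write(f"# S_observed: {ot.s_observed}"
                         f"\tp_simulation: {ot.p_simulation:.6g}\n")
                ot.per_gene.to_csv(fh, sep="\t", index=False)
            write_network(ot.network, out / "network.graphml", "graphml")
            write_network(ot.network, out / "network.sif", "sif")
            manifest["outputs"]["overtarget_result"] = _sha256(path)
            manifest["outputs"]["network_graphml"] = _sha256(out / "network.graphml")
            manifest["outputs"]["network_sif"] = _sha256(out / "network.sif")
            manifest["stages"].append("overtarget")
            manifest["p_simulation"] = ot.p_simulation

        if "enrich" in cfg.stages and ot is not None:
            stage = "enrich"
            if cfg.gmt_path:
                sets = read_gmt(cfg.gmt_path)
                manifest["inputs"]["gmt"] = _sha256(Path(cfg.gmt_path))
            else:
                sets = _default_gene_sets(db, seed=cfg.seed)
            universe = sorted(set(db.data["gene_symbol"]))
            res = enrich(ot.overtargeted_genes, universe, sets)
            path = out / "enrichment.tsv"
            res.table.to_csv(path, sep="\t", index=False)
            manifest["outputs"]["enrichment"] = _sha256(path)
            manifest["stages"].append("enrich")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def _default_gene_sets(db, *, seed: int, n_sets: int = 5, size: int = 50):
    """Synthetic gene sets over the database universe (used when no GMT is
    supplied with a synthetic run, so the enrich stage stays exercised)."""
    import numpy as np

    from .io import GeneSetCollection
    rng = np.random.default_rng(seed + 101)
    genes = sorted(set(db.data["gene_symbol"]))
    sets = {}
    for i in range(n_sets):
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        sets[f"SYNTH_SET_{i + 1}"] = (f"synthetic set {i + 1}",
                                      frozenset(map(str, members)))
    return GeneSetCollection(sets)
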