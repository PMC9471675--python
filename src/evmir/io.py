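"""Readers and writers for the external tables and graphs the pipeline touches.

Formats
-------
* Ct tables: long CSV/TSV with columns ``sample_id``, ``feature_id``, ``ct``.
  The literal token ``Undetermined`` (any case) marks a failed amplification
  and is carried as an explicit flag, never coerced to a number.
* Sample sheets: CSV with subject/arm/visit/compartment plus free-form
  numeric covariate columns (e.g. ``weight_kg``, ``hematocrit_pct``,
  ``metformin``).
* Validated miRNA-target interactions in the miRTarBase SE_WR dialect
  (columns ``miRNA``, ``Target Gene``, ``Support Type``, ``Experiments``),
  as TSV/CSV or .xlsx.
* GMT gene-set files; GraphML / SIF network export for Cytoscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "UNDETERMINED",
    "CtTable",
    "SampleSheet",
    "InteractionTable",
    "GeneSetCollection",
    "read_ct_table",
    "write_ct_table",
    "read_sample_sheet",
    "read_interactions",
    "read_gmt",
    "write_network",
    "normalize_mirna_id",
]

#: Sentinel token for a Ct that never crossed threshold.
UNDETERMINED = "Undetermined"

CT_MAX = 45.0  # accepted instrument ceiling on input

ARMS = ("PIO", "PLA")
VISITS = ("baseline", "week12")
COMPARTMENTS = ("plasma_EV", "adipose")

FEATURE_CLASSES = ("target", "spike_in", "endogenous_control")


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """Long-format cycle-threshold measurements.

    ``data`` holds one row per (sample, feature) with columns ``sample_id``,
    ``feature_id``, ``ct`` (float, NaN when undetermined) and ``undetermined``
    (bool).  ``feature_class`` maps each feature to one of
    ``target``/``spike_in``/``endogenous_control``.
    """

    data: pd.DataFrame
    feature_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        req = {"sample_id", "feature_id", "ct", "undetermined"}
        missing = req - set(self.data.columns)
        if missing:
            raise FormatError(f"CtTable missing columns: {sorted(missing)}")
        dup = self.data.duplicated(["sample_id", "feature_id"], keep=False)
        if dup.any():
            offenders = (
                self.data.loc[dup, ["sample_id", "feature_id"]]
                .drop_duplicates()
                .apply(lambda r: f"{r.sample_id}/{r.feature_id}", axis=1)
                .tolist()
            )
            raise FormatError(
                f"duplicate (sample, feature) pairs: {', '.join(offenders)}"
            )
        det = self.data.loc[~self.data["undetermined"], "ct"]
        bad = det[~((det > 0) & (det <= CT_MAX))]
        if len(bad) or det.isna().any():
            raise FormatError(
                f"determined Ct values must be finite and in (0, {CT_MAX}]; "
                f"offending rows at index {list(bad.index[:5])}"
            )
        for fid, cls in self.feature_class.items():
            if cls not in FEATURE_CLASSES:
                raise FormatError(f"unknown feature class {cls!r} for {fid!r}")

    # convenience -----------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    @property
    def features(self) -> list[str]:
        return sorted(self.data["feature_id"].unique())

    def features_of_class(self, cls: str) -> list[str]:
        return sorted(f for f, c in self.feature_class.items() if c == cls)

    def copy(self) -> "CtTable":
        return CtTable(self.data.copy(), dict(self.feature_class))


def read_ct_table(path: str | Path, feature_class_map: dict[str, str] | None = None,
                  *, exhaustive: bool = False) -> CtTable:
    """Read a long-format Ct table (CSV or TSV, sniffed by extension).

    ``Undetermined`` (case-insensitive) in the ``ct`` column becomes the
    undetermined flag.  With ``exhaustive=True`` every feature_id must appear
    in ``feature_class_map``; otherwise unmapped features default to
    ``target``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "feature_id": str},
                     comment="#")
    for col in ("sample_id", "feature_id", "ct"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    raw = df["ct"].astype(str).str.strip()
    undet = raw.str.lower().eq(UNDETERMINED.lower())
    ct = pd.to_numeric(raw.mask(undet), errors="raise")
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "feature_id": df["feature_id"],
            "ct": ct,
            "undetermined": undet,
        }
    )
    fcm = dict(feature_class_map or {})
    unknown = sorted(set(out["feature_id"]) - set(fcm))
    if exhaustive and unknown:
        raise FormatError(f"{path}: features missing from feature_class_map: {unknown}")
    for fid in unknown:
        fcm[fid] = "target"
    return CtTable(out, fcm)


def write_ct_table(ct: CtTable, path: str | Path) -> None:
    """Write a Ct table back to CSV/TSV; undetermined wells round-trip."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = ct.data.copy()
    out = df["ct"].map(lambda v: f"{v:.6g}" if pd.notna(v) else "")
    out = out.mask(df["undetermined"], UNDETERMINED)
    pd.DataFrame(
        {"sample_id": df["sample_id"], "feature_id": df["feature_id"], "ct": out}
    ).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Paired-design metadata: one row per sample.

    Columns ``sample_id``, ``subject_id``, ``arm`` (PIO/PLA), ``visit``
    (baseline/week12), ``compartment`` plus numeric covariates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        req = {"sample_id", "subject_id", "arm", "visit", "compartment"}
        missing = req - set(self.data.columns)
        if missing:
            raise FormatError(f"SampleSheet missing columns: {sorted(missing)}")
        bad_arm = set(self.data["arm"]) - set(ARMS)
        if bad_arm:
            raise FormatError(f"unknown arm values: {sorted(bad_arm)}")
        bad_v = set(self.data["visit"]) - set(VISITS)
        if bad_v:
            raise FormatError(f"unknown visit values: {sorted(bad_v)}")
        bad_c = set(self.data["compartment"]) - set(COMPARTMENTS)
        if bad_c:
            raise FormatError(f"unknown compartment values: {sorted(bad_c)}")
        if self.data["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in sample sheet")
        arms = self.data.groupby("subject_id")["arm"].nunique()
        if (arms > 1).any():
            raise FormatError(
                f"arm not constant within subject: {list(arms[arms > 1].index)}"
            )
        dup = self.data.duplicated(["subject_id", "visit", "compartment"], keep=False)
        if dup.any():
            raise FormatError(
                "more than one sample per (subject, visit, compartment): "
                f"{self.data.loc[dup, 'sample_id'].tolist()}"
            )

    @property
    def covariate_names(self) -> list[str]:
        meta = {"sample_id", "subject_id", "arm", "visit", "compartment"}
        return [c for c in self.data.columns if c not in meta]

    def resolve(self, sample_ids: list[str]) -> pd.DataFrame:
        """Rows for the given samples; error if any is unknown."""
        idx = self.data.set_index("sample_id")
        missing = sorted(set(sample_ids) - set(idx.index))
        if missing:
            raise FormatError(f"sample_ids absent from sample sheet: {missing}")
        return idx.loc[sample_ids].reset_index()


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "subject_id": str})
    return SampleSheet(df)


# ---------------------------------------------------------------------------
# miRNA identifiers
# ---------------------------------------------------------------------------

def normalize_mirna_id(name: str, *, strip_species_prefix: bool = True) -> str:
    """Canonicalize a mature miRNA name for matching across panels.

    By default strips the species prefix (``hsa-``, ``cel-``, ...) so that
    user panels written as ``miR-195-5p`` match database entries written as
    ``hsa-miR-195-5p``.  Arm suffixes (``-5p``/``-3p``) are preserved; their
    harmonization across database releases is a matter of curation, not
    string munging, so the matcher does not guess.
    """
    name = name.strip()
    if strip_species_prefix:
        parts = name.split("-", 1)
        if (len(parts) == 2 and len(parts[0]) == 3 and parts[0].isalpha()
                and parts[0].islower() and parts[0].lower() not in {"mir", "let"}):
            name = parts[1]
    return name


# ---------------------------------------------------------------------------
# Interaction tables (miRTarBase SE_WR dialect)
# ---------------------------------------------------------------------------

@dataclass
class InteractionTable:
    """Validated miRNA→gene interactions.

    ``data`` columns: ``mirna_id``, ``gene_symbol``, ``support_type``,
    ``evidence`` (list of experiment strings), ``pmids`` (list of strings).
    Gene symbols are uppercased; one row per (mirna, gene).
    """

    data: pd.DataFrame
    strong_only: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if self.data["mirna_id"].eq("").any():
            raise FormatError("empty mirna_id in interaction table")
        if self.data.duplicated(["mirna_id", "gene_symbol"]).any():
            raise FormatError("duplicate (mirna, gene) after collapsing")

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.data["mirna_id"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene_symbol"].unique())


#: Case-insensitive substrings marking strong (functional) evidence.
STRONG_EVIDENCE_TOKENS = ("reporter", "western")

_MIRTARBASE_COLS = {
    "mirna": "miRNA",
    "gene": "Target Gene",
    "support": "Support Type",
    "experiments": "Experiments",
}


def _is_strong(experiments: list[str], tokens: tuple[str, ...]) -> bool:
    joined = " ".join(experiments).lower()
    return any(t in joined for t in tokens)


def read_interactions(path: str | Path, strong_only: bool = True, *,
                      evidence_tokens: tuple[str, ...] = STRONG_EVIDENCE_TOKENS,
                      strip_species_prefix: bool = False) -> InteractionTable:
    """Read a miRTarBase SE_WR-style table (TSV/CSV/xlsx).

    With ``strong_only`` a record is kept iff its Experiments field contains
    a reporter-assay or Western-blot token (case-insensitive substring).
    Duplicate (miRNA, gene) records are collapsed with evidence and PMIDs
    merged.  Legacy binary ``.xls`` is not supported; convert to .xlsx or TSV.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        df = pd.read_excel(path, dtype=str)
    elif path.suffix.lower() == ".xls":
        raise FormatError(
            f"{path}: legacy binary .xls is not supported; convert to .xlsx or TSV"
        )
    else:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
    for key in ("mirna", "gene", "experiments"):
        col = _MIRTARBASE_COLS[key]
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    support_col = _MIRTARBASE_COLS["support"]
    pmid_col = next(
        (c for c in df.columns if c.lower().replace(" ", "") in
         {"references(pmid)", "pmid", "references"}), None)

    records: dict[tuple[str, str], dict] = {}
    for _, row in df.iterrows():
        mirna = normalize_mirna_id(str(row[_MIRTARBASE_COLS["mirna"]]),
                                   strip_species_prefix=strip_species_prefix)
        gene = str(row[_MIRTARBASE_COLS["gene"]]).strip().upper()
        if not mirna or mirna.lower() == "nan":
            raise FormatError(f"{path}: empty miRNA identifier in row {_}")
        evid = [e.strip() for e in
                str(row[_MIRTARBASE_COLS["experiments"]]).split("//") if e.strip()]
        support = str(row[support_col]).strip() if support_col in df.columns else ""
        pmids = []
        if pmid_col is not None and pd.notna(row[pmid_col]):
            pmids = [p.strip() for p in str(row[pmid_col]).split("//") if p.strip()]
        key = (mirna, gene)
        if key in records:
            rec = records[key]
            rec["evidence"] += [e for e in evid if e not in rec["evidence"]]
            rec["pmids"] += [p for p in pmids if p not in rec["pmids"]]
        else:
            records[key] = {
                "mirna_id": mirna, "gene_symbol": gene,
                "support_type": support, "evidence": evid, "pmids": pmids,
            }
    rows = list(records.values())
    if strong_only:
        rows = [r for r in rows if _is_strong(r["evidence"], evidence_tokens)]
    data = pd.DataFrame(rows, columns=["mirna_id", "gene_symbol", "support_type",
                                       "evidence", "pmids"])
    return InteractionTable(data, strong_only=strong_only, source=str(path))


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Mapping set name → (description, uppercased member symbols)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: tab-separated name, description, members...

    Empty gene sets are skipped with a warning.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}: malformed GMT line: {line[:60]!r}")
        name, desc = parts[0], parts[1]
        members = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
        if not members:
            warnings.warn(f"empty gene set {name!r} skipped", stacklevel=2)
            continue
        sets[name] = (desc, members)
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def write_network(net, path: str | Path, fmt: str = "graphml") -> None:
    """Export a bipartite miRNA→gene network for Cytoscape.

    SIF rows use the relation token ``targets``; GraphML carries node type
    (miRNA vs gene) and any overtarget flags as node attributes.  ``net`` is
    a :class:`~evmir.network.BipartiteNetwork`.
    """
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for mirna, gene in sorted(net.edges):
                fh.write(f"{mirna}\ttargets\t{gene}\n")
        return
    if fmt != "graphml":
        raise ValueError(f"unknown network format {fmt!r}")
    g = nx.DiGraph()
    for m in net.mirna_nodes:
        g.add_node(m, node_type="miRNA")
    for gene in net.gene_nodes:
        g.add_node(gene, node_type="gene",
                   overtargeted=bool(gene in getattr(net, "overtargeted", ())))
    g.add_edges_from(net.edges, relation="targets")
    nx.write_graphml(g, path)
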