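"""Tabular input/output and probe-level preprocessing.

Conventions used across the package:

* An **expression matrix** is a :class:`pandas.DataFrame` of log2-scale
  values with gene identifiers as the row index and sample identifiers as
  columns.  Values must be finite; missing values are rejected.
* A **sample table** is a DataFrame with columns ``sample_id`` and ``stage``
  where stage is one of ``normal``, ``early``, ``advanced`` (case-insensitive
  on input, stored lower-case).
* A **gene annotation** is a DataFrame indexed by ``gene_id`` with columns
  ``symbol``, ``biotype`` (``lncRNA`` / ``mRNA`` / ``other``), ``chrom``,
  ``start``, ``end``.  Coordinates are 1-based inclusive.

All files are plain TSV: UTF-8, tab separated, ``.`` decimal, no quoting.
Gene sets use the MSigDB GMT dialect (set name, description, then member
symbols, one set per line); the description field is reused to carry the
set category (``fibrosis`` / ``pathway`` / ``other``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("normal", "early", "advanced")
BIOTYPES = ("lncRNA", "mRNA", "other")
SET_CATEGORIES = ("fibrosis", "pathway", "other")


class StagenetError(Exception):
    """Base class for errors raised by this package."""


class NoMappableProbesError(StagenetError):
    """No probe in the matrix maps uniquely to a gene."""


class FormatError(StagenetError):
    """A file does not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    name: str
    category: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    """Named gene sets, each tagged with a category."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dupes = {n for n in names if names.count(n) > 1}
            raise ValueError(f"duplicate set names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def by_category(self, category: str) -> list[GeneSet]:
        return [s for s in self.sets if s.category == category]


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def validate_expression(em: pd.DataFrame) -> None:
    """Check the expression-matrix invariants (unique ids, finite values)."""
    if em.index.duplicated().any():
        dupes = em.index[em.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids: {dupes}")
    if em.columns.duplicated().any():
        raise FormatError("duplicate sample ids")
    values = em.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = em.index[~np.isfinite(values).all(axis=1)].tolist()
        raise FormatError(f"non-finite values in genes: {bad[:10]}")


def validate_samples(st: pd.DataFrame) -> None:
    if st["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in metadata")
    bad = set(st["stage"]) - set(STAGES)
    if bad:
        raise FormatError(f"unknown stage labels: {sorted(bad)}")


def stage_samples(st: pd.DataFrame, stage: str) -> list[str]:
    """Sample ids belonging to one stage (or ``'ipf'`` = early + advanced)."""
    if stage == "ipf":
        keep = st["stage"].isin(["early", "advanced"])
    elif stage == "all":
        keep = pd.Series(True, index=st.index)
    else:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        keep = st["stage"] == stage
    return st.loc[keep, "sample_id"].tolist()


# ---------------------------------------------------------------------------
# probe collapsing
# ---------------------------------------------------------------------------

def collapse_probes(
    probes: pd.DataFrame,
    probe_gene_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Collapse a probe-level matrix to a gene-level expression matrix.

    Probes that map to no gene, or ambiguously to two or more genes, are
    discarded.  Each gene's value per sample is the arithmetic mean of its
    surviving probes, taken directly on the log2 scale.

    Parameters
    ----------
    probes
        Probe-level log2 matrix (probe rows, sample columns).
    probe_gene_map
        Mapping ``probe_id -> iterable of gene ids`` (0, 1 or many).  Probes
        absent from the mapping are treated as unmapped.

    Raises
    ------
    NoMappableProbesError
        If no probe survives the uniqueness filter.
    """
    validate_expression(probes)
    assign: dict[str, str] = {}
    for probe in probes.index:
        genes = set(probe_gene_map.get(probe, ()))
        if len(genes) == 1:
            assign[probe] = next(iter(genes))
    if not assign:
        raise NoMappableProbesError("no probe maps uniquely to a gene")
    kept = probes.loc[list(assign)]
    gene_of = pd.Series({p: assign[p] for p in kept.index})
    collapsed = kept.groupby(gene_of).mean()
    collapsed.index.name = probes.index.name or "gene_id"
    return collapsed


# ---------------------------------------------------------------------------
# expression matrix + metadata TSV
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path, metadata_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an expression TSV and its companion sample-metadata TSV.

    The metadata must cover every sample present in the matrix; its stage
    labels are case-folded.  Sample order follows the matrix columns.
    """
    em = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression(em)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if not {"sample_id", "stage"} <= set(meta.columns):
        raise FormatError("metadata must have 'sample_id' and 'stage' columns")
    meta = meta.copy()
    meta["stage"] = meta["stage"].str.strip().str.lower()
    for row in meta.itertuples():
        if row.stage not in STAGES:
            raise FormatError(
                f"unknown stage {row.stage!r} for sample {row.sample_id!r}"
            )
    validate_samples(meta)
    missing = set(em.columns) - set(meta["sample_id"])
    if missing:
        raise FormatError(f"samples missing from metadata: {sorted(missing)}")
    meta = meta.set_index("sample_id").loc[list(em.columns)].reset_index()
    return em, meta[["sample_id", "stage"]]


def write_expression(
    em: pd.DataFrame,
    st: pd.DataFrame,
    path: str | Path,
    metadata_path: str | Path,
) -> None:
    validate_expression(em)
    validate_samples(st)
    em.to_csv(path, sep="\t")
    st[["sample_id", "stage"]].to_csv(metadata_path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "symbol", "biotype", "chrom", "start", "end"}
    if not required <= set(ann.columns):
        raise FormatError(f"annotation must have columns {sorted(required)}")
    ann = ann.set_index("gene_id")
    validate_annotation(ann)
    return ann


def validate_annotation(ann: pd.DataFrame) -> None:
    if ann.index.duplicated().any():
        raise FormatError("duplicate gene ids in annotation")
    bad = set(ann["biotype"]) - set(BIOTYPES)
    if bad:
        raise FormatError(f"unknown biotypes: {sorted(bad)}")
    if (ann["start"] > ann["end"]).any():
        raise FormatError("annotation rows with start > end")
    if (ann["start"] < 0).any():
        raise FormatError("negative coordinates")


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(ann)
    ann.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    One set per line: name, description, then member symbols, tab separated.
    Duplicate members within a line are collapsed; a duplicate set name or a
    line with fewer than three fields is an error.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            category = desc if desc in SET_CATEGORIES else "other"
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets.append(GeneSet(name=name, category=category, members=members))
    return GeneSetCollection(sets=sets)


def write_gene_sets(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in gsc:
            fh.write("\t".join([s.name, s.category, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# network export (Cytoscape-importable edge/node tables)
# ---------------------------------------------------------------------------

def write_network(
    net,
    outdir: str | Path,
    annotation: pd.DataFrame | None = None,
    prefix: str | None = None,
    sif: bool = False,
) -> dict[str, Path]:
    """Write a co-expression network as edge / node / chromosome-link TSVs.

    The edge table (source, target, r, p, sign, stage) and node table
    (gene_id, role, degree, chrom) import directly into Cytoscape.  When an
    annotation is given a link table pairing source and target chromosomes is
    emitted as well; nodes missing from the annotation get chrom ``NA`` with
    a logged warning.  Setting ``sif`` additionally writes a SIF file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or net.stage_tag
    paths: dict[str, Path] = {}

    edges = net.edges.copy()
    edges.insert(len(edges.columns), "stage", net.stage_tag)
    edges = edges.rename(columns={"lnc": "source", "mrna": "target"})
    paths["edges"] = outdir / f"{prefix}_edges.tsv"
    edges.to_csv(paths["edges"], sep="\t", index=False)

    degrees = net.degrees()
    chrom = {}
    if annotation is not None:
        chrom = annotation["chrom"].to_dict()
    rows = []
    for node, role in sorted(net.nodes.items()):
        if annotation is not None and node not in chrom:
            logger.warning("node %s missing from annotation", node)
        rows.append(
            {
                "gene_id": node,
                "role": role,
                "degree": degrees.get(node, 0),
                "chrom": chrom.get(node, "NA"),
            }
        )
    node_df = pd.DataFrame(rows, columns=["gene_id", "role", "degree", "chrom"])
    paths["nodes"] = outdir / f"{prefix}_nodes.tsv"
    node_df.to_csv(paths["nodes"], sep="\t", index=False)

    if annotation is not None:
        link = pd.DataFrame(
            {
                "source_chrom": [chrom.get(s, "NA") for s in edges["source"]],
                "target_chrom": [chrom.get(t, "NA") for t in edges["target"]],
            }
        )
        paths["links"] = outdir / f"{prefix}_chrom_links.tsv"
        link.to_csv(paths["links"], sep="\t", index=False)

    if sif:
        paths["sif"] = outdir / f"{prefix}.sif"
        with open(paths["sif"], "w", encoding="utf-8") as fh:
            for row in edges.itertuples():
                fh.write(f"{row.source}\tcoexp\t{row.target}\n")
    return paths
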