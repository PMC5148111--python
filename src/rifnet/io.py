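"""Readers and writers for every external file the pipeline touches.

All tabular I/O is tab-separated UTF-8 text with "." as the decimal mark,
matching common microarray community practice.  Probe ids are the primary
keys end to end; gene symbols attach only at reporting time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Dataset",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "read_expression",
    "read_flags",
    "read_design",
    "read_probe_annotation",
    "read_tr_list",
    "write_tr_list",
    "read_gmt",
    "write_gmt",
    "write_network",
    "read_sif",
    "resolve_group",
    "group_samples",
    "load_config",
    "run_metadata",
]

PRESENT = "P"
ABSENT = "A"


class DatasetError(ValueError):
    """Raised when an input file or in-memory dataset fails validation."""


@dataclass
class Dataset:
    """Probe × sample expression with detection flags and a 2×2 design.

    Attributes
    ----------
    expression : pandas.DataFrame
        log2 intensities, probes in rows, samples in columns.
    flags : pandas.DataFrame
        Detection calls over {"P", "A"}, same shape/ordering as expression.
    design : pandas.DataFrame
        One row per sample (index = sample id) with ``breed`` and
        ``altitude`` columns, each with exactly two levels.
    probe_annotation : pandas.Series or None
        probe id → gene symbol; probes may be missing (unannotated).
    """

    expression: pd.DataFrame
    flags: pd.DataFrame
    design: pd.DataFrame
    probe_annotation: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        expr, flags, design = self.expression, self.flags, self.design
        if expr.index.duplicated().any():
            dups = expr.index[expr.index.duplicated()].tolist()[:5]
            raise DatasetError(f"duplicate probe ids in expression matrix: {dups}")
        if not expr.index.equals(flags.index) or not expr.columns.equals(flags.columns):
            raise DatasetError(
                "expression and flags must share identical probe and sample orderings"
            )
        bad = ~flags.isin([PRESENT, ABSENT])
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise DatasetError(
                f"invalid detection flag {flags.iat[r, c]!r} at probe "
                f"{flags.index[r]!r}, sample {flags.columns[c]!r} (expected P or A)"
            )
        for col in ("breed", "altitude"):
            if col not in design.columns:
                raise DatasetError(f"design table lacks required column {col!r}")
            levels = sorted(design[col].unique())
            if len(levels) != 2:
                raise DatasetError(
                    f"design factor {col!r} must have exactly 2 levels, got {levels}"
                )
        if design.index.duplicated().any():
            raise DatasetError("duplicate sample ids in design table")
        if set(design.index) != set(expr.columns) or len(design) != expr.shape[1]:
            missing = sorted(set(design.index) ^ set(expr.columns))
            raise DatasetError(
                f"design samples and matrix columns disagree; offending ids: {missing[:5]}"
            )
        if not np.issubdtype(expr.to_numpy().dtype, np.number):
            raise DatasetError("expression matrix is not numeric")

    @property
    def probes(self) -> pd.Index:
        return self.expression.index

    @property
    def samples(self) -> pd.Index:
        return self.expression.columns

    def gene_of(self, probe: str) -> str | None:
        if self.probe_annotation is None:
            return None
        return self.probe_annotation.get(probe)


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------

def _read_matrix(path: str | Path, *, numeric: bool) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if numeric:
        out = df.apply(pd.to_numeric, errors="coerce")
        bad = out.isna() & df.notna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise DatasetError(
                f"{path}: non-numeric value {df.iat[r, c]!r} at row "
                f"{df.index[r]!r}, column {df.columns[c]!r}"
            )
        if out.isna().to_numpy().any():
            r, c = np.argwhere(out.isna().to_numpy())[0]
            raise DatasetError(
                f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        return out
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a probes × samples log2 expression TSV (first column = probe id)."""
    return _read_matrix(path, numeric=True)


def read_flags(path: str | Path) -> pd.DataFrame:
    """Read a probes × samples detection-flag TSV with values P/A."""
    return _read_matrix(path, numeric=False)


def read_design(path: str | Path) -> pd.DataFrame:
    """Read the sample design TSV: columns sample, breed, altitude."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "breed", "altitude"}
    if not required.issubset(df.columns):
        raise DatasetError(f"{path}: design table needs columns {sorted(required)}")
    return df.set_index("sample")


def read_probe_annotation(path: str | Path) -> pd.Series:
    """Read probe → gene-symbol mapping (two tab-separated columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DatasetError(f"{path}: probe annotation needs probe and gene columns")
    s = df.set_index(df.columns[0])[df.columns[1]]
    s.name = "gene"
    return s


def read_tr_list(path: str | Path) -> list[str]:
    """Read the transcriptional-regulator gene list (one symbol per line)."""
    symbols = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not symbols:
        raise DatasetError(f"{path}: regulator list is empty")
    if len(set(symbols)) != len(symbols):
        raise DatasetError(f"{path}: regulator list contains duplicate symbols")
    return symbols


def write_tr_list(symbols: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in symbols))


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT annotation file: term <tab> description <tab> gene...

    Returns ``{term: (description, gene_set)}``.
    """
    out: dict[str, tuple[str, set[str]]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DatasetError(f"{path}: malformed GMT line {ln[:50]!r}")
        out[parts[0]] = (parts[1], set(parts[2:]))
    return out


def write_gmt(annotation: Mapping[str, tuple[str, set[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation):
            desc, genes = annotation[term]
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_dataset(
    expression_path: str | Path,
    design_path: str | Path,
    flags_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
) -> Dataset:
    """Read and validate a full pipeline input dataset.

    The flags file is optional: when absent every probe is treated as
    detected ("P") in every sample.
    """
    expr = read_expression(expression_path)
    design = read_design(design_path)
    if flags_path is None:
        flags = pd.DataFrame(PRESENT, index=expr.index, columns=expr.columns)
    else:
        flags = read_flags(flags_path)
    annot = read_probe_annotation(annotation_path) if annotation_path else None
    return Dataset(expression=expr, flags=flags, design=design, probe_annotation=annot)


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write expression/flags/design/annotation TSVs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "flags": out / "flags.tsv",
        "design": out / "design.tsv",
    }
    dataset.expression.to_csv(paths["expression"], sep="\t", index_label="probe")
    dataset.flags.to_csv(paths["flags"], sep="\t", index_label="probe")
    dataset.design.to_csv(paths["design"], sep="\t", index_label="sample")
    if dataset.probe_annotation is not None:
        paths["annotation"] = out / "probe_annotation.tsv"
        dataset.probe_annotation.rename("gene").to_csv(
            paths["annotation"], sep="\t", index_label="probe"
        )
    return paths


# ---------------------------------------------------------------------------
# sample-group resolution
# ---------------------------------------------------------------------------

def resolve_group(design: pd.DataFrame, group: str | tuple[str, str]) -> tuple[str, str]:
    """Resolve a group spec to explicit (breed, altitude) levels.

    Accepts an explicit ``(breed, altitude)`` tuple, a ``"breed:altitude"``
    string, or a two-letter shorthand such as ``"TH"`` when each letter
    matches the initial of exactly one factor level (the TH/TL/DH/DL
    convention of the migrant design).
    """
    breeds = sorted(design["breed"].unique())
    alts = sorted(design["altitude"].unique())
    if isinstance(group, tuple):
        breed, alt = group
    elif ":" in group:
        breed, alt = group.split(":", 1)
    elif len(group) == 2:
        bmatch = [b for b in breeds if b.upper().startswith(group[0].upper())]
        amatch = [a for a in alts if a.upper().startswith(group[1].upper())]
        if len(bmatch) != 1 or len(amatch) != 1:
            raise DatasetError(
                f"group shorthand {group!r} is ambiguous for levels {breeds} × {alts}"
            )
        breed, alt = bmatch[0], amatch[0]
    else:
        raise DatasetError(f"cannot interpret group spec {group!r}")
    if breed not in breeds or alt not in alts:
        raise DatasetError(
            f"unknown group {group!r}: levels are {breeds} × {alts}"
        )
    return breed, alt


def group_samples(design: pd.DataFrame, group: str | tuple[str, str]) -> list[str]:
    """Sample ids in one cell of the 2×2 design."""
    breed, alt = resolve_group(design, group)
    mask = (design["breed"] == breed) & (design["altitude"] == alt)
    return design.index[mask].tolist()


# ---------------------------------------------------------------------------
# network output
# ---------------------------------------------------------------------------

def write_network(graph: nx.Graph, path: str | Path, fmt: str = "sif") -> None:
    """Write a co-expression network as SIF or GraphML.

    SIF uses the relation token "co", one edge per line, and appends
    isolated nodes as single-token lines so Cytoscape keeps them.  GraphML
    carries the node ``type`` and edge ``weight``/``group`` attributes.
    """
    fmt = fmt.lower()
    if fmt == "sif":
        lines = []
        covered: set[str] = set()
        for a, b in sorted(tuple(sorted((str(u), str(v)))) for u, v in graph.edges()):
            lines.append(f"{a}\tco\t{b}")
            covered.update((a, b))
        for node in sorted(str(n) for n in graph.nodes()):
            if node not in covered:
                lines.append(node)
        Path(path).write_text("".join(f"{ln}\n" for ln in lines))
    elif fmt == "graphml":
        # rebuild with sorted nodes/edges so output bytes are deterministic
        g = nx.Graph(**graph.graph)
        for n in sorted(graph.nodes()):
            g.add_node(n, **graph.nodes[n])
        for u, v in sorted(tuple(sorted((a, b))) for a, b in graph.edges()):
            g.add_edge(u, v, **graph.edges[u, v])
        nx.write_graphml(g, str(path), named_key_ids=True)
    else:
        raise ValueError(f"unknown network format {fmt!r} (expected 'sif' or 'graphml')")


def read_sif(path: str | Path) -> nx.Graph:
    """Read a SIF file written by :func:`write_network` back into a graph."""
    g = nx.Graph()
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) == 1:
            g.add_node(parts[0])
        elif len(parts) >= 3:
            g.add_edge(parts[0], parts[2])
        else:
            raise DatasetError(f"{path}: malformed SIF line {ln!r}")
    return g


# ---------------------------------------------------------------------------
# config and provenance
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML key-value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise DatasetError(f"{path}: config must be a mapping of keys to values")
    return cfg


def run_metadata(seed: int | None, config: Mapping) -> dict:
    """Provenance record for a run: seed, config and its hash, versions."""
    import scipy

    from . import __version__

    def _plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Mapping):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        return obj

    cfg = _plain(config)
    blob = json.dumps(cfg, sort_keys=True).encode()
    return {
        "seed": seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "versions": {
            "rifnet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "networkx": nx.__version__,
        },
    }
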