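"""Readers and writers for the tabular formats used throughout the pipeline.

All matrices travel as tab-separated files with a header row of column
identifiers and row identifiers in the first column.  Expression matrices
are genes x cell lines in log2 units and must be complete; drug response
matrices are drugs x cell lines in 1-AUC potency units and may contain
missing values (empty field or "NA", case-insensitive).  Interactomes are
STRING-dialect edge lists (node, node, integer confidence on a 0-1000
scale).  Gene set collections use the GMT dialect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

logger = logging.getLogger("drugmod")

MISSING_TOKENS = {"", "na", "nan"}

#: direction labels used throughout
POSITIVE = "positive"
NEGATIVE = "negative"

_DIRECTION_SUFFIX = {POSITIVE: "POS", NEGATIVE: "NEG"}
_SUFFIX_DIRECTION = {v: k for k, v in _DIRECTION_SUFFIX.items()}

#: per-gene provenance flags of a drug module
PATHWAY_FILTERED = "pathway_filtered"
DIAMOND_RECALLED = "diamond_recalled"


@dataclass(frozen=True)
class DrugModule:
    """A per-drug, per-direction network module of correlated genes.

    Parameters
    ----------
    drug : str
        Drug identifier.
    direction : {"positive", "negative"}
        Whether the module derives from positively or negatively
        correlated genes (PCM vs NCM).
    rank : int
        1 for the first (largest) module of the drug/direction, 2 for the
        secondary one.
    genes : frozenset of str
        Gene symbols in the module.
    origin : mapping gene -> {"pathway_filtered", "diamond_recalled"}
        Provenance of each gene; genes absent from the mapping default to
        ``pathway_filtered``.
    """

    drug: str
    direction: str
    rank: int = 1
    genes: frozenset = field(default_factory=frozenset)
    origin: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.direction not in (POSITIVE, NEGATIVE):
            raise ValidationError(f"invalid module direction {self.direction!r}")
        if self.rank not in (1, 2):
            raise ValidationError(f"invalid module rank {self.rank!r}")
        object.__setattr__(self, "genes", frozenset(self.genes))

    @property
    def name(self) -> str:
        """Set name used in GMT output: ``<drug>|<POS|NEG>``."""
        return f"{self.drug}|{_DIRECTION_SUFFIX[self.direction]}"

    @property
    def label(self) -> str:
        """Unique label; secondary modules receive the suffix ``_md2``."""
        return self.name + ("_md2" if self.rank == 2 else "")

    def gene_origin(self, gene: str) -> str:
        return self.origin.get(gene, PATHWAY_FILTERED)

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def _check_unique(ids: Iterable[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


def validate_expression(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce expression-matrix invariants: unique ids, all values finite."""
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "cell")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"expression matrix has a non-finite value at gene {df.index[i]!r}, "
            f"cell {df.columns[j]!r}; missing values are not allowed"
        )
    return df.astype(float)


def validate_response(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce response-matrix invariants: unique ids, >=1 measurement per
    drug, finite values where present."""
    _check_unique(df.index, "drug")
    _check_unique(df.columns, "cell")
    df = df.astype(float)
    values = df.to_numpy()
    if np.isinf(values).any():
        i, j = np.argwhere(np.isinf(values))[0]
        raise ValidationError(
            f"response matrix has an infinite value at drug {df.index[i]!r}, "
            f"cell {df.columns[j]!r}"
        )
    empty = df.index[np.isnan(values).all(axis=1)]
    if len(empty):
        raise ValidationError(f"drug {empty[0]!r} has no potency measurement")
    return df


def read_matrix(path, kind: str) -> pd.DataFrame:
    """Read a genes x cells (``kind="expression"``) or drugs x cells
    (``kind="response"``) TSV matrix.

    Missing cells (empty or "NA") are allowed only for ``kind="response"``.
    """
    if kind not in ("expression", "response"):
        raise ValueError(f"kind must be 'expression' or 'response', got {kind!r}")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        columns = header[1:]
        index, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            index.append(parts[0])
            row = []
            for col, tok in zip(columns, parts[1:]):
                tok_s = tok.strip()
                if tok_s.lower() in MISSING_TOKENS:
                    if kind == "expression":
                        raise ParseError(
                            f"{path}:{lineno}: missing value at row {parts[0]!r}, "
                            f"column {col!r}; expression matrices must be complete"
                        )
                    row.append(math.nan)
                    continue
                try:
                    row.append(float(tok_s))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric value {tok!r} at row "
                        f"{parts[0]!r}, column {col!r}"
                    ) from None
            rows.append(row)
    df = pd.DataFrame(rows, index=index, columns=columns, dtype=float)
    if kind == "expression":
        return validate_expression(df)
    return validate_response(df)


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a matrix as TSV; NaN cells are written as "NA"."""
    df.to_csv(path, sep="\t", na_rep="NA")


def read_tissues(path) -> pd.Series:
    """Read a two-column cell-line -> tissue annotation TSV (with header)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] < 1:
        raise ParseError(f"{path}: expected at least two columns")
    _check_unique(df.index, "cell")
    return df.iloc[:, 0]


def write_tissues(tissues: pd.Series, path) -> None:
    tissues.rename("tissue").to_csv(path, sep="\t", index_label="cell")


def read_targets(path) -> dict[str, set]:
    """Read a drug -> target annotation TSV: drug in column 1, one target
    per additional column (or one row per drug-target pair)."""
    targets: dict[str, set] = {}
    with open(path) as fh:
        header = fh.readline()  # header row required, content ignored
        if not header.strip():
            raise ParseError(f"{path}: empty file")
        for line in fh:
            parts = [p for p in line.rstrip("\n").split("\t") if p.strip()]
            if not parts:
                continue
            targets.setdefault(parts[0], set()).update(parts[1:])
    return targets


def write_targets(targets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("drug\ttargets\n")
        for drug in sorted(targets):
            fh.write("\t".join([drug, *sorted(targets[drug])]) + "\n")


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------

def read_interactome(path, min_confidence: int = 700) -> nx.Graph:
    """Read a STRING-dialect edge list and keep edges with confidence
    strictly greater than ``min_confidence``.

    Duplicate pairs keep the maximum score; self-loops are dropped with a
    warning.  The returned graph carries the size of its largest connected
    component in ``g.graph["lcc_size"]``.
    """
    if not 0 <= min_confidence <= 1000:
        raise ValueError("min_confidence must be in [0, 1000]")
    g = nx.Graph()
    n_self = 0
    with open(path) as fh:
        first = fh.readline()
        lines = [first] if first and not _is_edge_header(first) else []
        for lineno, line in enumerate([*lines, *fh], start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, score_s = parts[0], parts[1], parts[2]
            try:
                score = int(float(score_s))
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric confidence {score_s!r}"
                ) from None
            if a == b:
                n_self += 1
                continue
            if score > min_confidence:
                if g.has_edge(a, b):
                    g[a][b]["confidence"] = max(g[a][b]["confidence"], score)
                else:
                    g.add_edge(a, b, confidence=score)
    if n_self:
        logger.warning("dropped %d self-loop row(s) from %s", n_self, path)
    g.graph["lcc_size"] = (
        max((len(c) for c in nx.connected_components(g)), default=0)
    )
    logger.info(
        "interactome: %d nodes, %d edges, largest connected component %d",
        g.number_of_nodes(), g.number_of_edges(), g.graph["lcc_size"],
    )
    return g


def _is_edge_header(line: str) -> bool:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 3:
        return False  # malformed data line, not a header
    try:
        float(parts[2])
    except ValueError:
        return True
    return False


def build_interactome(edges: Iterable[tuple[str, str, int]],
                      min_confidence: int = 700) -> nx.Graph:
    """In-memory counterpart of :func:`read_interactome`."""
    g = nx.Graph()
    for a, b, score in edges:
        if a == b:
            logger.warning("dropping self-loop on %s", a)
            continue
        if score > min_confidence:
            if g.has_edge(a, b):
                g[a][b]["confidence"] = max(g[a][b]["confidence"], score)
            else:
                g.add_edge(a, b, confidence=score)
    g.graph["lcc_size"] = max((len(c) for c in nx.connected_components(g)), default=0)
    return g


def write_interactome(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tconfidence\n")
        for a, b, data in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{b}\t{int(data.get('confidence', 1000))}\n")


def largest_component(g: nx.Graph) -> nx.Graph:
    """Subgraph induced on the largest connected component (ties broken by
    smallest member node for determinism)."""
    if g.number_of_nodes() == 0:
        raise ValidationError("empty interactome")
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    return g.subgraph(comps[0]).copy()


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set]:
    """Read a GMT file into ``{set name: gene set}``.

    Column 2 (description) is preserved in the companion mapping returned
    by :func:`read_gmt_with_descriptions` but discarded here.
    """
    sets, _ = read_gmt_with_descriptions(path)
    return sets


def read_gmt_with_descriptions(path) -> tuple[dict[str, set], dict[str, str]]:
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line with <3 columns")
            name, desc, genes = parts[0], parts[1], parts[2:]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = {g for g in genes if g.strip()}
            if not genes:
                raise ValidationError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return sets, descriptions


def write_gmt(sets: Mapping[str, Iterable[str]], path,
              descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sets:
            genes = sorted(sets[name])
            fh.write("\t".join([name, descriptions.get(name, "na"), *genes]) + "\n")


def write_modules_gmt(modules: Iterable[DrugModule], path) -> None:
    """Write drug modules in GMT dialect: column 1 is ``<drug>|<POS|NEG>``,
    column 2 is "second_module" for rank-2 modules and "na" otherwise."""
    with open(path, "w") as fh:
        for m in modules:
            desc = "second_module" if m.rank == 2 else "na"
            fh.write("\t".join([m.name, desc, *sorted(m.genes)]) + "\n")


def read_modules_gmt(path) -> list[DrugModule]:
    """Inverse of :func:`write_modules_gmt` (gene origin flags are not part
    of the GMT dialect and default to pathway_filtered)."""
    modules = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line with <3 columns")
            name, desc, genes = parts[0], parts[1], parts[2:]
            if "|" not in name:
                raise ParseError(f"{path}:{lineno}: module name {name!r} lacks "
                                 "the '<drug>|<POS|NEG>' direction suffix")
            drug, suffix = name.rsplit("|", 1)
            if suffix not in _SUFFIX_DIRECTION:
                raise ParseError(f"{path}:{lineno}: unknown direction suffix {suffix!r}")
            rank = 2 if desc == "second_module" else 1
            modules.append(DrugModule(drug=drug,
                                      direction=_SUFFIX_DIRECTION[suffix],
                                      rank=rank,
                                      genes=frozenset(g for g in genes if g.strip())))
    return modules
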