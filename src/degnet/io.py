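"""Readers, writers and core table types.

The pipeline's entry point is a differential-expression (DEG) table: one
record per (gene, condition) pair carrying the log2 fold change and the
Benjamini-Hochberg adjusted p-value reported by an upstream DE caller.
Records are filtered at ingest with the conventional DEG rule
(adjusted p < 0.05 and |log2 FC| >= 1); a record's direction (up/down) is
the sign of its fold change. Gene-set collections are read from GMT files
and reference interaction / regulatory networks from 2-3 column edge-list
TSVs. Every writer produces a headered TSV that the matching reader
round-trips exactly; weights are rendered at fixed 6-decimal precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, IntegrityError, ParseError

logger = logging.getLogger(__name__)

DEG_COLUMNS = ("gene", "condition", "log_fc", "adj_p")

#: fixed precision for all floating-point file output, for reproducible artifacts
FLOAT_FORMAT = "%.6f"


@dataclass(frozen=True)
class DEGRecord:
    """A single differential-expression call for one gene in one condition."""

    gene: str
    condition: str
    log_fc: float
    adj_p: float

    @property
    def direction(self) -> str:
        """'up' if log_fc > 0 else 'down'."""
        return "up" if self.log_fc > 0 else "down"


class DEGTable:
    """Filtered differential-expression records with per-record direction.

    Wraps a DataFrame with columns gene, condition, log_fc, adj_p, direction.
    (gene, condition) pairs are unique; ``conditions`` and ``genes`` are the
    ids appearing in the records, in first-appearance order.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in DEG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"DEG table missing column(s): {', '.join(missing)}")
        dup = df.duplicated(subset=["gene", "condition"])
        if dup.any():
            pairs = df.loc[dup, ["gene", "condition"]].values.tolist()
            raise IntegrityError(f"duplicate (gene, condition) pairs: {pairs[:5]}")
        df = df.copy()
        df["direction"] = ["up" if x > 0 else "down" for x in df["log_fc"]]
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[DEGRecord]) -> "DEGTable":
        rows = [(r.gene, r.condition, r.log_fc, r.adj_p) for r in records]
        return cls(pd.DataFrame(rows, columns=list(DEG_COLUMNS)))

    @property
    def records(self) -> list[DEGRecord]:
        return [
            DEGRecord(r.gene, r.condition, r.log_fc, r.adj_p)
            for r in self.df.itertuples(index=False)
        ]

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.df["condition"]))

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.df["gene"]))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DEGTable):
            return NotImplemented
        a = self.df.sort_values(["gene", "condition"]).reset_index(drop=True)
        b = other.df.sort_values(["gene", "condition"]).reset_index(drop=True)
        if len(a) != len(b):
            return False
        same_ids = a[["gene", "condition", "direction"]].equals(
            b[["gene", "condition", "direction"]]
        )
        import numpy as np

        return bool(
            same_ids
            and np.allclose(a["log_fc"], b["log_fc"], atol=5e-7)
            and np.allclose(a["adj_p"], b["adj_p"], atol=5e-7)
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways, complexes, gene groups) keyed by term id."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def members(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass
class InteractionNetwork:
    """Undirected interaction network (e.g. protein-protein) as canonical pairs."""

    edges: frozenset[tuple[str, str]]

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(n for e in self.edges for n in e)

    @staticmethod
    def canonical(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        return cls(
            frozenset(cls.canonical(a, b) for a, b in pairs if a != b)
        )


@dataclass
class RegulatoryNetwork:
    """Directed TF -> target-gene map; a TF may itself appear as a target."""

    targets_of: dict[str, frozenset[str]]

    @property
    def tfs(self) -> list[str]:
        return list(self.targets_of)

    @property
    def all_targets(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.targets_of.values():
            out |= t
        return frozenset(out)


def read_deg_table(path, p_cutoff: float = 0.05, lfc_cutoff: float = 1.0) -> DEGTable:
    """Read a DEG TSV and apply the ingest filter.

    Keeps records with adj_p strictly below ``p_cutoff`` and |log_fc| of at
    least ``lfc_cutoff`` (inclusive), mirroring the standard call of
    "adjusted p < 0.05 and |log2 FC| >= 1".
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "condition": str})
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    for col in ("log_fc", "adj_p"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ParseError(f"{path}: non-numeric {col} at line {line}")
        df[col] = pd.to_numeric(df[col])
    n_in = len(df)
    df = df[(df["adj_p"] < p_cutoff) & (df["log_fc"].abs() >= lfc_cutoff)]
    logger.info(
        "read_deg_table: %d of %d records pass adj_p<%g, |log_fc|>=%g",
        len(df), n_in, p_cutoff, lfc_cutoff,
    )
    return DEGTable(df[list(DEG_COLUMNS)])


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: one line per term: id<TAB>description<TAB>member..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{i}: GMT line has {len(parts)} fields, need >=3")
            term, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{i}: term {term!r} has no members")
            if term in sets:
                raise IntegrityError(f"{path}:{i}: duplicate term id {term!r}")
            sets[term] = (desc, frozenset(members))
    return GeneSetCollection(sets)


def read_edge_list(path, directed: bool = False):
    """Read a 2-3 column edge-list TSV (third column, if present, ignored).

    Undirected mode canonicalizes pairs and drops duplicates and self-loops
    (counts logged), returning an InteractionNetwork. Directed mode treats
    column 1 as the regulator and column 2 as its target, returning a
    RegulatoryNetwork.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{i}: expected at least 2 columns")
            pairs.append((parts[0], parts[1]))
    # skip a header row if one is present
    if pairs and pairs[0][0] in ("node1", "source", "tf", "gene1"):
        pairs = pairs[1:]
    if directed:
        targets: dict[str, set[str]] = {}
        for tf, g in pairs:
            targets.setdefault(tf, set()).add(g)
        return RegulatoryNetwork({tf: frozenset(gs) for tf, gs in targets.items()})
    seen: set[tuple[str, str]] = set()
    dropped = 0
    for a, b in pairs:
        if a == b:
            dropped += 1
            continue
        e = InteractionNetwork.canonical(a, b)
        if e in seen:
            dropped += 1
        else:
            seen.add(e)
    if dropped:
        logger.info("read_edge_list: dropped %d duplicate/self-loop rows", dropped)
    return InteractionNetwork(frozenset(seen))


def write_deg_table(table: DEGTable, path) -> None:
    table.df[list(DEG_COLUMNS)].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result DataFrame as a headered TSV at fixed precision."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_network(network, path) -> None:
    """Write a network as an edge-list TSV.

    InteractionNetwork -> 2 columns; a weighted edge mapping or
    ProjectedNetwork (anything with ``.edges`` being a dict pair->weight)
    -> 3 columns with 6-decimal weights.
    """
    edges = network.edges
    if isinstance(edges, Mapping):
        rows = sorted(edges.items())
        df = pd.DataFrame(
            [(a, b, w) for (a, b), w in rows], columns=["node1", "node2", "weight"]
        )
    else:
        df = pd.DataFrame(sorted(edges), columns=["node1", "node2"])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
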