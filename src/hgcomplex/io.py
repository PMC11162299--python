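"""Readers and writers for the flat-file formats the tool exchanges.

Formats handled here:

* FASTA protein sequences (via Biopython),
* two-column tab/whitespace-separated PPI edge lists,
* complex membership files (one complex per line, whitespace-separated
  member ids, optional trailing ``score=<value>`` token),
* abundance tables (TSV, header row of sample names, first column of
  protein ids).

Identifiers are treated as opaque strings; no attempt is made to map
between UniProt accessions, systematic names, or gene symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinCatalog",
    "InteractionNetwork",
    "Complex",
    "ComplexSet",
    "read_fasta",
    "read_edge_list",
    "read_complex_sets",
    "write_complexes",
    "write_edge_list",
    "write_fasta",
    "read_abundance",
    "write_abundance",
]


@dataclass
class ProteinCatalog:
    """An ordered collection of (protein_id, amino-acid sequence) pairs."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.entries]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            for pid in ids:
                if pid in seen:
                    raise ValueError(f"duplicate protein id: {pid!r}")
                seen.add(pid)

    @property
    def ids(self) -> list[str]:
        return [pid for pid, _ in self.entries]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.entries]

    def sequence_of(self, protein_id: str) -> str:
        for pid, seq in self.entries:
            if pid == protein_id:
                return seq
        raise KeyError(protein_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass
class InteractionNetwork:
    """An undirected PPI network: ordered nodes and a set of edges.

    Edges are stored as sorted 2-tuples of protein ids; self-loops and
    duplicates are disallowed by construction.
    """

    nodes: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node ids in network")
        canon = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint not in node list: ({u!r}, {v!r})")
            canon.add((u, v) if u < v else (v, u))
        self.edges = canon

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for u, v in self.edges:
            if u == node:
                out.add(v)
            elif v == node:
                out.add(u)
        return out

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g) -> "InteractionNetwork":
        return cls(nodes=list(g.nodes), edges={tuple(sorted(e)) for e in g.edges})


@dataclass
class Complex:
    """A candidate or reference protein complex: a member set and a score."""

    members: frozenset[str]
    score: float | None = None

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError("complex with no members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ComplexSet:
    """A list of complexes (predicted or gold standard)."""

    complexes: list[Complex] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def __getitem__(self, i):
        return self.complexes[i]

    @property
    def member_sets(self) -> list[frozenset[str]]:
        return [c.members for c in self.complexes]

    @property
    def sizes(self) -> list[int]:
        return [c.size for c in self.complexes]


def read_fasta(path: str | Path) -> ProteinCatalog:
    """Read a FASTA file into a :class:`ProteinCatalog`.

    The protein id is the header token before the first whitespace;
    sequences are upper-cased. Duplicate ids and empty files are errors.
    """
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        pid = record.id
        if pid in seen:
            raise ValueError(f"duplicate protein id in {path}: {pid!r}")
        seen.add(pid)
        entries.append((pid, str(record.seq).upper()))
    if not entries:
        raise ValueError(f"no FASTA records in {path}")
    return ProteinCatalog(entries)


def write_fasta(catalog: ProteinCatalog, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in catalog:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_edge_list(path: str | Path) -> InteractionNetwork:
    """Read a two-column edge list into an undirected network.

    Lines beginning with ``#`` are skipped. Duplicate edges are collapsed
    and self-loops dropped (with a logged count). Node order follows first
    appearance in the file, so permuting input lines changes node order but
    not the edge set.
    """
    nodes: list[str] = []
    node_seen: set[str] = set()
    edges: set[tuple[str, str]] = set()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tokens, got {len(tokens)}"
                )
            u, v = tokens
            for t in (u, v):
                if t not in node_seen:
                    node_seen.add(t)
                    nodes.append(t)
            if u == v:
                n_self += 1
                continue
            edges.add((u, v) if u < v else (v, u))
    if n_self:
        logger.info("dropped %d self-loop(s) reading %s", n_self, path)
    # node order independent of line order for the edge-set representation:
    # keep first-appearance order but the set semantics make the network
    # equal under line permutation (nodes compared as sets downstream).
    return InteractionNetwork(nodes=nodes, edges=edges)


def write_edge_list(network: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(network.edges):
            fh.write(f"{u}\t{v}\n")


def read_complex_sets(path: str | Path, min_size: int = 1) -> ComplexSet:
    """Read a complex membership file: one complex per line.

    Members are whitespace-separated; duplicates within a line collapse.
    A trailing ``score=<value>`` token is parsed as the complex score.
    Complexes with fewer than ``min_size`` members are dropped (gold
    standards for training conventionally use ``min_size=3``).
    """
    complexes: list[Complex] = []
    n_dropped = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            score: float | None = None
            if tokens and tokens[-1].startswith("score="):
                score = float(tokens[-1][len("score=") :])
                tokens = tokens[:-1]
            members = frozenset(tokens)
            if not members:
                continue
            if len(members) < min_size:
                n_dropped += 1
                continue
            complexes.append(Complex(members=members, score=score))
    if n_dropped:
        logger.info(
            "dropped %d complex(es) smaller than %d reading %s",
            n_dropped,
            min_size,
            path,
        )
    return ComplexSet(complexes)


def write_complexes(complexes: ComplexSet | Iterable[Complex], path: str | Path) -> None:
    """Write complexes one per line, tab-separated members, optional score."""
    with open(path, "w") as fh:
        for c in complexes:
            line = "\t".join(sorted(c.members))
            if c.score is not None:
                line += f"\tscore={c.score:.6f}"
            fh.write(line + "\n")


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read a protein-abundance table (proteins x samples, TSV).

    The first column holds protein ids; the header row holds sample names.
    Rows containing missing values are dropped (with a logged count), so the
    returned frame has no NaNs; duplicate protein ids are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein ids in abundance table: {dupes}")
    n_before = len(df)
    df = df.dropna(axis=0)
    if len(df) < n_before:
        logger.info(
            "dropped %d abundance row(s) with missing values reading %s",
            n_before - len(df),
            path,
        )
    if (df.values < 0).any():
        raise ValueError("negative abundance values")
    return df


def write_abundance(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
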