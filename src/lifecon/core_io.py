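"""Domain types and readers/writers for every external format the pipeline touches.

Formats: TSV (expression, trait and gene-set tables, results), Newick tree
ensembles (one tree per line), JASPAR PFM text, and FASTA promoters with
``geneID|speciesID`` headers. Missing expression is an empty cell or ``NA``;
no imputation is ever performed. Gene identifiers are opaque, case-sensitive
strings.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# IUPAC ambiguity codes are accepted on input and collapsed to N.
_IUPAC_DNA = set("ACGTNRYSWKMBDHV")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ConsistencyError(ValueError):
    """Raised when related inputs disagree (e.g. differing tree leaf sets)."""


# ---------------------------------------------------------------------------
# species trait table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesRecord:
    """One species with its life-history traits (maximum lifespan in years)."""

    species_id: str
    mls_years: float
    body_weight_g: float | None = None
    sexual_maturity_days: float | None = None
    order_name: str | None = None

    def __post_init__(self) -> None:
        if not self.mls_years > 0:
            raise ValueError(f"mls_years must be > 0, got {self.mls_years}")


def read_species_tsv(path) -> list[SpeciesRecord]:
    """Read a species trait table (columns: species_id, mls_years, optional
    body_weight_g, sexual_maturity_days, order_name)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"species_id": str})
    if {"species_id", "mls_years"} - set(df.columns):
        raise FormatError("species table needs columns species_id, mls_years")
    if df["species_id"].duplicated().any():
        dups = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
        raise FormatError(f"duplicate species ids: {dups}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SpeciesRecord(
                species_id=row.species_id,
                mls_years=float(row.mls_years),
                body_weight_g=float(row.body_weight_g)
                if "body_weight_g" in df.columns and pd.notna(row.body_weight_g)
                else None,
                sexual_maturity_days=float(row.sexual_maturity_days)
                if "sexual_maturity_days" in df.columns
                and pd.notna(row.sexual_maturity_days)
                else None,
                order_name=row.order_name
                if "order_name" in df.columns and pd.notna(row.order_name)
                else None,
            )
        )
    return records


def write_species_tsv(records: Sequence[SpeciesRecord], path) -> None:
    df = pd.DataFrame(
        {
            "species_id": [r.species_id for r in records],
            "mls_years": [r.mls_years for r in records],
            "body_weight_g": [r.body_weight_g for r in records],
            "sexual_maturity_days": [r.sexual_maturity_days for r in records],
            "order_name": [r.order_name for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x species matrix of (log2-scale) expression with missing entries.

    ``values`` holds NaN where data is missing; ``mask`` is True where a
    measurement is present.
    """

    gene_ids: list[str]
    species_ids: list[str]
    values: np.ndarray  # float, shape (n_genes, n_species), NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise FormatError("duplicate species ids")
        if self.values.shape != (len(self.gene_ids), len(self.species_ids)):
            raise ValueError("values shape does not match id lists")

    @property
    def mask(self) -> np.ndarray:
        """Boolean presence mask, same shape as ``values``."""
        return ~np.isnan(self.values)

    @property
    def n_observed(self) -> np.ndarray:
        """Per-gene count of non-missing species."""
        return self.mask.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.species_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a TSV with a header row of species ids and gene ids in column 1.

    Empty cells or ``NA`` mean missing. Duplicated ids or non-numeric cells
    raise :class:`FormatError`.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, comment="#"
    )
    if df.index.duplicated().any():
        raise FormatError(f"duplicate gene ids: {df.index[df.index.duplicated()].tolist()}")
    if df.columns.duplicated().any():
        raise FormatError("duplicate species ids in header")
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            if cell in ("", "NA"):
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError as exc:
                    raise FormatError(
                        f"non-numeric cell at gene {df.index[i]!r}, "
                        f"species {df.columns[j]!r}: {cell!r}"
                    ) from exc
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    """Write an expression matrix; missing entries become ``NA``.

    Floats are written with repr precision so a read-back reproduces the
    values bit-exactly.
    """
    frame = expr.to_frame()
    frame.to_csv(path, sep="\t", na_rep="NA", float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# phylogenetic trees
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """A rooted tree with non-negative branch lengths, wrapping dendropy."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.leaf_labels
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate leaf labels")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise FormatError(f"negative branch length: {edge.length}")

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise FormatError(f"unparsable Newick: {exc}") from exc
        return cls(tree)

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class PhyloTreeEnsemble:
    """A non-empty list of trees over the same leaf set (phylogenetic
    uncertainty is handled downstream by max-p aggregation)."""

    trees: list[PhyloTree]

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("ensemble must contain at least one tree")
        ref = set(self.trees[0].leaf_labels)
        for i, t in enumerate(self.trees[1:], start=2):
            if set(t.leaf_labels) != ref:
                raise ConsistencyError(
                    f"tree {i} has a different leaf set than tree 1"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    @property
    def leaf_labels(self) -> list[str]:
        return self.trees[0].leaf_labels


def read_newick_ensemble(path) -> PhyloTreeEnsemble:
    """Read one Newick string per non-blank line; all trees must share the
    same leaf set."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(PhyloTree.from_newick(line))
    return PhyloTreeEnsemble(trees)


def write_newick_ensemble(ensemble: PhyloTreeEnsemble, path) -> None:
    with open(path, "w") as fh:
        for tree in ensemble:
            fh.write(tree.to_newick() + "\n")


def prune_tree(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Restrict a tree to ``keep``, collapsing degree-2 nodes by summing
    branch lengths so root-to-leaf path lengths of retained leaves are
    preserved."""
    keep = set(keep)
    leaves = set(tree.leaf_labels)
    if not keep <= leaves:
        raise ValueError(f"keep set not a subset of leaves: {sorted(keep - leaves)}")
    if len(keep) < 3:
        raise ValueError(f"need at least 3 retained leaves, got {len(keep)}")
    pruned = tree.tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True
    )
    return PhyloTree(pruned)


def phylo_covariance(tree: PhyloTree, species_order: Sequence[str]) -> np.ndarray:
    """Brownian-motion covariance: V[i, j] is the shared branch length from
    the root to the MRCA of leaves i and j; the diagonal is root-to-tip
    distance. Matches the covariance structure of ape/nlme's corBrownian."""
    order = {s: i for i, s in enumerate(species_order)}
    leaves = set(tree.leaf_labels)
    missing = [s for s in species_order if s not in leaves]
    if missing:
        raise ValueError(f"species not in tree: {missing}")
    n = len(species_order)
    V = np.zeros((n, n))
    # For each edge, its length accrues to the covariance of every pair of
    # requested leaves below it (including self-pairs -> diagonal).
    for node in tree.tree.preorder_node_iter():
        length = node.edge.length
        if length is None or node.parent_node is None:
            continue
        idx = [
            order[lf.taxon.label]
            for lf in node.leaf_iter()
            if lf.taxon.label in order
        ]
        if idx:
            V[np.ix_(idx, idx)] += length
    return V


# ---------------------------------------------------------------------------
# signed gene sets
# ---------------------------------------------------------------------------

@dataclass
class SignedGeneSet:
    """Mapping gene -> sign in {+1, -1} with free-text provenance labels."""

    entries: dict[str, int]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: s for g, s in self.entries.items() if s not in (1, -1)}
        if bad:
            raise ValueError(f"signs must be +1/-1: {bad}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def genes(self, sign: int | None = None) -> set[str]:
        if sign is None:
            return set(self.entries)
        return {g for g, s in self.entries.items() if s == sign}

    @property
    def positive(self) -> set[str]:
        return self.genes(+1)

    @property
    def negative(self) -> set[str]:
        return self.genes(-1)

    def restrict(self, universe: Iterable[str]) -> "SignedGeneSet":
        universe = set(universe)
        return SignedGeneSet(
            {g: s for g, s in self.entries.items() if g in universe},
            dict(self.provenance),
        )


_SIGN_TOKENS = {"+": 1, "+1": 1, "1": 1, "-": -1, "-1": -1}


def read_signed_gene_set(path, **provenance: str) -> SignedGeneSet:
    """Read a two-column TSV (gene_id, sign in {+,-,+1,-1}).

    A gene listed with both signs is dropped with a logged warning, mirroring
    the exclusion of genes flagged in both directions by different probes.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", dtype=str, comment="#", header=None, skip_blank_lines=True
        )
    except pd.errors.EmptyDataError:
        return SignedGeneSet({}, dict(provenance))
    # tolerate an optional header row
    if df.iloc[0, 0] in ("gene_id", "gene"):
        df = df.iloc[1:]
    entries: dict[str, int] = {}
    conflicted: set[str] = set()
    for gene, token in zip(df.iloc[:, 0], df.iloc[:, 1]):
        token = str(token).strip()
        if token not in _SIGN_TOKENS:
            raise FormatError(f"unknown sign token {token!r} for gene {gene!r}")
        sign = _SIGN_TOKENS[token]
        if gene in entries and entries[gene] != sign:
            conflicted.add(gene)
        entries[gene] = sign
    for gene in conflicted:
        del entries[gene]
    if conflicted:
        logger.warning(
            "dropped %d gene(s) listed with both signs: %s",
            len(conflicted),
            sorted(conflicted),
        )
    return SignedGeneSet(entries, dict(provenance))


def write_signed_gene_set(gene_set: SignedGeneSet, path) -> None:
    with open(path, "w") as fh:
        for label, value in gene_set.provenance.items():
            fh.write(f"# {label}: {value}\n")
        for gene in sorted(gene_set.entries):
            sign = "+" if gene_set.entries[gene] > 0 else "-"
            fh.write(f"{gene}\t{sign}\n")


# ---------------------------------------------------------------------------
# motifs (JASPAR PFM)
# ---------------------------------------------------------------------------

@dataclass
class MotifModel:
    """A position frequency/weight matrix with its background model.

    Row order is A, C, G, T. ``log_odds`` is log2(frequency / background);
    entries may be -inf when a zero frequency survives the pseudocount.
    """

    motif_id: str
    frequencies: np.ndarray  # (4, width)
    background: np.ndarray  # (4,)
    name: str = ""

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.frequencies.ndim != 2 or self.frequencies.shape[0] != 4:
            raise ValueError("frequencies must be 4 x width")
        if not np.allclose(self.frequencies.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("frequency columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.frequencies.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.frequencies / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.frequencies.argmax(axis=0))

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(
            self.motif_id,
            self.frequencies[::-1, ::-1],
            self.background[::-1],
            name=self.name,
        )


UNIFORM_BACKGROUND = np.full(4, 0.25)


def read_jaspar_pfm(
    path,
    pseudocount: float = 0.01,
    background: Sequence[float] = UNIFORM_BACKGROUND,
) -> list[MotifModel]:
    """Read a JASPAR-style PFM text file into MotifModels.

    ``pseudocount`` is added to every count cell before per-column
    normalization; log-odds are taken against ``background``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    background = np.asarray(background, dtype=float)
    with open(path) as fh:
        text = fh.read()
    try:
        parsed = bio_motifs.parse(io.StringIO(text), "jaspar")
    except Exception as exc:
        raise FormatError(f"unparsable JASPAR PFM file: {exc}") from exc
    models = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        if (counts < 0).any():
            raise FormatError(f"negative counts in motif {m.matrix_id}")
        counts = counts + pseudocount
        colsums = counts.sum(axis=0)
        if (colsums == 0).any():
            raise FormatError(f"all-zero column in motif {m.matrix_id}")
        freqs = counts / colsums
        models.append(
            MotifModel(
                motif_id=m.matrix_id or m.name,
                frequencies=freqs,
                background=background,
                name=m.name or "",
            )
        )
    return models


# ---------------------------------------------------------------------------
# promoters (FASTA)
# ---------------------------------------------------------------------------

def read_fasta_promoters(path) -> dict[tuple[str, str], str]:
    """Read promoter FASTA keyed by ``geneID|speciesID`` headers.

    Sequences are uppercased; IUPAC ambiguity codes collapse to N; anything
    outside IUPAC DNA raises :class:`FormatError`.
    """
    promoters: dict[tuple[str, str], str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.id
        if "|" not in header:
            raise FormatError(f"header {header!r} is not geneID|speciesID")
        gene_id, species_id = header.split("|", 1)
        key = (gene_id, species_id)
        if key in promoters:
            raise FormatError(f"duplicate promoter header {header!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _IUPAC_DNA
        if bad:
            raise FormatError(f"non-IUPAC characters {sorted(bad)} in {header!r}")
        seq = "".join(c if c in "ACGT" else "N" for c in seq)
        promoters[key] = seq
    return promoters


def write_fasta_promoters(promoters: Mapping[tuple[str, str], str], path) -> None:
    with open(path, "w") as fh:
        for (gene_id, species_id), seq in promoters.items():
            fh.write(f">{gene_id}|{species_id}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
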