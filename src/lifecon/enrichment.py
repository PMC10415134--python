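"""Fisher-exact enrichment of a query gene set against an annotation library.

Each term is tested on a 2x2 table (in-query x in-term) over an explicit
background universe of investigated genes — the background choice matters
and is always caller-supplied. Libraries are read from GMT files (term,
description, genes...).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .association import bky_fdr


@dataclass
class AnnotationLibrary:
    terms: dict[str, set[str]]
    library_name: str = ""

    def __post_init__(self) -> None:
        empty = [t for t, genes in self.terms.items() if not genes]
        if empty:
            raise ValueError(f"terms with no genes: {empty}")


def read_gmt(path, library_name: str | None = None) -> AnnotationLibrary:
    """Read a GMT file: TERM <tab> description <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line with < 3 fields: {line[:80]!r}")
            terms[fields[0]] = {g for g in fields[2:] if g}
    return AnnotationLibrary(terms, library_name or str(path))


def fisher_enrichment(
    query: set[str],
    library: AnnotationLibrary,
    background: set[str],
    fdr_level: float = 0.05,
    haldane: bool = False,
) -> pd.DataFrame:
    """Per-term two-sided Fisher exact test of the query against the
    background, with BKY FDR across terms.

    The sample odds ratio is ad/bc; with a zero cell it is reported as NaN
    unless ``haldane`` adds the Haldane-Anscombe 0.5 correction (display
    only; the p-value is always from the uncorrected table).
    """
    query = set(query)
    background = set(background)
    if not query:
        raise ValueError("empty query set")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    rows = []
    for term, genes in library.terms.items():
        term_genes = genes & background
        a = len(query & term_genes)
        b = len(query) - a
        c = len(term_genes) - a
        d = len(background) - a - b - c
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if haldane:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c) if b * c > 0 else float("nan")
        rows.append((term, a, len(term_genes), odds, float(p)))
    df = pd.DataFrame(
        rows, columns=["term", "overlap", "term_size", "odds_ratio", "p"]
    )
    if len(df):
        _, qvals = bky_fdr(df["p"].to_numpy(), q=fdr_level)
        df["q"] = qvals
        df["significant"] = df["q"] < fdr_level
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df
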