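"""Trait-expression association across species: Spearman rank correlation and
phylogenetic generalized least squares (PGLS), with two-stage adaptive FDR.

The PGLS error covariance is Brownian motion fixed by the tree (shared
root-to-ancestor branch length), the default behaviour of ape/nlme's
corBrownian; no lambda or OU transform is estimated. Phylogenetic
uncertainty is treated conservatively: the model is fit on every tree of an
ensemble and the *maximum* p-value across trees is the gene's p-value.
Multiple testing uses the Benjamini-Krieger-Yekutieli two-stage linear
step-up procedure; genes are called at q < level (strict).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats as sps
from scipy.linalg import cho_factor, cho_solve

from .core_io import ExpressionMatrix, PhyloTreeEnsemble, SignedGeneSet, phylo_covariance

logger = logging.getLogger(__name__)

EXACT_SPEARMAN_MAX_N = 7


class DegenerateInputError(ValueError):
    """Raised when a correlation/regression input is constant or too small."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass
class AssociationRecord:
    gene_id: str
    method: str  # "spearman" | "pgls"
    statistic: float  # Spearman rho or PGLS slope
    p_value: float
    n_species: int
    q_value: float = float("nan")
    sign_consistent: bool = True  # slope signs agreed across the tree ensemble

    @property
    def sign(self) -> int:
        return 1 if self.statistic >= 0 else -1


@dataclass
class AssociationTable:
    records: list[AssociationRecord]
    trait_name: str = "log2_mls"
    fdr_method: str = "bky"
    fdr_level: float = 0.10

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene": [r.gene_id for r in self.records],
                "method": [r.method for r in self.records],
                "statistic": [r.statistic for r in self.records],
                "p": [r.p_value for r in self.records],
                "q": [r.q_value for r in self.records],
                "n_species": [r.n_species for r in self.records],
                "sign": [r.sign for r in self.records],
                "called": [r.q_value < self.fdr_level for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# gene filtering
# ---------------------------------------------------------------------------

def filter_min_species(expr: ExpressionMatrix, min_n: int = 10) -> ExpressionMatrix:
    """Keep genes observed in at least ``min_n`` species (boundary inclusive).

    The surviving genes define the "all investigated genes" background used
    by every downstream enrichment/overlap test.
    """
    keep = expr.n_observed >= min_n
    if not keep.any():
        raise ValueError("no gene passes the minimum-species filter")
    kept_ids = [g for g, k in zip(expr.gene_ids, keep) if k]
    logger.info(
        "min-species filter (>= %d): %d of %d genes retained",
        min_n, len(kept_ids), len(expr.gene_ids),
    )
    return ExpressionMatrix(kept_ids, list(expr.species_ids), expr.values[keep])


# ---------------------------------------------------------------------------
# Spearman with exact small-n permutation p
# ---------------------------------------------------------------------------

_perm_null_cache: dict[tuple, np.ndarray] = {}


def _exact_rho_null(x_ranks: np.ndarray, y_ranks: np.ndarray) -> np.ndarray:
    """All n! values of corr(x_ranks, permuted y_ranks).

    The distribution depends only on the two rank multisets (permuting
    positions relabels the permutation group), so results are cached on the
    sorted rank tuples.
    """
    key = (tuple(np.sort(x_ranks)), tuple(np.sort(y_ranks)))
    if key not in _perm_null_cache:
        xs = np.sort(x_ranks)
        perms = np.array(list(itertools.permutations(np.sort(y_ranks))))
        xc = xs - xs.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc @ xc) * (pc * pc).sum(axis=1))
        _perm_null_cache[key] = (pc @ xc) / denom
    return _perm_null_cache[key]


def spearman_association(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with a two-sided p-value.

    Exact permutation enumeration for n <= 7; the usual t-distribution
    approximation for larger n. NaN pairs are dropped before ranking.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise DegenerateInputError(f"need >= 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input: correlation undefined")
    if n <= EXACT_SPEARMAN_MAX_N:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rho = float(np.corrcoef(rx, ry)[0, 1])
        null = _exact_rho_null(rx, ry)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        res = sps.spearmanr(x, y)
        rho, p = float(res.statistic), float(res.pvalue)
    return rho, p


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PglsFit:
    slope: float
    intercept: float
    slope_se: float
    t: float
    p: float
    n: int


def pgls_fit(y: np.ndarray, x: np.ndarray, V: np.ndarray) -> PglsFit:
    """Closed-form GLS of y on [1, x] with error covariance proportional to V.

    beta = (X' V^-1 X)^-1 X' V^-1 y; the slope is tested two-sided against a
    t distribution with n - 2 degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if n < 3:
        raise DegenerateInputError(f"need >= 3 observations, got {n}")
    X = np.column_stack([np.ones(n), x])
    try:
        cf = cho_factor(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    Vinv_X = cho_solve(cf, X)
    XtVinvX = X.T @ Vinv_X
    if abs(np.linalg.det(XtVinvX)) < 1e-300:
        raise DegenerateInputError("singular design (constant predictor?)")
    beta = np.linalg.solve(XtVinvX, Vinv_X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ cho_solve(cf, resid))
    sigma2 = rss / (n - 2)
    cov_beta = sigma2 * np.linalg.inv(XtVinvX)
    se = float(np.sqrt(max(cov_beta[1, 1], 0.0)))
    slope = float(beta[1])
    if se == 0.0:
        t = np.inf if slope != 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / se
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return PglsFit(slope, float(beta[0]), se, float(t), p, n)


@dataclass
class EnsembleFit:
    """Max-p aggregation of per-tree PGLS fits: the reported slope is the one
    from the fit attaining the maximum p."""

    p_max: float
    slope: float
    sign_consistent: bool
    n: int


def pgls_ensemble(
    y: np.ndarray,
    x: np.ndarray,
    ensemble: PhyloTreeEnsemble,
    species: list[str],
    covariances: list[np.ndarray] | None = None,
) -> EnsembleFit:
    """Fit PGLS on every tree (restricted to ``species``) and keep the
    maximum p-value. Slope-sign disagreement across trees is logged and
    flagged.

    ``covariances`` may pass precomputed per-tree matrices over ``species``
    (used by the batch driver to avoid recomputing shared-branch lengths).
    """
    if len(ensemble) == 0:
        raise ValueError("empty tree ensemble")
    fits = []
    for k, tree in enumerate(ensemble):
        V = covariances[k] if covariances is not None else phylo_covariance(tree, species)
        fits.append(pgls_fit(y, x, V))
    worst = max(fits, key=lambda f: f.p)
    signs = {1 if f.slope >= 0 else -1 for f in fits}
    consistent = len(signs) == 1
    if not consistent:
        logger.warning("PGLS slope signs disagree across the tree ensemble")
    return EnsembleFit(worst.p, worst.slope, consistent, worst.n)


# ---------------------------------------------------------------------------
# two-stage BKY FDR
# ---------------------------------------------------------------------------

def _bh_adjust(p: np.ndarray, m0: int) -> np.ndarray:
    """Step-up adjusted values using m0 in place of m: adj_(i) = min_{j>=i}
    p_(j) * m0 / j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m0 / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def bky_fdr(p_values, q: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Krieger-Yekutieli two-stage linear step-up FDR control.

    Stage 1 is Benjamini-Hochberg at q' = q/(1+q); with r1 rejections and
    r1 not in {0, m}, the null count is estimated as m0 = m - r1 and stage 2
    re-runs BH at q' with m0. The returned q_values satisfy
    ``{q_value <= q} == rejected`` for the q the procedure was run at.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    q_prime = q / (1.0 + q)
    stage1 = _bh_adjust(p, m)
    r1 = int((stage1 <= q_prime).sum())
    if r1 == 0 or r1 == m:
        q_values = np.minimum(stage1 * (1.0 + q), 1.0)
    else:
        q_values = np.minimum(_bh_adjust(p, m - r1) * (1.0 + q), 1.0)
    rejected = q_values <= q
    return rejected, q_values


# ---------------------------------------------------------------------------
# calling and merging signed gene sets
# ---------------------------------------------------------------------------

def call_signed_set(table: AssociationTable, fdr_level: float) -> SignedGeneSet:
    """Genes with q strictly below ``fdr_level``, signed by their statistic.

    Records whose slope sign disagreed across the tree ensemble are excluded
    (logged): their direction is not interpretable.
    """
    entries: dict[str, int] = {}
    conflicted: set[str] = set()
    for rec in table.records:
        if not rec.q_value < fdr_level:
            continue
        if not rec.sign_consistent:
            logger.warning(
                "gene %s significant but slope signs disagree across trees; excluded",
                rec.gene_id,
            )
            continue
        if rec.gene_id in entries and entries[rec.gene_id] != rec.sign:
            conflicted.add(rec.gene_id)
        entries[rec.gene_id] = rec.sign
    for gene in conflicted:
        del entries[gene]
        logger.warning("gene %s called with opposite signs; excluded", gene)
    methods = sorted({r.method for r in table.records})
    return SignedGeneSet(
        entries,
        {
            "trait": table.trait_name,
            "method": "+".join(methods),
            "fdr_level": str(fdr_level),
        },
    )


def merge_method_calls(a: SignedGeneSet, b: SignedGeneSet) -> SignedGeneSet:
    """Union of two signed call sets; genes called with opposite signs by the
    two methods are excluded with a logged warning."""
    entries = dict(a.entries)
    dropped = []
    for gene, sign in b.entries.items():
        if gene in entries and entries[gene] != sign:
            dropped.append(gene)
        else:
            entries[gene] = sign
    for gene in dropped:
        entries.pop(gene, None)
    if dropped:
        logger.warning(
            "merge: %d gene(s) called with opposite signs excluded: %s",
            len(dropped), sorted(dropped),
        )
    prov = {"method": "merged"}
    for src in (a.provenance, b.provenance):
        for k, v in src.items():
            if k != "method":
                prov.setdefault(k, v)
    return SignedGeneSet(entries, prov)


# ---------------------------------------------------------------------------
# batch driver over an expression matrix
# ---------------------------------------------------------------------------

def associate_expression(
    expr: ExpressionMatrix,
    trait: dict[str, float],
    ensemble: PhyloTreeEnsemble | None = None,
    methods: tuple[str, ...] = ("spearman", "pgls"),
    fdr_level: float = 0.10,
    min_species: int = 10,
    trait_name: str = "log2_mls",
) -> dict[str, AssociationTable]:
    """Run the per-gene association tests over a whole matrix.

    Returns one AssociationTable per method, each with BKY q-values computed
    across its tested genes. Genes with constant expression are skipped (and
    excluded from the tested set) with a logged reason.
    """
    expr = filter_min_species(expr, min_species)
    species = expr.species_ids
    t_vec = np.array([trait[s] for s in species])
    tables: dict[str, AssociationTable] = {}

    if "pgls" in methods:
        if ensemble is None:
            raise ValueError("PGLS requires a tree ensemble")
        full_covs = [phylo_covariance(tree, species) for tree in ensemble]

    for method in methods:
        records: list[AssociationRecord] = []
        for i, gene in enumerate(expr.gene_ids):
            row = expr.values[i]
            obs = ~np.isnan(row)
            x = row[obs]
            y = t_vec[obs]
            try:
                if method == "spearman":
                    rho, p = spearman_association(x, y)
                    records.append(AssociationRecord(gene, method, rho, p, int(obs.sum())))
                elif method == "pgls":
                    idx = np.flatnonzero(obs)
                    covs = [C[np.ix_(idx, idx)] for C in full_covs]
                    fit = pgls_ensemble(
                        x, y, ensemble, [species[j] for j in idx], covariances=covs
                    )
                    records.append(
                        AssociationRecord(
                            gene, method, fit.slope, fit.p_max, fit.n,
                            sign_consistent=fit.sign_consistent,
                        )
                    )
                else:
                    raise ValueError(f"unknown method {method!r}")
            except DegenerateInputError as exc:
                logger.info("gene %s skipped (%s): %s", gene, method, exc)
        if records:
            _, qvals = bky_fdr([r.p_value for r in records], q=fdr_level)
            for rec, qv in zip(records, qvals):
                rec.q_value = float(qv)
        tables[method] = AssociationTable(records, trait_name, "bky", fdr_level)
    return tables
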