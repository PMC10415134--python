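"""Similarity between two signed gene sets.

Two signed sets A (e.g. MLS-associated genes) and B (e.g. aging-associated
genes) over a shared universe of investigated genes are compared by counting
*concordant* members (same sign in both) and *discordant* members (opposite
signs). Expected counts under independence come from the sign-stratum sizes:
E[concordant] = sum_s |A_s||B_s|/N, E[discordant] = sum_s |A_s||B_-s|/N.

The headline statistic is an observed-vs-expected odds ratio conditioned on
A: OR = [O/(n_a - O)] / [E/(n_a - E)] with n_a = |A|. Significance uses an
exact two-sided binomial test of the observed count against the chance rate
E/n_a. Note the asymmetry: swapping A and B changes n_a and hence the ORs
(the discordant *count* is symmetric, the ORs are not).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats as sps

from .association import bky_fdr
from .core_io import SignedGeneSet

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceCounts:
    n_universe: int
    n_a: int  # |A| within the universe (both strata pooled)
    concordant: int
    discordant: int
    expected_concordant: float
    expected_discordant: float


@dataclass
class ConcordanceResult:
    counts: ConcordanceCounts
    or_concordant: float | None  # None when a denominator vanishes
    or_discordant: float | None
    p_concordant: float
    p_discordant: float
    q_concordant: float = float("nan")
    q_discordant: float = float("nan")


def classify_concordance(
    a: SignedGeneSet, b: SignedGeneSet, universe: set[str]
) -> ConcordanceCounts:
    """Count concordant/discordant members of A (restricted to the universe)
    and their expectations under independence."""
    if not universe:
        raise ValueError("empty universe")
    universe = set(universe)
    a = a.restrict(universe)
    b = b.restrict(universe)
    N = len(universe)
    a_pos, a_neg = a.positive, a.negative
    b_pos, b_neg = b.positive, b.negative
    concordant = len(a_pos & b_pos) + len(a_neg & b_neg)
    discordant = len(a_pos & b_neg) + len(a_neg & b_pos)
    exp_conc = (len(a_pos) * len(b_pos) + len(a_neg) * len(b_neg)) / N
    exp_disc = (len(a_pos) * len(b_neg) + len(a_neg) * len(b_pos)) / N
    return ConcordanceCounts(
        n_universe=N,
        n_a=len(a),
        concordant=concordant,
        discordant=discordant,
        expected_concordant=exp_conc,
        expected_discordant=exp_disc,
    )


def overlap_binomial_test(k: int, n_a: int, p0: float) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood-sum convention)
    for k successes in n_a trials under success probability p0 — the null
    that the two gene sets overlap only by chance."""
    if not 0 <= k <= n_a:
        raise ValueError(f"k={k} outside [0, {n_a}]")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0={p0} outside [0, 1]")
    if n_a == 0:
        return 1.0
    return float(sps.binomtest(k, n_a, p0, alternative="two-sided").pvalue)


def _odds(count: float, total: int) -> float | None:
    if total <= 0 or count >= total or count < 0:
        return None
    return count / (total - count)


def concordance_odds_ratio(counts: ConcordanceCounts) -> tuple[float | None, float | None]:
    """Observed-vs-expected odds ratios for the concordant and discordant
    counts, conditioned on membership in A. ``None`` encodes an undefined
    ratio (a zero denominator, e.g. O = n_a or E = 0)."""
    def ratio(obs: float, exp: float) -> float | None:
        o_obs = _odds(obs, counts.n_a)
        o_exp = _odds(exp, counts.n_a)
        if o_obs is None or o_exp is None or o_exp == 0:
            if o_exp == 0 and o_obs == 0:
                return None
            if o_exp is not None and o_exp > 0 and o_obs is None:
                logger.warning("odds ratio undefined (saturated observed count)")
            return None
        return o_obs / o_exp

    return ratio(counts.concordant, counts.expected_concordant), ratio(
        counts.discordant, counts.expected_discordant
    )


def concordance_test(
    a: SignedGeneSet, b: SignedGeneSet, universe: set[str]
) -> ConcordanceResult:
    """Full concordance comparison of two signed sets on a universe: counts,
    odds ratios, and binomial p-values for both directions."""
    counts = classify_concordance(a, b, universe)
    or_c, or_d = concordance_odds_ratio(counts)
    if counts.n_a > 0:
        p_c = overlap_binomial_test(
            counts.concordant, counts.n_a, counts.expected_concordant / counts.n_a
        )
        p_d = overlap_binomial_test(
            counts.discordant, counts.n_a, counts.expected_discordant / counts.n_a
        )
    else:
        p_c = p_d = 1.0
    return ConcordanceResult(counts, or_c, or_d, p_c, p_d)


def concordance_battery(
    comparisons: list[tuple[SignedGeneSet, SignedGeneSet, set[str]]],
    fdr_level: float = 0.05,
) -> list[ConcordanceResult]:
    """Run many comparisons and apply BKY FDR across all their binomial
    p-values (concordant and discordant tested jointly, mirroring per-panel
    asterisks at a single FDR level)."""
    results = [concordance_test(a, b, u) for a, b, u in comparisons]
    pvals = [r.p_concordant for r in results] + [r.p_discordant for r in results]
    _, qvals = bky_fdr(pvals, q=fdr_level)
    n = len(results)
    for i, res in enumerate(results):
        res.q_concordant = float(qvals[i])
        res.q_discordant = float(qvals[n + i])
    return results


# ---------------------------------------------------------------------------
# coefficient-level comparisons
# ---------------------------------------------------------------------------

def compare_coefficient_profiles(
    rho_set_1: np.ndarray, rho_set_2: np.ndarray
) -> tuple[float, float]:
    """Welch two-sample two-tailed t-test between two per-gene vectors of
    correlation coefficients (e.g. across tissues of two species panels).

    Zero within-group variance with different means is degenerate: p is
    reported as 0.0 with a logged flag.
    """
    a = np.asarray(rho_set_1, dtype=float)
    b = np.asarray(rho_set_2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each coefficient vector needs length >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        logger.warning("degenerate Welch test: zero variance, unequal means")
        return float("inf") if a[0] > b[0] else float("-inf"), 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def one_sample_wilcoxon(values: np.ndarray, mu0: float = 0.0) -> float:
    """Two-sided one-sample Wilcoxon signed-rank test of median == mu0.

    Exact null distribution for n <= 25 (after dropping values equal to
    mu0), normal approximation with continuity correction otherwise.
    """
    diffs = np.asarray(values, dtype=float) - mu0
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        raise ValueError("all values equal mu0")
    if n < 5:
        raise ValueError(f"need >= 5 non-zero differences, got {n}")
    has_ties = len(np.unique(np.abs(diffs))) < n
    method = "exact" if n <= 25 and not has_ties else "approx"
    res = sps.wilcoxon(
        diffs, alternative="two-sided", method=method, correction=(method == "approx")
    )
    return float(res.pvalue)
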