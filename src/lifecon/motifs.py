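"""PWM promoter scanning with exact null p-values, and the motif/MLS
co-evolution trend test.

Scanning follows the FIMO conventions: log-odds scores against a zero-order
background, both strands, every overlapping window reported, p-value of a
window = probability that a random background-distributed window scores at
least as high. The null distribution is computed exactly by dynamic
programming over integer-discretized scores, so the scanner's p-values are
reproducible by brute-force enumeration of all 4^w windows for small w.

Scores are discretized on a single global grid (about ``granularity`` bins
for the widest-ranging column) so column scores stay additive. The reverse
strand is scored with the reverse-complemented integer matrix; its null
distribution equals the forward one because backgrounds are
strand-symmetric (uniform, or symmetrized by :func:`estimate_background`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .association import DegenerateInputError, bky_fdr, spearman_association
from .core_io import MotifModel, SpeciesRecord

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_GRANULARITY = 1000

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and anything else (N) -> 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def estimate_background(sequences) -> np.ndarray:
    """Zero-order background from a set of sequences, symmetrized across
    strands (A~T, C~G) so reverse-strand nulls match forward ones."""
    counts = np.zeros(4)
    for seq in sequences:
        enc = encode_sequence(seq)
        counts += np.bincount(enc[enc < 4], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    at = (counts[0] + counts[3]) / 2.0
    cg = (counts[1] + counts[2]) / 2.0
    bg = np.array([at, cg, cg, at])
    return bg / bg.sum()


# ---------------------------------------------------------------------------
# exact null score distribution
# ---------------------------------------------------------------------------

@dataclass
class ScoreDistribution:
    """Exact null distribution of a motif's integer-discretized log-odds score.

    ``int_log_odds[b, i]`` is the integer score of base b at column i;
    ``scale`` converts integers back to bits. ``tail[s - min_score]`` is
    P(score >= s) under the background.
    """

    motif_id: str
    int_log_odds: np.ndarray  # (4, width) int64
    scale: float  # integer units per bit
    min_score: int
    tail: np.ndarray  # suffix tail probabilities over the integer support

    @property
    def max_score(self) -> int:
        return self.min_score + len(self.tail) - 1

    def pvalue_int(self, score) -> np.ndarray:
        """Tail probability P(null >= score) for integer score(s)."""
        s = np.asarray(score, dtype=np.int64)
        idx = np.clip(s - self.min_score, 0, len(self.tail) - 1)
        out = self.tail[idx]
        out = np.where(s <= self.min_score, 1.0, out)
        out = np.where(s > self.max_score, 0.0, out)
        return out

    def pvalue_bits(self, score_bits: float) -> float:
        return float(self.pvalue_int(int(round(score_bits * self.scale))))

    def min_score_for(self, p_threshold: float) -> int:
        """Smallest integer score whose tail probability is strictly below
        ``p_threshold`` (score >= this value <=> p < threshold)."""
        below = np.flatnonzero(self.tail < p_threshold)
        if len(below) == 0:
            return self.max_score + 1
        return self.min_score + int(below[0])

    def as_mapping(self) -> dict[float, float]:
        """Score threshold (bits) -> tail probability, over the support."""
        scores = np.arange(self.min_score, self.max_score + 1) / self.scale
        return dict(zip(scores.tolist(), self.tail.tolist()))


def _discretize_log_odds(motif: MotifModel, granularity: int) -> tuple[np.ndarray, float]:
    lo = motif.log_odds
    finite = np.isfinite(lo)
    if not finite.any():
        raise ValueError("motif has no finite log-odds entries")
    col_range = 0.0
    for i in range(motif.width):
        col = lo[:, i][finite[:, i]]
        if len(col):
            col_range = max(col_range, float(col.max() - col.min()))
    scale = granularity / col_range if col_range > 0 else float(granularity)
    ints = np.zeros_like(lo, dtype=np.int64)
    ints[finite] = np.round(lo[finite] * scale).astype(np.int64)
    if (~finite).any():
        # -inf entries: below anything a finite-only window can reach
        floor = ints[finite].min() - granularity * (motif.width + 1)
        ints[~finite] = floor
    return ints, scale


def exact_score_distribution(
    motif: MotifModel, granularity: int = DEFAULT_GRANULARITY
) -> ScoreDistribution:
    """Exact null score distribution by convolution across columns.

    ``granularity`` (>= 100) sets the number of discretization bins spanned
    by the widest-ranging column; the tail probability function over scores
    is non-increasing by construction.
    """
    if granularity < 100:
        raise ValueError("granularity must be >= 100")
    ints, scale = _discretize_log_odds(motif, granularity)
    bg = motif.background
    # pmf over integer score sums, tracked with an explicit offset
    pmf = np.array([1.0])
    offset = 0  # score of pmf[0]
    for i in range(motif.width):
        col = ints[:, i]
        lo_min, lo_max = int(col.min()), int(col.max())
        new_len = len(pmf) + (lo_max - lo_min)
        new = np.zeros(new_len)
        for b in range(4):
            if bg[b] > 0:
                shift = int(col[b]) - lo_min
                new[shift : shift + len(pmf)] += bg[b] * pmf
        pmf = new
        offset += lo_min
    tail = np.cumsum(pmf[::-1])[::-1]
    tail = np.minimum(tail, 1.0)
    return ScoreDistribution(motif.motif_id, ints, scale, offset, tail)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

@dataclass
class MotifHit:
    gene_id: str
    species_id: str
    motif_id: str
    offset: int  # 0-based start on the forward strand
    strand: str  # "+" or "-"
    score: float  # bits
    p: float


def _window_scores(encoded: np.ndarray, int_lo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores of every window plus a validity mask (no N)."""
    width = int_lo.shape[1]
    n_win = len(encoded) - width + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    scores = np.zeros(n_win, dtype=np.int64)
    tmp = np.empty(n_win, dtype=np.int64)
    for i in range(width):
        lut = np.append(int_lo[:, i], 0)  # index 4 (N) scores 0, masked below
        np.take(lut, encoded[i : i + n_win], out=tmp)
        scores += tmp
    # a window is valid iff it contains no N: prefix sums of the N indicator
    n_prefix = np.concatenate([[0], np.cumsum(encoded == 4)])
    valid = (n_prefix[width:] - n_prefix[:-width]) == 0
    return scores, valid


def scan_promoter(
    seq: str,
    motif: MotifModel,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    dist: ScoreDistribution | None = None,
    granularity: int = DEFAULT_GRANULARITY,
    gene_id: str = "",
    species_id: str = "",
) -> list[MotifHit]:
    """Score every window of ``seq`` on both strands and report hits with
    null p strictly below ``p_threshold``.

    Offsets are 0-based starts of the half-open window [offset, offset+width)
    in forward coordinates regardless of strand; windows containing N are
    skipped. A sequence shorter than the motif yields no hits.
    """
    if dist is None:
        dist = exact_score_distribution(motif, granularity)
    encoded = encode_sequence(seq)
    width = motif.width
    hits: list[MotifHit] = []
    rc_lo = dist.int_log_odds[::-1, ::-1]
    for strand, int_lo in (("+", dist.int_log_odds), ("-", rc_lo)):
        scores, valid = _window_scores(encoded, int_lo)
        if not len(scores):
            continue
        pvals = dist.pvalue_int(scores)
        sel = valid & (pvals < p_threshold)
        for off in np.flatnonzero(sel):
            hits.append(
                MotifHit(
                    gene_id=gene_id,
                    species_id=species_id,
                    motif_id=motif.motif_id,
                    offset=int(off),
                    strand=strand,
                    score=float(scores[off] / dist.scale),
                    p=float(pvals[off]),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_promoters(
    promoters: dict[tuple[str, str], str],
    motifs: list[MotifModel],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    granularity: int = DEFAULT_GRANULARITY,
) -> list[MotifHit]:
    """Scan every promoter with every motif (shared null distribution per
    motif).

    Sequences are concatenated with N separators and scanned in one pass per
    motif and strand; windows straddling a boundary contain N and are
    discarded, so results equal per-sequence :func:`scan_promoter` calls.
    """
    if not promoters or not motifs:
        return []
    keys = list(promoters)
    max_width = max(m.width for m in motifs)
    sep = "N" * max_width
    encoded = encode_sequence(sep.join(promoters[k] for k in keys))
    starts = np.cumsum([0] + [len(promoters[k]) + max_width for k in keys[:-1]])
    ends = starts + np.array([len(promoters[k]) for k in keys])

    hits: list[MotifHit] = []
    for motif in motifs:
        dist = exact_score_distribution(motif, granularity)
        rc_lo = dist.int_log_odds[::-1, ::-1]
        score_min = dist.min_score_for(p_threshold)
        for strand, scores, valid in _dual_strand_scores(
            encoded, dist.int_log_odds, rc_lo, granularity
        ):
            for pos in np.flatnonzero(valid & (scores >= score_min)):
                idx = int(np.searchsorted(starts, pos, side="right") - 1)
                if pos + motif.width > ends[idx]:
                    continue  # unreachable: boundary windows contain N
                gene_id, species_id = keys[idx]
                hits.append(
                    MotifHit(
                        gene_id=gene_id,
                        species_id=species_id,
                        motif_id=motif.motif_id,
                        offset=int(pos - starts[idx]),
                        strand=strand,
                        score=float(scores[pos] / dist.scale),
                        p=float(dist.pvalue_int(scores[pos])),
                    )
                )
    hits.sort(key=lambda h: (h.gene_id, h.species_id, h.motif_id, h.offset, h.strand))
    return hits


def _dual_strand_scores(encoded, fwd_lo, rc_lo, granularity):
    """Window scores for both strands with one table gather per column.

    Column scores of the two strands are bit-packed into a single int64
    lookup (each column's shifted score fits well under the 24-bit lane) so
    long concatenated sequences are traversed once.
    """
    width = fwd_lo.shape[1]
    n_win = len(encoded) - width + 1
    if n_win <= 0:
        return
    shift = 24
    if width * granularity * 2 >= (1 << shift):
        # lane could overflow: fall back to two independent passes
        for strand, int_lo in (("+", fwd_lo), ("-", rc_lo)):
            scores, valid = _window_scores(encoded, int_lo)
            yield strand, scores, valid
        return
    fwd_min = fwd_lo.min(axis=0)
    rc_min = rc_lo.min(axis=0)
    packed = np.zeros(n_win, dtype=np.int64)
    idx = encoded.astype(np.intp)  # intp indices keep the gather on a fast path
    for i in range(width):
        lane = ((fwd_lo[:, i] - fwd_min[i]) << shift) | (rc_lo[:, i] - rc_min[i])
        lut = np.append(lane, 0)  # N never scores; masked below
        packed += lut[idx[i : i + n_win]]
    n_prefix = np.concatenate([[0], np.cumsum(encoded == 4)])
    valid = (n_prefix[width:] - n_prefix[:-width]) == 0
    yield "+", (packed >> shift) + int(fwd_min.sum()), valid
    yield "-", (packed & ((1 << shift) - 1)) + int(rc_min.sum()), valid


# ---------------------------------------------------------------------------
# per-species motif statistics and the co-evolution trend test
# ---------------------------------------------------------------------------

def motif_gene_stats(
    hits: list[MotifHit],
    gene_set: list[str],
    genes_with_promoters: set[str] | None = None,
) -> tuple[float, float]:
    """Presence ratio (fraction of genes with >= 1 hit) and mean hit count
    per promoter, over one species and one motif.

    Genes without an available promoter are excluded from the denominator
    (logged).
    """
    if not gene_set:
        raise ValueError("empty gene set")
    genes = list(dict.fromkeys(gene_set))
    if genes_with_promoters is not None:
        usable = [g for g in genes if g in genes_with_promoters]
        if len(usable) < len(genes):
            logger.info(
                "%d gene(s) without promoters excluded from motif stats",
                len(genes) - len(usable),
            )
        genes = usable
        if not genes:
            raise ValueError("no gene in the set has a promoter")
    counts = {g: 0 for g in genes}
    for hit in hits:
        if hit.gene_id in counts:
            counts[hit.gene_id] += 1
    values = np.array([counts[g] for g in genes], dtype=float)
    return float((values > 0).mean()), float(values.mean())


@dataclass
class CoevolutionRecord:
    motif_id: str
    metric: str  # "presence_ratio" | "mean_count"
    species_ids: list[str] = field(default_factory=list)
    odds_ratios: list[float] = field(default_factory=list)
    rho: float = float("nan")
    p: float = float("nan")
    q: float = float("nan")
    called: bool = False  # motif-level call: both metrics significant, same direction


MIN_TREND_SPECIES = 5


def coevolution_trend(
    mls_set_stats: dict[str, dict[str, tuple[float, float]]],
    background_stats: dict[str, dict[str, tuple[float, float]]],
    species: list[SpeciesRecord],
    fdr: float = 0.05,
) -> list[CoevolutionRecord]:
    """Test whether per-species motif enrichment of the MLS gene set trends
    with MLS.

    Inputs map motif -> species -> (presence_ratio, mean_count) for the MLS
    set and the background set. Per species, the presence metric becomes a
    true odds ratio [p1/(1-p1)]/[p0/(1-p0)] (species with p in {0, 1}
    dropped and logged) and the mean-count metric a plain ratio of means.
    Each (motif, metric) series is Spearman-correlated with MLS; BKY FDR is
    applied across all tests; a motif is called MLS-associated only when
    BOTH metrics are significant at ``fdr`` with the same trend direction.
    """
    mls_by_species = {r.species_id: r.mls_years for r in species}
    records: list[CoevolutionRecord] = []
    for motif_id, per_species in mls_set_stats.items():
        bg = background_stats.get(motif_id, {})
        for metric_idx, metric in enumerate(("presence_ratio", "mean_count")):
            sp_ids, ors = [], []
            for sp, stats1 in per_species.items():
                if sp not in bg or sp not in mls_by_species:
                    continue
                v1, v0 = stats1[metric_idx], bg[sp][metric_idx]
                if metric == "presence_ratio":
                    if v1 in (0.0, 1.0) or v0 in (0.0, 1.0):
                        logger.info(
                            "motif %s species %s: presence OR undefined, dropped",
                            motif_id, sp,
                        )
                        continue
                    value = (v1 / (1 - v1)) / (v0 / (1 - v0))
                else:
                    if v0 == 0.0:
                        logger.info(
                            "motif %s species %s: zero background mean count, dropped",
                            motif_id, sp,
                        )
                        continue
                    value = v1 / v0
                sp_ids.append(sp)
                ors.append(value)
            rec = CoevolutionRecord(motif_id, metric, sp_ids, ors)
            if len(sp_ids) < MIN_TREND_SPECIES:
                logger.info(
                    "motif %s metric %s: only %d usable species, skipped",
                    motif_id, metric, len(sp_ids),
                )
            else:
                mls = np.array([mls_by_species[s] for s in sp_ids])
                try:
                    rec.rho, rec.p = spearman_association(np.array(ors), mls)
                except DegenerateInputError:
                    logger.info(
                        "motif %s metric %s: constant series, rho undefined",
                        motif_id, metric,
                    )
            records.append(rec)

    tested = [r for r in records if np.isfinite(r.p)]
    if tested:
        _, qvals = bky_fdr([r.p for r in tested], q=fdr)
        for rec, qv in zip(tested, qvals):
            rec.q = float(qv)
    by_motif: dict[str, list[CoevolutionRecord]] = {}
    for rec in records:
        by_motif.setdefault(rec.motif_id, []).append(rec)
    for motif_id, recs in by_motif.items():
        if len(recs) == 2 and all(np.isfinite(r.q) and r.q < fdr for r in recs):
            same_direction = np.sign(recs[0].rho) == np.sign(recs[1].rho) != 0
            if same_direction:
                for r in recs:
                    r.called = True
    return records
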