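"""Synthetic data generators with the statistical structure the analysis assumes.

Every generator is a pure function of its arguments and a seed: repeat calls
are byte-identical. The generators emulate the pipeline's real inputs — a
species phylogeny, log2 maximum lifespan (MLS) evolving under Brownian
motion, expression rows with a planted linear dependence on log2(MLS) plus
phylogenetic and independent noise, per-cell missingness, sign-labeled
partner gene sets with a controllable concordance odds ratio, and promoter
sequences whose planted motif content trends with MLS.

The trait is simulated directly on the log2 scale (the analysis regresses on
log2 MLS); exported MLS in years is ``2 ** trait``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .core_io import (
    ExpressionMatrix,
    MotifModel,
    PhyloTree,
    PhyloTreeEnsemble,
    SignedGeneSet,
    SpeciesRecord,
    phylo_covariance,
)

MIN_OBSERVED_SPECIES = 10  # genes must stay observable in >= 10 species


@dataclass
class SimulationConfig:
    """Study conditions for the end-to-end synthetic analysis.

    Defaults model a 29-mammal compendium: a unit-height ultrametric tree,
    log2(MLS) as Brownian motion of rate 1 around log2(32 years), and planted
    genes whose expected Spearman |rho| with the trait is about 0.8. The
    noise budget (phylogenetic SD 0.1, independent SD 0.54 against slope 1)
    keeps the planted correlation at that level while leaving null genes
    close enough to exchangeable that the rank test retains near-nominal
    error control; the phylogenetic component stays nonzero so the PGLS
    covariance model is genuinely exercised.
    """

    n_species: int = 29
    n_genes: int = 2000
    n_planted: int = 200
    effect_slope: float = 1.0  # log2-TPM change per doubling of MLS
    phylo_noise_sd: float = 0.1
    iid_noise_sd: float = 0.54
    missing_rate: float = 0.10
    concordance_target: float = 3.0
    trait_sigma: float = 1.0
    trait_root: float = 5.0  # log2 years; 2**5 = 32 years
    motif_planted: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted must not exceed n_genes")
        if min(self.phylo_noise_sd, self.iid_noise_sd, self.trait_sigma) < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_species < MIN_OBSERVED_SPECIES:
            raise ValueError(f"need at least {MIN_OBSERVED_SPECIES} species")
        if self.concordance_target <= 0:
            raise ValueError("concordance_target must be positive")


def simulate_tree(n_species: int, seed: int) -> PhyloTree:
    """Pure-birth (Yule) tree rescaled to unit height, leaves sp001..spNNN."""
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(seed)
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    # start from the root split: two active lineages at time 0
    first, second = dendropy.Node(), dendropy.Node()
    tree.seed_node.add_child(first)
    tree.seed_node.add_child(second)
    active: list[tuple[dendropy.Node, float]] = [(first, 0.0), (second, 0.0)]
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node, birth = active.pop(i)
        node.edge.length = t - birth
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        active.append((left, t))
        active.append((right, t))
    t_end = t + rng.exponential(1.0 / n_species)
    labels = iter(f"sp{i + 1:03d}" for i in range(n_species))
    for node, birth in active:
        node.edge.length = t_end - birth
        node.taxon = taxon_namespace.new_taxon(next(labels))
    # rescale to unit height (root-to-tip distance 1 for every leaf)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t_end
    tree.seed_node.edge.length = None
    return PhyloTree(tree)


def simulate_tree_ensemble(
    n_species: int, n_trees: int, seed: int, jitter_sd: float = 0.1
) -> PhyloTreeEnsemble:
    """An ensemble sharing one topology with log-normally jittered branch
    lengths, a desk-scale stand-in for posterior tree samples. The first
    member is the unjittered base tree."""
    base = simulate_tree(n_species, seed)
    rng = np.random.default_rng(seed + 1)
    trees = [base]
    for _ in range(n_trees - 1):
        clone = PhyloTree.from_newick(base.to_newick())
        for edge in clone.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= math.exp(rng.normal(0.0, jitter_sd))
        trees.append(clone)
    return PhyloTreeEnsemble(trees)


def simulate_trait_bm(
    tree: PhyloTree, sigma: float, root_value: float, seed: int
) -> dict[str, float]:
    """Brownian motion down the tree: tip covariance is sigma^2 times the
    shared-branch-length matrix."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.tree.seed_node): root_value}
    out: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_value = values[id(node.parent_node)]
        step_sd = sigma * math.sqrt(node.edge.length or 0.0)
        value = parent_value + (rng.normal(0.0, step_sd) if step_sd > 0 else 0.0)
        values[id(node)] = value
        if node.is_leaf():
            out[node.taxon.label] = value
    return out


def species_records_from_trait(trait: dict[str, float]) -> list[SpeciesRecord]:
    """Turn a simulated log2(MLS) mapping into species trait records
    (MLS in years = 2 ** trait)."""
    return [
        SpeciesRecord(species_id=sp, mls_years=2.0 ** value)
        for sp, value in sorted(trait.items())
    ]


def simulate_expression(
    cfg: SimulationConfig, tree: PhyloTree, trait: dict[str, float]
) -> tuple[ExpressionMatrix, SignedGeneSet]:
    """Expression rows: planted genes follow ``sign * slope * trait`` plus
    Brownian (phylogenetic) and i.i.d. Gaussian noise; null genes are noise
    only. Missingness is per-cell at ``missing_rate`` but every gene keeps at
    least 10 observed species (rows are re-drawn as needed)."""
    species = tree.leaf_labels
    missing_trait = [s for s in species if s not in trait]
    if missing_trait:
        raise ValueError(f"trait undefined for species: {missing_trait}")
    n_sp, n_genes = len(species), cfg.n_genes
    rng = np.random.default_rng(cfg.seed)
    t = np.array([trait[s] for s in species])
    t_centered = t - t.mean()

    # Correlated (phylogenetic) noise via the Cholesky factor of the BM
    # covariance -- equivalent to simulating BM per gene, but vectorized.
    if cfg.phylo_noise_sd > 0:
        V = phylo_covariance(tree, species)
        L = np.linalg.cholesky(V + 1e-12 * np.eye(n_sp))
        phylo_noise = cfg.phylo_noise_sd * rng.standard_normal((n_genes, n_sp)) @ L.T
    else:
        phylo_noise = np.zeros((n_genes, n_sp))
    values = phylo_noise + cfg.iid_noise_sd * rng.standard_normal((n_genes, n_sp))

    planted_idx = rng.choice(n_genes, size=cfg.n_planted, replace=False)
    signs = np.ones(cfg.n_planted, dtype=int)
    signs[1::2] = -1
    for idx, sign in zip(planted_idx, signs):
        values[idx] += sign * cfg.effect_slope * t_centered

    # per-cell missingness, re-drawn per gene until >= 10 species observed
    if cfg.missing_rate > 0:
        expected_kept = n_sp * (1 - cfg.missing_rate)
        if expected_kept < MIN_OBSERVED_SPECIES / 2:
            raise ValueError("missing_rate leaves too few species to be feasible")
        for i in range(n_genes):
            for attempt in range(1000):
                keep = rng.random(n_sp) >= cfg.missing_rate
                if keep.sum() >= MIN_OBSERVED_SPECIES:
                    break
            else:
                raise ValueError("could not satisfy the 10-species floor")
            values[i, ~keep] = np.nan

    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    planted = SignedGeneSet(
        {gene_ids[idx]: int(sign) for idx, sign in zip(planted_idx, signs)},
        {"source": "planted", "trait": "log2_mls"},
    )
    return ExpressionMatrix(gene_ids, list(species), values), planted


def simulate_signed_partner_set(
    universe: list[str],
    anchor: SignedGeneSet,
    target_or: float,
    set_size: int,
    seed: int,
) -> SignedGeneSet:
    """A signed set whose expected concordance odds ratio with ``anchor`` is
    ``target_or``.

    Sign-matched anchor members receive sampling weight ``w`` (solved from
    the odds-ratio equation below) while every other (gene, sign) item has
    weight 1; ``target_or = 1`` gives w = 1, i.e. uniform sampling. With
    E = n_a * S / (2N) the expected concordant count under independence, the
    required observed count is O = n_a * t * E / (n_a - E + t * E) and
    w = O (2N - n_a) / (n_a (S - O)).
    """
    if set_size > len(universe):
        raise ValueError("set_size exceeds universe")
    if target_or <= 0:
        raise ValueError("target_or must be positive")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    N = len(universe)
    anchor = anchor.restrict(universe)
    n_a = len(anchor)
    anchor_sign = anchor.entries

    if math.isinf(target_or):
        if set_size > n_a:
            raise ValueError("infinite target needs set_size <= |anchor|")
        members = rng.choice(sorted(anchor_sign), size=set_size, replace=False)
        return SignedGeneSet(
            {g: anchor_sign[g] for g in members}, {"source": "partner"}
        )

    E = n_a * set_size / (2 * N)
    O = n_a * target_or * E / (n_a - E + target_or * E)
    if O >= set_size or O >= n_a:
        raise ValueError(
            f"target_or={target_or} infeasible: needs {O:.1f} concordant "
            f"members out of {set_size}"
        )
    w = O * (2 * N - n_a) / (n_a * (set_size - O))

    # weighted sampling of genes without replacement (Efraimidis-Spirakis),
    # gene weight = sum of its two signed-item weights
    is_anchor = np.array([g in anchor_sign for g in universe])
    weights = np.where(is_anchor, w + 1.0, 2.0)
    keys = rng.random(N) ** (1.0 / weights)
    chosen = np.argsort(keys)[-set_size:]

    entries: dict[str, int] = {}
    for idx in chosen:
        gene = universe[idx]
        if gene in anchor_sign:
            match = rng.random() < w / (w + 1.0)
            entries[gene] = anchor_sign[gene] if match else -anchor_sign[gene]
        else:
            entries[gene] = 1 if rng.random() < 0.5 else -1
    return SignedGeneSet(entries, {"source": "partner", "target_or": str(target_or)})


def synthetic_motif(
    motif_id: str,
    consensus: str,
    concentration: float = 0.9,
    background: np.ndarray | None = None,
) -> MotifModel:
    """A sharp synthetic PWM: the consensus base carries ``concentration``
    probability per column, the rest is spread evenly. Labelled synthetic;
    stands in for a JASPAR matrix in simulated runs."""
    consensus = consensus.upper()
    if not set(consensus) <= set("ACGT"):
        raise ValueError("consensus must be over ACGT")
    width = len(consensus)
    freqs = np.full((4, width), (1.0 - concentration) / 3.0)
    for i, base in enumerate(consensus):
        freqs["ACGT".index(base), i] = concentration
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return MotifModel(motif_id, freqs, bg, name=motif_id)


def random_motif(
    motif_id: str,
    width: int,
    seed: int,
    concentration: float = 2.0,
    background: np.ndarray | None = None,
) -> MotifModel:
    """A random PWM with Dirichlet-distributed columns.

    ``concentration`` around 2 yields moderately informative columns whose
    null score distribution is dense, like a typical JASPAR matrix — windows
    near a scan threshold then occur at close to the nominal rate, unlike the
    sharp consensus motifs from :func:`synthetic_motif`.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.dirichlet(np.full(4, concentration), size=width).T
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return MotifModel(motif_id, freqs, bg, name=motif_id)


def write_jaspar_pfm(motifs: list[MotifModel], path, counts_total: int = 100) -> None:
    """Write motifs as JASPAR-style PFM text (counts = frequencies scaled to
    ``counts_total`` per column), round-trippable by the JASPAR reader."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.name or m.motif_id}\n")
            counts = m.frequencies * counts_total
            for b, row in zip("ACGT", counts):
                cells = " ".join(f"{v:.2f}" for v in row)
                fh.write(f"{b} [ {cells} ]\n")


def simulate_promoters(
    species: list[SpeciesRecord],
    genes: list[str],
    motif: MotifModel,
    trend: str = "none",
    length: int = 1000,
    max_insertions: int = 2,
    seed: int = 0,
) -> dict[tuple[str, str], str]:
    """I.i.d. uniform background promoters with planted consensus insertions.

    For ``trend='gain'`` the *mean* planted per-promoter count rises linearly
    with the species' MLS rank, from 0 to ``max_insertions``: each species
    gets a deterministic insertion total ``round(n_genes * max_insertions *
    rank_fraction)`` spread over the genes at random, so the per-species mean
    count is an exact monotone function of MLS rank while per-gene counts
    vary (keeping presence ratios off the 0/1 boundary). ``'loss'`` reverses
    the ramp; ``'none'`` plants nothing. Insertions never overlap within a
    promoter.
    """
    if trend not in ("gain", "loss", "none"):
        raise ValueError(f"unknown trend {trend!r}")
    width = motif.width
    if length < width:
        raise ValueError("promoter length shorter than motif width")
    rng = np.random.default_rng(seed)
    consensus = motif.consensus
    n_sp = len(species)
    ranked = sorted(species, key=lambda r: r.mls_years)
    rank = {r.species_id: i for i, r in enumerate(ranked)}

    out: dict[tuple[str, str], str] = {}
    for rec in species:
        if trend == "none" or n_sp == 1:
            total = 0
        else:
            frac = rank[rec.species_id] / (n_sp - 1)
            if trend == "loss":
                frac = 1.0 - frac
            total = round(len(genes) * max_insertions * frac)
        per_gene = np.bincount(
            rng.integers(0, len(genes), size=total), minlength=len(genes)
        )
        base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
        consensus_bytes = np.frombuffer(consensus.encode("ascii"), dtype=np.uint8)
        for gene, count in zip(genes, per_gene):
            seq = base_bytes[rng.integers(0, 4, size=length)]
            taken: list[tuple[int, int]] = []
            placed = 0
            attempts = 0
            while placed < count and attempts < 1000:
                attempts += 1
                start = int(rng.integers(0, length - width + 1))
                if any(start < e and start + width > s for s, e in taken):
                    continue
                seq[start : start + width] = consensus_bytes
                taken.append((start, start + width))
                placed += 1
            out[(gene, rec.species_id)] = seq.tobytes().decode("ascii")
    return out
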