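"""Forward simulation of a field ``18O``-water qSIP experiment with known truth.

The generator emulates the measurement structure of a replicated warming
experiment: three treatments (ambient control, short-term warming, long-term
warming) x four field blocks x paired ``16O``/``18O`` tubes = 24 tubes, each
fractionated on a CsCl density grid.  For each taxon, DNA mass is spread over
the gradient as a Gaussian centred at its buoyant density — determined by GC
content and, in labeled tubes, its true excess atom fraction — then observed
through noisy qPCR totals and multinomial sequencing counts.

Ground truth (GC, per-treatment EAF, phylogeny, nested taxonomy) is retained
so every downstream stage has a parameter-recovery test surface.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.special import ndtr

from .core import labeled_density, unlabeled_density
from .data import RANKS, QsipDataset

__all__ = [
    "SimConfig",
    "TrueCommunity",
    "simulate_tree",
    "simulate_bm_trait",
    "assign_taxonomy",
    "simulate_tube",
    "simulate_experiment",
]

#: Tree cut heights (fraction of root-to-tip height) defining ranks
#: phylum .. species; the domain rank is the whole tree.
DEFAULT_RANK_DEPTHS = (0.15, 0.35, 0.55, 0.70, 0.85, 0.95)


@dataclass
class SimConfig:
    """Study-design and noise parameters of the simulated experiment.

    Defaults mirror a field qSIP warming study: 3 treatments x 4 blocks with
    paired isotope tubes (24 tubes), an 18-fraction CsCl gradient, ~66 atom %
    ``18O`` water capping attainable enrichment, and latent growth rates with
    phylogenetic signal (Brownian motion on the simulated tree) shifted
    additively by warming.
    """

    n_taxa: int = 200
    n_blocks: int = 4
    treatments: tuple = ("control", "STW", "LTW")
    #: additive shift of the latent growth trait per treatment (same order
    #: as ``treatments``); defaults give assemblage means near 0.07 / 0.095 /
    #: 0.176 among growing taxa.
    treatment_effect: tuple = (0.0, 0.025, 0.106)
    n_fractions: int = 18
    density_range: tuple = (1.640, 1.760)
    profile_sd: float = 0.006
    sequencing_depth: int = 10_000
    qpcr_total: float = 1e8
    qpcr_cv: float = 0.15
    #: Brownian-motion rate of the latent growth trait (unit-height tree).
    bm_sigma2: float = 0.004
    #: root value of the latent growth trait (EAF scale).
    eaf_root: float = 0.07
    #: cap on true EAF; ~66 atom % labeling water makes higher values
    #: physically unattainable.
    eaf_cap: float = 0.6
    gc_range: tuple = (0.35, 0.65)
    #: lognormal sigma of per-taxon biomass weights.
    biomass_sigma: float = 1.0
    #: per-fraction relative abundances below this are unobserved (dropout).
    detection_floor: float = 1e-3
    #: bypass the multinomial draw and report exact relative abundances.
    exact_abundances: bool = False
    rank_depths: tuple = DEFAULT_RANK_DEPTHS
    seed: int = 0

    def __post_init__(self):
        if self.n_fractions < 4:
            raise ValueError("n_fractions must be >= 4")
        if not self.density_range[0] < self.density_range[1]:
            raise ValueError("density_range must be (min, max) with min < max")
        if self.profile_sd <= 0:
            raise ValueError("profile_sd must be positive")
        for name in ("n_taxa", "n_blocks", "sequencing_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.treatment_effect) != len(self.treatments):
            raise ValueError("one treatment_effect per treatment")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class TrueCommunity:
    """Simulator ground truth: what the pipeline should recover."""

    taxa: list
    gc: np.ndarray                      # (n,) in (0, 1)
    true_eaf: dict                      # treatment -> (n,) array in [0, eaf_cap]
    weights: np.ndarray                 # (n,) relative biomass, sums to 1
    tree: dendropy.Tree
    taxonomy: pd.DataFrame
    latent_trait: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "taxa": list(self.taxa),
            "gc": self.gc.tolist(),
            "true_eaf": {str(t): v.tolist() for t, v in self.true_eaf.items()},
            "weights": self.weights.tolist(),
        }


# ---------------------------------------------------------------------------
# phylogeny, traits, taxonomy
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) phylogeny with ``n_taxa`` tips, scaled to unit height.

    Terminal edges are extended by the waiting time to the next (unrealised)
    speciation so the final cherry does not sit on zero-length branches; the
    tree is ultrametric and deterministic given ``seed``.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa, rng=rng,
        repeat_until_success=True,
    )
    extra = rng.expovariate(n_taxa * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    if tree.seed_node.edge is not None:
        tree.seed_node.edge.length = None
    tree.calc_node_root_distances()
    height = max(lf.root_distance for lf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height

    ns = dendropy.TaxonNamespace()
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(),
                                    key=lambda lf: lf.taxon.label)):
        taxon = dendropy.Taxon(label=f"ASV{i + 1:04d}")
        ns.add_taxon(taxon)
        leaf.taxon = taxon
    tree.taxon_namespace = ns
    tree.calc_node_root_distances()
    return tree


def simulate_bm_trait(tree: dendropy.Tree, sigma2: float, root_value: float,
                      seed) -> pd.Series:
    """Brownian-motion trait evolved along the tree; one value per tip.

    The marginal variance of tip ``i`` is ``sigma2 * depth(i)`` and the
    covariance of two tips is ``sigma2`` times their shared root-to-MRCA
    branch length.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    values = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = float(root_value)
        else:
            edge = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(
                0.0, np.sqrt(sigma2 * edge))
    tips = {lf.taxon.label: values[lf] for lf in tree.leaf_node_iter()}
    return pd.Series(tips).sort_index()


def assign_taxonomy(tree: dendropy.Tree,
                    rank_depths=DEFAULT_RANK_DEPTHS) -> pd.DataFrame:
    """Nested rank labels from cutting the (unit-height) tree at fixed depths.

    Each tip's label at a rank is the clade it falls in when the tree is cut
    at that rank's depth; because depths increase, labels are strictly nested
    (each genus maps into exactly one family, and so on).  The domain rank is
    constant and the species label is the tip itself.
    """
    depths = tuple(rank_depths)
    if list(depths) != sorted(depths) or len(set(depths)) != len(depths):
        raise ValueError("rank_depths must be strictly increasing")
    if not all(0 < d < 1 for d in depths):
        raise ValueError("rank_depths must lie in (0, 1)")
    if len(depths) > len(RANKS) - 1:
        raise ValueError(f"at most {len(RANKS) - 1} cut depths supported")
    cut_ranks = RANKS[1:1 + len(depths)]
    tree.calc_node_root_distances()
    node_id = {nd: i for i, nd in enumerate(tree.preorder_node_iter())}

    rows = {}
    for leaf in tree.leaf_node_iter():
        chain = []
        nd = leaf
        while nd is not None:
            chain.append(nd)
            nd = nd.parent_node
        chain.reverse()  # root .. leaf
        labels = {"domain": "d__Bacteria"}
        for rank, h in zip(cut_ranks, depths):
            clade = next(nd for nd in chain[1:] if nd.root_distance > h)
            labels[rank] = f"{rank[0]}__{rank[0].upper()}{node_id[clade]}"
        for rank in RANKS[1 + len(depths):]:  # un-cut fine ranks: tip identity
            labels[rank] = f"{rank[0]}__{leaf.taxon.label}"
        rows[leaf.taxon.label] = labels
    tax = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    tax.index.name = "taxon_id"
    return tax[list(RANKS)]


# ---------------------------------------------------------------------------
# measurement model
# ---------------------------------------------------------------------------

def _fraction_grid(config: SimConfig):
    edges = np.linspace(*config.density_range, config.n_fractions + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    return edges, mids


def simulate_tube(community: TrueCommunity, treatment, isotope: str,
                  block, config: SimConfig, rng: np.random.Generator):
    """Simulate one fractionated tube.

    Returns ``(fraction_rows, counts)``: per-fraction metadata rows (list of
    dicts) and the taxa x fractions count (or exact-abundance) matrix.
    """
    if isotope not in ("16O", "18O"):
        raise ValueError(f"unknown isotope {isotope!r}")
    if treatment not in config.treatments:
        raise ValueError(f"unknown treatment {treatment!r}")
    gc = community.gc
    if isotope == "18O":
        centers = labeled_density(gc, community.true_eaf[treatment])
    else:
        centers = unlabeled_density(gc)

    lo, hi = config.density_range
    clearance = 3 * config.profile_sd
    n_out = int(np.sum((centers < lo + clearance) | (centers > hi - clearance)))
    if n_out:
        warnings.warn(
            f"{n_out} taxon density center(s) within 3 sd of the gradient "
            "edge; profile mass truncated", stacklevel=2)

    edges, mids = _fraction_grid(config)
    z_hi = (edges[None, 1:] - centers[:, None]) / config.profile_sd
    z_lo = (edges[None, :-1] - centers[:, None]) / config.profile_sd
    probs = ndtr(z_hi) - ndtr(z_lo)                     # (taxa, fractions)
    mass = community.weights[:, None] * probs
    frac_mass = mass.sum(axis=0)
    totals = config.qpcr_total * frac_mass / mass.sum()
    if config.qpcr_cv > 0:
        sig2 = np.log1p(config.qpcr_cv ** 2)
        totals = totals * rng.lognormal(-sig2 / 2, np.sqrt(sig2), size=totals.shape)

    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(frac_mass > 0, mass / frac_mass, 0.0)
    shares[shares < config.detection_floor] = 0.0
    colsum = shares.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(colsum > 0, shares / colsum, 0.0)

    if config.exact_abundances:
        counts = shares
    else:
        counts = np.zeros_like(shares)
        for j in range(shares.shape[1]):
            if shares[:, j].sum() > 0:
                counts[:, j] = rng.multinomial(config.sequencing_depth, shares[:, j])

    tube_id = f"{treatment}.B{block}.{isotope}"
    rows = [
        {
            "tube_id": tube_id, "treatment": treatment, "block": block,
            "isotope": isotope, "fraction_idx": j + 1,
            "density_g_ml": mids[j], "total_16s_copies": totals[j],
        }
        for j in range(config.n_fractions)
    ]
    return rows, counts


def _build_community(config: SimConfig, ss: np.random.SeedSequence) -> TrueCommunity:
    s_tree, s_trait, s_gc, s_w = ss.spawn(4)
    tree = simulate_tree(config.n_taxa, seed=s_tree.generate_state(1)[0] % (2**31))
    taxonomy = assign_taxonomy(tree, config.rank_depths)
    latent = simulate_bm_trait(tree, config.bm_sigma2, config.eaf_root,
                               seed=s_trait)
    taxa = list(latent.index)
    rng_gc = np.random.default_rng(s_gc)
    gc = rng_gc.uniform(*config.gc_range, size=config.n_taxa)
    rng_w = np.random.default_rng(s_w)
    w = rng_w.lognormal(0.0, config.biomass_sigma, size=config.n_taxa)
    w /= w.sum()
    true_eaf = {
        tr: np.clip(latent.to_numpy() + eff, 0.0, config.eaf_cap)
        for tr, eff in zip(config.treatments, config.treatment_effect)
    }
    return TrueCommunity(taxa=taxa, gc=gc, true_eaf=true_eaf, weights=w,
                         tree=tree, taxonomy=taxonomy,
                         latent_trait=latent.to_numpy())


def simulate_experiment(config: SimConfig) -> QsipDataset:
    """Simulate the full experiment: all treatments x blocks x isotopes.

    Randomness flows from ``config.seed`` through a ``numpy.random.SeedSequence``
    split (community first, then one child stream per tube in a fixed order),
    so the output is byte-identical across runs with the same config.
    """
    ss = np.random.SeedSequence(config.seed)
    ss_comm, ss_tubes = ss.spawn(2)
    community = _build_community(config, ss_comm)

    tube_keys = [
        (tr, b, iso)
        for tr in config.treatments
        for b in range(1, config.n_blocks + 1)
        for iso in ("16O", "18O")
    ]
    tube_seeds = ss_tubes.spawn(len(tube_keys))

    frac_rows = []
    count_cols = {}
    for (tr, b, iso), child in zip(tube_keys, tube_seeds):
        rng = np.random.default_rng(child)
        rows, counts = simulate_tube(community, tr, iso, b, config, rng)
        frac_rows.extend(rows)
        for j, row in enumerate(rows):
            count_cols[f"{row['tube_id']}.F{row['fraction_idx']}"] = counts[:, j]

    fractions = pd.DataFrame(frac_rows)
    counts = pd.DataFrame(count_cols, index=community.taxa)
    truth = {
        "seed": int(config.seed),
        **community.to_dict(),
        "growing": {str(tr): (community.true_eaf[tr] > 0).tolist()
                    for tr in config.treatments},
    }
    return QsipDataset(fractions=fractions, counts=counts,
                       taxonomy=community.taxonomy, tree=community.tree,
                       truth=truth, config=config.to_dict())
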