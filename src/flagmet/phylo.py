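"""Phylogenetic and taxonomic conservatism of a binary trait.

Three analyses:

* the Fritz–Purvis D statistic for binary traits.  Trait values are
  propagated to internal nodes by averaging descendants and the observed
  statistic d_obs is the sum of |sister differences| over internal nodes.
  Two nulls scale it: tip-permutation (phylogenetically random) and
  threshold Brownian motion (conserved).  D = (d_obs − mean_brownian) /
  (mean_random − mean_brownian), so D ≈ 1 for random traits and D ≈ 0 for
  Brownian-like conservatism;

* mean within-taxon standard deviation of the trait per taxonomic rank
  (taxa represented by a single genome are excluded);

* genome-size-corrected gene-category enrichment between trait classes
  (Mann–Whitney U with Bonferroni correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from flagmet.errors import ValidationError

logger = logging.getLogger("flagmet")

RANKS = ("phylum", "class", "order", "family", "genus")


# ---------------------------------------------------------------------------
# Tree linearization
# ---------------------------------------------------------------------------

@dataclass
class _LinearTree:
    tip_labels: list[str]
    # internal nodes in postorder; children indices refer to the global
    # node numbering (tips 0..n_tips-1, internals n_tips..)
    child_pairs: np.ndarray  # (n_internal, 2)
    parents: np.ndarray      # (n_nodes,) parent index, -1 for root
    edge_lengths: np.ndarray  # (n_nodes,) length of the edge above each node
    preorder: np.ndarray     # node indices root-first

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parents)


def _linearize(tree: dendropy.Tree) -> _LinearTree:
    """Resolve polytomies to binary (zero-length branches) and index nodes."""
    tree = tree.clone(depth=1)
    tree.resolve_polytomies(limit=2, update_bipartitions=False)
    tips = [leaf for leaf in tree.leaf_node_iter()]
    idx: dict = {}
    for i, leaf in enumerate(tips):
        idx[leaf] = i
    internals = [
        nd for nd in tree.postorder_node_iter() if not nd.is_leaf()
    ]
    for j, nd in enumerate(internals):
        idx[nd] = len(tips) + j
    n_nodes = len(tips) + len(internals)
    child_pairs = np.empty((len(internals), 2), dtype=int)
    parents = np.full(n_nodes, -1, dtype=int)
    edge_lengths = np.zeros(n_nodes)
    for j, nd in enumerate(internals):
        children = nd.child_nodes()
        if len(children) != 2:
            raise ValidationError(
                f"internal node with {len(children)} children after resolution"
            )
        child_pairs[j] = [idx[c] for c in children]
        for c in children:
            parents[idx[c]] = idx[nd]
    for nd, i in idx.items():
        if nd.edge.length is not None:
            edge_lengths[i] = float(nd.edge.length)
        elif parents[i] != -1:
            edge_lengths[i] = 1.0  # missing branch lengths default to 1
    labels = []
    for leaf in tips:
        if leaf.taxon is None or leaf.taxon.label is None:
            raise ValidationError("tree contains an unlabeled tip")
        labels.append(leaf.taxon.label)
    preorder = np.array([idx[nd] for nd in tree.preorder_node_iter()], dtype=int)
    return _LinearTree(labels, child_pairs, parents, edge_lengths, preorder)


def _d_sums(lt: _LinearTree, tip_values: np.ndarray) -> np.ndarray:
    """Sister-clade difference sums for one or many tip labelings.

    ``tip_values`` has shape (n_tips,) or (n_tips, n_sims); returns an
    array of shape (n_sims,) (or (1,)).
    """
    vals2 = tip_values if tip_values.ndim == 2 else tip_values[:, None]
    n_sims = vals2.shape[1]
    nodes = np.empty((lt.n_nodes, n_sims))
    nodes[: lt.n_tips] = vals2
    d = np.zeros(n_sims)
    for j, (c1, c2) in enumerate(lt.child_pairs):
        v1, v2 = nodes[c1], nodes[c2]
        nodes[lt.n_tips + j] = (v1 + v2) / 2.0
        d += np.abs(v1 - v2)
    return d


def _brownian_tips(
    lt: _LinearTree, n_sims: int, rng: np.random.Generator
) -> np.ndarray:
    """Brownian values at the tips: root-to-tip sums of N(0, branch length)."""
    vals = np.zeros((lt.n_nodes, n_sims))
    for i in lt.preorder:
        p = lt.parents[i]
        if p == -1:
            continue
        sd = np.sqrt(max(lt.edge_lengths[i], 0.0))
        vals[i] = vals[p] + rng.standard_normal(n_sims) * sd
    return vals[: lt.n_tips]


# ---------------------------------------------------------------------------
# D statistic
# ---------------------------------------------------------------------------

@dataclass
class DResult:
    """Observed sister-difference sum, its two nulls and the D statistic.

    ``p_random`` is the fraction of permutation-null sums ≤ d_obs (small
    means more conserved than random); ``p_brownian`` is the fraction of
    Brownian-null sums ≥ d_obs (small means more overdispersed than
    Brownian).  Both use the add-one empirical estimator.
    """

    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    D: float
    p_random: float
    p_brownian: float
    n_sims: int
    seed: int

    def summary(self) -> str:
        return (
            "Phylogenetic D (binary trait)\n"
            "-----------------------------\n"
            f"d_obs              = {self.d_obs:.4f}\n"
            f"mean d (random)    = {self.mean_d_random:.4f}\n"
            f"mean d (Brownian)  = {self.mean_d_brownian:.4f}\n"
            f"D                  = {self.D:.4f}\n"
            f"P(random <= obs)   = {self.p_random:.4g}\n"
            f"P(Brownian >= obs) = {self.p_brownian:.4g}\n"
            f"simulations        = {self.n_sims} per null"
        )


def estimate_D(
    tree: dendropy.Tree,
    traits: dict[str, int] | pd.Series,
    n_sims: int = 1000,
    seed: int = 0,
) -> DResult:
    """Fritz–Purvis D with permutation and threshold-Brownian nulls.

    ``traits`` maps tip labels to 0/1.  The Brownian null thresholds each
    simulated continuous trait so that its prevalence matches the observed
    count of ones (rank matching).  Reproducible under ``seed``; requires
    at least 4 tips, both states present and ``n_sims`` ≥ 100.
    """
    if isinstance(traits, pd.Series):
        traits = traits.to_dict()
    if n_sims < 100:
        raise ValidationError("n_sims must be >= 100 for a stable D estimate")
    lt = _linearize(tree)
    if lt.n_tips < 4:
        raise ValidationError("D needs a tree with >= 4 tips")
    missing = [t for t in lt.tip_labels if t not in traits]
    if missing:
        raise ValidationError(f"tips without trait values: {missing}")
    obs = np.array([int(traits[t]) for t in lt.tip_labels], dtype=float)
    if not set(np.unique(obs)) == {0.0, 1.0}:
        raise ValidationError("trait must be binary with both states present")
    k_ones = int(obs.sum())
    rng = np.random.default_rng(seed)

    d_obs = float(_d_sums(lt, obs)[0])

    perm = np.empty((lt.n_tips, n_sims))
    for s in range(n_sims):
        perm[:, s] = rng.permutation(obs)
    d_rand = _d_sums(lt, perm)

    bm = _brownian_tips(lt, n_sims, rng)
    thresh = np.zeros_like(bm)
    top = np.argpartition(-bm, k_ones - 1, axis=0)[:k_ones]
    np.put_along_axis(thresh, top, 1.0, axis=0)
    d_brown = _d_sums(lt, thresh)

    mean_rand = float(d_rand.mean())
    mean_brown = float(d_brown.mean())
    denom = mean_rand - mean_brown
    if abs(denom) < 1e-12:
        raise ValidationError("degenerate nulls: random and Brownian means coincide")
    D = (d_obs - mean_brown) / denom
    p_random = float((1 + (d_rand <= d_obs).sum()) / (n_sims + 1))
    p_brownian = float((1 + (d_brown >= d_obs).sum()) / (n_sims + 1))
    return DResult(
        d_obs=d_obs, mean_d_random=mean_rand, mean_d_brownian=mean_brown,
        D=float(D), p_random=p_random, p_brownian=p_brownian,
        n_sims=n_sims, seed=seed,
    )


# ---------------------------------------------------------------------------
# Rank conservation
# ---------------------------------------------------------------------------

@dataclass
class RankConservation:
    """Mean within-taxon trait SD per taxonomic rank."""

    table: pd.DataFrame  # index rank; columns mean_sd, n_taxa

    def summary(self) -> str:
        return self.table.to_string()


def rank_conservation(
    taxonomy: pd.DataFrame, traits: pd.Series, ranks: tuple[str, ...] = RANKS
) -> RankConservation:
    """Per rank, the mean sample SD of the binary trait within taxa.

    ``taxonomy`` is indexed by genome id with one column per rank.  Taxa
    represented by a single genome are excluded; ranks missing from the
    taxonomy are skipped with a warning.
    """
    rows = []
    traits = traits.astype(float)
    for rank in ranks:
        if rank not in taxonomy.columns:
            logger.warning("rank %r absent from taxonomy; skipped", rank)
            continue
        joined = pd.DataFrame({
            "taxon": taxonomy[rank], "trait": traits.reindex(taxonomy.index)
        }).dropna()
        sds = []
        for _, grp in joined.groupby("taxon"):
            if len(grp) >= 2:
                sds.append(float(grp["trait"].std(ddof=1)))
        if sds:
            rows.append({"rank": rank, "mean_sd": float(np.mean(sds)),
                         "n_taxa": len(sds)})
        else:
            rows.append({"rank": rank, "mean_sd": float("nan"), "n_taxa": 0})
    return RankConservation(pd.DataFrame(rows).set_index("rank"))


# ---------------------------------------------------------------------------
# Group enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentTable:
    """Per-category group means, log2 fold ratio, and corrected p-values."""

    table: pd.DataFrame
    alpha: float
    group_names: tuple[str, str]

    def summary(self) -> str:
        return self.table.to_string()


def group_enrichment(
    feature_counts: pd.DataFrame,
    genome_sizes: pd.Series,
    groups: pd.Series,
    alpha: float = 0.01,
) -> EnrichmentTable:
    """Compare genome-size-corrected category prevalence between two groups.

    Per-genome prevalence is the category count divided by the genome's
    total annotated gene count.  For each category the table reports the
    two group means, log2(mean_A / mean_B), the two-sided Mann–Whitney U
    p-value (exact where scipy can), the Bonferroni-adjusted p
    (min(1, p × n_categories)) and a significance flag at ``alpha``.
    Categories absent from both groups are reported with missing values.
    """
    names = sorted(groups.dropna().unique().tolist())
    if len(names) != 2:
        raise ValidationError(f"need exactly two groups, got {names}")
    g_a, g_b = names
    ids_a = groups.index[groups == g_a]
    ids_b = groups.index[groups == g_b]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError("each group needs at least 2 genomes")
    prevalence = feature_counts.div(genome_sizes.reindex(feature_counts.index), axis=0)
    rows = []
    categories = list(feature_counts.columns)
    for cat in categories:
        a = prevalence.loc[ids_a, cat].dropna().to_numpy()
        b = prevalence.loc[ids_b, cat].dropna().to_numpy()
        mean_a, mean_b = float(a.mean()), float(b.mean())
        if mean_a == 0.0 and mean_b == 0.0:
            rows.append({
                "category": cat, f"mean_{g_a}": 0.0, f"mean_{g_b}": 0.0,
                "log2_ratio": float("nan"), "p_value": float("nan"),
                "p_adjusted": float("nan"), "significant": False,
            })
            continue
        if mean_a > 0 and mean_b > 0:
            log2_ratio = float(np.log2(mean_a / mean_b))
        else:
            log2_ratio = float("nan")
        if np.array_equal(np.sort(a), np.sort(b)):
            p = 1.0  # identical samples; U test is uninformative
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({
            "category": cat, f"mean_{g_a}": mean_a, f"mean_{g_b}": mean_b,
            "log2_ratio": log2_ratio, "p_value": p,
            "p_adjusted": min(1.0, p * len(categories)),
            "significant": False,
        })
    table = pd.DataFrame(rows).set_index("category")
    table["significant"] = table["p_adjusted"] <= alpha
    return EnrichmentTable(table=table, alpha=alpha, group_names=(g_a, g_b))
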