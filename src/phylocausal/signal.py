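"""Phylogenetic signal for binary traits: the D statistic.

D contrasts the observed sum of sister-clade differences of a binary trait
with two reference distributions obtained by simulation on the same tree:

* a *random* null, where tip values are permuted across tips (no signal,
  D calibrated to 1), and
* a *Brownian threshold* null, where a continuous liability evolves by
  Brownian motion along the branches and is thresholded to match the
  observed prevalence (strong signal, D calibrated to 0).

``D = (d_obs - mean_brownian) / (mean_random - mean_brownian)``.

Node values for the sister-clade sums are obtained by a single post-order
pass of branch-length-weighted child averaging (weights 1/branch length,
Felsenstein-style), so trees must be binary; polytomies are resolved with
zero-length branches beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treedata import Phylogeny

# Relative floor applied to branch lengths when forming 1/length weights, so
# zero-length branches (e.g. from polytomy resolution) dominate their sister
# without producing infinities.
_LENGTH_FLOOR = 1e-9


@dataclass(frozen=True)
class DResult:
    """Result of a D-statistic computation for one binary trait."""

    trait: str
    d_obs: float
    mean_random: float
    mean_brownian: float
    D: float
    p_random: float      # P(permuted sum <= observed): departure from D = 1
    p_brownian: float    # P(Brownian sum >= observed): departure from D = 0
    n_perm: int
    n_sim: int
    n_tips: int
    prevalence: float
    seed: int

    def as_dict(self) -> dict:
        return {
            "trait": self.trait,
            "d_obs": self.d_obs,
            "mean_random": self.mean_random,
            "mean_brownian": self.mean_brownian,
            "D": self.D,
            "p_random": self.p_random,
            "p_brownian": self.p_brownian,
            "n_perm": self.n_perm,
            "n_sim": self.n_sim,
            "n_tips": self.n_tips,
            "prevalence": self.prevalence,
            "seed": self.seed,
        }


def _check_binary(trait: np.ndarray) -> np.ndarray:
    trait = np.asarray(trait, dtype=float)
    if np.isnan(trait).any():
        raise ValueError("trait contains NA; complete data required")
    if not np.isin(trait, (0.0, 1.0)).all():
        raise ValueError("trait values must be 0 or 1")
    return trait


def estimate_node_values(tree: Phylogeny, trait: np.ndarray) -> np.ndarray:
    """Internal-node trait values by branch-length-weighted child averaging.

    Returns an array over all nodes (tips first, then internals) in the
    tree's index order; each internal value lies in [0, 1].
    """
    trait = _check_binary(trait)
    idx = tree.index()
    if trait.shape[0] != idx.n_tips:
        raise ValueError("trait length does not match number of tips")
    values = np.zeros(idx.n_nodes)
    values[: idx.n_tips] = trait
    scale = max(tree.height, _LENGTH_FLOOR)
    floor = _LENGTH_FLOOR * scale
    for nid in idx.internal_postorder:
        kids = idx.children[nid]
        w = np.array([1.0 / max(idx.edge_length[k], floor) for k in kids])
        values[nid] = float(np.dot(w, values[list(kids)]) / w.sum())
    return values


def _sister_sums(tree: Phylogeny, traits: np.ndarray) -> np.ndarray:
    """Vectorized sum of sister-clade differences, one per trait column.

    ``traits`` is (n_tips, m); the weighted-averaging recursion and the
    |left - right| sums are evaluated for all m columns in one post-order
    sweep.
    """
    idx = tree.index()
    n_tips = idx.n_tips
    m = traits.shape[1]
    values = np.empty((idx.n_nodes, m))
    values[:n_tips] = traits
    scale = 1.0
    depths = idx.depth[:n_tips]
    if depths.size:
        scale = max(float(depths.max()), _LENGTH_FLOOR)
    floor = _LENGTH_FLOOR * scale
    sums = np.zeros(m)
    for nid in idx.internal_postorder:
        kids = idx.children[nid]
        if len(kids) != 2:
            raise ValueError(
                "sister-clade sums require a binary tree; resolve polytomies first"
            )
        a, b = kids
        wa = 1.0 / max(idx.edge_length[a], floor)
        wb = 1.0 / max(idx.edge_length[b], floor)
        va, vb = values[a], values[b]
        sums += np.abs(va - vb)
        values[nid] = (wa * va + wb * vb) / (wa + wb)
    return sums


def sum_sister_differences(tree: Phylogeny, trait: np.ndarray) -> float:
    """Observed sum over internal nodes of |value(left) - value(right)|."""
    trait = _check_binary(trait)
    return float(_sister_sums(tree, trait[:, None])[0])


def brownian_liabilities(tree: Phylogeny, n_reps: int, rng: np.random.Generator) -> np.ndarray:
    """Tip liabilities of ``n_reps`` independent Brownian motions on the tree.

    Increments along each branch are Normal(0, branch length); returns an
    (n_tips, n_reps) array.
    """
    idx = tree.index()
    values = np.zeros((idx.n_nodes, n_reps))
    order = idx.postorder[::-1]  # preorder: parents before children
    sd = np.sqrt(idx.edge_length)
    for nid in order:
        p = idx.parent[nid]
        if p < 0:
            continue
        values[nid] = values[p] + sd[nid] * rng.standard_normal(n_reps)
    return values[: idx.n_tips]


def threshold_at_prevalence(liabilities: np.ndarray, k_ones: int) -> np.ndarray:
    """Binarize each liability column so exactly ``k_ones`` tips get a 1.

    The tips with the largest liabilities become 1; ties (absent almost
    surely for continuous liabilities) resolve by position.
    """
    n = liabilities.shape[0]
    if not 0 <= k_ones <= n:
        raise ValueError("k_ones out of range")
    out = np.zeros_like(liabilities)
    if k_ones == 0:
        return out
    order = np.argsort(-liabilities, axis=0, kind="stable")
    cols = np.arange(liabilities.shape[1])
    out[order[:k_ones], cols] = 1.0
    return out


def simulate_threshold_binary(tree: Phylogeny, prevalence: float, seed) -> np.ndarray:
    """One binary trait under the Brownian threshold model.

    The liability is Brownian on the tree; the threshold is the empirical
    quantile giving exactly ``round(prevalence * n_tips)`` ones.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = tree.n_tips
    k = int(round(prevalence * n))
    k = min(max(k, 1), n - 1)
    liab = brownian_liabilities(tree, 1, rng)
    return threshold_at_prevalence(liab, k)[:, 0]


def d_statistic(
    tree: Phylogeny,
    trait: np.ndarray,
    n_perm: int = 1000,
    n_sim: int = 1000,
    seed: int = 0,
    trait_name: str = "trait",
) -> DResult:
    """Compute D with permutation and Brownian-threshold null distributions.

    Parameters
    ----------
    tree
        Rooted phylogeny; polytomies are resolved internally.
    trait
        Binary tip values aligned with ``tree.tip_labels``; must contain at
        least one 0 and one 1.
    n_perm, n_sim
        Sizes of the random (tip-permutation) and Brownian nulls.
    seed
        Seed for both null streams.
    """
    trait = _check_binary(trait)
    if trait.min() == trait.max():
        raise ValueError("D undefined for a constant trait")
    if n_perm < 1 or n_sim < 1:
        raise ValueError("n_perm and n_sim must be positive")
    btree = tree.resolved_binary()
    if list(btree.tip_labels) != list(tree.tip_labels):
        # polytomy resolution preserves tip order; guard anyway
        order = [btree.tip_labels.index(l) for l in tree.tip_labels]
        raise AssertionError(f"tip order changed during resolution: {order[:3]}...")
    rng = np.random.default_rng(seed)
    n = btree.n_tips
    k = int(trait.sum())

    d_obs = float(_sister_sums(btree, trait[:, None])[0])

    perm = np.empty((n, n_perm))
    for j in range(n_perm):
        perm[:, j] = rng.permutation(trait)
    perm_sums = _sister_sums(btree, perm)

    liab = brownian_liabilities(btree, n_sim, rng)
    brown = threshold_at_prevalence(liab, k)
    brown_sums = _sister_sums(btree, brown)

    mean_random = float(perm_sums.mean())
    mean_brownian = float(brown_sums.mean())
    denom = mean_random - mean_brownian
    if denom <= 0:
        raise ValueError(
            "degenerate nulls: mean permuted sum does not exceed mean Brownian sum"
        )
    D = (d_obs - mean_brownian) / denom
    p_random = float(np.mean(perm_sums <= d_obs))
    p_brownian = float(np.mean(brown_sums >= d_obs))
    return DResult(
        trait=trait_name,
        d_obs=d_obs,
        mean_random=mean_random,
        mean_brownian=mean_brownian,
        D=float(D),
        p_random=p_random,
        p_brownian=p_brownian,
        n_perm=n_perm,
        n_sim=n_sim,
        n_tips=n,
        prevalence=k / n,
        seed=seed,
    )
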