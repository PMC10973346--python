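"""Trees, trait tables, and coordinates: parsing, validation, and alignment.

This module provides the data layer for the comparative analyses: a validated
rooted :class:`Phylogeny` (backed by dendropy), readers for long-format binary
trait tables and coordinate tables, the derivation of the three analysis
traits (``case``, ``verb_final``, ``flexible``) from raw Grambank-style
feature codes, and the phylogenetic correlation matrix used by every
downstream regression.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("phylocausal")

#: The three derived analysis traits, in canonical column order.
ANALYSIS_TRAITS = ("case", "verb_final", "flexible")

#: Raw feature codes consumed by :func:`derive_features`.
RAW_FEATURES = ("GB070", "GB131", "GB132", "GB133", "GB136")


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed into a valid phylogeny."""


class AlignmentError(ValueError):
    """Raised when tree tips and trait taxa cannot be reconciled."""


@dataclass(frozen=True)
class TreeIndex:
    """Array view of a phylogeny used by the numerical routines.

    Nodes are numbered so that tips come first (0..n_tips-1, in
    ``tip_labels`` order) followed by internal nodes; ``postorder`` visits
    children before parents and ends at the root.
    """

    n_tips: int
    n_nodes: int
    parent: np.ndarray          # (n_nodes,) int, -1 at the root
    edge_length: np.ndarray     # (n_nodes,) float, 0.0 at the root
    postorder: np.ndarray       # (n_nodes,) int
    children: tuple             # tuple of tuples of child ids
    depth: np.ndarray           # (n_nodes,) root-to-node path length

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    @property
    def internal_postorder(self) -> np.ndarray:
        return self.postorder[self.postorder >= self.n_tips]


class Phylogeny:
    """A rooted phylogeny with non-negative branch lengths and unique tips.

    Instances are treated as immutable: transforming methods
    (:meth:`pruned_to`, :meth:`resolved_binary`, :meth:`scaled_to_unit_height`)
    return new objects.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._index_cache: TreeIndex | None = None

    # ------------------------------------------------------------------ IO

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        if not isinstance(text, str) or not text.strip():
            raise NewickParseError("empty Newick input")
        stripped = text.strip()
        if stripped.count(";") > 1:
            raise NewickParseError("expected a single Newick statement")
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path, "r", encoding="utf-8-sig", newline=None) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        out = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        )
        return out.strip() + "\n"

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick())

    # ---------------------------------------------------------- validation

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise NewickParseError("unlabeled tip in tree")
            labels.append(leaf.taxon.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickParseError(f"duplicate tip labels: {sorted(dupes)}")
        for node in self._tree.preorder_node_iter():
            el = node.edge.length
            if node is self._tree.seed_node:
                continue
            if el is None:
                label = node.taxon.label if node.taxon else "<internal>"
                raise NewickParseError(f"missing branch length above {label!r}")
            if el < 0:
                label = node.taxon.label if node.taxon else "<internal>"
                raise NewickParseError(
                    f"negative branch length {el} above {label!r}"
                )

    # ------------------------------------------------------------ accessors

    @property
    def tip_labels(self) -> list:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def height(self) -> float:
        idx = self.index()
        return float(idx.depth[: idx.n_tips].max())

    @property
    def is_binary(self) -> bool:
        for node in self._tree.preorder_internal_node_iter():
            k = len(node.child_nodes())
            if node is self._tree.seed_node:
                if k > 2:
                    return False
            elif k != 2:
                return False
        return True

    def index(self) -> TreeIndex:
        if self._index_cache is None:
            self._index_cache = self._build_index()
        return self._index_cache

    def _build_index(self) -> TreeIndex:
        tips = list(self._tree.leaf_node_iter())
        n_tips = len(tips)
        ids: dict = {}
        for i, leaf in enumerate(tips):
            ids[leaf] = i
        next_id = n_tips
        postorder_nodes = list(self._tree.postorder_node_iter())
        for node in postorder_nodes:
            if node not in ids:
                ids[node] = next_id
                next_id += 1
        n_nodes = next_id
        parent = np.full(n_nodes, -1, dtype=np.int64)
        edge_length = np.zeros(n_nodes)
        children: list = [[] for _ in range(n_nodes)]
        for node in postorder_nodes:
            nid = ids[node]
            if node.parent_node is not None:
                parent[nid] = ids[node.parent_node]
                edge_length[nid] = float(node.edge.length or 0.0)
                children[ids[node.parent_node]].append(nid)
        postorder = np.array([ids[n] for n in postorder_nodes], dtype=np.int64)
        depth = np.zeros(n_nodes)
        for nid in postorder[::-1]:  # preorder
            p = parent[nid]
            if p >= 0:
                depth[nid] = depth[p] + edge_length[nid]
        return TreeIndex(
            n_tips=n_tips,
            n_nodes=n_nodes,
            parent=parent,
            edge_length=edge_length,
            postorder=postorder,
            children=tuple(tuple(c) for c in children),
            depth=depth,
        )

    # -------------------------------------------------------- transformers

    def _clone(self) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )

    def pruned_to(self, labels) -> "Phylogeny":
        """Return the tree restricted to ``labels`` (unifurcations collapsed)."""
        keep = set(labels)
        present = set(self.tip_labels)
        missing = keep - present
        if missing:
            raise AlignmentError(f"labels not in tree: {sorted(missing)[:5]}")
        if not keep:
            raise AlignmentError("cannot prune to an empty label set")
        tree = self._clone()
        tree.retain_taxa_with_labels(sorted(keep))
        return Phylogeny(tree)

    def resolved_binary(self) -> "Phylogeny":
        """Resolve polytomies to a binary tree with zero-length branches.

        Children are combined deterministically left-to-right, so the result
        depends only on the input topology and its child order.
        """
        if self.is_binary:
            return self
        tree = self._clone()
        for node in list(tree.postorder_internal_node_iter()):
            while len(node.child_nodes()) > 2:
                kids = node.child_nodes()
                c1, c2 = kids[0], kids[1]
                node.remove_child(c1)
                node.remove_child(c2)
                merged = dendropy.Node()
                merged.edge.length = 0.0
                merged.add_child(c1)
                merged.add_child(c2)
                node.insert_child(0, merged)
        return Phylogeny(tree)

    def scaled_to_unit_height(self) -> "Phylogeny":
        """Rescale branch lengths so the maximum root-to-tip depth is 1."""
        h = self.height
        if h <= 0:
            raise ValueError("cannot scale a zero-height tree")
        tree = self._clone()
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length / h
        return Phylogeny(tree)

    # ------------------------------------------------------------- matrices

    def shared_depth_matrix(self) -> np.ndarray:
        """Matrix of root-to-MRCA path lengths between tip pairs."""
        idx = self.index()
        n = idx.n_tips
        C = np.zeros((n, n))
        tipsets: dict = {}
        for nid in idx.postorder:
            if nid < n:
                tipsets[nid] = np.array([nid], dtype=np.int64)
                C[nid, nid] = idx.depth[nid]
            else:
                groups = [tipsets.pop(c) for c in idx.children[nid]]
                d = idx.depth[nid]
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        C[np.ix_(groups[a], groups[b])] = d
                        C[np.ix_(groups[b], groups[a])] = d
                tipsets[nid] = np.concatenate(groups)
        return C

    def correlation_matrix(self) -> np.ndarray:
        """Phylogenetic correlation matrix: shared depth scaled to unit diagonal.

        Equivalent to the Brownian-motion variance-covariance matrix of a
        tree rescaled to unit height (for ultrametric trees); symmetric and
        positive semi-definite by construction.
        """
        C = self.shared_depth_matrix()
        diag = np.diag(C).copy()
        if np.any(diag <= 0):
            raise ValueError("zero-height tree: some tips have zero depth")
        corr = C / np.sqrt(np.outer(diag, diag))
        np.fill_diagonal(corr, 1.0)
        return corr

    def patristic_scaled_distance(self) -> np.ndarray:
        """Tip-tip distance on the correlation scale, d_ij = 2 (1 - rho_ij)."""
        return 2.0 * (1.0 - self.correlation_matrix())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips}, height={self.height:.4g})"


# ---------------------------------------------------------------- trait IO


def _parse_binary(value):
    if value is None:
        return np.nan
    s = str(value).strip()
    if s in ("", "?", "NA", "nan", "NaN"):
        return np.nan
    if s in ("0", "0.0"):
        return 0.0
    if s in ("1", "1.0"):
        return 1.0
    raise ValueError(f"trait values must be 0, 1 or NA; got {value!r}")


def read_trait_table(path_or_buffer) -> pd.DataFrame:
    """Read a long-format trait table with columns taxon_id, feature_id, value.

    Tolerates BOM, CRLF line endings, and "?"/empty strings as missing.
    """
    if isinstance(path_or_buffer, io.StringIO):
        df = pd.read_csv(path_or_buffer, dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(
            path_or_buffer, dtype=str, keep_default_na=False,
            encoding="utf-8-sig",
        )
    required = {"taxon_id", "feature_id", "value"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"trait table must have columns {sorted(required)}; "
            f"got {list(df.columns)}"
        )
    dup = df.duplicated(subset=["taxon_id", "feature_id"])
    if dup.any():
        bad = df.loc[dup, ["taxon_id", "feature_id"]].iloc[0]
        raise ValueError(
            f"duplicate (taxon_id, feature_id) pair: "
            f"({bad['taxon_id']}, {bad['feature_id']})"
        )
    df = df.copy()
    df["value"] = df["value"].map(_parse_binary)
    return df[["taxon_id", "feature_id", "value"]]


def derive_features(table: pd.DataFrame, conflict_policy: str = "zero") -> pd.DataFrame:
    """Derive the three analysis traits from raw Grambank-style feature codes.

    Parameters
    ----------
    table
        Long-format frame with columns taxon_id, feature_id, value (0/1/NaN).
    conflict_policy
        What to do when a taxon is coded verb-final (GB133 = 1) *and*
        verb-initial/medial (GB131 or GB132 = 1): ``"zero"`` (default) codes
        verb_final = 0 on the grounds that the order is not exclusively
        verb-final; ``"na"`` treats the conflict as missing.

    Returns
    -------
    DataFrame indexed by taxon_id with float columns case, verb_final,
    flexible (NaN where undetermined).
    """
    if conflict_policy not in ("zero", "na"):
        raise ValueError("conflict_policy must be 'zero' or 'na'")
    unknown = sorted(set(table["feature_id"]) - set(RAW_FEATURES))
    if unknown:
        logger.warning("ignoring unknown feature ids: %s", unknown)
        table = table[table["feature_id"].isin(RAW_FEATURES)]
    wide = table.pivot(index="taxon_id", columns="feature_id", values="value")
    for feat in RAW_FEATURES:
        if feat not in wide.columns:
            wide[feat] = np.nan
    gb070, gb131 = wide["GB070"], wide["GB131"]
    gb132, gb133, gb136 = wide["GB132"], wide["GB133"], wide["GB136"]

    case = gb070.astype(float)

    verb_final = pd.Series(np.nan, index=wide.index)
    non_final = (gb131 == 1) | (gb132 == 1)
    verb_final[non_final] = 0.0
    strictly_final = (gb133 == 1) & (gb131 == 0) & (gb132 == 0)
    verb_final[strictly_final] = 1.0
    conflicts = (gb133 == 1) & non_final
    if conflicts.any():
        logger.warning(
            "%d taxa coded verb-final together with verb-initial/medial order; "
            "conflict_policy=%s", int(conflicts.sum()), conflict_policy,
        )
        if conflict_policy == "na":
            verb_final[conflicts] = np.nan

    flexible = 1.0 - gb136.astype(float)

    out = pd.DataFrame(
        {"case": case, "verb_final": verb_final, "flexible": flexible}
    )
    out.index.name = "taxon_id"
    return out.sort_index()


def read_trait_matrix(path_or_buffer) -> pd.DataFrame:
    """Read a wide trait matrix CSV (taxon_id plus the three trait columns)."""
    df = pd.read_csv(path_or_buffer, dtype=str, keep_default_na=False,
                     encoding="utf-8-sig")
    if "taxon_id" not in df.columns:
        raise ValueError("trait matrix must have a taxon_id column")
    missing = [c for c in ANALYSIS_TRAITS if c not in df.columns]
    if missing:
        raise ValueError(f"trait matrix missing columns: {missing}")
    df = df.set_index("taxon_id")
    out = df[list(ANALYSIS_TRAITS)].apply(lambda col: col.map(_parse_binary))
    return out


def read_coordinates(path_or_buffer) -> pd.DataFrame:
    """Read a coordinates CSV with columns taxon_id, latitude, longitude."""
    df = pd.read_csv(path_or_buffer, encoding="utf-8-sig")
    required = {"taxon_id", "latitude", "longitude"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinates table must have columns {sorted(required)}")
    if df["taxon_id"].duplicated().any():
        dup = df.loc[df["taxon_id"].duplicated(), "taxon_id"].iloc[0]
        raise ValueError(f"duplicate taxon_id in coordinates: {dup!r}")
    df = df.set_index("taxon_id")[["latitude", "longitude"]].astype(float)
    lat, lon = df["latitude"], df["longitude"]
    if ((lat < -90) | (lat > 90)).any():
        raise ValueError("latitude out of [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise ValueError("longitude out of [-180, 180]")
    return df


def align_tree_and_traits(
    tree: Phylogeny,
    traits: pd.DataFrame,
    locations: pd.DataFrame | None = None,
    require=ANALYSIS_TRAITS,
):
    """Restrict tree and data to taxa with complete trait values.

    Listwise deletion over ``require`` is applied first, then the tree is
    pruned to the surviving taxa that are also tips; the returned trait (and
    coordinate) rows follow the pruned tree's tip order.
    """
    require = [c for c in require if c in traits.columns]
    complete = traits.dropna(subset=require)
    taxa = set(complete.index) & set(tree.tip_labels)
    if locations is not None:
        taxa &= set(locations.index)
    if not taxa:
        raise AlignmentError("no taxa shared between tree and complete trait data")
    pruned = tree.pruned_to(taxa)
    order = pruned.tip_labels
    traits_out = complete.loc[order, require].astype(float)
    logger.info("aligned sample: %d taxa across %d traits", len(order), len(require))
    if locations is not None:
        return pruned, traits_out, locations.loc[order]
    return pruned, traits_out, None
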