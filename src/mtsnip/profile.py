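"""Per-column variation profiling on a neighbour-joining tree.

Pipeline: p-distance matrix -> NJ tree -> 5-state (A,C,G,T,gap) Fitch
parsimony per column -> change classification (transition, transversion,
insertion, deletion) -> fixed-width binning and rate calibration against a
user-supplied control-region rate in %/Myr.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .io import GAP_CODE, N_CODE, LabelledAlignment

__all__ = [
    "Tree",
    "ChangeCounts",
    "VariationProfile",
    "pairwise_distance_matrix",
    "build_nj_tree",
    "count_changes",
    "bin_changes",
    "calibrate_rates",
    "make_profile",
]


# ---------------------------------------------------------------------------
# tree structure


class Tree:
    """Minimal rooted tree node; NJ returns the (trifurcating) root."""

    __slots__ = ("name", "children", "branch_length")

    def __init__(self, name: Optional[str] = None, branch_length: float = 0.0):
        self.name = name
        self.children: list[Tree] = []
        self.branch_length = branch_length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Tree"]:
        if self.is_leaf:
            return [self]
        out: list[Tree] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def postorder(self) -> list["Tree"]:
        out: list[Tree] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        out.reverse()
        return out

    def to_newick(self) -> str:
        return self._newick_str(top=True) + ";"

    def _newick_str(self, top: bool = False) -> str:
        if self.is_leaf:
            body = _quote_newick(self.name or "")
        else:
            body = "(" + ",".join(c._newick_str() for c in self.children) + ")"
        if top:
            return body
        return f"{body}:{self.branch_length:.10g}"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({self.to_newick()})"


def _quote_newick(name: str) -> str:
    if any(c in name for c in " ():;,'\t"):
        return "'" + name.replace("'", "''") + "'"
    return name


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # (n, n) float, symmetric, zero diagonal

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])


def pairwise_distance_matrix(aln: LabelledAlignment, mode: str = "pairwise_deletion") -> DistanceMatrix:
    """p-distance matrix (mismatches / compared sites).

    ``mode="pairwise_deletion"`` excludes sites with a gap or N in either
    sequence; ``mode="gap_fifth"`` compares gaps as a fifth symbol and
    excludes only N sites.
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least two sequences for a distance matrix")
    if mode not in ("pairwise_deletion", "gap_fifth"):
        raise ValueError(f"unknown distance mode {mode!r}")
    ids, mat = aln.to_codes()
    n = len(ids)
    usable = mat != N_CODE
    if mode == "pairwise_deletion":
        usable &= mat != GAP_CODE
    dist = np.zeros((n, n), dtype=float)
    for i in range(n):
        comp = usable[i] & usable[i + 1:]
        mism = (mat[i] != mat[i + 1:]) & comp
        n_comp = comp.sum(axis=1)
        zero = np.nonzero(n_comp == 0)[0]
        if zero.size:
            j = i + 1 + int(zero[0])
            raise ValueError(f"no comparable sites between {ids[i]!r} and {ids[j]!r}")
        d = mism.sum(axis=1) / n_comp
        dist[i, i + 1:] = d
        dist[i + 1:, i] = d
    return DistanceMatrix(ids=ids, values=dist)


# ---------------------------------------------------------------------------
# neighbour joining


def build_nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbour joining with a deterministic tie-break.

    Ties in the Q criterion are resolved toward the lowest-index pair in the
    current working order (new internal nodes are appended at the end).
    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.  Returns the unrooted tree as a trifurcating root.
    """
    D = np.asarray(dm.values, dtype=float)
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if np.any(D < 0):
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal is not zero")

    nodes: list[Tree] = [Tree(name) for name in dm.ids]
    D = D.copy()

    while len(nodes) > 3:
        r = len(nodes)
        sums = D.sum(axis=1)
        Q = (r - 2) * D - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # lowest-index (i, j) among exact ties
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        i, j = min((int(a), int(b)) for a, b in ties if a < b)
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = Tree()
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        parent.children = [nodes[i], nodes[j]]
        new_row = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.empty((r - 1, r - 1), dtype=float)
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = new_row[keep]
        D2[:-1, -1] = new_row[keep]
        D2[-1, -1] = 0.0
        np.maximum(D2, 0.0, out=D2)
        nodes = [nodes[k] for k in keep] + [parent]
        D = D2

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    la, lb = _clamp_pair(la, lb)
    lc = max(lc, 0.0)
    root = Tree()
    a.branch_length, b.branch_length, c.branch_length = la, lb, lc
    root.children = [a, b, c]
    return root


def _clamp_pair(x: float, y: float) -> tuple[float, float]:
    if x < 0:
        y += -x  # transfer the deficit so path lengths are preserved
        x = 0.0
    if y < 0:
        x = max(x + y, 0.0)
        y = 0.0
    return x, y


# ---------------------------------------------------------------------------
# Fitch parsimony change counting


@dataclass
class ChangeCounts:
    """Per-column minimum change counts split by change type."""

    transitions: np.ndarray
    transversions: np.ndarray
    insertions: np.ndarray
    deletions: np.ndarray

    @property
    def length(self) -> int:
        return len(self.transitions)

    @property
    def totals(self) -> np.ndarray:
        return self.transitions + self.transversions + self.insertions + self.deletions

    def per_column(self) -> list[dict[str, int]]:
        return [
            {
                "transitions": int(self.transitions[i]),
                "transversions": int(self.transversions[i]),
                "insertions": int(self.insertions[i]),
                "deletions": int(self.deletions[i]),
            }
            for i in range(self.length)
        ]


# state bit masks for {A, C, G, T, -}; N is treated as missing (all bits)
_STATE_BITS = np.array([1, 2, 4, 8, 16, 31], dtype=np.uint8)
_PURINE = {1, 4}  # A, G bits
_PYRIMIDINE = {2, 8}  # C, T bits
_GAP_BIT = 16


def _binary_root(tree: Tree) -> Tree:
    """Resolve a trifurcating root into a binary one (zero-length edge).

    The parsimony minimum is unchanged by this refinement; it lets plain
    Fitch set operations (defined for binary nodes) apply exactly.
    """
    if len(tree.children) <= 2:
        return tree
    root = Tree()
    inner = Tree()
    inner.children = list(tree.children[:-1])
    inner.branch_length = 0.0
    last = tree.children[-1]
    root.children = [inner, last]
    return root


def count_changes(aln: LabelledAlignment, tree: Tree) -> ChangeCounts:
    """Minimum-mutation change counts per column, classified by type.

    Each column is scored by Fitch parsimony over the five states
    A, C, G, T and gap; N contributes no constraint at its tip.  One
    deterministic optimal ancestral labelling (prefer the state earliest in
    A < C < G < T < gap) is traversed to classify every inferred change as
    transition, transversion, insertion (gap -> base) or deletion
    (base -> gap).  The per-column total equals the Fitch minimum and does
    not depend on the tie-break.
    """
    tip_names = tree.leaf_names()
    missing = [t for t in tip_names if t not in aln.sequences]
    if missing:
        raise ValueError(f"tree tips without a sequence: {sorted(missing)}")
    _, mat = aln.to_codes(tip_names)
    tip_index = {name: i for i, name in enumerate(tip_names)}
    L = aln.length
    root = _binary_root(tree)
    order = root.postorder()

    masks: dict[int, np.ndarray] = {}
    for node in order:
        if node.is_leaf:
            idx = tip_index[node.name]
            masks[id(node)] = _STATE_BITS[mat[idx]]
        else:
            child_masks = [masks[id(c)] for c in node.children]
            inter = child_masks[0] & child_masks[1]
            union = child_masks[0] | child_masks[1]
            masks[id(node)] = np.where(inter != 0, inter, union)

    # deterministic labelling: root takes its lowest admissible state; each
    # child keeps the parent state when admissible, else its lowest state
    lowest = lambda m: (m & (~m + 1)).astype(np.uint8)  # lowest set bit
    states: dict[int, np.ndarray] = {id(root): lowest(masks[id(root)])}
    ti = np.zeros(L, dtype=int)
    tv = np.zeros(L, dtype=int)
    ins = np.zeros(L, dtype=int)
    dele = np.zeros(L, dtype=int)
    for node in reversed(order):  # preorder
        parent_state = states[id(node)]
        for child in node.children:
            cmask = masks[id(child)]
            keep = (cmask & parent_state) != 0
            child_state = np.where(keep, parent_state, lowest(cmask))
            states[id(child)] = child_state
            changed = np.nonzero(child_state != parent_state)[0]
            for col in changed:
                a, b = int(parent_state[col]), int(child_state[col])
                if a == _GAP_BIT:
                    ins[col] += 1
                elif b == _GAP_BIT:
                    dele[col] += 1
                elif (a in _PURINE) == (b in _PURINE):
                    ti[col] += 1
                else:
                    tv[col] += 1
    return ChangeCounts(transitions=ti, transversions=tv, insertions=ins, deletions=dele)


# ---------------------------------------------------------------------------
# binning and rate calibration


@dataclass
class Bin:
    start_col: int  # 1-based inclusive
    end_col: int
    value: float


def bin_changes(counts: ChangeCounts, width: int = 6) -> list[Bin]:
    """Sum change totals over consecutive column bins (last bin may be short)."""
    if width < 1:
        raise ValueError("bin width must be >= 1")
    totals = counts.totals
    bins = []
    for start in range(0, counts.length, width):
        end = min(start + width, counts.length)
        bins.append(Bin(start_col=start + 1, end_col=end, value=float(totals[start:end].sum())))
    return bins


def calibrate_rates(counts: ChangeCounts, calibration_rate: float, width: int = 30) -> list[Bin]:
    """Per-bin mutation rates in %/Myr.

    Each bin's changes-per-site density is scaled so that the length-weighted
    mean over bins equals ``calibration_rate`` (the alignment-wide rate taken
    from an external calibration).
    """
    if calibration_rate <= 0:
        raise ValueError("calibration_rate must be positive")
    totals = counts.totals
    grand_total = float(totals.sum())
    if grand_total == 0:
        raise ValueError("no changes in alignment: cannot calibrate rates")
    mean_density = grand_total / counts.length
    bins = []
    for start in range(0, counts.length, width):
        end = min(start + width, counts.length)
        density = float(totals[start:end].sum()) / (end - start)
        bins.append(
            Bin(start_col=start + 1, end_col=end, value=calibration_rate * density / mean_density)
        )
    return bins


@dataclass
class VariationProfile:
    """Binned change totals plus calibrated per-bin rates for an alignment."""

    change_bins: list[Bin]
    rate_bins: list[Bin]
    calibration_rate_pct_per_myr: float
    counts: ChangeCounts = field(repr=False)


def make_profile(
    aln: LabelledAlignment,
    calibration_rate: float,
    change_width: int = 6,
    rate_width: int = 30,
    distance_mode: str = "pairwise_deletion",
) -> tuple[VariationProfile, Tree]:
    """Convenience wrapper: distances -> NJ -> Fitch counts -> bins + rates."""
    dm = pairwise_distance_matrix(aln, mode=distance_mode)
    tree = build_nj_tree(dm)
    counts = count_changes(aln, tree)
    profile = VariationProfile(
        change_bins=bin_changes(counts, width=change_width),
        rate_bins=calibrate_rates(counts, calibration_rate, width=rate_width),
        calibration_rate_pct_per_myr=calibration_rate,
        counts=counts,
    )
    return profile, tree


def write_bins_tsv(bins: list[Bin], path, value_name: str) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"bin_start\tbin_end\t{value_name}\n")
        for b in bins:
            handle.write(f"{b.start_col}\t{b.end_col}\t{b.value:.10g}\n")


def plot_profile(profile: VariationProfile, path) -> None:  # pragma: no cover - cosmetic
    """Two-panel variation plot (change counts per small bin, rates per wide bin)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 5), sharex=True)
    mids = [(b.start_col + b.end_col) / 2 for b in profile.change_bins]
    widths = [b.end_col - b.start_col + 1 for b in profile.change_bins]
    ax1.bar(mids, [b.value for b in profile.change_bins], width=widths, color="firebrick")
    ax1.set_ylabel("changes / bin")
    mids = [(b.start_col + b.end_col) / 2 for b in profile.rate_bins]
    widths = [b.end_col - b.start_col + 1 for b in profile.rate_bins]
    ax2.bar(mids, [b.value for b in profile.rate_bins], width=widths, color="steelblue")
    ax2.set_ylabel("rate (%/Myr)")
    ax2.set_xlabel("alignment column")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
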