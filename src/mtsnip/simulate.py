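"""Synthetic data generation for end-to-end testing of the pipeline.

A single-population Kingman coalescent genealogy is drawn per species and
hung off a common ancestor; mutations fall as a Poisson process along
branches with a planted rate-multiplier window (the hypervariable target),
a transition/transversion odds ratio, and occasional gap events.  Further
generators produce degraded fragment sets (lognormal lengths) and
molecular-sexing assay tables with configurable allelic dropout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .io import LabelledAlignment, SampleRecord, SexAssayRecord
from .profile import Tree

__all__ = [
    "SimConfig",
    "simulate_alignment",
    "degrade_fragments",
    "amplicon_success",
    "fragment_window_sequences",
    "simulate_assays",
]


@dataclass
class SimConfig:
    n_samples: int = 100
    seq_len: int = 683
    background_rate: float = 0.01  # expected substitutions/site per unit branch
    hot_window: tuple[int, int] = (554, 583)  # 1-based inclusive columns
    hot_factor: float = 4.0
    titv_ratio: float = 10.0
    indel_prob: float = 0.02  # chance a mutation event is a gap event
    n_species: int = 3
    n_localities: int = 6
    geo_structure: float = 0.0  # 0 panmictic .. 1 haplotypes confined
    species_divergence: float = 1.5  # branch from common ancestor, coalescent units
    genealogy: str = "kingman"  # "kingman" | "star"
    star_depth: float = 1.0  # per-tip branch length under the star genealogy
    frag_len_logmean: float = math.log(100.0)
    frag_len_logsd: float = 0.5
    n_fragments: int = 20  # fragments drawn per sample
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.hot_window
        if not 1 <= lo <= hi <= self.seq_len:
            raise ValueError(f"hot_window {self.hot_window} outside 1..{self.seq_len}")
        if self.hot_factor < 1:
            raise ValueError("hot_factor must be >= 1")
        for name in ("indel_prob", "geo_structure"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 1 <= self.n_species <= self.n_samples:
            raise ValueError("n_species must be in 1..n_samples")
        if self.genealogy not in ("kingman", "star"):
            raise ValueError(f"unknown genealogy {self.genealogy!r}")


# ---------------------------------------------------------------------------
# genealogy and mutation


def _coalescent_tree(tips: list[str], rng: np.random.Generator) -> Tree:
    """Single-population Kingman genealogy; branch lengths in coalescent units."""
    nodes = [Tree(name) for name in tips]
    pending = [0.0] * len(nodes)
    if len(nodes) == 1:
        return nodes[0]
    while len(nodes) > 1:
        k = len(nodes)
        t = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        pending = [p + t for p in pending]
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = Tree()
        nodes[i].branch_length = pending[i]
        nodes[j].branch_length = pending[j]
        parent.children = [nodes[i], nodes[j]]
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [parent]
        pending = [p for idx, p in enumerate(pending) if idx not in (i, j)] + [0.0]
    return nodes[0]


def _star_tree(tips: list[str], depth: float) -> Tree:
    """Star genealogy: every tip hangs off one ancestor at the same depth."""
    root = Tree()
    for name in tips:
        root.children.append(Tree(name, branch_length=depth))
    return root


_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T
_TRANSVERSIONS = {0: (1, 3), 2: (1, 3), 1: (0, 2), 3: (0, 2)}


def _evolve(
    tree: Tree,
    root_seq: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    out: dict[str, np.ndarray],
) -> None:
    """Recursively mutate ``root_seq`` down the tree, filling tip rows."""
    weights = np.ones(cfg.seq_len)
    lo, hi = cfg.hot_window
    weights[lo - 1 : hi] = cfg.hot_factor
    site_probs = weights / weights.sum()
    total_rate = cfg.background_rate * weights.sum()
    p_transition = cfg.titv_ratio / (cfg.titv_ratio + 1.0)

    stack = [(tree, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node.is_leaf:
            out[node.name] = seq
            continue
        for child in node.children:
            child_seq = seq.copy()
            n_mut = rng.poisson(child.branch_length * total_rate)
            if n_mut:
                sites = rng.choice(cfg.seq_len, size=n_mut, p=site_probs)
                for site in sites:
                    state = child_seq[site]
                    if state == 4:  # gap reverts to a random base (insertion)
                        child_seq[site] = rng.integers(0, 4)
                    elif rng.random() < cfg.indel_prob:
                        child_seq[site] = 4  # deletion
                    elif rng.random() < p_transition:
                        child_seq[site] = _TRANSITION[int(state)]
                    else:
                        child_seq[site] = _TRANSVERSIONS[int(state)][rng.integers(0, 2)]
            stack.append((child, child_seq))


_CODE_TO_SYM = np.array(list("ACGT-"), dtype="U1")


def simulate_alignment(cfg: SimConfig) -> tuple[LabelledAlignment, dict[str, str]]:
    """Generate a labelled alignment plus true window-haplotype labels.

    Deterministic given ``cfg.seed``.  Returns ``(alignment, truth)`` where
    ``truth`` maps sample id to its species-scoped haplotype label derived
    from the exact string over the planted window.
    """
    rng = np.random.default_rng(cfg.seed)
    # split samples across species as evenly as possible
    base, extra = divmod(cfg.n_samples, cfg.n_species)
    sizes = [base + (1 if i < extra else 0) for i in range(cfg.n_species)]
    species_names = [f"sp{i + 1}" for i in range(cfg.n_species)]

    ancestor = rng.integers(0, 4, size=cfg.seq_len).astype(np.uint8)
    tip_seqs: dict[str, np.ndarray] = {}
    sample_species: dict[str, str] = {}
    idx = 0
    for sp, size in zip(species_names, sizes):
        tips = []
        for _ in range(size):
            idx += 1
            sid = f"S{idx:03d}"
            tips.append(sid)
            sample_species[sid] = sp
        if cfg.genealogy == "star":
            subtree = _star_tree(tips, cfg.star_depth)
        else:
            subtree = _coalescent_tree(tips, rng)
        subtree.branch_length = cfg.species_divergence
        root = Tree()
        root.children = [subtree]
        _evolve(root, ancestor, cfg, rng, tip_seqs)

    sequences = {
        sid: "".join(_CODE_TO_SYM[tip_seqs[sid]]) for sid in sorted(tip_seqs)
    }

    # true haplotype labels: distinct planted-window strings per species,
    # numbered by first occurrence
    lo, hi = cfg.hot_window
    truth: dict[str, str] = {}
    label_of: dict[tuple[str, str], str] = {}
    counters = {sp: 0 for sp in species_names}
    for sid in sorted(sequences):
        sp = sample_species[sid]
        window = sequences[sid][lo - 1 : hi]
        key = (sp, window)
        if key not in label_of:
            counters[sp] += 1
            label_of[key] = f"{sp}-H{counters[sp]}"
        truth[sid] = label_of[key]

    localities = _locality_grid(cfg.n_localities)
    hap_rank = {lab: i for i, lab in enumerate(sorted(set(truth.values())))}
    metadata = []
    for sid in sorted(sequences):
        if rng.random() < cfg.geo_structure:
            loc = localities[hap_rank[truth[sid]] % cfg.n_localities]
        else:
            loc = localities[rng.integers(0, cfg.n_localities)]
        metadata.append(
            SampleRecord(
                sample_id=sid,
                species=sample_species[sid],
                tissue="bone",
                source="swamp",
                locality_name=loc[0],
                lat=loc[1],
                lon=loc[2],
                haplotype_label=truth[sid],
            )
        )
    aln = LabelledAlignment(sequences=sequences, metadata=metadata)
    return aln, truth


def _locality_grid(n: int) -> list[tuple[str, float, float]]:
    """Named sampling sites ~55 km apart (never merged at a 25 km threshold)."""
    return [(f"loc{i + 1:02d}", -45.0 + 0.5 * i, 170.0) for i in range(n)]


# ---------------------------------------------------------------------------
# fragmentation


def degrade_fragments(
    aln: LabelledAlignment,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, list[tuple[int, int]]]:
    """Draw surviving fragments per sample as 1-based inclusive intervals.

    Lengths are lognormal(frag_len_logmean, frag_len_logsd), positions
    uniform; fragments longer than the sequence are truncated to it.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    L = aln.length
    fragments: dict[str, list[tuple[int, int]]] = {}
    for sid in aln.ids:
        lens = np.clip(
            np.round(rng.lognormal(cfg.frag_len_logmean, cfg.frag_len_logsd, cfg.n_fragments)),
            1,
            L,
        ).astype(int)
        intervals = []
        for flen in lens:
            start = int(rng.integers(1, L - flen + 2))
            intervals.append((start, start + flen - 1))
        fragments[sid] = intervals
    return fragments


def amplicon_success(intervals: list[tuple[int, int]], start: int, length: int) -> bool:
    """True iff some fragment fully spans the amplicon [start, start+length-1]."""
    end = start + length - 1
    return any(s <= start and e >= end for s, e in intervals)


def fragment_window_sequences(
    aln: LabelledAlignment,
    fragments: dict[str, list[tuple[int, int]]],
    window: tuple[int, int],
) -> dict[str, str]:
    """Window sequences recoverable from the fragment sets (spanning reads only)."""
    lo, hi = window
    out = {}
    for sid, intervals in fragments.items():
        if amplicon_success(intervals, lo, hi - lo + 1):
            out[sid] = aln.sequences[sid][lo - 1 : hi]
    return out


# ---------------------------------------------------------------------------
# sexing assays


def simulate_assays(
    true_sexes: dict[str, str],
    dropout_w: float = 0.0,
    dropout_auto: float = 0.0,
    seed: int = 0,
) -> list[SexAssayRecord]:
    """Run the three-step assay protocol in silico with allelic dropout.

    A female's W product amplifies with probability ``1 - dropout_w`` per
    attempt; the autosomal product with ``1 - dropout_auto`` for either sex.
    Males never yield a W product.
    """
    for name, p in (("dropout_w", dropout_w), ("dropout_auto", dropout_auto)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for sid in sorted(true_sexes):
        sex = true_sexes[sid].lower()[0]  # 'f' or 'm'
        if sex not in ("f", "m"):
            raise ValueError(f"unknown sex {true_sexes[sid]!r} for {sid!r}")
        is_female = sex == "f"
        w1 = "positive" if is_female and rng.random() >= dropout_w else "negative"
        if w1 == "positive":
            records.append(SexAssayRecord(sid, w_assay=w1))
            continue
        auto = "positive" if rng.random() >= dropout_auto else "negative"
        if auto == "negative":
            records.append(SexAssayRecord(sid, w_assay=w1, autosomal_assay=auto))
            continue
        w2 = "positive" if is_female and rng.random() >= dropout_w else "negative"
        records.append(
            SexAssayRecord(sid, w_assay=w1, autosomal_assay=auto, w_retest=w2)
        )
    return records
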