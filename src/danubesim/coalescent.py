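"""Backward-in-time structured coalescent conditioned on a forward trace.

Lineages sampled at arbitrary demes, generations and layers are traced
backwards through the recorded demography (:class:`~danubesim.world.
DemographyTrace`).  Per backward generation each lineage may

1. switch from the farmer to the hunter-gatherer layer with probability
   ``A / N_FA`` (the fraction of the local farmer deme assimilated from the
   HG deme during that forward generation),
2. migrate backwards to a source deme with probability proportional to the
   forward emigrant counts into its current deme, and
3. coalesce with another lineage sitting in the same deme and layer, each
   pair with probability ``1/N`` given the local deme size.

Farmer lineages reaching the farmer founding generation join the local
hunter-gatherer layer (the Palaeolithic layer creates the initial Neolithic
source population).  Lineages reaching the start of the simulation continue
in a single panmictic founder deme of constant size until the MRCA.

Sequences evolve on the resulting genealogy under a finite-site model of
HVS-I mitochondrial DNA: Poisson numbers of mutations per branch placed on
uniform sites, each a transition with probability ``ts_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .world import OCCUPANCY_THRESHOLD, DemographyTrace

__all__ = [
    "MutationModel",
    "SamplingScheme",
    "Genealogy",
    "HaplotypeSample",
    "TraceInconsistencyError",
    "simulate_genealogy",
    "mutate",
    "sample_population_sequences",
]

SCHEME_COLUMNS = ("sample_id", "row", "col", "generation", "layer", "n", "group_id")

#: Safety cap on the pre-origin panmictic phase, in generations.
MAX_TAIL_GENERATIONS = 5_000_000


class TraceInconsistencyError(RuntimeError):
    """A lineage ended up in a deme the forward trace says is empty."""


@dataclass(frozen=True)
class MutationModel:
    """Finite-site mtDNA mutation model (347 bp HVS-I by default).

    ``mu`` is interpreted per site per generation when ``per_site`` is True
    (the default), otherwise per sequence per generation.  ``ts_fraction``
    is the probability that a mutation is a transition; HVS-I is strongly
    transition-biased, hence the high default.
    """

    L: int = 347
    mu: float = 7.5e-6
    ts_fraction: float = 0.9841
    per_site: bool = True

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not 0.0 <= self.ts_fraction <= 1.0:
            raise ValueError("ts_fraction must be in [0, 1]")

    @property
    def mu_per_sequence(self) -> float:
        return self.mu * self.L if self.per_site else self.mu


@dataclass
class SamplingScheme:
    """Who is sampled, where, when and from which layer.

    ``table`` has one row per population sample: columns ``sample_id, row,
    col, generation, layer, n, group_id`` (grid indices 0-based,
    generations 0-based from simulation start).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SCHEME_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"sampling scheme missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        if (self.table["n"] < 0).any():
            raise ValueError("sample sizes must be >= 0")
        bad = ~self.table["layer"].isin(["HG", "FA"])
        if bad.any():
            raise ValueError("layer must be 'HG' or 'FA'")

    @classmethod
    def from_rows(cls, rows: Iterable[dict]) -> "SamplingScheme":
        return cls(pd.DataFrame(list(rows), columns=list(SCHEME_COLUMNS)))

    @property
    def n_lineages(self) -> int:
        return int(self.table["n"].sum())

    @property
    def group_ids(self) -> list:
        return list(dict.fromkeys(self.table["group_id"]))

    def validate(self, trace: DemographyTrace) -> None:
        """Check every sampled deme is occupied in the requested layer at
        the requested generation."""
        G = trace.n_generations
        for _, row in self.table.iterrows():
            if not 0 <= row["generation"] <= G:
                raise ValueError(
                    f"sample {row['sample_id']}: generation {row['generation']} "
                    f"outside [0, {G}]"
                )
            d = (int(row["row"]), int(row["col"]))
            if not trace.config.land_mask[d]:
                raise ValueError(f"sample {row['sample_id']}: deme {d} is sea")
            N = trace.n_end(row["layer"])[int(row["generation"])][d]
            if row["n"] > 0 and N < OCCUPANCY_THRESHOLD:
                raise ValueError(
                    f"sample {row['sample_id']}: deme {d} unoccupied in layer "
                    f"{row['layer']} at generation {row['generation']} (N={N:.3g})"
                )


@dataclass
class Genealogy:
    """Binary genealogy over the sampled lineages.

    Nodes 0..n_tips-1 are tips; ``parent[i] == -1`` marks the root.  Node
    times are forward generation indices (tips at their sampling
    generation, internal nodes at their coalescence generation; negative
    times lie in the pre-origin founder phase).  ``switched[i]`` records
    whether an assimilation (FA -> HG) switch occurred on the branch
    segment belonging to node ``i``.
    """

    parent: np.ndarray
    time: np.ndarray
    n_tips: int
    tip_ids: list
    tip_groups: list
    switched: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        roots = np.flatnonzero(self.parent < 0)
        return int(roots[0])

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        if p < 0:
            return 0.0
        return float(self.time[node] - self.time[p])

    def assimilation_in_ancestry(self) -> np.ndarray:
        """Per tip: does any ancestral segment carry an FA -> HG switch?"""
        out = np.zeros(self.n_tips, dtype=bool)
        for tip in range(self.n_tips):
            node = tip
            while node >= 0:
                if self.switched[node]:
                    out[tip] = True
                    break
                node = self.parent[node]
        return out

    def total_branch_length(self) -> float:
        return float(
            sum(self.branch_length(i) for i in range(self.n_nodes) if self.parent[i] >= 0)
        )


@dataclass
class HaplotypeSample:
    """Aligned sequences of one population sample."""

    group_id: str
    sequences: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ids:
            self.ids = [f"{self.group_id}_{i}" for i in range(len(self.sequences))]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences must be aligned (equal length)")
        alphabet = set("ACGT")
        for s in self.sequences:
            if set(s) - alphabet:
                raise ValueError("sequences must be over the alphabet ACGT")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def L(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


# ---------------------------------------------------------------------------
# Genealogy simulation
# ---------------------------------------------------------------------------


class _Builder:
    """Mutable node store while the genealogy is under construction."""

    def __init__(self) -> None:
        self.parent: list[int] = []
        self.time: list[float] = []
        self.switched: list[bool] = []

    def new_node(self, time: float) -> int:
        self.parent.append(-1)
        self.time.append(float(time))
        self.switched.append(False)
        return len(self.parent) - 1

    def merge(self, a: int, b: int, time: float) -> int:
        node = self.new_node(time)
        self.parent[a] = node
        self.parent[b] = node
        return node


_PAIR_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _pair_indices(j: int) -> tuple[np.ndarray, np.ndarray]:
    if j not in _PAIR_CACHE:
        _PAIR_CACHE[j] = np.triu_indices(j, k=1)
    return _PAIR_CACHE[j]


def _apply_merges(
    nodes: list[int],
    chosen: np.ndarray,
    j: int,
    t_new: float,
    builder: _Builder,
) -> list[int]:
    """Merge the chosen pairs (given in random order); pairs sharing a
    lineage with an earlier merge are skipped, as in sequential draws."""
    ii, jj = _pair_indices(j)
    merged: set[int] = set()
    parents: list[int] = []
    for h in chosen:
        a, b = int(ii[h]), int(jj[h])
        if a in merged or b in merged:
            continue
        merged.update((a, b))
        parents.append(builder.merge(nodes[a], nodes[b], t_new))
    return [n for k, n in enumerate(nodes) if k not in merged] + parents


def _coalesce_group(
    nodes: list[int],
    N: float,
    t_new: float,
    builder: _Builder,
    rng: np.random.Generator,
) -> list[int]:
    """One generation of sequential pair draws within a deme-layer group.

    Every unordered pair of lineages, visited in random order, merges with
    probability 1/N unless one member already merged this generation.  The
    number of successful pair draws is Binomial(C(j,2), 1/N) and the
    successful pairs are a uniform subset, so the draw is collapsed to one
    binomial variate plus a subset choice.
    """
    j = len(nodes)
    if j < 2:
        return nodes
    N = max(float(N), 1.0)
    pairs = j * (j - 1) // 2
    k = int(rng.binomial(pairs, 1.0 / N))
    if k == 0:
        return nodes
    chosen = rng.choice(pairs, size=k, replace=False)
    return _apply_merges(nodes, chosen, j, t_new, builder)


def _conditioned_positive_binomial(n: int, p: float, rng: np.random.Generator) -> int:
    """Sample Binomial(n, p) conditioned on being >= 1 (inverse CDF)."""
    from scipy.stats import binom

    p0 = binom.pmf(0, n, p)
    u = p0 + rng.random() * (1.0 - p0)
    return int(binom.ppf(u, n, p))


def _tail_coalesce(
    nodes: list[int],
    N: float,
    t_start: float,
    builder: _Builder,
    rng: np.random.Generator,
) -> int:
    """Coalesce the remaining lineages in a constant-size panmictic deme.

    Uses geometric skip-ahead between coalescent events; the event-time
    distribution is identical to stepping generation by generation with the
    sequential pair-draw rule (the probability of a silent generation is
    (1 - 1/N)^C(j,2)).
    """
    N = max(float(N), 1.0)
    t = t_start
    nodes = list(nodes)
    while len(nodes) > 1:
        j = len(nodes)
        pairs = j * (j - 1) // 2
        p = 1.0 / N
        q = 1.0 - (1.0 - p) ** pairs
        wait = rng.geometric(q) if q < 1.0 else 1
        t -= wait
        if t_start - t > MAX_TAIL_GENERATIONS:
            raise TraceInconsistencyError(
                "pre-origin coalescence did not complete within the time cap"
            )
        k = _conditioned_positive_binomial(pairs, p, rng)
        chosen = rng.choice(pairs, size=k, replace=False)
        nodes = _apply_merges(nodes, chosen, j, t, builder)
    return nodes[0]


def _is_single_constant_deme(trace: DemographyTrace) -> Optional[tuple[str, float]]:
    if trace.config.shape != (1, 1):
        return None
    if np.any(trace.admix != 0):
        return None
    for layer in ("HG", "FA"):
        n = trace.n_end(layer)[:, 0, 0]
        if n[0] > 0:
            if np.all(n == n[0]) and np.all(trace.n_mid(layer)[:, 0, 0] == n[0]):
                other = trace.n_end("FA" if layer == "HG" else "HG")
                if np.all(other == 0):
                    return layer, float(n[0])
    return None


def simulate_genealogy(
    scheme: SamplingScheme,
    trace: DemographyTrace,
    seed: int,
    fast_single_deme: bool = True,
) -> Genealogy:
    """Simulate one genealogy of all sampled lineages under the trace.

    Reproducible for a fixed ``seed``.  With ``fast_single_deme`` (default)
    a single-deme constant-size trace without admixture is simulated with
    geometric skip-ahead between coalescences, which samples from the same
    distribution as the generation-by-generation walk.
    """
    scheme.validate(trace)
    rng = np.random.default_rng(seed)
    builder = _Builder()

    tip_ids: list[str] = []
    tip_groups: list = []
    by_gen: dict[int, list[tuple[int, int, int, int]]] = {}
    for _, row in scheme.table.iterrows():
        g = int(row["generation"])
        layer = 0 if row["layer"] == "HG" else 1
        for i in range(int(row["n"])):
            node = builder.new_node(g)
            tip_ids.append(f"{row['sample_id']}_{i}")
            tip_groups.append(row["group_id"])
            by_gen.setdefault(g, []).append((node, int(row["row"]), int(row["col"]), layer))
    n_tips = len(tip_ids)
    if n_tips == 0:
        return Genealogy(
            parent=np.zeros(0, dtype=np.int64),
            time=np.zeros(0),
            n_tips=0,
            tip_ids=[],
            tip_groups=[],
            switched=np.zeros(0, dtype=bool),
        )

    fast = fast_single_deme and _is_single_constant_deme(trace)
    if fast:
        _, N = fast
        gens = sorted(by_gen, reverse=True)
        nodes: list[int] = []
        t = gens[0]
        for g in gens:
            if nodes and len(nodes) > 1:
                nodes = _tail_segment(nodes, N, t, g, builder, rng)
            t = g
            nodes.extend(n for (n, _, _, _) in by_gen[g])
        if len(nodes) > 1:
            _tail_coalesce(nodes, N, t, builder, rng)
        return _finish(builder, n_tips, tip_ids, tip_groups)

    scen = trace.scenario
    fa_active = trace.fa is not None and scen.fa_start_gen is not None

    # lineage state arrays
    node = np.zeros(0, dtype=np.int64)
    row_ = np.zeros(0, dtype=np.int64)
    col_ = np.zeros(0, dtype=np.int64)
    layer_ = np.zeros(0, dtype=np.int64)  # 0 = HG, 1 = FA

    start_t = max(by_gen)
    for t in range(start_t, 0, -1):
        if t in by_gen:
            add = by_gen[t]
            node = np.concatenate([node, [a[0] for a in add]]).astype(np.int64)
            row_ = np.concatenate([row_, [a[1] for a in add]]).astype(np.int64)
            col_ = np.concatenate([col_, [a[2] for a in add]]).astype(np.int64)
            layer_ = np.concatenate([layer_, [a[3] for a in add]]).astype(np.int64)
        if node.shape[0] == 0:
            continue
        if node.shape[0] == 1 and not any(g < t for g in by_gen):
            break

        # (1) assimilation switch FA -> HG
        fa_idx = np.flatnonzero(layer_ == 1)
        if fa_idx.size and fa_active:
            A = trace.admix[t][row_[fa_idx], col_[fa_idx]]
            nfa_mid = trace.n_fa_mid[t][row_[fa_idx], col_[fa_idx]]
            p_sw = np.where(nfa_mid > 0, A / np.where(nfa_mid > 0, nfa_mid, 1.0), 0.0)
            sw = fa_idx[rng.random(fa_idx.size) < p_sw]
            if sw.size:
                layer_[sw] = 0
                for n_id in node[sw]:
                    builder.switched[int(n_id)] = True

        # (2) backward migration, per layer
        for lay, lay_name in ((0, "HG"), (1, "FA")):
            idx = np.flatnonzero(layer_ == lay)
            if idx.size == 0:
                continue
            outflux, share = trace.emigration(lay_name, t)
            n_post = trace.n_end(lay_name)[t]
            r, c = row_[idx], col_[idx]
            denom = n_post[r, c]
            if np.any(denom <= 0):
                bad = idx[denom <= 0][0]
                raise TraceInconsistencyError(
                    f"lineage in empty deme ({row_[bad]}, {col_[bad]}) layer "
                    f"{lay_name} at generation {t}"
                )
            n_mid = trace.n_mid(lay_name)[t]
            pad = np.pad(share, 1)
            stay = n_mid[r, c] - outflux[r, c]
            # source neighbours: north, south, west, east of the focal deme
            probs = np.stack(
                [
                    stay,
                    pad[r, c + 1],      # from (r-1, c)
                    pad[r + 2, c + 1],  # from (r+1, c)
                    pad[r + 1, c],      # from (r, c-1)
                    pad[r + 1, c + 2],  # from (r, c+1)
                ],
                axis=1,
            ) / denom[:, None]
            cum = np.cumsum(probs, axis=1)
            u = rng.random(idx.size)
            choice = (u[:, None] > cum).sum(axis=1)
            choice = np.minimum(choice, 4)
            dr = np.array([0, -1, 1, 0, 0])
            dc = np.array([0, 0, 0, -1, 1])
            row_[idx] = r + dr[choice]
            col_[idx] = c + dc[choice]

        # farmer founding: FA lineages at the founding generation join the
        # local HG layer (the source population of the expansion)
        if fa_active and t == scen.fa_start_gen:
            fa_idx = np.flatnonzero(layer_ == 1)
            if fa_idx.size:
                at_origin = (row_[fa_idx] == scen.fa_origin[0]) & (
                    col_[fa_idx] == scen.fa_origin[1]
                )
                if not np.all(at_origin):
                    raise TraceInconsistencyError(
                        "farmer lineage not at the founder deme at the founding generation"
                    )
                layer_[fa_idx] = 0

        # (3) coalescence within deme-layer groups at the parental generation
        if node.shape[0] >= 2:
            R, C = trace.config.shape
            key = (layer_ * R + row_) * C + col_
            order = np.argsort(key, kind="stable")
            key_sorted = key[order]
            bounds = np.flatnonzero(np.diff(key_sorted)) + 1
            groups = np.split(order, bounds)
            removed: list[int] = []
            for grp in groups:
                if grp.shape[0] < 2:
                    continue
                lay = int(layer_[grp[0]])
                d = (int(row_[grp[0]]), int(col_[grp[0]]))
                N_par = trace.n_end("HG" if lay == 0 else "FA")[t - 1][d]
                members = [int(node[i]) for i in grp]
                kept = _coalesce_group(members, N_par, t - 1, builder, rng)
                if len(kept) < len(members):
                    # survivors and freshly created parents stay in the deme
                    node[grp[: len(kept)]] = kept
                    removed.extend(int(i) for i in grp[len(kept):])
            if removed:
                mask = np.ones(node.shape[0], dtype=bool)
                mask[removed] = False
                node, row_, col_, layer_ = node[mask], row_[mask], col_[mask], layer_[mask]

    # at t = 0 every lineage must sit in the HG origin deme
    if 0 in by_gen:
        add = by_gen[0]
        node = np.concatenate([node, [a[0] for a in add]]).astype(np.int64)
        row_ = np.concatenate([row_, [a[1] for a in add]]).astype(np.int64)
        col_ = np.concatenate([col_, [a[2] for a in add]]).astype(np.int64)
        layer_ = np.concatenate([layer_, [a[3] for a in add]]).astype(np.int64)
    if node.shape[0] > 1:
        origin = scen.hg_origin
        if not (np.all(row_ == origin[0]) and np.all(col_ == origin[1])):
            raise TraceInconsistencyError(
                "lineages did not converge on the origin deme at generation 0 "
                "(disconnected demes or inconsistent trace)"
            )
        _tail_coalesce([int(n) for n in node], scen.founder_size, 0.0, builder, rng)

    return _finish(builder, n_tips, tip_ids, tip_groups)


def _tail_segment(
    nodes: list[int],
    N: float,
    t_from: float,
    t_until: float,
    builder: _Builder,
    rng: np.random.Generator,
) -> list[int]:
    """Constant-N coalescence between two sampling times (skip-ahead),
    stopping at ``t_until`` (memorylessness of the geometric waiting time
    makes truncation exact)."""
    N = max(float(N), 1.0)
    t = t_from
    nodes = list(nodes)
    while len(nodes) > 1 and t > t_until:
        j = len(nodes)
        pairs = j * (j - 1) // 2
        p = 1.0 / N
        q = 1.0 - (1.0 - p) ** pairs
        wait = rng.geometric(q) if q < 1.0 else 1
        if t - wait < t_until:
            break
        t -= wait
        k = _conditioned_positive_binomial(pairs, p, rng)
        chosen = rng.choice(pairs, size=k, replace=False)
        nodes = _apply_merges(nodes, chosen, j, t, builder)
    return nodes


def _finish(builder: _Builder, n_tips: int, tip_ids: list, tip_groups: list) -> Genealogy:
    return Genealogy(
        parent=np.asarray(builder.parent, dtype=np.int64),
        time=np.asarray(builder.time, dtype=float),
        n_tips=n_tips,
        tip_ids=tip_ids,
        tip_groups=tip_groups,
        switched=np.asarray(builder.switched, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def mutate(genealogy: Genealogy, model: MutationModel, seed: int) -> list[str]:
    """Drop mutations on the genealogy and return one sequence per tip.

    Mutation counts per branch are Poisson with mean ``mu_per_sequence *
    branch_length``; sites are uniform (finite sites, recurrent hits
    allowed); each mutation is a transition with probability
    ``ts_fraction``, otherwise one of the two transversions uniformly.  The
    root sequence is all-'A' by convention, which is irrelevant to the
    distance-based statistics computed downstream.
    """
    rng = np.random.default_rng(seed)
    n_nodes = genealogy.n_nodes
    if n_nodes == 0:
        return []
    children: dict[int, list[int]] = {}
    for i in range(n_nodes):
        p = int(genealogy.parent[i])
        if p >= 0:
            children.setdefault(p, []).append(i)
    root = genealogy.root
    seqs: dict[int, np.ndarray] = {}
    base = np.zeros(model.L, dtype=np.uint8)  # 0 = 'A'
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    ts_code = np.array([2, 3, 0, 1])  # A<->G, C<->T in ACGT coding
    tv_codes = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])

    stack = [(root, base)]
    while stack:
        nd, seq = stack.pop()
        blen = genealogy.branch_length(nd)
        if blen > 0 and model.mu_per_sequence > 0:
            k = rng.poisson(model.mu_per_sequence * blen)
            if k:
                seq = seq.copy()
                sites = rng.integers(0, model.L, size=k)
                is_ts = rng.random(k) < model.ts_fraction
                for s, ts in zip(sites, is_ts):
                    cur = seq[s]
                    if ts:
                        seq[s] = ts_code[cur]
                    else:
                        seq[s] = tv_codes[cur][rng.integers(0, 2)]
        if nd < genealogy.n_tips:
            seqs[nd] = seq
        for ch in children.get(nd, []):
            stack.append((ch, seq))
    return [
        alphabet[seqs[i]].tobytes().decode("ascii") for i in range(genealogy.n_tips)
    ]


def sample_population_sequences(
    scheme: SamplingScheme,
    trace: DemographyTrace,
    model: MutationModel,
    seed: int,
    return_genealogy: bool = False,
):
    """Simulate one genealogy for the whole scheme and return one
    :class:`HaplotypeSample` per group (a single genealogy underlies all
    groups of one simulation)."""
    if scheme.table.empty or scheme.n_lineages == 0:
        return ([], None) if return_genealogy else []
    rng = np.random.default_rng(seed)
    g_seed, m_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    gen = simulate_genealogy(scheme, trace, g_seed)
    seqs = mutate(gen, model, m_seed)
    groups: dict = {}
    for tip, grp in enumerate(gen.tip_groups):
        groups.setdefault(grp, ([], []))
        groups[grp][0].append(seqs[tip])
        groups[grp][1].append(gen.tip_ids[tip])
    out = [
        HaplotypeSample(group_id=str(g), sequences=s, ids=i)
        for g, (s, i) in groups.items()
    ]
    if return_genealogy:
        return out, gen
    return out
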