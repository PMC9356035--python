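"""Within- and between-population mtDNA summary statistics.

Implements the molecular-diversity indices used throughout the pipeline:
Kimura 2-parameter (K2P) distances between haplotypes, gene diversity H,
mean pairwise differences (nucleotide diversity) pi, haplotype counts k,
and the AMOVA-based fixation index PhiST between population samples with a
permutation significance test.  A fixed 14-statistic vector summarises the
seven-population Danubian sampling design: mean and SD of k, H and pi
across populations, plus mean and SD of pairwise PhiST within four groups
of population pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .coalescent import HaplotypeSample

__all__ = [
    "K2PSaturationError",
    "k2p_distance",
    "gene_diversity",
    "haplotype_count",
    "mean_pairwise_diff",
    "pairwise_phist",
    "fst_permutation_p",
    "GroupingPlan",
    "STAT_NAMES",
    "stats_vector",
]


class K2PSaturationError(ValueError):
    """The K2P correction is undefined (distances are saturated)."""


def _seq_array(seqs: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


_PURINE = frozenset(b"AG")


def _pq_counts(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Transition (P) and transversion (Q) proportions between two coded
    sequences."""
    diff = a != b
    L = a.shape[0]
    if not diff.any():
        return 0.0, 0.0
    da, db = a[diff], b[diff]
    pur_a = (da == ord("A")) | (da == ord("G"))
    pur_b = (db == ord("A")) | (db == ord("G"))
    transitions = int((pur_a == pur_b).sum())
    transversions = int(diff.sum()) - transitions
    return transitions / L, transversions / L


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura 2-parameter distance in substitutions per site.

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)) with P and Q the observed
    transition and transversion proportions.  Raises
    :class:`K2PSaturationError` when the correction is undefined.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    a = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)
    P, Q = _pq_counts(a, b)
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise K2PSaturationError(
            f"K2P distance undefined for P={P:.4g}, Q={Q:.4g} (saturation)"
        )
    return float(-0.5 * np.log(w1 * np.sqrt(w2)))


def _distance_matrix(seqs: Sequence[str], corrected: bool = True) -> np.ndarray:
    """Pairwise distance matrix: K2P substitutions/site (corrected) or raw
    difference counts."""
    arr = _seq_array(seqs)
    n, L = arr.shape
    D = np.zeros((n, n))
    for i in range(n):
        diff = arr[i] != arr[i + 1 :]
        if not corrected:
            D[i, i + 1 :] = diff.sum(axis=1)
        else:
            for off, d in enumerate(diff):
                j = i + 1 + off
                if not d.any():
                    continue
                da, db = arr[i][d], arr[j][d]
                pur_a = (da == ord("A")) | (da == ord("G"))
                pur_b = (db == ord("A")) | (db == ord("G"))
                ts = int((pur_a == pur_b).sum())
                P = ts / L
                Q = (int(d.sum()) - ts) / L
                w1 = 1.0 - 2.0 * P - Q
                w2 = 1.0 - 2.0 * Q
                if w1 <= 0 or w2 <= 0:
                    raise K2PSaturationError(
                        f"saturated pair ({i}, {j}): P={P:.4g}, Q={Q:.4g}"
                    )
                D[i, j] = -0.5 * np.log(w1 * np.sqrt(w2))
    return D + D.T


def gene_diversity(sample: HaplotypeSample) -> float:
    """Gene diversity H = n/(n-1) (1 - sum p_i^2) over haplotype
    frequencies; the probability that two random haplotypes differ, with
    small-sample correction."""
    n = sample.n
    if n < 2:
        raise ValueError("gene diversity requires n >= 2")
    _, counts = np.unique(sample.sequences, return_counts=True)
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def haplotype_count(sample: HaplotypeSample) -> int:
    """Number of distinct haplotypes k."""
    return int(len(set(sample.sequences)))


def mean_pairwise_diff(sample: HaplotypeSample, corrected: bool = True) -> float:
    """Mean pairwise difference pi within a sample.

    ``corrected=True`` (default) averages K2P distances (substitutions per
    site); ``corrected=False`` averages raw difference counts.  Saturated
    pairs are excluded with a warning under the corrected model.
    """
    n = sample.n
    if n < 2:
        raise ValueError("pi requires n >= 2")
    if not corrected:
        D = _distance_matrix(sample.sequences, corrected=False)
        iu = np.triu_indices(n, 1)
        return float(D[iu].mean())
    vals = []
    skipped = 0
    for i, j in combinations(range(n), 2):
        try:
            vals.append(k2p_distance(sample.sequences[i], sample.sequences[j]))
        except K2PSaturationError:
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} saturated pairs excluded from pi")
    if not vals:
        raise K2PSaturationError("all pairs saturated")
    return float(np.mean(vals))


def _amova_phist(D: np.ndarray, sizes: Sequence[int]) -> float:
    """PhiST from a matrix of molecular distances (treated as squared
    Euclidean distances, the Arlequin convention for AMOVA)."""
    N = D.shape[0]
    G = len(sizes)
    bounds = np.cumsum([0, *sizes])
    iu = np.triu_indices(N, 1)
    ssd_total = D[iu].sum() / N
    ssd_within = 0.0
    for g in range(G):
        lo, hi = bounds[g], bounds[g + 1]
        sub = D[lo:hi, lo:hi]
        ssd_within += sub[np.triu_indices(hi - lo, 1)].sum() / (hi - lo)
    ssd_among = ssd_total - ssd_within
    df_within = N - G
    df_among = G - 1
    if df_within <= 0:
        return 0.0
    msd_within = ssd_within / df_within
    msd_among = ssd_among / df_among
    n_c = (N - sum(s**2 for s in sizes) / N) / df_among
    sigma_a = (msd_among - msd_within) / n_c
    denom = sigma_a + msd_within
    if denom == 0:
        return 0.0
    return float(sigma_a / denom)


def pairwise_phist(
    sample_a: HaplotypeSample,
    sample_b: HaplotypeSample,
    corrected: bool = True,
    clamp: bool = True,
) -> float:
    """AMOVA-based PhiST between two population samples.

    Distances are K2P (``corrected=True``) or raw difference counts.
    Negative estimates (common under no differentiation) are clamped to 0
    for reporting when ``clamp=True``; pass ``clamp=False`` to retain the
    raw estimator.
    """
    if sample_a.n < 2 or sample_b.n < 2:
        raise ValueError("PhiST requires n >= 2 in both samples")
    seqs = list(sample_a.sequences) + list(sample_b.sequences)
    if len(set(seqs)) == 1:
        return 0.0
    D = _distance_matrix(seqs, corrected=corrected)
    phi = _amova_phist(D, (sample_a.n, sample_b.n))
    if clamp:
        return max(phi, 0.0)
    return phi


def fst_permutation_p(
    sample_a: HaplotypeSample,
    sample_b: HaplotypeSample,
    n_perm: int = 1000,
    seed: int = 0,
    corrected: bool = True,
) -> float:
    """One-tailed permutation P-value for PhiST between two samples.

    Individuals are permuted between the two samples; P is the smoothed
    proportion (1 + #{perm >= obs}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    seqs = list(sample_a.sequences) + list(sample_b.sequences)
    D = _distance_matrix(seqs, corrected=corrected)
    na = sample_a.n
    N = len(seqs)
    obs = _amova_phist(D, (na, N - na))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(N)
        Dp = D[np.ix_(perm, perm)]
        if _amova_phist(Dp, (na, N - na)) >= obs:
            hits += 1
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# The 14-statistic summary vector
# ---------------------------------------------------------------------------

STAT_NAMES = (
    "k_mean",
    "k_sd",
    "H_mean",
    "H_sd",
    "pi_mean",
    "pi_sd",
    "fst_hg_cefarmers_mean",
    "fst_hg_cefarmers_sd",
    "fst_early_mean",
    "fst_early_sd",
    "fst_late_mean",
    "fst_late_sd",
    "fst_serial_mean",
    "fst_serial_sd",
)


@dataclass(frozen=True)
class GroupingPlan:
    """Names the seven population samples and the four PhiST pair groups.

    ``early`` and ``late`` map an area label (e.g. 'greece', 'balkans',
    'central_europe') to the group_id of the Early resp. Middle-Late
    Neolithic farmer sample of that area; ``hg`` is the hunter-gatherer
    sample and ``hg_pair_areas`` the farmer areas it is paired with
    (central Europe, Early and Late, by default).
    """

    hg: str
    early: dict
    late: dict
    hg_pair_areas: tuple = ("central_europe",)

    @property
    def group_ids(self) -> list:
        return [self.hg, *self.early.values(), *self.late.values()]

    def pair_groups(self) -> dict:
        areas = sorted(self.early)
        return {
            "hg_cefarmers": [
                (self.hg, self.early[a]) for a in self.hg_pair_areas
            ]
            + [(self.hg, self.late[a]) for a in self.hg_pair_areas],
            "early": list(combinations([self.early[a] for a in areas], 2)),
            "late": list(combinations([self.late[a] for a in areas], 2)),
            "serial": [(self.early[a], self.late[a]) for a in areas],
        }

    @classmethod
    def danubian(cls) -> "GroupingPlan":
        areas = ("greece", "balkans", "central_europe")
        return cls(
            hg="HG_CE",
            early={a: f"EN_{a}" for a in areas},
            late={a: f"LN_{a}" for a in areas},
        )


def _sd(values: Sequence[float]) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def stats_vector(
    groups: dict,
    plan: Optional[GroupingPlan] = None,
    corrected: bool = True,
) -> np.ndarray:
    """The 14-statistic summary of seven population samples.

    ``groups`` maps group_id to :class:`HaplotypeSample`.  Returns the
    statistics in the fixed order of :data:`STAT_NAMES`: mean and sample SD
    (n-1 denominator) of k, H and pi across the seven samples, then mean
    and SD of pairwise PhiST within each of the four pair groups
    (hunter-gatherers vs central-European farmers, among Early Neolithic
    samples, among Late Neolithic samples, Early vs Late of the same area).
    PhiST values are clamped at 0, matching how they are reported.
    """
    plan = plan or GroupingPlan.danubian()
    missing = [g for g in plan.group_ids if g not in groups]
    if missing:
        raise ValueError(f"missing population samples: {missing}")
    ordered = [groups[g] for g in plan.group_ids]
    ks = [float(haplotype_count(s)) for s in ordered]
    Hs = [gene_diversity(s) for s in ordered]
    pis = [mean_pairwise_diff(s, corrected=corrected) for s in ordered]
    out = [np.mean(ks), _sd(ks), np.mean(Hs), _sd(Hs), np.mean(pis), _sd(pis)]
    for _, pairs in plan.pair_groups().items():
        fsts = [
            pairwise_phist(groups[a], groups[b], corrected=corrected, clamp=True)
            for a, b in pairs
        ]
        out.extend([float(np.mean(fsts)), _sd(fsts)])
    return np.asarray(out, dtype=float)
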