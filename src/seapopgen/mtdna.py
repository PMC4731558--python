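"""Sequence-based population statistics for a non-recombining mtDNA locus.

Implements the full haplotype workflow: collapsing an alignment into a
haplotype frequency table, Nei's haplotype and nucleotide diversity, TN93
model distances with gamma rate correction, AMOVA-based Phi_ST with
permutation tests (pairwise and hierarchical), Slatkin linearization,
mismatch distributions with the sudden-expansion (Rogers-Harpending) fit and
Harpending's raggedness, Tajima's D and Fu's Fs with coalescent significance,
Benjamini-Hochberg FDR, and the minimum-spanning haplotype network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import msprime
import networkx as nx
import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from statsmodels.stats.multitest import multipletests

from .io import MatrixTable, SequenceAlignment

_COMPARABLE = set("ACGT")
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class SaturationError(ValueError):
    """Model distance undefined: substitution saturation (log of non-positive)."""


class UndefinedStatistic(ValueError):
    """Statistic undefined for this input (e.g. n < 2 or S = 0)."""


# ---------------------------------------------------------------------------
# Haplotype table


@dataclass
class HaplotypeTable:
    """Unique haplotypes with per-population counts.

    ``counts`` is (n_haplotypes, n_populations); column sums are the
    population sample sizes.
    """

    haplotypes: list[str]
    populations: list[str]
    counts: np.ndarray
    length: int
    polymorphic_sites: int = 0
    transitions: int = 0
    transversions: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        assert self.counts.shape == (len(self.haplotypes), len(self.populations))
        if np.any(self.counts.sum(axis=1) < 1):
            raise ValueError("every haplotype needs total count >= 1")

    def n(self, population: Optional[str] = None) -> int:
        if population is None:
            return int(self.counts.sum())
        return int(self.counts[:, self.populations.index(population)].sum())

    def pop_counts(self, population: str) -> np.ndarray:
        return self.counts[:, self.populations.index(population)]

    def private_haplotypes(self, population: str) -> int:
        j = self.populations.index(population)
        present = self.counts[:, j] > 0
        elsewhere = np.delete(self.counts, j, axis=1).sum(axis=1) > 0
        return int(np.sum(present & ~elsewhere))


def collapse_haplotypes(alignment: SequenceAlignment) -> HaplotypeTable:
    """Merge identical sequences into haplotypes with per-population counts.

    Haplotypes are defined by exact sequence identity over all sites
    (ambiguous sites are part of the haplotype string; distance computations
    apply pairwise deletion separately).  Also tallies polymorphic sites and
    the transition/transversion changes observed at them.
    """
    if alignment.n_samples == 0:
        raise UndefinedStatistic("empty alignment")
    pops = alignment.populations
    order: dict[str, int] = {}
    counts_rows: list[np.ndarray] = []
    for seq, pop in zip(alignment.sites, alignment.population):
        if seq not in order:
            order[seq] = len(order)
            counts_rows.append(np.zeros(len(pops), dtype=int))
        counts_rows[order[seq]][pops.index(pop)] += 1
    haplos = list(order)
    counts = np.vstack(counts_rows)

    poly = ts = tv = 0
    for site in range(alignment.length):
        bases = {s[site] for s in haplos} & _COMPARABLE
        if len(bases) > 1:
            poly += 1
            for a in bases:
                for b in bases:
                    if a < b:
                        if {a, b} <= _PURINES or {a, b} <= _PYRIMIDINES:
                            ts += 1
                        else:
                            tv += 1
    return HaplotypeTable(
        haplotypes=haplos, populations=pops, counts=counts,
        length=alignment.length, polymorphic_sites=poly,
        transitions=ts, transversions=tv,
    )


# ---------------------------------------------------------------------------
# Diversity


def haplotype_diversity(counts: Sequence[int]) -> float:
    """Nei's unbiased haplotype diversity h = n/(n-1) (1 - sum p_k^2)."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise UndefinedStatistic("haplotype diversity needs n >= 2")
    p = c / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


@dataclass
class DistanceModel:
    """Molecular distance between haplotypes.

    ``name`` is ``"hamming"`` (site differences), ``"p"`` (per-site), or
    ``"tn93"`` (per-site TN93, with gamma correction when ``alpha`` is set —
    the mtDNA analyses of the study use alpha = 0.023).  Base frequencies
    default to the empirical frequencies of the compared pair.
    """

    name: str = "hamming"
    alpha: Optional[float] = None
    freqs: Optional[tuple[float, float, float, float]] = None

    def __post_init__(self) -> None:
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape alpha must be positive")
        if self.name not in ("hamming", "p", "tn93"):
            raise ValueError(f"unknown distance model {self.name!r}")

    def distance(self, a: str, b: str) -> float:
        if self.name == "tn93":
            return tn93_gamma_distance(a, b, self)
        diffs, comparable = _site_differences(a, b)
        if comparable == 0:
            raise SaturationError("no comparable sites")
        return diffs if self.name == "hamming" else diffs / comparable


def _site_differences(a: str, b: str) -> tuple[int, int]:
    diffs = comparable = 0
    for x, y in zip(a, b):
        if x in _COMPARABLE and y in _COMPARABLE:
            comparable += 1
            if x != y:
                diffs += 1
    return diffs, comparable


def tn93_gamma_distance(seq_a: str, seq_b: str, model: DistanceModel) -> float:
    """Tamura-Nei distance, optionally gamma-corrected.

    With shape alpha, each -ln(e) term of the TN93 formula is replaced by
    alpha (e^(-1/alpha) - 1), the standard gamma-rates correction.  Raises
    ``SaturationError`` when any log/power argument is non-positive.
    """
    pairs = [
        (x, y) for x, y in zip(seq_a, seq_b)
        if x in _COMPARABLE and y in _COMPARABLE
    ]
    if not pairs:
        raise SaturationError("no comparable sites after pairwise deletion")
    n = len(pairs)
    p1 = sum({x, y} == _PURINES for x, y in pairs) / n
    p2 = sum({x, y} == _PYRIMIDINES for x, y in pairs) / n
    q = sum((x in _PURINES) != (y in _PURINES) for x, y in pairs) / n

    if model.freqs is not None:
        pa, pc, pg, pt = model.freqs
    else:
        all_bases = [z for x, y in pairs for z in (x, y)]
        m = len(all_bases)
        pa = all_bases.count("A") / m
        pc = all_bases.count("C") / m
        pg = all_bases.count("G") / m
        pt = all_bases.count("T") / m
    pr, py = pa + pg, pc + pt
    if min(pa, pc, pg, pt) <= 0:
        raise SaturationError("a base frequency is zero; TN93 undefined")

    k1 = pa * pg / pr
    k2 = pc * pt / py
    k3 = pr * py - pa * pg * py / pr - pc * pt * pr / py
    e1 = 1.0 - p1 / (2.0 * k1) - q / (2.0 * pr)
    e2 = 1.0 - p2 / (2.0 * k2) - q / (2.0 * py)
    e3 = 1.0 - q / (2.0 * pr * py)
    if e1 <= 0 or e2 <= 0 or e3 <= 0:
        raise SaturationError("substitution saturation: log argument <= 0")
    if model.alpha is None:
        return float(-2 * (k1 * math.log(e1) + k2 * math.log(e2) + k3 * math.log(e3)))
    a = model.alpha
    g = lambda e: e ** (-1.0 / a) - 1.0
    return float(2 * a * (k1 * g(e1) + k2 * g(e2) + k3 * g(e3)))


def haplotype_distance_matrix(table: HaplotypeTable, model: DistanceModel) -> np.ndarray:
    H = len(table.haplotypes)
    D = np.zeros((H, H))
    for i in range(H):
        for j in range(i + 1, H):
            D[i, j] = D[j, i] = model.distance(table.haplotypes[i], table.haplotypes[j])
    return D


def nucleotide_diversity(
    table: HaplotypeTable,
    model: DistanceModel | None = None,
    population: Optional[str] = None,
) -> float:
    """Nei's nucleotide diversity: sample-size-corrected mean per-site
    pairwise distance, pi = n/(n-1) sum_{k!=l} x_k x_l d_kl / L."""
    model = model or DistanceModel("hamming")
    c = table.counts.sum(axis=1) if population is None else table.pop_counts(population)
    n = c.sum()
    if n < 2:
        raise UndefinedStatistic("nucleotide diversity needs n >= 2")
    keep = np.flatnonzero(c)
    x = c[keep] / n
    D = np.zeros((len(keep), len(keep)))
    for a, i in enumerate(keep):
        for b, j in enumerate(keep):
            if a < b:
                D[a, b] = D[b, a] = model.distance(
                    table.haplotypes[i], table.haplotypes[j]
                )
    per_seq = float(x @ D @ x) * n / (n - 1)
    if model.name == "hamming":
        per_seq /= table.length
    return per_seq


def mean_pairwise_differences(table: HaplotypeTable, population: Optional[str] = None) -> float:
    """Mean number of Hamming site differences over all C(n,2) pairs."""
    c = table.counts.sum(axis=1) if population is None else table.pop_counts(population)
    n = c.sum()
    if n < 2:
        raise UndefinedStatistic("needs n >= 2")
    keep = np.flatnonzero(c)
    tot = 0.0
    for a, i in enumerate(keep):
        for b, j in enumerate(keep):
            if a < b:
                d, _ = _site_differences(table.haplotypes[i], table.haplotypes[j])
                tot += c[i] * c[j] * d
    return tot / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# AMOVA / Phi_ST


def _amova_two_level(D2: np.ndarray, hap_idx: np.ndarray, pop_idx: np.ndarray, n_pops: int):
    """Variance components for individuals (haplotype indices) in pops.

    ``D2`` is the squared-distance matrix between haplotypes; returns
    (sigma2_a, sigma2_w, phi_st).
    """
    N = len(hap_idx)
    counts = np.zeros((D2.shape[0], n_pops))
    np.add.at(counts, (hap_idx, pop_idx), 1)
    n_p = counts.sum(axis=0)
    total = counts.sum(axis=1)
    ss_total = float(total @ D2 @ total) / (2.0 * N)
    ss_within = sum(
        float(counts[:, p] @ D2 @ counts[:, p]) / (2.0 * n_p[p])
        for p in range(n_pops) if n_p[p] > 0
    )
    ss_among = ss_total - ss_within
    P = int(np.sum(n_p > 0))
    sigma_w = ss_within / (N - P)
    n_prime = (N - np.sum(n_p**2) / N) / (P - 1)
    ms_among = ss_among / (P - 1)
    sigma_a = (ms_among - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom != 0 else 0.0
    return sigma_a, sigma_w, phi


def pairwise_phist(
    table: HaplotypeTable,
    model: DistanceModel | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> MatrixTable:
    """Pairwise Phi_ST (AMOVA on squared model distances) with permutation p.

    For each population pair, individuals are shuffled between the two
    populations; p = (#{Phi* >= Phi} + 1) / (n_perm + 1).  Negative estimates
    are retained.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    model = model or DistanceModel("tn93", alpha=0.023)
    pops = table.populations
    if len(pops) < 2:
        raise UndefinedStatistic("need >= 2 populations")
    D2 = haplotype_distance_matrix(table, model) ** 2
    rng = np.random.default_rng(seed)
    K = len(pops)
    vals = np.zeros((K, K))
    pvals = np.ones((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            ci, cj = table.counts[:, i], table.counts[:, j]
            if ci.sum() < 2 or cj.sum() < 2:
                raise UndefinedStatistic(f"population {pops[i]} or {pops[j]} has n < 2")
            hap_idx = np.concatenate(
                [np.repeat(np.arange(len(ci)), ci), np.repeat(np.arange(len(cj)), cj)]
            )
            pop_idx = np.concatenate(
                [np.zeros(ci.sum(), dtype=int), np.ones(cj.sum(), dtype=int)]
            )
            _, _, phi = _amova_two_level(D2, hap_idx, pop_idx, 2)
            hits = 0
            labels = pop_idx.copy()
            for _ in range(n_perm):
                rng.shuffle(labels)
                _, _, phi_star = _amova_two_level(D2, hap_idx, labels, 2)
                if phi_star >= phi - 1e-12:
                    hits += 1
            vals[i, j] = vals[j, i] = phi
            pvals[i, j] = pvals[j, i] = (hits + 1) / (n_perm + 1)
    np.fill_diagonal(pvals, np.nan)
    return MatrixTable(labels=list(pops), values=vals, pvalues=pvals, symmetric=True)


@dataclass
class AmovaResult:
    sigma_a: float  # among groups
    sigma_b: float  # among populations within groups
    sigma_c: float  # within populations
    f_ct: float
    f_sc: float
    f_st: float
    p_ct: float
    p_sc: float
    p_st: float


def _amova_three_level(D2, hap_idx, pop_idx, group_of_pop):
    N = len(hap_idx)
    n_pops = len(group_of_pop)
    counts = np.zeros((D2.shape[0], n_pops))
    np.add.at(counts, (hap_idx, pop_idx), 1)
    n_p = counts.sum(axis=0)
    groups = sorted(set(group_of_pop))
    G = len(groups)
    P = int(np.sum(n_p > 0))
    ss_total = float(counts.sum(axis=1) @ D2 @ counts.sum(axis=1)) / (2.0 * N)
    ss_pop = np.array([
        float(counts[:, p] @ D2 @ counts[:, p]) / (2.0 * n_p[p]) if n_p[p] > 0 else 0.0
        for p in range(n_pops)
    ])
    ssd_wp = ss_pop.sum()
    ssd_ap = 0.0
    n_g = {}
    for g in groups:
        members = [p for p in range(n_pops) if group_of_pop[p] == g]
        cg = counts[:, members].sum(axis=1)
        ng = cg.sum()
        n_g[g] = ng
        if ng == 0:
            raise UndefinedStatistic(f"group {g} has no samples")
        ss_g = float(cg @ D2 @ cg) / (2.0 * ng)
        ssd_ap += ss_g - ss_pop[members].sum()
    ssd_ag = ss_total - ssd_wp - ssd_ap

    sigma_c = ssd_wp / (N - P)
    sum_npg = sum(
        sum(n_p[p] ** 2 for p in range(n_pops) if group_of_pop[p] == g) / n_g[g]
        for g in groups
    )
    n1 = (N - sum_npg) / (P - G)
    sigma_b = (ssd_ap / (P - G) - sigma_c) / n1 if P > G else 0.0
    n2 = (sum_npg - np.sum(n_p**2) / N) / (G - 1)
    n3 = (N - sum(n_g[g] ** 2 for g in groups) / N) / (G - 1)
    sigma_a = (ssd_ag / (G - 1) - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


def amova_hierarchical(
    table: HaplotypeTable,
    groups: dict[str, str],
    model: DistanceModel | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> AmovaResult:
    """Three-level AMOVA: among groups / among pops within groups / within.

    Permutation schemes: whole populations among groups for F_CT;
    individuals among populations within their group for F_SC; individuals
    among all populations for F_ST.
    """
    model = model or DistanceModel("tn93", alpha=0.023)
    pops = table.populations
    group_of_pop = [groups[p] for p in pops]
    if len(set(group_of_pop)) < 2:
        raise UndefinedStatistic("need >= 2 groups")
    D2 = haplotype_distance_matrix(table, model) ** 2
    hap_idx = np.concatenate([
        np.repeat(np.arange(table.counts.shape[0]), table.counts[:, p])
        for p in range(len(pops))
    ])
    pop_idx = np.concatenate([
        np.full(int(table.counts[:, p].sum()), p) for p in range(len(pops))
    ])

    def _ratio(num, den):
        return num / den if den != 0 else 0.0

    sa, sb, sc = _amova_three_level(D2, hap_idx, pop_idx, group_of_pop)
    tot = sa + sb + sc
    f_ct = _ratio(sa, tot)
    f_sc = _ratio(sb, sb + sc)
    f_st = _ratio(sa + sb, tot)

    rng = np.random.default_rng(seed)
    hits_ct = hits_sc = hits_st = 0
    # F_CT: permute populations among groups
    gop = list(group_of_pop)
    for _ in range(n_perm):
        rng.shuffle(gop)
        a, b, c = _amova_three_level(D2, hap_idx, pop_idx, gop)
        if _ratio(a, a + b + c) >= f_ct - 1e-12:
            hits_ct += 1
    # F_SC: permute individuals among pops within groups
    for _ in range(n_perm):
        perm_pop = pop_idx.copy()
        for g in set(group_of_pop):
            sel = np.isin(perm_pop, [p for p in range(len(pops)) if group_of_pop[p] == g])
            vals = perm_pop[sel]
            rng.shuffle(vals)
            perm_pop[sel] = vals
        a, b, c = _amova_three_level(D2, hap_idx, perm_pop, group_of_pop)
        if _ratio(b, b + c) >= f_sc - 1e-12:
            hits_sc += 1
    # F_ST: permute individuals among all pops
    perm_pop = pop_idx.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_pop)
        a, b, c = _amova_three_level(D2, hap_idx, perm_pop, group_of_pop)
        if _ratio(a + b, a + b + c) >= f_st - 1e-12:
            hits_st += 1

    return AmovaResult(
        sigma_a=sa, sigma_b=sb, sigma_c=sc,
        f_ct=f_ct, f_sc=f_sc, f_st=f_st,
        p_ct=(hits_ct + 1) / (n_perm + 1),
        p_sc=(hits_sc + 1) / (n_perm + 1),
        p_st=(hits_st + 1) / (n_perm + 1),
    )


def slatkin_linearize(value: float) -> float:
    """Slatkin's linearization x / (1 - x); negative inputs pass through."""
    if value >= 1:
        return math.inf
    return value / (1.0 - value)


# ---------------------------------------------------------------------------
# Mismatch distribution and sudden-expansion fit


def mismatch_distribution(table: HaplotypeTable, population: str) -> np.ndarray:
    """Relative frequencies of pairwise Hamming difference counts 0..d_max."""
    c = table.pop_counts(population)
    n = c.sum()
    if n < 2:
        raise UndefinedStatistic("mismatch distribution needs n >= 2")
    keep = np.flatnonzero(c)
    pair_counts: dict[int, float] = {}
    for a, i in enumerate(keep):
        for b, j in enumerate(keep):
            if a > b:
                continue
            d, _ = _site_differences(table.haplotypes[i], table.haplotypes[j])
            w = c[i] * (c[i] - 1) / 2 if i == j else c[i] * c[j]
            pair_counts[d] = pair_counts.get(d, 0.0) + w
    d_max = max(pair_counts)
    hist = np.zeros(d_max + 1)
    for d, w in pair_counts.items():
        hist[d] = w
    return hist / hist.sum()


def expected_mismatch(i_max: int, tau: float, theta0: float, theta1: float) -> np.ndarray:
    """Sudden-expansion expected mismatch probabilities F_i for i = 0..i_max.

    F_i = Fhat_i(theta1) + e^-tau sum_j tau^j/j! [Fhat_{i-j}(theta0) -
    Fhat_{i-j}(theta1)], with Fhat the geometric equilibrium distribution
    Fhat_i(theta) = theta^i / (1+theta)^(i+1).
    """
    i = np.arange(i_max + 1)

    def fhat(theta: float) -> np.ndarray:
        if theta <= 0:
            out = np.zeros(i_max + 1)
            out[0] = 1.0
            return out
        return np.exp(i * math.log(theta) - (i + 1) * math.log1p(theta))

    f0, f1 = fhat(theta0), fhat(theta1)
    out = f1.copy()
    pois = stats.poisson.pmf(i, tau) if tau > 0 else np.where(i == 0, 1.0, 0.0)
    diff = f0 - f1
    for k in range(i_max + 1):
        out[k] += np.sum(pois[: k + 1] * diff[k::-1])
    return out


def raggedness(hist: Sequence[float]) -> float:
    """Harpending's raggedness with zero classes padded on both sides."""
    x = np.concatenate([[0.0], np.asarray(hist, dtype=float), [0.0]])
    return float(np.sum(np.diff(x) ** 2))


@dataclass
class ExpansionFit:
    tau: float
    theta0: float
    theta1: float
    ssd: float
    raggedness: float
    p_ssd: Optional[float] = None
    p_raggedness: Optional[float] = None
    converged: bool = True


def _fit_mismatch_curve(
    hist: np.ndarray,
    starts: Optional[list[tuple[float, float, float]]] = None,
) -> tuple[float, float, float, float, bool]:
    d_max = len(hist) - 1
    mean_d = float(np.sum(np.arange(d_max + 1) * hist))

    def resid(params):
        tau, th0, dth = params
        return expected_mismatch(d_max, tau, th0, th0 + dth) - hist

    if starts is None:
        starts = [
            (tau0, th0, dth)
            for tau0 in (max(mean_d, 0.5), max(mean_d / 2, 0.25))
            for th0 in (0.1, 1.0)
            for dth in (10.0, 100.0)
        ]
    best = None
    for x0 in starts:
        sol = least_squares(
            resid, x0=list(x0),
            bounds=([0, 0, 0], [np.inf, np.inf, np.inf]),
            xtol=1e-10, ftol=1e-10,
        )
        ssd = float(np.sum(sol.fun**2))
        if best is None or ssd < best[3]:
            best = (sol.x[0], sol.x[1], sol.x[1] + sol.x[2], ssd, sol.success)
    tau, th0, th1, ssd, ok = best
    return float(tau), float(th0), float(th1), ssd, bool(ok)


def _simulate_mismatch(
    n: int, tau: float, theta0: float, theta1: float, rng: np.random.Generator
) -> np.ndarray:
    """One coalescent dataset under sudden expansion; mismatch histogram.

    Parametrized in mutation units: per-lineage mutation rate 1/generation,
    present haploid size theta1/2, size theta0/2 before generation tau/2.
    """
    dem = msprime.Demography()
    dem.add_population(name="P", initial_size=max(theta1, 1e-6) / 2.0)
    dem.add_population_parameters_change(
        time=tau / 2.0, initial_size=max(theta0, 1e-6) / 2.0, population="P"
    )
    ts = msprime.sim_ancestry(
        samples={"P": n}, demography=dem, ploidy=1,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    tree = ts.first()
    sigs = {u: [] for u in ts.samples()}
    mut_id = 0
    for u in tree.nodes():
        if u == tree.root:
            continue
        k = rng.poisson(tree.branch_length(u))
        if k:
            below = list(tree.samples(u))
            for s in below:
                sigs[s].extend(range(mut_id, mut_id + k))
            mut_id += k
    samples = list(ts.samples())
    sets = [frozenset(sigs[s]) for s in samples]
    counts: dict[int, int] = {}
    for a in range(n):
        for b in range(a + 1, n):
            d = len(sets[a] ^ sets[b])
            counts[d] = counts.get(d, 0) + 1
    d_max = max(counts)
    hist = np.zeros(d_max + 1)
    for d, w in counts.items():
        hist[d] = w
    return hist / hist.sum()


def fit_sudden_expansion(
    hist: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
    sample_size: Optional[int] = None,
) -> ExpansionFit:
    """Least-squares fit of the sudden-expansion model to a mismatch histogram.

    Returns (tau, theta0, theta1), the sum of squared deviations (SSD) and
    raggedness, with parametric-bootstrap p-values when ``n_boot > 0`` (this
    requires ``sample_size``, the number of sequences behind the histogram):
    datasets are simulated under the fitted model, refit, and
    p = P(statistic_sim >= statistic_obs).
    """
    hist = np.asarray(hist, dtype=float)
    if hist.ndim != 1 or len(hist) < 1:
        raise ValueError("histogram must be a 1-D frequency vector")
    tau, th0, th1, ssd, ok = _fit_mismatch_curve(hist)
    r_obs = raggedness(hist)
    fit = ExpansionFit(tau=tau, theta0=th0, theta1=th1, ssd=ssd, raggedness=r_obs, converged=ok)
    if n_boot > 0:
        if sample_size is None or sample_size < 2:
            raise ValueError("bootstrap requires sample_size >= 2")
        rng = np.random.default_rng(seed)
        hits_ssd = hits_r = 0
        boot_starts = [(max(tau, 0.1), max(th0, 0.05), max(th1 - th0, 1.0))]
        for _ in range(n_boot):
            h = _simulate_mismatch(sample_size, tau, th0, th1, rng)
            _, _, _, ssd_sim, _ = _fit_mismatch_curve(h, starts=boot_starts)
            if ssd_sim >= ssd - 1e-15:
                hits_ssd += 1
            if raggedness(h) >= r_obs - 1e-15:
                hits_r += 1
        fit.p_ssd = (hits_ssd + 1) / (n_boot + 1)
        fit.p_raggedness = (hits_r + 1) / (n_boot + 1)
    return fit


# ---------------------------------------------------------------------------
# Neutrality tests


@dataclass
class NeutralityResult:
    statistic: float
    p: Optional[float]
    s: int
    theta_pi: float
    defined: bool = True


def _segregating_sites(table: HaplotypeTable, population: str) -> int:
    c = table.pop_counts(population)
    seqs = [table.haplotypes[i] for i in np.flatnonzero(c)]
    s = 0
    for site in range(table.length):
        bases = {q[site] for q in seqs} & _COMPARABLE
        if len(bases) > 1:
            s += 1
    return s


def _coalescent_branches(n: int, rng: np.random.Generator) -> list[tuple[frozenset, float]]:
    """Kingman genealogy (time in 2N units); branches as (tip set, length)."""
    active: list[tuple[frozenset, float]] = [(frozenset([i]), 0.0) for i in range(n)]
    t = 0.0
    branches: list[tuple[frozenset, float]] = []
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        (si, bi), (sj, bj) = active[i], active[j]
        branches.append((si, t - bi))
        branches.append((sj, t - bj))
        merged = (si | sj, t)
        active = [a for idx, a in enumerate(active) if idx not in (i, j)]
        active.append(merged)
    return branches


def _simulate_conditional_s(
    n: int, s: int, rng: np.random.Generator
) -> tuple[float, int]:
    """Simulate one neutral genealogy, place S mutations, return (pi, k)."""
    branches = _coalescent_branches(n, rng)
    lens = np.array([b for _, b in branches])
    probs = lens / lens.sum()
    which = rng.choice(len(branches), size=s, p=probs)
    pi = 0.0
    sigs: dict[int, list[int]] = {i: [] for i in range(n)}
    for m, bi in enumerate(which):
        tips = branches[bi][0]
        i = len(tips)
        pi += i * (n - i)
        for tip in tips:
            sigs[tip].append(m)
    pi /= n * (n - 1) / 2
    k = len({tuple(v) for v in sigs.values()})
    return pi, k


def tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {
        "a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
        "e1": c1 / a1, "e2": c2 / (a1**2 + a2),
    }


def tajimas_d(
    table: HaplotypeTable,
    population: str,
    n_sim: int = 10_000,
    seed: int = 0,
) -> NeutralityResult:
    """Tajima's D with coalescent significance conditional on n and S.

    p is the lower-tail probability P(D_sim <= D_obs) (small values signal
    the excess of rare variants expected after expansion).
    """
    n = table.n(population)
    s = _segregating_sites(table, population)
    pi = mean_pairwise_differences(table, population)
    if s == 0 or n < 4:
        return NeutralityResult(statistic=math.nan, p=None, s=s, theta_pi=pi, defined=False)
    c = tajima_constants(n)
    d_obs = (pi - s / c["a1"]) / math.sqrt(c["e1"] * s + c["e2"] * s * (s - 1))
    p = None
    if n_sim > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_sim):
            pi_sim, _ = _simulate_conditional_s(n, s, rng)
            d_sim = (pi_sim - s / c["a1"]) / math.sqrt(
                c["e1"] * s + c["e2"] * s * (s - 1)
            )
            if d_sim <= d_obs + 1e-12:
                hits += 1
        p = (hits + 1) / (n_sim + 1)
    return NeutralityResult(statistic=d_obs, p=p, s=s, theta_pi=pi)


def ewens_k_pmf(n: int, theta: float) -> np.ndarray:
    """P(K = k) for k = 1..n under the Ewens sampling formula.

    Uses unsigned Stirling numbers of the first kind:
    P(K=k) = |s(n,k)| theta^k / (theta)_n.
    """
    if theta <= 0:
        raise UndefinedStatistic("Ewens pmf needs theta > 0")
    # Stirling triangle |s(n, k)| by the recurrence, exact integers
    row = [0, 1]  # n = 1
    for m in range(1, n):
        new = [0] * (m + 2)
        for k in range(1, m + 2):
            new[k] = row[k - 1] + (m) * (row[k] if k <= m else 0)
        row = new
    rising = 1.0
    log_rising = sum(math.log(theta + i) for i in range(n))
    pmf = np.zeros(n)
    for k in range(1, n + 1):
        log_p = math.log(row[k]) + k * math.log(theta) - log_rising
        pmf[k - 1] = math.exp(log_p)
    return pmf


def _fs_from(n: int, k: int, theta: float) -> float:
    pmf = ewens_k_pmf(n, theta)
    s_prime = float(pmf[k - 1 :].sum())
    s_prime = min(max(s_prime, 0.0), 1.0)
    if s_prime >= 1.0:
        return math.inf
    if s_prime <= 0.0:
        return -math.inf
    return math.log(s_prime / (1.0 - s_prime))


def fus_fs(
    table: HaplotypeTable,
    population: str,
    n_sim: int = 10_000,
    seed: int = 0,
) -> NeutralityResult:
    """Fu's Fs: log-odds that a neutral sample with theta = pi-hat shows at
    least the observed number of haplotypes; coalescent p-value conditional
    on n and S (strongly negative Fs signals expansion; the reporting
    significance level is 0.02)."""
    n = table.n(population)
    pi = mean_pairwise_differences(table, population)
    k_obs = int(np.sum(table.pop_counts(population) > 0))
    s = _segregating_sites(table, population)
    if pi <= 0:
        return NeutralityResult(statistic=math.nan, p=None, s=s, theta_pi=pi, defined=False)
    fs_obs = _fs_from(n, k_obs, pi)
    p = None
    if n_sim > 0 and math.isfinite(fs_obs):
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_sim):
            pi_sim, k_sim = _simulate_conditional_s(n, s, rng)
            fs_sim = _fs_from(n, k_sim, pi_sim) if pi_sim > 0 else math.inf
            if fs_sim <= fs_obs + 1e-12:
                hits += 1
        p = (hits + 1) / (n_sim + 1)
    return NeutralityResult(statistic=fs_obs, p=p, s=s, theta_pi=pi)


# ---------------------------------------------------------------------------
# FDR and the haplotype network


def fdr_adjust(p_values: Sequence[float], alpha: float = 0.05):
    """Benjamini-Hochberg step-up: (reject flags, adjusted p, threshold)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([]), 0.0
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject, p_adj, threshold


def haplotype_mst(table: HaplotypeTable) -> list[tuple[int, int, int]]:
    """Minimum spanning tree over haplotypes on Hamming distances.

    Ties are broken deterministically by (distance, lower index pair);
    returns edges ``(i, j, steps)`` with i < j.
    """
    H = len(table.haplotypes)
    if H < 2:
        raise UndefinedStatistic("MST needs >= 2 haplotypes")
    G = nx.Graph()
    edges = []
    for i in range(H):
        for j in range(i + 1, H):
            d, _ = _site_differences(table.haplotypes[i], table.haplotypes[j])
            edges.append((d, i, j))
    edges.sort()
    for d, i, j in edges:
        G.add_edge(i, j, weight=d)
    mst = nx.minimum_spanning_tree(G, algorithm="kruskal")
    out = sorted(
        (min(u, v), max(u, v), int(G[u][v]["weight"])) for u, v in mst.edges()
    )
    return out
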