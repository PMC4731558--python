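"""Microsatellite statistics: diversity, HWE/LD permutation tests, rarefied
allelic richness, EM null-allele estimation, Weir-Cockerham theta with the
ENA null-allele correction, and the two-phase-model bottleneck test.

Null alleles (amplification failures at the primer site) inflate apparent
homozygosity; the EM estimator recovers their frequency per locus and
population under Hardy-Weinberg with a blank (failed-genotype) class, and
the ENA correction recomputes theta treating the null as an extra allelic
state so that differentiation is not biased by locus-specific artefacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeTable, MatrixTable
from .mtdna import UndefinedStatistic, _coalescent_branches


# ---------------------------------------------------------------------------
# Per-locus/population summaries


def _pop_locus_calls(table: GenotypeTable, locus: str, pop: str):
    l = table.loci.index(locus)
    return [
        row[l]
        for i, row in enumerate(table.calls)
        if table.population[i] == pop and row[l] is not None
    ]


def unbiased_he(alleles: Sequence[int]) -> float:
    a = np.asarray(alleles)
    n2 = len(a)
    if n2 < 2:
        raise UndefinedStatistic("He needs >= 2 gene copies")
    _, cnt = np.unique(a, return_counts=True)
    p = cnt / n2
    return float(n2 / (n2 - 1) * (1.0 - np.sum(p**2)))


def locus_pop_stats(table: GenotypeTable) -> pd.DataFrame:
    """Per locus and population: N, allele count, Ho, unbiased He, F_IS.

    F_IS = 1 - Ho/He (undefined, NaN, at monomorphic loci); under random
    mating its expectation is ~0 because the unbiased He estimates the
    heterozygosity of two copies drawn without replacement.
    """
    rows = []
    for pop in table.populations:
        for locus in table.loci:
            calls = _pop_locus_calls(table, locus, pop)
            if not calls:
                continue
            n = len(calls)
            alleles = [x for c in calls for x in c]
            na = len(set(alleles))
            ho = sum(a != b for a, b in calls) / n
            he = unbiased_he(alleles) if na > 1 else 0.0
            fis = 1.0 - ho / he if he > 0 else math.nan
            rows.append(
                {"population": pop, "locus": locus, "N": n, "Na": na,
                 "Ho": ho, "He": he, "F_IS": fis}
            )
    return pd.DataFrame(rows)


@dataclass
class HweResult:
    f_is: float
    p_two_sided: float
    p_deficit: float
    #: randomized tie-smoothed p-values: exactly uniform under the null even
    #: though the heterozygote count is discrete; use for calibration work
    p_two_sided_smoothed: float = float("nan")
    p_deficit_smoothed: float = float("nan")


def _smoothed_p(greater: int, ties: int, n_perm: int, u: float) -> float:
    """Randomized permutation p: ties (incl. the observed draw) broken by u."""
    return (greater + u * (ties + 1)) / (n_perm + 1)


def hwe_test(
    table: GenotypeTable, locus: str, population: str,
    n_perm: int = 10_000, seed: int = 0,
) -> HweResult:
    """Permutation HWE test: gene copies shuffled into genotypes, F_IS statistic.

    ``p_deficit`` is the one-sided heterozygote-deficit tail
    (F_IS* >= observed), the direction null alleles push.
    """
    calls = _pop_locus_calls(table, locus, population)
    if len(calls) < 5:
        raise UndefinedStatistic("HWE test needs >= 5 genotypes")
    alleles = np.array([x for c in calls for x in c])
    if len(set(alleles)) < 2:
        return HweResult(f_is=math.nan, p_two_sided=1.0, p_deficit=1.0)
    n = len(calls)
    he = unbiased_he(alleles)

    def fis_of(pairs: np.ndarray) -> float:
        ho = np.mean(pairs[:, 0] != pairs[:, 1])
        return 1.0 - ho / he

    obs = fis_of(np.array(calls))
    rng = np.random.default_rng(seed)
    copies = alleles.copy()
    gt_two = tie_two = gt_def = tie_def = 0
    for _ in range(n_perm):
        rng.shuffle(copies)
        f = fis_of(copies.reshape(n, 2))
        if abs(f) > abs(obs) + 1e-12:
            gt_two += 1
        elif abs(f) >= abs(obs) - 1e-12:
            tie_two += 1
        if f > obs + 1e-12:
            gt_def += 1
        elif f >= obs - 1e-12:
            tie_def += 1
    u1, u2 = rng.random(2)
    return HweResult(
        f_is=obs,
        p_two_sided=(gt_two + tie_two + 1) / (n_perm + 1),
        p_deficit=(gt_def + tie_def + 1) / (n_perm + 1),
        p_two_sided_smoothed=_smoothed_p(gt_two, tie_two, n_perm, u1),
        p_deficit_smoothed=_smoothed_p(gt_def, tie_def, n_perm, u2),
    )


def _codes(values: list) -> np.ndarray:
    lookup: dict = {}
    return np.array([lookup.setdefault(v, len(lookup)) for v in values])


def _g_statistic(xs: np.ndarray, ys: np.ndarray) -> float:
    kx, ky = xs.max() + 1, ys.max() + 1
    if kx < 2 or ky < 2:
        return 0.0
    tab = np.bincount(xs * ky + ys, minlength=kx * ky).reshape(kx, ky).astype(float)
    exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(tab > 0, tab * np.log(tab / exp), 0.0)
    return 2.0 * float(terms.sum())


def ld_test(
    table: GenotypeTable, locus_pair: tuple[str, str],
    n_perm: int = 10_000, seed: int = 0,
    smoothed: bool = False,
) -> float:
    """Genotypic linkage-disequilibrium permutation test for a locus pair.

    Statistic: log-likelihood G of the genotype contingency table, summed
    over populations; one locus's genotypes are shuffled among individuals
    within each population.  Returns the one-sided p (with ``smoothed`` the
    randomized tie-smoothed p, exactly uniform under independence).
    """
    la, lb = (table.loci.index(l) for l in locus_pair)
    per_pop: list[tuple[list, list]] = []
    for pop in table.populations:
        xs, ys = [], []
        for i, row in enumerate(table.calls):
            if table.population[i] == pop and row[la] is not None and row[lb] is not None:
                xs.append(row[la])
                ys.append(row[lb])
        if len(xs) >= 5:
            per_pop.append((_codes(xs), _codes(ys)))
    if not per_pop:
        raise UndefinedStatistic("LD test needs >= 5 doubly genotyped individuals")
    obs = sum(_g_statistic(xs, ys) for xs, ys in per_pop)
    if obs == 0.0:
        return 1.0
    rng = np.random.default_rng(seed)
    gt = ties = 0
    shuffled = [ys.copy() for _, ys in per_pop]
    for _ in range(n_perm):
        g = 0.0
        for (xs, _), ys in zip(per_pop, shuffled):
            rng.shuffle(ys)
            g += _g_statistic(xs, ys)
        if g > obs + 1e-9:
            gt += 1
        elif g >= obs - 1e-9:
            ties += 1
    if smoothed:
        return _smoothed_p(gt, ties, n_perm, float(rng.random()))
    return (gt + ties + 1) / (n_perm + 1)


def allelic_richness(table: GenotypeTable, g: int = 34) -> pd.DataFrame:
    """Rarefied allelic richness: expected allele count in g gene copies.

    Ar(g) = sum_a [1 - C(Ng - Na, g) / C(Ng, g)]; g defaults to 34 gene
    copies (17 diploids).  Raises if any population has fewer than g copies
    at a locus, naming the population.
    """
    rows = []
    for pop in table.populations:
        for locus in table.loci:
            alleles = table.alleles(locus, pop)
            ng = len(alleles)
            if ng == 0:
                continue
            if ng < g:
                raise UndefinedStatistic(
                    f"population {pop} has only {ng} gene copies at {locus}, need {g}"
                )
            _, cnt = np.unique(alleles, return_counts=True)
            ar = sum(
                1.0 - math.comb(ng - na, g) / math.comb(ng, g) for na in cnt
            )
            rows.append({"population": pop, "locus": locus, "Ng": ng, "Ar": ar})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Null-allele EM


@dataclass
class NullAlleleEstimate:
    r: float
    beta: float  # technical-failure probability for blanks
    freqs: dict[int, float]
    converged: bool
    iterations: int


def null_allele_em(
    table: GenotypeTable, locus: str, population: str,
    tol: float = 1e-7, max_iter: int = 2000,
) -> NullAlleleEstimate:
    """EM estimate of the null-allele frequency under HWE with blanks.

    The observed data per locus/population are apparent heterozygotes,
    apparent homozygotes (a mixture of true homozygotes and visible/null
    heterozygotes) and blanks (null homozygotes or technical failures with
    probability beta).  The E-step apportions homozygotes and blanks; the
    M-step re-estimates visible allele frequencies, r and beta.
    """
    l = table.loci.index(locus)
    rows = [
        row[l] for i, row in enumerate(table.calls)
        if table.population[i] == population
    ]
    calls = [c for c in rows if c is not None]
    n_blank = sum(c is None for c in rows)
    if len(calls) < 5:
        raise UndefinedStatistic("null-allele EM needs >= 5 genotypes")
    n_het: dict[tuple[int, int], int] = {}
    n_hom: dict[int, int] = {}
    for a, b in calls:
        if a == b:
            n_hom[a] = n_hom.get(a, 0) + 1
        else:
            key = (min(a, b), max(a, b))
            n_het[key] = n_het.get(key, 0) + 1
    alleles = sorted(set(n_hom) | {x for k in n_het for x in k})
    N = len(rows)

    # init: naive frequencies, small r and beta
    copies0 = {a: 0.0 for a in alleles}
    for (a, b), k in n_het.items():
        copies0[a] += k
        copies0[b] += k
    for a, k in n_hom.items():
        copies0[a] += 2 * k
    tot0 = sum(copies0.values())
    p = {a: v / tot0 for a, v in copies0.items()}
    r, beta = 0.05, 0.05
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        copies = {a: 0.0 for a in alleles}
        null_copies = 0.0
        for (a, b), k in n_het.items():
            copies[a] += k
            copies[b] += k
        for a, k in n_hom.items():
            w_null = 2.0 * r / (p[a] + 2.0 * r) if (p[a] + 2 * r) > 0 else 0.0
            copies[a] += k * (2.0 - w_null)
            null_copies += k * w_null
        blank_prob = beta + (1 - beta) * r * r
        w_nn = (1 - beta) * r * r / blank_prob if blank_prob > 0 else 0.0
        null_copies += n_blank * 2.0 * w_nn
        genotyped_equiv = len(calls) + n_blank * w_nn
        total = 2.0 * genotyped_equiv
        new_p = {a: v / total for a, v in copies.items()}
        new_r = null_copies / total
        new_beta = (n_blank * (1.0 - w_nn)) / N
        delta = max(
            abs(new_r - r), abs(new_beta - beta),
            max(abs(new_p[a] - p[a]) for a in alleles),
        )
        p, r, beta = new_p, new_r, new_beta
        if delta < tol:
            converged = True
            break
    return NullAlleleEstimate(r=r, beta=beta, freqs=p, converged=converged, iterations=it)


def null_allele_table(table: GenotypeTable) -> pd.DataFrame:
    """r-hat for every locus x population (index locus, columns populations)."""
    out = pd.DataFrame(index=table.loci, columns=table.populations, dtype=float)
    for locus in table.loci:
        for pop in table.populations:
            out.loc[locus, pop] = null_allele_em(table, locus, pop).r
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham theta and the ENA correction


def _wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) a, b, c for one allele over r populations.

    ``n`` individuals per population, ``p`` allele frequency, ``h`` observed
    frequency of heterozygotes carrying the allele.
    """
    r = len(n)
    nbar = n.mean()
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    pbar = np.sum(n * p) / (r * nbar)
    s2 = np.sum(n * (p - pbar) ** 2) / ((r - 1) * nbar)
    hbar = np.sum(n * h) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def _locus_freq_het(
    table: GenotypeTable, locus: str, pops: Sequence[str]
) -> Optional[tuple[np.ndarray, dict[int, np.ndarray], dict[int, np.ndarray]]]:
    """(n per pop, per-allele frequency vectors, per-allele het frequencies)."""
    per_pop = [(pop, _pop_locus_calls(table, locus, pop)) for pop in pops]
    if any(len(calls) < 2 for _, calls in per_pop):
        return None
    alleles = sorted({x for _, calls in per_pop for c in calls for x in c})
    n = np.array([len(calls) for _, calls in per_pop], dtype=float)
    freqs = {a: np.zeros(len(pops)) for a in alleles}
    hets = {a: np.zeros(len(pops)) for a in alleles}
    for k, (_, calls) in enumerate(per_pop):
        for a, b in calls:
            freqs[a][k] += 1
            freqs[b][k] += 1
            if a != b:
                hets[a][k] += 1
                hets[b][k] += 1
        for a in alleles:
            freqs[a][k] /= 2 * n[k]
            hets[a][k] /= n[k]
    return n, freqs, hets


def theta_components(
    table: GenotypeTable, pops: Sequence[str]
) -> tuple[float, float, float]:
    """Summed W&C components (a, b, c) over alleles and loci for ``pops``."""
    A = B = C = 0.0
    usable = 0
    for locus in table.loci:
        parsed = _locus_freq_het(table, locus, pops)
        if parsed is None:
            continue
        n, freqs, hets = parsed
        if len(freqs) < 2:
            continue  # monomorphic
        usable += 1
        for al in freqs:
            a, b, c = _wc_components(n, freqs[al], hets[al])
            A += a
            B += b
            C += c
    if usable == 0:
        raise UndefinedStatistic("no shared polymorphic loci")
    return A, B, C


def theta_fst(
    table: GenotypeTable,
    pair: tuple[str, str],
    n_perm: int = 0,
    seed: int = 0,
) -> tuple[float, Optional[float]]:
    """Multi-locus Weir & Cockerham theta for a population pair.

    With ``n_perm > 0``, significance comes from permuting individuals
    (whole multilocus genotypes) between the two populations.
    """
    sub = table.subset(pair)
    A, B, C = theta_components(sub, list(pair))
    denom = A + B + C
    theta = A / denom if denom != 0 else 0.0
    if n_perm <= 0:
        return theta, None
    rng = np.random.default_rng(seed)
    labels = np.array(sub.population)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(labels)
        perm = GenotypeTable(
            ids=list(sub.ids), population=list(labels),
            loci=list(sub.loci), calls=sub.calls,
        )
        try:
            A2, B2, C2 = theta_components(perm, list(pair))
        except UndefinedStatistic:
            continue
        d = A2 + B2 + C2
        t_star = A2 / d if d != 0 else 0.0
        if t_star >= theta - 1e-12:
            hits += 1
    return theta, (hits + 1) / (n_perm + 1)


def pairwise_theta(
    table: GenotypeTable, n_perm: int = 0, seed: int = 0
) -> MatrixTable:
    pops = table.populations
    K = len(pops)
    vals = np.zeros((K, K))
    pvals = np.full((K, K), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(K):
        for j in range(i + 1, K):
            t, p = theta_fst(
                table, (pops[i], pops[j]), n_perm=n_perm,
                seed=int(rng.integers(1, 2**31 - 1)),
            )
            vals[i, j] = vals[j, i] = t
            if p is not None:
                pvals[i, j] = pvals[j, i] = p
    return MatrixTable(labels=list(pops), values=vals,
                       pvalues=pvals if n_perm > 0 else None, symmetric=True)


def theta_fst_ena(
    table: GenotypeTable,
    null_estimates: pd.DataFrame,
    pair: tuple[str, str],
) -> float:
    """ENA-corrected theta: the null allele enters as an extra allelic state.

    A null allele is a segregating lineage that never amplifies: apparent
    heterozygotes carrying it look homozygous and null homozygotes look
    missing.  The visible allele frequencies observed among genotyped
    individuals estimate the true visible frequencies renormalized to the
    visible total, so the correction rescales them by (1 - r) and appends a
    null state of frequency r (never observed heterozygous); Weir &
    Cockerham components are then summed over the augmented allele set.
    With r = 0 everywhere this reproduces the uncorrected theta exactly.
    Missing estimates fall back to r = 0 with a warning.
    """
    import warnings

    A = B = C = 0.0
    usable = 0
    for locus in table.loci:
        parsed = _locus_freq_het(table, locus, pair)
        if parsed is None:
            continue
        n, freqs, hets = parsed
        if len(freqs) < 2:
            continue
        usable += 1
        rvec = np.zeros(len(pair))
        for k, pop in enumerate(pair):
            try:
                rvec[k] = float(null_estimates.loc[locus, pop])
            except (KeyError, TypeError):
                warnings.warn(
                    f"no null estimate for {locus}/{pop}; using r=0", stacklevel=2
                )
        for al in freqs:
            a, b, c = _wc_components(n, freqs[al] * (1.0 - rvec), hets[al])
            A += a
            B += b
            C += c
        if np.any(rvec > 0):
            a, b, c = _wc_components(n, rvec, np.zeros(len(pair)))
            A += a
            B += b
            C += c
    if usable == 0:
        raise UndefinedStatistic("no shared polymorphic loci")
    denom = A + B + C
    return A / denom if denom != 0 else 0.0


def pairwise_theta_ena(table: GenotypeTable, null_estimates: pd.DataFrame) -> MatrixTable:
    pops = table.populations
    K = len(pops)
    vals = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            vals[i, j] = vals[j, i] = theta_fst_ena(
                table, null_estimates, (pops[i], pops[j])
            )
    return MatrixTable(labels=list(pops), values=vals, symmetric=True)


# ---------------------------------------------------------------------------
# Bottleneck (heterozygosity excess) test


@dataclass
class BottleneckResult:
    loci: list[str]
    he_obs: list[float]
    heq_mean: list[float]
    heq_sd: list[float]
    standardized: list[float]
    p_excess: float


def _geom_param_from_variance(variance: float) -> float:
    """Success probability of the multi-step geometric with the given variance."""
    if variance <= 0:
        return 1.0
    return (-1.0 + math.sqrt(1.0 + 4.0 * variance)) / (2.0 * variance)


def _tpm_sample_he(
    n_copies: int, theta: float, p_smm: float, q_multi: float,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """One coalescent TPM sample: (unbiased He, allele count)."""
    branches = _coalescent_branches(n_copies, rng)
    vals = np.zeros(n_copies, dtype=int)
    for tips, length in branches:
        k = rng.poisson(theta / 2.0 * length)
        if k == 0:
            continue
        delta = 0
        for _ in range(k):
            step = 1 if rng.random() < p_smm else int(rng.geometric(q_multi))
            delta += step if rng.random() < 0.5 else -step
        if delta:
            idx = list(tips)
            vals[idx] += delta
    _, cnt = np.unique(vals, return_counts=True)
    p = cnt / n_copies
    he = n_copies / (n_copies - 1) * (1.0 - np.sum(p**2))
    return float(he), len(cnt)


def _calibrate_theta(
    n_copies: int, k_target: int, p_smm: float, q_multi: float,
    rng: np.random.Generator, pilot: int = 60,
) -> float:
    theta = max(k_target - 1, 0.5)  # IAM-flavoured starting point
    for _ in range(12):
        ks = [
            _tpm_sample_he(n_copies, theta, p_smm, q_multi, rng)[1]
            for _ in range(pilot)
        ]
        mean_k = np.mean(ks)
        if abs(mean_k - k_target) < 0.25:
            break
        theta *= (k_target / max(mean_k, 1.001)) ** 1.5
        theta = min(max(theta, 1e-3), 1e3)
    return theta


def bottleneck_test(
    table: GenotypeTable,
    population: str,
    p_smm: float = 0.8,
    variance: float = 20.0,
    n_iter: int = 10_000,
    seed: int = 0,
    min_keep: int = 100,
) -> BottleneckResult:
    """Heterozygosity-excess bottleneck test under the two-phase model.

    Per polymorphic locus, coalescent samples under the TPM (fraction
    ``p_smm`` single-step, multi-step geometric with the stated variance)
    are retained when they match the observed allele count and sample size,
    giving the mutation-drift equilibrium Heq distribution; the one-tailed
    Wilcoxon signed-rank across loci tests for He > Heq (excess after a
    bottleneck).  ``n_iter`` is the simulation budget per locus.
    """
    q_multi = _geom_param_from_variance(variance)
    rng = np.random.default_rng(seed)
    loci, he_obs, heq_mean, heq_sd, std = [], [], [], [], []
    for locus in table.loci:
        alleles = table.alleles(locus, population)
        if not alleles:
            continue
        uniq = len(set(alleles))
        if uniq < 2:
            continue
        n_copies = len(alleles)
        he = unbiased_he(alleles)
        theta = _calibrate_theta(n_copies, uniq, p_smm, q_multi, rng)
        kept = []
        for _ in range(n_iter):
            h, k = _tpm_sample_he(n_copies, theta, p_smm, q_multi, rng)
            if k == uniq:
                kept.append(h)
            if len(kept) >= min_keep:
                break
        if len(kept) < 10:
            continue
        kept = np.asarray(kept)
        loci.append(locus)
        he_obs.append(he)
        heq_mean.append(float(kept.mean()))
        sd = float(kept.std(ddof=1))
        heq_sd.append(sd)
        std.append((he - kept.mean()) / sd if sd > 0 else 0.0)
    if len(loci) < 2:
        raise UndefinedStatistic("bottleneck test needs >= 2 usable polymorphic loci")
    diffs = np.array(he_obs) - np.array(heq_mean)
    mode = "exact" if len(diffs) <= 25 else "approx"
    p = float(stats.wilcoxon(diffs, alternative="greater", mode=mode).pvalue)
    return BottleneckResult(
        loci=loci, he_obs=he_obs, heq_mean=heq_mean, heq_sd=heq_sd,
        standardized=std, p_excess=p,
    )
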