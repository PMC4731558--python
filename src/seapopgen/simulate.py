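"""Synthetic data generators for every stage of the pipeline.

Three families of fixtures are produced, each with the statistical structure
the downstream analyses assume:

* coalescent mtDNA sequence alignments under a Tamura-Nei (TN93) mutation
  model with gamma rate heterogeneity across sites, on genealogies simulated
  by msprime under rooted split histories (no migration);
* diploid microsatellite genotypes under the generalized stepwise mutation
  model (GSM: geometrically distributed step sizes), optionally degraded by
  per-locus/per-population null alleles;
* divergence-free, time-varying gyre velocity fields over a coastline mask
  with habitat localities, for the larval-dispersal tracker.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` substreams, so identical seeds give identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import msprime
import numpy as np
import pandas as pd

from .dispersal import Cell, DispersalSpecError, VelocityField
from .io import (
    GenotypeTable,
    LocalityTable,
    MatrixTable,
    SequenceAlignment,
    write_fasta_alignment,
    write_genepop,
    write_locality_csv,
    write_matrix_csv,
)
from .scenarios import Scenario, single_population

BASES = "ACGT"


class ParameterError(ValueError):
    pass


@dataclass
class SimParams:
    """Parameters of the coalescent simulators.

    Defaults sit in the middle of the uniform priors used for scenario
    inference: Ne 1e4-1e5 (sequences) / 1e4-2e5 (microsatellites), per-site
    sequence mutation rate 1e-8-1e-6, microsatellite rate 1e-4-1e-3 per
    generation.  ``p_gsm`` is the success probability of the geometric step
    distribution (1.0 = strict single-step SMM); 0.8 keeps 80% of mutations
    single-step, consistent with the two-phase-model range used for the
    bottleneck tests.  ``gamma_shape`` controls among-site rate variation
    of the sequence model.
    """

    ne: dict[str, float] | float = 50_000.0
    mu_seq: float = 1e-7
    mu_ms: float = 5e-4
    base_freqs: tuple[float, float, float, float] = (0.25, 0.16, 0.17, 0.42)
    kappa1: float = 10.0  # A<->G transition/transversion rate ratio
    kappa2: float = 10.0  # C<->T
    gamma_shape: float = 0.5
    p_gsm: float = 0.8
    ancestral_repeat: int = 30
    repeat_bound: int = 40  # reflecting bounds at ancestral +/- this many steps

    def __post_init__(self) -> None:
        if isinstance(self.ne, dict):
            if any(v <= 0 for v in self.ne.values()):
                raise ParameterError("Ne must be positive")
        elif self.ne <= 0:
            raise ParameterError("Ne must be positive")
        if self.mu_seq < 0 or self.mu_ms < 0:
            raise ParameterError("mutation rates must be nonnegative")
        if not 0 < self.p_gsm <= 1:
            raise ParameterError("p_gsm must be in (0, 1]")
        if abs(sum(self.base_freqs) - 1) > 1e-9 or min(self.base_freqs) <= 0:
            raise ParameterError("base frequencies must be positive and sum to 1")
        if self.gamma_shape <= 0:
            raise ParameterError("gamma shape must be positive")

    def ne_of(self, pop: str) -> float:
        return self.ne[pop] if isinstance(self.ne, dict) else float(self.ne)


# ---------------------------------------------------------------------------
# TN93 substitution machinery


def tn93_rate_matrix(
    freqs: tuple[float, float, float, float], kappa1: float, kappa2: float
) -> np.ndarray:
    """TN93 instantaneous rate matrix (states A,C,G,T), mean rate scaled to 1."""
    pi = np.asarray(freqs, dtype=float)
    Q = np.zeros((4, 4))
    for a in range(4):
        for b in range(4):
            if a == b:
                continue
            rate = pi[b]
            if {a, b} == {0, 2}:  # A<->G purine transition
                rate *= kappa1
            elif {a, b} == {1, 3}:  # C<->T pyrimidine transition
                rate *= kappa2
            Q[a, b] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.sum(pi * np.diag(Q))
    return Q / mean_rate


def _tn93_spectral(Q: np.ndarray, freqs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of a reversible Q via the symmetrizing similarity."""
    pi = np.asarray(freqs)
    d = np.sqrt(pi)
    B = (Q * d[:, None]) / d[None, :]
    lam, V = np.linalg.eigh((B + B.T) / 2)
    U = V / d[:, None]
    Uinv = V.T * d[None, :]
    return lam, U, Uinv


def _evolve_states(
    tree, root_states: np.ndarray, tau_per_site_per_gen: np.ndarray,
    lam: np.ndarray, coeff: np.ndarray, rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Sample site states down a tskit tree under exp(Q * tau) transitions."""
    L = len(root_states)
    states: dict[int, np.ndarray] = {tree.root: root_states}
    for u in tree.nodes(order="preorder"):
        if u == tree.root:
            continue
        parent = states[tree.parent(u)]
        tau = tau_per_site_per_gen * tree.branch_length(u)
        E = np.exp(np.outer(tau, lam))  # (L, 4)
        probs = np.einsum("lk,lkb->lb", E, coeff[parent])
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum(axis=1, keepdims=True)
        draws = rng.random(L)
        states[u] = (probs.cumsum(axis=1) < draws[:, None]).sum(axis=1).astype(np.int8)
    return states


def _msprime_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_sequence_matrix(
    scenario: Scenario,
    params: SimParams,
    sample_sizes: dict[str, int],
    L: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Core coalescent + TN93 simulation returning encoded states.

    Returns (states (n, L) with 0..3 = A,C,G,T; population index per
    sample; population names).
    """
    if L <= 0:
        raise ParameterError("L must be positive")
    for pop, n in sample_sizes.items():
        if n > 2 * params.ne_of(pop):
            raise ParameterError(f"sample size {n} for {pop} exceeds 2*Ne")
    ne = {p: params.ne_of(p) for p in scenario.populations}
    pi = np.asarray(params.base_freqs)
    pop_names = list(scenario.populations)

    if params.mu_seq == 0:
        root = rng.choice(4, size=L, p=pi).astype(np.int8)
        idx, mats = [], []
        for k, pop in enumerate(pop_names):
            n = sample_sizes.get(pop, 0)
            idx.extend([k] * n)
            mats.extend([root] * n)
        return np.vstack(mats), np.asarray(idx), pop_names

    ts = msprime.sim_ancestry(
        samples={p: n for p, n in sample_sizes.items() if n > 0},
        demography=scenario.demography(ne),
        ploidy=1,
        random_seed=_msprime_seed(rng),
    )
    tree = ts.first()
    site_rates = rng.gamma(params.gamma_shape, 1.0 / params.gamma_shape, size=L)
    tau = params.mu_seq * site_rates
    Q = tn93_rate_matrix(params.base_freqs, params.kappa1, params.kappa2)
    lam, U, Uinv = _tn93_spectral(Q, pi)
    coeff = np.einsum("ak,kb->akb", U, Uinv)
    root_states = rng.choice(4, size=L, p=pi).astype(np.int8)
    states = _evolve_states(tree, root_states, tau, lam, coeff, rng)
    samples = list(ts.samples())
    mat = np.vstack([states[u] for u in samples])
    pop_idx = np.array([ts.node(u).population for u in samples])
    return mat, pop_idx, pop_names


def simulate_sequences(
    scenario: Scenario,
    params: SimParams,
    sample_sizes: dict[str, int],
    L: int,
    seed: int | np.random.Generator = 0,
) -> SequenceAlignment:
    """Coalescent mtDNA alignment under a scenario, TN93 + gamma mutations.

    The locus is non-recombining; ``ne_of(pop)`` is used directly as the
    haploid effective size of the sequence genealogy.  Per-site rate
    multipliers are drawn once per simulation from Gamma(shape, 1/shape).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mat, pop_idx, pop_names = simulate_sequence_matrix(
        scenario, params, sample_sizes, L, rng
    )
    ids, pops, seqs = [], [], []
    counters: dict[str, int] = {}
    for row, k in zip(mat, pop_idx):
        pop = pop_names[k]
        i = counters.get(pop, 0)
        counters[pop] = i + 1
        ids.append(f"{pop}_{i}")
        pops.append(pop)
        seqs.append(_BASE_BYTES[row.astype(np.intp)].tobytes().decode())
    return SequenceAlignment(ids=ids, population=pops, sites=seqs)


# ---------------------------------------------------------------------------
# Microsatellites


def _reflect(val: int, lo: int, hi: int) -> int:
    while val < lo or val > hi:
        if val < lo:
            val = 2 * lo - val
        else:
            val = 2 * hi - val
    return val


def simulate_microsatellites(
    scenario: Scenario,
    params: SimParams,
    sample_sizes: dict[str, int],
    n_loci: int,
    seed: int | np.random.Generator = 0,
) -> GenotypeTable:
    """Diploid GSM microsatellite genotypes under a scenario.

    Each locus gets an independent genealogy (2n gene copies per population);
    allele sizes mutate by +/- k repeat units with k ~ Geometric(p_gsm),
    reflecting at ancestral +/- ``repeat_bound`` to keep sizes positive and
    bounded.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for pop, n in sample_sizes.items():
        if n > 2 * params.ne_of(pop):
            raise ParameterError(f"sample size {n} for {pop} exceeds 2*Ne")
    ne = {p: params.ne_of(p) for p in scenario.populations}
    lo = max(2, params.ancestral_repeat - params.repeat_bound)
    hi = params.ancestral_repeat + params.repeat_bound
    pop_names = list(scenario.populations)

    per_locus: list[dict[str, list[tuple[int, int]]]] = []
    for _ in range(n_loci):
        ts = msprime.sim_ancestry(
            samples={p: n for p, n in sample_sizes.items() if n > 0},
            demography=scenario.demography(ne),
            ploidy=2,
            random_seed=_msprime_seed(rng),
        )
        tree = ts.first()
        sizes: dict[int, int] = {tree.root: params.ancestral_repeat}
        if params.mu_ms == 0:
            node_sizes = {u: params.ancestral_repeat for u in ts.samples()}
        else:
            for u in tree.nodes(order="preorder"):
                if u == tree.root:
                    continue
                val = sizes[tree.parent(u)]
                n_mut = rng.poisson(params.mu_ms * tree.branch_length(u))
                for _m in range(n_mut):
                    step = int(rng.geometric(params.p_gsm))
                    if rng.random() < 0.5:
                        step = -step
                    val = _reflect(val + step, lo, hi)
                sizes[u] = val
            node_sizes = {u: sizes[u] for u in ts.samples()}
        calls: dict[str, list[tuple[int, int]]] = {p: [] for p in pop_names}
        for ind in ts.individuals():
            a, b = (node_sizes[n] for n in ind.nodes)
            pop = pop_names[ts.node(ind.nodes[0]).population]
            calls[pop].append((min(a, b), max(a, b)))
        per_locus.append(calls)

    ids, pops, rows = [], [], []
    for pop in pop_names:
        for k in range(sample_sizes.get(pop, 0)):
            ids.append(f"{pop}_{k}")
            pops.append(pop)
            rows.append([per_locus[l][pop][k] for l in range(n_loci)])
    return GenotypeTable(
        ids=ids, population=pops,
        loci=[f"L{l+1}" for l in range(n_loci)], calls=rows,
    )


def apply_null_alleles(
    genotypes: GenotypeTable,
    r_table: float | dict | pd.DataFrame,
    seed: int | np.random.Generator = 0,
) -> GenotypeTable:
    """Mask gene copies as null alleles with per-locus/population rate r.

    Each gene copy independently fails to amplify with probability r; a
    genotype with one null appears homozygous for its visible allele, two
    nulls appear missing.  ``r_table`` may be a scalar, ``{locus: r}``, or a
    DataFrame indexed by locus with one column per population.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def rate(locus: str, pop: str) -> float:
        if isinstance(r_table, pd.DataFrame):
            r = float(r_table.loc[locus, pop])
        elif isinstance(r_table, dict):
            v = r_table[locus]
            r = float(v[pop]) if isinstance(v, dict) else float(v)
        else:
            r = float(r_table)
        if not 0 <= r < 1:
            raise ParameterError(f"null rate {r} outside [0, 1) for {locus}/{pop}")
        return r

    new_calls = []
    for i, row in enumerate(genotypes.calls):
        pop = genotypes.population[i]
        out_row: list[Optional[tuple[int, int]]] = []
        for l, call in enumerate(row):
            if call is None:
                out_row.append(None)
                continue
            r = rate(genotypes.loci[l], pop)
            null_a = rng.random() < r
            null_b = rng.random() < r
            a, b = call
            if null_a and null_b:
                out_row.append(None)
            elif null_a:
                out_row.append((b, b))
            elif null_b:
                out_row.append((a, a))
            else:
                out_row.append(call)
        new_calls.append(out_row)
    return GenotypeTable(
        ids=list(genotypes.ids), population=list(genotypes.population),
        loci=list(genotypes.loci), calls=new_calls,
    )


def segregating_nulls(
    genotypes: GenotypeTable, target_frequency: float = 0.4, seed: int = 0
) -> tuple[GenotypeTable, dict[str, set[int]]]:
    """Turn existing allele lineages into heritable null alleles.

    Per locus, allele sizes are accumulated (largest first) until their
    pooled frequency reaches ``target_frequency``; every copy of those
    alleles becomes a null: heterozygotes appear homozygous for their
    visible allele and null homozygotes become missing.  This is the
    primer-site-mutation mechanism behind real null alleles (a lineage that
    drifts per population), in contrast to ``apply_null_alleles`` which
    models per-copy amplification failure.  Returns the masked table and
    the chosen null allele sets.
    """
    chosen: dict[str, set[int]] = {}
    for l, locus in enumerate(genotypes.loci):
        alleles = genotypes.alleles(locus)
        vals, counts = np.unique(alleles, return_counts=True)
        order = np.argsort(-vals)  # deterministic: largest sizes first
        total = counts.sum()
        cum = 0
        nulls: set[int] = set()
        for k in order:
            if cum / total >= target_frequency:
                break
            nulls.add(int(vals[k]))
            cum += counts[k]
        # never null the whole locus
        if len(nulls) == len(vals):
            nulls.discard(int(vals[order[-1]]))
        chosen[locus] = nulls
    new_calls = []
    for row in genotypes.calls:
        out_row: list[Optional[tuple[int, int]]] = []
        for l, call in enumerate(row):
            if call is None:
                out_row.append(None)
                continue
            a, b = call
            nulls = chosen[genotypes.loci[l]]
            na, nb = a in nulls, b in nulls
            if na and nb:
                out_row.append(None)
            elif na:
                out_row.append((b, b))
            elif nb:
                out_row.append((a, a))
            else:
                out_row.append(call)
        new_calls.append(out_row)
    masked = GenotypeTable(
        ids=list(genotypes.ids), population=list(genotypes.population),
        loci=list(genotypes.loci), calls=new_calls,
    )
    return masked, chosen


# ---------------------------------------------------------------------------
# Velocity fields


@dataclass
class FlowFieldSpec:
    """Specification of a synthetic gyre flow field over a coastal grid.

    The field derives from a discrete stream function (oscillating double
    gyre plus smooth seeded noise), so its centred-difference divergence
    vanishes at interior nodes.  ``amplitude`` is the peak current speed in
    m/s.  Land occupies ``mask`` (default: a western coastline strip);
    habitat localities are sets of water cells, 10 per locality by default.
    """

    nx: int = 40
    ny: int = 60
    spacing_km: float = 3.7
    time_step_hours: float = 3.0
    duration_days: float = 40.0
    amplitude: float = 0.3
    gyre_period_days: float = 20.0
    noise_fraction: float = 0.3
    n_noise_modes: int = 6
    coast_cols: int = 3
    habitat_depth_cutoff: float = 100.0
    mask: Optional[np.ndarray] = None
    depth: Optional[np.ndarray] = None
    localities: dict[str, list[Cell]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spacing_km <= 0 or self.time_step_hours <= 0:
            raise DispersalSpecError("spacing and time step must be positive")
        if self.mask is None:
            m = np.zeros((self.ny, self.nx), dtype=bool)
            m[:, : self.coast_cols] = True
            self.mask = m
        if self.depth is None:
            # shelf deepening offshore; the far-offshore basin exceeds the
            # habitat cutoff so locality validation is exercised
            ix = np.arange(self.nx, dtype=float)
            prof = 10.0 + 150.0 * ((ix - self.coast_cols) / max(self.nx - self.coast_cols, 1)) ** 2
            self.depth = np.tile(np.clip(prof, 5.0, None), (self.ny, 1))
            self.depth[self.mask] = 0.0
        for name, cells in self.localities.items():
            for iy, ix in cells:
                if self.mask[iy, ix]:
                    raise DispersalSpecError(f"habitat cell {(iy, ix)} of {name} is on land")
                if self.depth[iy, ix] > self.habitat_depth_cutoff:
                    raise DispersalSpecError(
                        f"habitat cell {(iy, ix)} of {name} deeper than cutoff"
                    )


def make_velocity_field(spec: FlowFieldSpec, seed: int) -> VelocityField:
    """Build the divergence-free gyre field described by ``spec``."""
    rng = np.random.default_rng(seed)
    ny, nx = spec.ny, spec.nx
    dx = dy = spec.spacing_km
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    nt = int(round(spec.duration_days * 24.0 / spec.time_step_hours)) + 1
    times = np.arange(nt) * spec.time_step_hours

    X = (np.arange(nx) + 0.5) / nx
    Y = (np.arange(ny) + 0.5) / ny
    XX, YY = np.meshgrid(X, Y)

    omega = 2 * np.pi / (spec.gyre_period_days * 24.0)
    eps = 0.25
    # half of the eddy modes are steady: persistent recirculations act as
    # dispersal barriers/conduits decoupled from along-coast separation
    modes = [
        (
            rng.uniform(0.5, 1.0),
            rng.integers(1, 4), rng.integers(1, 4),
            rng.uniform(0, 2 * np.pi),
            0.0 if k < spec.n_noise_modes // 2 else rng.uniform(0.3, 1.5) * omega,
        )
        for k in range(spec.n_noise_modes)
    ]

    psi = np.empty((nt, ny, nx))
    for k, t in enumerate(times):
        a = eps * np.sin(omega * t)
        f = a * XX**2 + (1 - 2 * a) * XX
        # the gyre circulation reverses over its period, so along-coast
        # transport alternates direction and exchange is two-way
        base = np.cos(omega * t) * np.sin(np.pi * f) * np.sin(np.pi * YY)
        noise = np.zeros_like(base)
        for c, kx, ky, phi, om in modes:
            noise += c * np.sin(2 * np.pi * (kx * XX + ky * YY) + phi + om * t)
        if spec.n_noise_modes:
            noise /= spec.n_noise_modes
        psi[k] = base + spec.noise_fraction * noise

    # stream-function velocities by centred differences (km grid, m/s out)
    u = np.zeros_like(psi)
    v = np.zeros_like(psi)
    u[:, 1:-1, :] = -(psi[:, 2:, :] - psi[:, :-2, :]) / (2 * dy)
    v[:, :, 1:-1] = (psi[:, :, 2:] - psi[:, :, :-2]) / (2 * dx)
    if spec.amplitude == 0:
        u[:] = 0.0
        v[:] = 0.0
    else:
        speed = np.sqrt(u**2 + v**2).max()
        if speed > 0:
            scale = spec.amplitude / speed
            u *= scale
            v *= scale
    u[:, spec.mask] = 0.0
    v[:, spec.mask] = 0.0
    return VelocityField(
        x=x, y=y, times=times, u=u, v=v, mask=spec.mask.copy(), depth=spec.depth.copy()
    )


def default_localities(spec: FlowFieldSpec, names: list[str]) -> dict[str, list[Cell]]:
    """Place one 10-cell habitat patch per locality hugging the coastline.

    Patches are 5 cells along-shore by 2 across-shore, the shape that best
    intercepts larvae drifting in the coastal boundary flow.
    """
    ny = spec.ny
    n = len(names)
    centers = np.linspace(5, ny - 6, n).astype(int)
    out: dict[str, list[Cell]] = {}
    col0 = spec.coast_cols
    for name, cy in zip(names, centers):
        out[name] = [(int(cy + r), col0 + c) for r in range(-2, 3) for c in range(2)]
    return out


# ---------------------------------------------------------------------------
# Reference bundle


@dataclass
class ReferenceConfig:
    """Study-condition defaults for the synthetic Baltic-like reference set."""

    localities: tuple[str, ...] = ("SA", "KL", "TO", "GD", "ES", "OR", "UM")
    groups: dict[str, str] = field(default_factory=lambda: {
        "SA": "Baltic-S", "KL": "Baltic-S", "TO": "Baltic-S", "GD": "Baltic-S",
        "ES": "Baltic-S", "OR": "Baltic-N", "UM": "Baltic-N",
    })
    n_per_pop: int = 30
    seq_length: int = 694
    n_loci: int = 4
    null_rates: tuple[float, ...] = (0.39, 0.0, 0.23, 0.48)
    split_time: float = 2000.0
    params: SimParams = field(default_factory=SimParams)
    flow: FlowFieldSpec = field(default_factory=lambda: FlowFieldSpec(duration_days=35.0))


@dataclass
class ReferenceBundle:
    alignment: SequenceAlignment
    genotypes: GenotypeTable
    localities: LocalityTable
    shipping: MatrixTable
    field: VelocityField
    habitat: dict[str, list[Cell]]
    paths: dict[str, Path]


def chain_scenario(localities: list[str], split_time: float) -> Scenario:
    """Stepping colonization along the coast: each locality splits from the
    previous one at evenly spaced times (oldest split first)."""
    n = len(localities)
    events = [
        (split_time * (n - i) / n, localities[i], localities[i - 1])
        for i in range(1, n)
    ]
    return Scenario(name="coastal-chain", populations=list(localities), events=events)


def make_reference_dataset(
    out_dir: str | Path, seed: int, config: ReferenceConfig | None = None
) -> ReferenceBundle:
    """Write a complete synthetic Baltic-like dataset reproducibly.

    Produces an aligned FASTA, a GENEPOP file with null alleles applied, a
    locality CSV with habitat cells, a shipping-distance CSV and a velocity
    field, all derived from one seed.
    """
    cfg = config or ReferenceConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]

    locs = list(cfg.localities)
    scen = chain_scenario(locs, cfg.split_time)
    sizes = {p: cfg.n_per_pop for p in locs}

    aln = simulate_sequences(scen, cfg.params, sizes, cfg.seq_length, rngs[0])
    geno = simulate_microsatellites(scen, cfg.params, sizes, cfg.n_loci, rngs[1])
    r_table = {f"L{l+1}": cfg.null_rates[l] for l in range(cfg.n_loci)}
    geno = apply_null_alleles(geno, r_table, rngs[1])

    flow = replace(cfg.flow)
    habitat = default_localities(flow, locs)
    flow.localities = habitat
    vfield = make_velocity_field(flow, int(rngs[2].integers(1, 2**31 - 1)))

    # locality coordinates: along-coast placement; shipping distance =
    # along-coast separation plus a port detour constant
    centers = {name: np.mean([c[0] for c in cells]) for name, cells in habitat.items()}
    lat0 = 54.0
    lats = [lat0 + centers[n] * flow.spacing_km / 111.0 for n in locs]
    lons = [12.0 + 0.2 * i for i in range(len(locs))]
    loc_table = LocalityTable(
        names=locs, longitude=lons, latitude=lats,
        group=[cfg.groups[n] for n in locs], habitat_cells=[habitat[n] for n in locs],
    )
    D = np.zeros((len(locs), len(locs)))
    for i in range(len(locs)):
        for j in range(len(locs)):
            if i != j:
                D[i, j] = abs(centers[locs[i]] - centers[locs[j]]) * flow.spacing_km + 25.0
    shipping = MatrixTable(labels=locs, values=D, symmetric=True)

    paths = {
        "fasta": out / "sequences.fasta",
        "genepop": out / "genotypes.gen",
        "localities": out / "localities.csv",
        "shipping": out / "shipping_km.csv",
        "field": out / "velocity.nc",
    }
    write_fasta_alignment(aln, paths["fasta"])
    write_genepop(geno, paths["genepop"])
    write_locality_csv(loc_table, paths["localities"])
    write_matrix_csv(shipping, paths["shipping"])
    vfield.save(paths["field"])
    return ReferenceBundle(
        alignment=aln, genotypes=geno, localities=loc_table,
        shipping=shipping, field=vfield, habitat=habitat, paths=paths,
    )
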