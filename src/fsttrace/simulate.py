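"""Forward-time stepping-stone colonization simulator.

A single ancestral deme (deme 1) colonizes a lattice of 24 initially
vacant habitats under one of five range-expansion scenarios: one-, two-
and three-directional chains, a 5x5 grid colonized from a corner
("edge", three directions under 8-neighborhoods) and a 5x5 grid
colonized from the center (eight directions).  Once every
``founding_interval`` generations, 1% of Ne gene copies found each
vacant deme adjacent to an occupied one; a founded deme grows to the
common deme size Ne after one generation and thereafter exchanges
``m`` (1%) of its gene copies with each occupied neighbor every
generation.

Loci are unlinked biallelic SNPs.  The ancestral deme starts with
``n_ancestral_loci`` SNPs whose frequencies are drawn from the neutral
equilibrium density f(q) ∝ 1/(q(1-q)), discretized on the 1/Ne grid.
Each occupied deme also gains ``new_snps_per_deme_per_gen`` newly
derived SNPs per generation at frequency ``new_snp_freq`` (new
mutations that survived their initial phase).  Allele frequencies
drift by binomial sampling of Ne gene copies per generation.

At the end of the run, SNPs still polymorphic (pooled frequency over
all demes strictly inside (0, 1)) are sampled as the "observed" panel
and diploid genotypes are drawn for ``individuals_per_pop`` individuals
per deme, yielding a Genepop-exportable genotype table plus the ground
truth (founding schedule and per-locus origin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genepop import GenotypeTable

__all__ = [
    "SCENARIOS",
    "ColonizationConfig",
    "DemeLattice",
    "SimTruth",
    "scenario_adjacency",
    "draw_ancestral_frequencies",
    "step_generation",
    "run_simulation",
    "reduced_scale_config",
]

SCENARIOS = (
    "one_directional",
    "two_directional",
    "three_directional",
    "grid_edge",
    "grid_center",
)
_GRID_SCENARIOS = ("grid_edge", "grid_center")


@dataclass
class ColonizationConfig:
    """Scenario layout and demographic rates.

    ``ne`` counts gene copies per occupied deme (twice the diploid
    census); drift draws Binomial(ne, q).  Defaults are the study
    conditions: Ne = 10^4, 1% per-neighbor exchange each generation,
    founding events of 1% of Ne every 10 generations, 260 generations
    for chain scenarios and 100 for grids, a 100,000-SNP ancestral pool
    with 10 new SNPs per deme per generation at initial frequency 0.01,
    and an observed panel of 10,000 ancestral + 500 derived SNPs typed
    on 50 diploid individuals per deme.
    """

    scenario: str = "one_directional"
    n_demes: int = 25
    ne: int = 10_000
    ne_ancestral: Optional[int] = None
    m: float = 0.01
    founding_fraction: float = 0.01
    founding_interval: int = 10
    generations: Optional[int] = None
    n_ancestral_loci: int = 100_000
    new_snps_per_deme_per_gen: int = 10
    new_snp_freq: float = 0.01
    sample_ancestral: int = 10_000
    sample_derived: int = 500
    individuals_per_pop: int = 50
    seed: int = 0
    stochastic_migration: bool = False
    founder_sized_first_generation: bool = False
    grid_origin: Optional[tuple[int, int]] = None
    prune_interval: int = 10

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.generations is None:
            self.generations = 100 if self.scenario in _GRID_SCENARIOS else 260
        if self.ne_ancestral is None:
            self.ne_ancestral = self.ne
        for name in ("m", "founding_fraction", "new_snp_freq"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.ne < 2:
            raise ValueError("ne must be at least 2 gene copies")


def scenario_adjacency(scenario: str, n_demes: int = 25,
                       grid_origin: Optional[tuple[int, int]] = None):
    """Neighbor graph and plotting coordinates for a scenario.

    Returns ``(adjacency, positions)`` where ``adjacency`` is a boolean
    (n_demes, n_demes) matrix and ``positions`` an (n_demes, 2) array of
    schematic x/y coordinates.  Deme numbering is 0-based internally;
    deme 0 is ancestral.  Both grids use 8-neighborhoods; the ancestral
    cell defaults to the middle of the top edge for ``grid_edge``
    (expansion in three directions: along the edge both ways and
    inward) and to the center for ``grid_center`` (eight directions);
    ``grid_origin`` overrides it.
    """
    if n_demes != 25:
        raise ValueError("the five scenarios are defined on 25 demes")
    adj = np.zeros((25, 25), dtype=bool)
    pos = np.zeros((25, 2))

    def link(a, b):
        adj[a, b] = adj[b, a] = True

    def chain(seq):
        for a, b in zip(seq, seq[1:]):
            link(a, b)

    if scenario == "one_directional":
        chain(range(25))
        pos[:, 0] = np.arange(25)
    elif scenario == "two_directional":
        # chain 1..9, splitting at deme 9 into 10..16 and 17..25 (1-based)
        chain(range(9))
        chain([8] + list(range(9, 16)))
        chain([8] + list(range(16, 25)))
        pos[:9] = np.column_stack([np.arange(9), np.zeros(9)])
        pos[9:16] = np.column_stack([8 + np.arange(1, 8), np.arange(1, 8)])
        pos[16:25] = np.column_stack([8 + np.arange(1, 10), -np.arange(1, 10)])
    elif scenario == "three_directional":
        # branches 2..8, 9..16, 17..25 all starting at deme 1 (1-based)
        chain(range(8))
        chain([0] + list(range(8, 16)))
        chain([0] + list(range(16, 25)))
        pos[:8] = np.column_stack([np.arange(8), np.zeros(8)])
        pos[8:16] = np.column_stack([np.arange(1, 9), np.arange(1, 9)])
        pos[16:25] = np.column_stack([np.arange(1, 10), -np.arange(1, 10)])
    elif scenario in _GRID_SCENARIOS:
        origin = (2, 2) if scenario == "grid_center" else (0, 2)
        if grid_origin is not None:
            origin = tuple(grid_origin)
        cells = [origin] + [
            (r, c) for r in range(5) for c in range(5) if (r, c) != origin
        ]
        index = {cell: i for i, cell in enumerate(cells)}
        for (r, c), i in index.items():
            pos[i] = (c, -r)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    nb = (r + dr, c + dc)
                    if nb in index:
                        link(i, index[nb])
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return adj, pos


def draw_ancestral_frequencies(n_loci: int, ne: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Sample initial SNP frequencies from f(q) ∝ 1/(q(1-q)).

    The density is improper on (0, 1); it is discretized on the grid
    {1/Ne, ..., (Ne-1)/Ne} — the resolution of Ne gene copies — which
    makes it proper while concentrating mass near the boundaries, as the
    neutral equilibrium predicts.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be positive")
    if ne < 2:
        raise ValueError("ne must be at least 2")
    grid = np.arange(1, ne) / ne
    w = 1.0 / (grid * (1.0 - grid))
    w /= w.sum()
    return rng.choice(grid, size=n_loci, p=w)


@dataclass
class DemeLattice:
    """Evolving state: occupancy, per-locus frequencies, locus origins.

    ``ne`` is each deme's long-run size; ``ne_now`` its current size,
    which equals the founder count for the first generation after a
    founding event and ``ne`` afterwards ("increased to the same size
    as the ancestral population after one generation").
    """

    adjacency: np.ndarray
    occupied: np.ndarray
    founded_gen: np.ndarray
    ne: np.ndarray
    ne_now: np.ndarray
    q: np.ndarray                 # (n_loci_live, n_demes); vacant columns 0
    birth_deme: np.ndarray        # -1 for ancestral loci
    birth_gen: np.ndarray         # -1 for ancestral loci

    @property
    def n_demes(self) -> int:
        return self.adjacency.shape[0]

    def prune_monomorphic(self) -> None:
        """Drop loci fixed (all 0 or all 1) across every occupied deme.

        Such loci can never become polymorphic again: vacant demes are
        founded from occupied ones and migration only mixes occupied
        frequencies.
        """
        occ = self.occupied
        qo = self.q[:, occ]
        keep = ~((qo == 0.0).all(axis=1) | (qo == 1.0).all(axis=1))
        if not keep.all():
            self.q = self.q[keep]
            self.birth_deme = self.birth_deme[keep]
            self.birth_gen = self.birth_gen[keep]


@dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    scenario: str
    founded_gen: np.ndarray
    positions: np.ndarray
    adjacency: np.ndarray
    loci: pd.DataFrame  # locus, origin, birth_deme, birth_gen

    def founding_order(self) -> np.ndarray:
        """Deme indices sorted by founding generation (ties by index)."""
        return np.lexsort((np.arange(len(self.founded_gen)), self.founded_gen))

    def deme_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "deme": np.arange(1, len(self.founded_gen) + 1),
            "founding_generation": self.founded_gen,
            "x": self.positions[:, 0],
            "y": self.positions[:, 1],
        })


def _init_lattice(cfg: ColonizationConfig, rng: np.random.Generator) -> DemeLattice:
    adj, _ = scenario_adjacency(cfg.scenario, cfg.n_demes, cfg.grid_origin)
    D = cfg.n_demes
    occupied = np.zeros(D, dtype=bool)
    occupied[0] = True
    founded_gen = np.full(D, -1, dtype=np.int64)
    founded_gen[0] = 0
    ne = np.full(D, cfg.ne, dtype=np.int64)
    ne[0] = cfg.ne_ancestral
    q = np.zeros((cfg.n_ancestral_loci, D))
    q[:, 0] = draw_ancestral_frequencies(cfg.n_ancestral_loci, cfg.ne_ancestral, rng)
    birth_deme = np.full(cfg.n_ancestral_loci, -1, dtype=np.int64)
    birth_gen = np.full(cfg.n_ancestral_loci, -1, dtype=np.int64)
    return DemeLattice(adj, occupied, founded_gen, ne, ne.copy(), q,
                       birth_deme, birth_gen)


def step_generation(lattice: DemeLattice, cfg: ColonizationConfig,
                    rng: np.random.Generator, gen: int) -> DemeLattice:
    """Advance the lattice one generation (in place; also returned).

    Event order: (1) migration mixing among occupied neighbors,
    (2) binomial drift, (3) new-SNP injection, (4) founding of vacant
    neighbors every ``founding_interval`` generations.
    """
    occ = np.nonzero(lattice.occupied)[0]
    m = cfg.m
    q_occ = lattice.q[:, occ]

    # 1. migration: q_i <- (1 - k_i m) q_i + m sum_{j in nbrs} q_j
    if len(occ) > 1 and m > 0.0:
        a = lattice.adjacency[np.ix_(occ, occ)].astype(float)
        k = a.sum(axis=1)
        if cfg.stochastic_migration:
            # migrant pools drawn per directed edge: deme j sends a
            # binomial sample of round(m * Ne_j) gene copies to each
            # occupied neighbor i
            ne_mig = lattice.ne[occ].astype(float)
            copies = q_occ * ne_mig
            src, dst = np.nonzero(a)
            n_mig = np.round(m * ne_mig[src]).astype(np.int64)
            sent = rng.binomial(n_mig[None, :], q_occ[:, src]).astype(float)
            delta = np.zeros_like(copies)
            np.add.at(delta.T, dst, sent.T)
            np.subtract.at(delta.T, src, sent.T)
            q_occ = np.clip((copies + delta) / ne_mig, 0.0, 1.0)
        else:
            mix = np.eye(len(occ)) * (1.0 - m * k) + m * a
            q_occ = q_occ @ mix.T

    # 2. drift: one binomial draw of the deme's current gene-copy count;
    # a deme founded last wave drifts once at founder size, then grows.
    # q = 0 and q = 1 are absorbing, so only segregating cells are drawn.
    ne_occ = lattice.ne_now[occ]
    seg = (q_occ > 0.0) & (q_occ < 1.0)
    ne_grid = np.broadcast_to(ne_occ[None, :], q_occ.shape)
    q_occ[seg] = rng.binomial(ne_grid[seg], q_occ[seg]) / ne_grid[seg]
    lattice.q[:, occ] = q_occ
    lattice.ne_now[occ] = lattice.ne[occ]

    # 3. new derived SNPs in every occupied deme
    if cfg.new_snps_per_deme_per_gen > 0:
        n_new = cfg.new_snps_per_deme_per_gen * len(occ)
        q_new = np.zeros((n_new, lattice.n_demes))
        bd = np.repeat(occ, cfg.new_snps_per_deme_per_gen)
        q_new[np.arange(n_new), bd] = cfg.new_snp_freq
        lattice.q = np.concatenate([lattice.q, q_new])
        lattice.birth_deme = np.concatenate([lattice.birth_deme, bd])
        lattice.birth_gen = np.concatenate(
            [lattice.birth_gen, np.full(n_new, gen, dtype=np.int64)]
        )

    # 4. founding wave
    if gen % cfg.founding_interval == 0 and not lattice.occupied.all():
        frontier = [
            d for d in range(lattice.n_demes)
            if not lattice.occupied[d] and lattice.adjacency[d, lattice.occupied].any()
        ]
        founder_n = []
        for d in frontier:
            nbrs = np.nonzero(lattice.adjacency[d] & lattice.occupied)[0]
            src = int(nbrs.min())  # deterministic source: lowest index
            n_found = max(1, int(round(cfg.founding_fraction * lattice.ne[src])))
            lattice.q[:, d] = rng.binomial(n_found, lattice.q[:, src]) / n_found
            founder_n.append(n_found)
        for d, n_found in zip(frontier, founder_n):
            lattice.occupied[d] = True
            lattice.founded_gen[d] = gen
            # optionally let the new deme reproduce once at founder size
            # before growing to Ne ("increased ... after one generation")
            if cfg.founder_sized_first_generation:
                lattice.ne_now[d] = n_found

    if gen % cfg.prune_interval == 0:
        lattice.prune_monomorphic()
    return lattice


def _sample_observed(lattice, cfg, rng):
    """Pick the observed SNP panel among loci still polymorphic."""
    occ = lattice.occupied
    pooled = lattice.q[:, occ].mean(axis=1)
    poly = (pooled > 0.0) & (pooled < 1.0)
    is_derived = lattice.birth_deme >= 0
    anc_pool = np.nonzero(poly & ~is_derived)[0]
    der_pool = np.nonzero(poly & is_derived)[0]
    if len(anc_pool) < cfg.sample_ancestral:
        raise RuntimeError(
            f"only {len(anc_pool)} polymorphic ancestral SNPs survive; "
            f"{cfg.sample_ancestral} requested "
            f"(short by {cfg.sample_ancestral - len(anc_pool)})"
        )
    if len(der_pool) < cfg.sample_derived:
        raise RuntimeError(
            f"only {len(der_pool)} polymorphic derived SNPs survive; "
            f"{cfg.sample_derived} requested "
            f"(short by {cfg.sample_derived - len(der_pool)})"
        )
    anc = rng.choice(anc_pool, size=cfg.sample_ancestral, replace=False)
    der = rng.choice(der_pool, size=cfg.sample_derived, replace=False)
    return np.concatenate([np.sort(anc), np.sort(der)])


def run_simulation(cfg: ColonizationConfig):
    """Run a scenario end to end.

    Returns ``(genotypes, truth)``: a :class:`GenotypeTable` of
    ``individuals_per_pop`` diploid individuals per deme typed at the
    sampled ancestral + derived SNPs (allele 1 = the tracked allele),
    and the :class:`SimTruth`.  The same seed yields a bit-identical
    table.
    """
    rng = np.random.default_rng(cfg.seed)
    lattice = _init_lattice(cfg, rng)
    for gen in range(1, cfg.generations + 1):
        step_generation(lattice, cfg, rng, gen)
    lattice.prune_monomorphic()

    if not lattice.occupied.all():
        warnings.warn(
            f"only {int(lattice.occupied.sum())} of {cfg.n_demes} demes were "
            "colonized within the configured generations; the genotype table "
            "covers occupied demes only"
        )
    demes = np.nonzero(lattice.occupied)[0]
    sel = _sample_observed(lattice, cfg, rng)
    q_sel = lattice.q[np.ix_(sel, demes)]  # (L, n_occupied)
    L, D = q_sel.shape
    names = []
    n_anc = int((lattice.birth_deme[sel] < 0).sum())
    for idx, locus in enumerate(sel):
        if lattice.birth_deme[locus] < 0:
            names.append(f"anc{idx + 1:06d}")
        else:
            names.append(f"der{idx + 1:06d}")

    n_ind = cfg.individuals_per_pop
    genotypes = np.zeros((n_ind * D, L, 2), dtype=np.int32)
    pop_index = np.zeros(n_ind * D, dtype=np.int64)
    populations, individuals = [], []
    for d in range(D):
        g = rng.binomial(2, np.broadcast_to(q_sel[:, d], (n_ind, L)))
        rows = slice(d * n_ind, (d + 1) * n_ind)
        # g copies of allele 1, (2 - g) of allele 2
        genotypes[rows, :, 0] = np.where(g >= 1, 1, 2)
        genotypes[rows, :, 1] = np.where(g == 2, 1, 2)
        pop_index[rows] = d
        label = f"pop{demes[d] + 1:02d}"
        populations.append(label)
        individuals.append([f"{label}_{i + 1:03d}" for i in range(n_ind)])
    gt = GenotypeTable(populations, individuals, names, genotypes, pop_index)

    _, positions = scenario_adjacency(cfg.scenario, cfg.n_demes, cfg.grid_origin)
    loci_df = pd.DataFrame({
        "locus": names,
        "origin": np.where(lattice.birth_deme[sel] < 0, "ancestral", "derived"),
        "birth_deme": np.where(
            lattice.birth_deme[sel] < 0, 0, lattice.birth_deme[sel] + 1
        ),
        "birth_generation": lattice.birth_gen[sel],
    })
    truth = SimTruth(cfg.scenario, lattice.founded_gen.copy(), positions,
                     lattice.adjacency.copy(), loci_df)
    return gt, truth


def reduced_scale_config(scenario: str, seed: int = 0,
                         **overrides) -> ColonizationConfig:
    """Small preset for smoke tests and Monte Carlo checks.

    Ne = 10^3 gene copies and a 2,000-SNP ancestral pool (sampling
    400 ancestral + 20 derived SNPs, keeping the 20:1 panel ratio),
    with the full generation counts and migration/founding rates.
    """
    base = dict(
        scenario=scenario,
        ne=1_000,
        n_ancestral_loci=2_000,
        new_snps_per_deme_per_gen=2,
        sample_ancestral=400,
        sample_derived=20,
        individuals_per_pop=50,
        seed=seed,
    )
    base.update(overrides)
    return ColonizationConfig(**base)
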