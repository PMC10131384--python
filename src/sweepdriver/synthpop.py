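"""Forward Wright–Fisher simulator for phased multi-population haplotypes.

Produces binary (ancestral/derived) phased haplotypes for several demes with
known ground truth, emulating the structure of multi-population human cohorts:
serial population splits, symmetric migration, neutral background variation,
and an optional hard selective sweep at a focal site in one deme.

Model
-----
Discrete non-overlapping generations; each deme holds ``deme_size`` diploids
(2N haplotypes). Every child gamete picks a diploid parent (uniformly, or
proportionally to fitness 1 / 1+s / 1+2s at the focal site in the sweep deme),
recombines the parent's two haplotypes with a Poisson(rec_rate × seq_length)
number of crossovers, and acquires Poisson(mu × seq_length) new mutations
under the infinite-sites model. Demes split serially (deme i+1 is founded as a
full copy of deme i, no bottleneck) and exchange migrants at ``migration_rate``
per gamete per generation thereafter. The ancestral state of every site is the
allele of the founding population, so polarization of the output is exact.

The ancestral deme is initialized either from a neutral coalescent sample
(``init="coalescent"``, via msprime; the standard recapitation-style shortcut
that starts the forward phase at mutation–drift equilibrium) or from a
mutation-free founder population aged forward for ``burn_in`` generations
(``init="founder"``).

Randomness is drawn from per-(attempt, deme, generation) streams spawned off
the master seed, so adding a deme or retrying a lost sweep does not perturb
the other streams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _ehh_kernels as _kernels
from .popio import HaplotypeMatrix

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SweepSpec:
    """Hard sweep: a new beneficial mutation in one deme.

    Genic selection with diploid fitnesses 1, 1+s, 1+2s. ``onset`` is in
    generations before present; the mutation starts as a single copy.
    """

    deme: int
    position: int
    s: float
    onset: int


@dataclass
class SimConfig:
    """Simulation parameters; defaults give a desk-scale three-deme cohort.

    The defaults emulate (at reduced scale N=500, L=2×10^5) an
    African-like outgroup deme, a sister deme split 600 generations ago and a
    focal deme split 300 generations ago. The scaled mutation rate (2.5e-7
    per bp per generation, θ ≈ 5e-4 per bp) is human-like; the scaled
    recombination rate is set higher (2e-6 per bp) so that a hard sweep's
    footprint, roughly s/(r·ln 2Ns) ≈ 6 kb per side at s = 0.05, stays well
    inside the 200 kb region — empirical outlier scans need a predominantly
    neutral background, which a whole genome provides for free and a short
    simulated region must buy with a faster recombination clock.
    """

    n_demes: int = 3
    deme_size: int = 500
    split_generations: tuple[int, ...] = (600, 300)
    migration_rate: float = 1e-3
    seq_length: int = 200_000
    mu: float = 2.5e-7
    rec_rate: float = 2e-6
    sweep: Optional[SweepSpec] = None
    sample_sizes: tuple[int, ...] | int = 100
    seed: int = 0
    init: str = "coalescent"  # or "founder"
    burn_in: Optional[int] = None  # founder init only; default 8N
    deme_labels: Optional[tuple[str, ...]] = None
    max_sweep_retries: int = 100
    cleanup_interval: int = 5

    def __post_init__(self) -> None:
        if self.n_demes < 1 or self.deme_size < 2:
            raise ValueError("need n_demes >= 1 and deme_size >= 2")
        if min(self.migration_rate, self.mu, self.rec_rate) < 0:
            raise ValueError("rates must be non-negative")
        if len(self.split_generations) != self.n_demes - 1:
            raise ValueError("need one split time per deme beyond the first")
        if list(self.split_generations) != sorted(
            self.split_generations, reverse=True
        ):
            raise ValueError("split_generations must be decreasing (gens BP)")
        if isinstance(self.sample_sizes, int):
            self.sample_sizes = (self.sample_sizes,) * self.n_demes
        for k in self.sample_sizes:
            if k % 2 or not 2 <= k <= 2 * self.deme_size:
                raise ValueError("sample sizes must be even and <= 2N")
        if self.deme_labels is None:
            self.deme_labels = tuple(f"pop{d}" for d in range(self.n_demes))
        if self.init not in ("coalescent", "founder"):
            raise ValueError(f"unknown init mode {self.init!r}")
        if self.burn_in is None:
            self.burn_in = 8 * self.deme_size
        sw = self.sweep
        if sw is not None:
            if sw.s < 0 or not 0 <= sw.deme < self.n_demes:
                raise ValueError("invalid sweep spec")
            if not 1 <= sw.position <= self.seq_length:
                raise ValueError("sweep position outside the sequence")
            if sw.deme > 0 and sw.onset > self.split_generations[sw.deme - 1]:
                raise ValueError("sweep predates its deme's founding")

    @property
    def forward_span(self) -> int:
        """Number of forward generations simulated before present."""
        span = self.split_generations[0] if self.n_demes > 1 else 0
        if self.sweep is not None:
            span = max(span, self.sweep.onset)
        if self.init == "founder":
            span += self.burn_in
        return span


@dataclass
class TruthTable:
    """Ground truth for one simulation."""

    focal_position: Optional[int]
    sweep_deme: Optional[str]
    focal_final_freqs: dict[str, float] = field(default_factory=dict)
    trajectory: list[tuple[int, float]] = field(default_factory=list)
    site_labels: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_sweep_restarts: int = 0


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


class _State:
    """Mutable simulation state: a shared site list across demes.

    Matrices are kept in capacity buffers wider than the live site count
    ``S`` so per-generation mutation columns append in place; compaction
    (dropping pooled-fixed/lost columns) rebuilds the buffers periodically.
    """

    def __init__(self) -> None:
        self.S = 0
        self.positions = np.empty(0, dtype=np.int64)  # valid [:S]
        self.used: set[int] = set()
        self.demes: list[np.ndarray] = []  # each (2N, cap), valid [:, :S]
        self.focal_col: int = -1  # -1 = no sweep allele present

    @property
    def cap(self) -> int:
        return self.positions.size

    def live_positions(self) -> np.ndarray:
        return self.positions[: self.S]

    def set_initial(self, geno: np.ndarray, positions: np.ndarray) -> None:
        self.S = positions.size
        self.positions = positions.copy()
        self.demes = [np.ascontiguousarray(geno)]

    def snapshot(self):
        return (
            self.positions[: self.S].copy(),
            [m[:, : self.S].copy() for m in self.demes],
            set(self.used),
            self.focal_col,
        )

    def restore(self, snap) -> None:
        positions, demes, used, focal = snap
        self.S = positions.size
        self.positions = positions.copy()
        self.demes = [m.copy() for m in demes]
        self.used = set(used)
        self.focal_col = focal

    def _grow(self, need: int) -> None:
        newcap = self.S + need + 512
        pos = np.zeros(newcap, dtype=np.int64)
        pos[: self.S] = self.positions[: self.S]
        self.positions = pos
        grown = []
        for m in self.demes:
            g = np.zeros((m.shape[0], newcap), dtype=np.uint8)
            g[:, : self.S] = m[:, : self.S]
            grown.append(g)
        self.demes = grown

    def append_columns(self, new_pos: list[int], carriers: list[tuple[int, int]]):
        """Add one column per new mutation; ``carriers[i] = (deme, row)``."""
        k = len(new_pos)
        if k == 0:
            return
        if self.S + k > self.cap:
            self._grow(k)
        lo, hi = self.S, self.S + k
        self.positions[lo:hi] = new_pos
        for m in self.demes:
            m[:, lo:hi] = 0
        for j, (dd, row) in enumerate(carriers):
            self.demes[dd][row, lo + j] = 1
        self.S = hi

    def cleanup(self) -> None:
        """Drop columns fixed or lost in the pooled population (compaction)."""
        if self.S == 0:
            return
        pooled = sum(m[:, : self.S].sum(axis=0, dtype=np.int64) for m in self.demes)
        total = sum(m.shape[0] for m in self.demes)
        keep = (pooled > 0) & (pooled < total)
        if self.focal_col >= 0:
            keep[self.focal_col] = True
        if keep.all():
            return
        idx = np.flatnonzero(keep)
        newS = idx.size
        newcap = newS + 512
        pos = np.zeros(newcap, dtype=np.int64)
        pos[:newS] = self.positions[idx]
        compacted = []
        for m in self.demes:
            g = np.zeros((m.shape[0], newcap), dtype=np.uint8)
            g[:, :newS] = m[:, idx]
            compacted.append(g)
        self.positions = pos
        self.demes = compacted
        if self.focal_col >= 0:
            self.focal_col = int(np.searchsorted(idx, self.focal_col))
        self.S = newS


def _coalescent_init(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, set[int]]:
    """Neutral equilibrium sample of 2N haplotypes for the ancestral deme."""
    import msprime

    ms_seed = int(_stream(cfg.seed, 2, 0).integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=cfg.deme_size,
        population_size=cfg.deme_size,
        sequence_length=cfg.seq_length,
        recombination_rate=cfg.rec_rate,
        random_seed=ms_seed,
    )
    mts = msprime.sim_mutations(
        ts, rate=cfg.mu, random_seed=ms_seed, discrete_genome=False
    )
    geno = mts.genotype_matrix().T.astype(np.uint8)  # (2N, S)
    raw = [site.position for site in mts.sites()]
    positions, used, keep = [], set(), []
    for j, x in enumerate(raw):
        p = int(np.floor(x)) + 1  # (0,L) float -> 1-based bp
        while p in used and p <= cfg.seq_length:
            p += 1
        if p > cfg.seq_length or p in used:
            continue
        used.add(p)
        positions.append(p)
        keep.append(j)
    geno = np.ascontiguousarray(geno[:, keep])
    # multi-hit float positions are vanishingly rare; clip to presence
    np.clip(geno, 0, 1, out=geno)
    return geno, np.asarray(positions, dtype=np.int64), used


def _make_children(
    state: _State,
    d: int,
    rng: np.random.Generator,
    cfg: SimConfig,
    select_here: bool,
) -> np.ndarray:
    """One generation of reproduction for deme ``d`` (parents = old state)."""
    M = state.demes[d]
    n = M.shape[0]
    N = n // 2
    L = cfg.seq_length
    S = state.S
    n_active = len(state.demes)

    if select_here and state.focal_col >= 0:
        g = M[0::2, state.focal_col].astype(np.float64) + M[1::2, state.focal_col]
        w = 1.0 + cfg.sweep.s * g
        parents = rng.choice(N, size=n, p=w / w.sum())
    else:
        parents = rng.integers(0, N, size=n)
    start = rng.integers(0, 2, size=n)
    ncross = rng.poisson(cfg.rec_rate * L, size=n)
    if n_active > 1 and cfg.migration_rate > 0:
        mig = rng.random(n) < cfg.migration_rate
    else:
        mig = np.zeros(n, dtype=bool)

    # compiled bulk path: copy-or-recombine every gamete from its own-deme
    # parent; migrant gametes are redrawn individually below
    hap_idx = 2 * parents + start
    other_idx = 2 * parents + 1 - start
    breaks_off = np.zeros(n + 1, dtype=np.int64)
    breaks_off[1:] = np.cumsum(ncross)
    breaks_flat = rng.random(int(breaks_off[-1])) * L
    children = np.empty_like(M)
    _kernels.wf_children(
        M, S, state.positions, hap_idx, other_idx, breaks_flat, breaks_off,
        children,
    )

    for i in np.flatnonzero(mig):
        others = [dd for dd in range(n_active) if dd != d]
        src = state.demes[others[int(rng.integers(len(others)))]]
        pi = int(rng.integers(src.shape[0] // 2))
        a = src[2 * pi + start[i], :S]
        b = src[2 * pi + 1 - start[i], :S]
        k = int(ncross[i])
        if k > 0:
            cuts = rng.random(k) * L
            parity = (cuts[None, :] < state.positions[:S, None]).sum(axis=1) % 2
            children[i, :S] = np.where(parity == 1, b, a)
        else:
            children[i, :S] = a
    return children


def simulate(cfg: SimConfig) -> tuple[dict[str, HaplotypeMatrix], TruthTable]:
    """Run the simulation and sample phased haplotype matrices per deme.

    Returns matrices (already polarized: 1 = derived) sharing one site list
    restricted to sites polymorphic in the pooled sample, plus a TruthTable.
    If the sweep allele is lost, the sweep phase restarts from its onset
    snapshot, up to ``max_sweep_retries`` times.
    """
    state = _State()
    n_hap = 2 * cfg.deme_size
    if cfg.init == "coalescent":
        geno, positions, used = _coalescent_init(cfg)
        state.set_initial(geno, positions)
        state.used = used
    else:
        state.demes = [np.zeros((n_hap, 0), dtype=np.uint8)]
    if cfg.sweep is not None:
        state.used.add(cfg.sweep.position)

    truth = TruthTable(
        focal_position=cfg.sweep.position if cfg.sweep else None,
        sweep_deme=cfg.deme_labels[cfg.sweep.deme] if cfg.sweep else None,
    )
    split_at = {t: i + 1 for i, t in enumerate(cfg.split_generations)}
    attempt = 0
    snap = None
    gen = cfg.forward_span
    mu_per_gamete = cfg.mu * cfg.seq_length

    while gen > 0:
        if gen in split_at and len(state.demes) == split_at[gen]:
            src = split_at[gen] - 1
            state.demes.append(state.demes[src].copy())
        if cfg.sweep is not None and gen == cfg.sweep.onset and state.focal_col < 0:
            if snap is None:
                snap = state.snapshot()
            rng0 = _stream(cfg.seed, 3, attempt)
            row = int(rng0.integers(2 * cfg.deme_size))
            state.append_columns(
                [cfg.sweep.position], [(cfg.sweep.deme, row)]
            )
            state.focal_col = state.S - 1

        new_demes = []
        new_pos: list[int] = []
        carriers: list[tuple[int, int]] = []
        for d in range(len(state.demes)):
            rng = _stream(cfg.seed, 1, attempt, d, gen)
            children = _make_children(
                state, d, rng, cfg,
                select_here=cfg.sweep is not None and d == cfg.sweep.deme,
            )
            n = children.shape[0]
            k = int(rng.poisson(n * mu_per_gamete))
            if k:
                pos_draw = rng.integers(1, cfg.seq_length + 1, size=k)
                row_draw = rng.integers(n, size=k)
                for p, row in zip(pos_draw, row_draw):
                    p = int(p)
                    while p in state.used:  # infinite sites: re-draw collisions
                        p = int(rng.integers(1, cfg.seq_length + 1))
                    state.used.add(p)
                    new_pos.append(p)
                    carriers.append((d, int(row)))
            new_demes.append(children)
        state.demes = new_demes
        state.append_columns(new_pos, carriers)

        if state.focal_col >= 0:
            pooled = sum(int(m[:, state.focal_col].sum()) for m in state.demes)
            sweep_m = state.demes[cfg.sweep.deme]
            truth.trajectory.append(
                (gen - 1, float(sweep_m[:, state.focal_col].mean()))
            )
            if pooled == 0:
                attempt += 1
                if attempt > cfg.max_sweep_retries:
                    raise SimulationError(
                        f"sweep allele lost {attempt} times; giving up"
                    )
                state.restore(snap)
                truth.trajectory.clear()
                truth.n_sweep_restarts = attempt
                gen = cfg.sweep.onset
                continue
        if gen % cfg.cleanup_interval == 0:
            state.cleanup()
        gen -= 1

    state.cleanup()
    return _sample_output(cfg, state, truth)


def _sample_output(
    cfg: SimConfig, state: _State, truth: TruthTable
) -> tuple[dict[str, HaplotypeMatrix], TruthTable]:
    sampled = []
    for d in range(cfg.n_demes):
        rng = _stream(cfg.seed, 4, d)
        dip = rng.choice(cfg.deme_size, size=cfg.sample_sizes[d] // 2, replace=False)
        rows = np.empty(cfg.sample_sizes[d], dtype=np.int64)
        rows[0::2], rows[1::2] = 2 * dip, 2 * dip + 1
        sampled.append(state.demes[d][rows][:, : state.S])
        if state.focal_col >= 0:
            truth.focal_final_freqs[cfg.deme_labels[d]] = float(
                state.demes[d][:, state.focal_col].mean()
            )

    pooled = sum(m.sum(axis=0, dtype=np.int64) for m in sampled)
    total = sum(m.shape[0] for m in sampled)
    poly = np.flatnonzero((pooled > 0) & (pooled < total))
    live = state.live_positions()
    order = poly[np.argsort(live[poly], kind="stable")]
    positions = live[order]

    rng = _stream(cfg.seed, 5, 0)
    base_idx = rng.integers(0, 4, size=positions.size)
    anc = _BASES[base_idx]
    # derived base: a uniformly chosen base different from the ancestral one
    der = _BASES[(base_idx + rng.integers(1, 4, size=positions.size)) % 4]

    sites = pd.DataFrame(
        {
            "chrom": "1",
            "pos": positions,
            "ref": anc,
            "alt": der,
            "ancestral": anc,
            "derived": der,
        }
    )
    out = {}
    for d, label in enumerate(cfg.deme_labels):
        k = cfg.sample_sizes[d]
        out[label] = HaplotypeMatrix(
            entries=np.ascontiguousarray(sampled[d][:, order]),
            sites=sites.copy(),
            sample_ids=[f"{label}_{i}" for i in range(k // 2)],
            population=label,
            polarized=True,
        )
    truth.site_labels = pd.DataFrame(
        {
            "pos": positions,
            "selected": (
                positions == truth.focal_position
                if truth.focal_position is not None
                else np.zeros(positions.size, dtype=bool)
            ),
        }
    )
    return out, truth


def emit_vcf(
    matrices: dict[str, HaplotypeMatrix],
    truth: Optional[TruthTable],
    vcf_path,
    truth_path=None,
    panel_path=None,
) -> None:
    """Write a phased VCF (INFO/AA from founder alleles) and optional truth TSV.

    Haplotype rows 2i, 2i+1 become sample i's phased genotype. All matrices
    must share one site list.
    """
    mats = list(matrices.values())
    first = mats[0]
    for m in mats[1:]:
        if not np.array_equal(m.positions, first.positions):
            raise ValueError("matrices do not share a site list")
    for m in mats:
        if m.entries.shape[0] % 2:
            raise ValueError("odd haplotype count cannot form diploid samples")

    sample_names = [s for m in mats for s in m.sample_ids]
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chrom = str(first.sites["chrom"].iloc[0]) if len(first.sites) else "1"
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for j in range(first.n_sites):
            row = first.sites.iloc[j]
            gts = []
            for m in mats:
                col = m.entries[:, j]
                gts.extend(
                    f"{col[2 * i]}|{col[2 * i + 1]}"
                    for i in range(len(m.sample_ids))
                )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\tAA={row['ancestral']}\tGT\t" + "\t".join(gts) + "\n"
            )

    if truth_path is not None and truth is not None:
        labels = truth.site_labels
        if len(labels) != first.n_sites:
            raise ValueError("truth table does not match the site list")
        with open(truth_path, "w") as fh:
            fh.write(f"# focal_position={truth.focal_position}\n")
            fh.write(f"# sweep_deme={truth.sweep_deme}\n")
            fh.write(f"# n_sweep_restarts={truth.n_sweep_restarts}\n")
            labels.to_csv(fh, sep="\t", index=False)
    if panel_path is not None:
        with open(panel_path, "w") as fh:
            for m in mats:
                for s in m.sample_ids:
                    fh.write(f"{s}\t{m.population}\n")
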