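"""Multi-trait biparental breeding-population simulator.

The simulated genome mimics a dense-marker maize F2 design: ``n_chrom``
linkage groups, each carrying an ordered row of markers a fixed
recombination fraction apart, with biallelic QTL dropped into the
inter-marker slots.  A QTL is either fully linked to its left flanking
marker (recombination 0 on one side, one marker interval on the other) or,
for a small "linkage equilibrium" subset, segregates independently of the
whole map.  Meiosis is a first-order Markov walk along each chromosome
driven by the recombination fractions (no crossover interference), which is
the model implied by fraction-based simulators such as QU-GENE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeConfig",
    "Genome",
    "Population",
    "build_genome",
    "meiosis",
    "make_f2",
    "advance_cycle",
    "compute_tbv",
]


@dataclass(frozen=True)
class GenomeConfig:
    """Settings for :func:`build_genome`.

    Defaults follow the dense-marker maize design used throughout the
    package: 10 chromosomes x 250 markers (2500 markers), 315 QTL of which
    15 segregate in linkage equilibrium with the markers, and a
    recombination fraction of 0.0906 between adjacent markers.
    """

    n_chromosomes: int = 10
    markers_per_chromosome: int = 250
    n_qtl: int = 315
    n_le_qtl: int = 15
    marker_frac: float = 0.0906
    qtl_marker_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.markers_per_chromosome < 2:
            raise ValueError("need >= 1 chromosome with >= 2 markers each")
        if self.n_qtl < 0 or not 0 <= self.n_le_qtl <= self.n_qtl:
            raise ValueError("invalid QTL counts")
        for f in (self.marker_frac, self.qtl_marker_frac):
            if not 0.0 <= f <= 0.5:
                raise ValueError("recombination fractions must lie in [0, 0.5]")


@dataclass
class Genome:
    """An ordered multi-chromosome marker/QTL map.

    Loci are stored genome-wide in map order.  ``rec_prev[i]`` is the
    recombination fraction between locus ``i`` and the locus before it on
    the same chromosome (0.5 at chromosome starts, i.e. free recombination
    between chromosomes).  LE QTL carry 0.5 on both sides and are simulated
    as independently segregating; they are excluded from the Markov chain so
    that their flanking markers keep their true one-interval linkage.
    """

    config: GenomeConfig
    locus_chrom: np.ndarray  # (L,) chromosome index per locus
    is_qtl: np.ndarray       # (L,) bool
    rec_prev: np.ndarray     # (L,) fraction to previous locus
    marker_loci: np.ndarray  # (n_markers,) locus index of marker j
    qtl_loci: np.ndarray     # (n_qtl,) locus index of QTL q
    le_qtl_ids: np.ndarray   # QTL indices simulated in linkage equilibrium
    # Markov-chain view used by meiosis (LE QTL excluded):
    chain_loci: np.ndarray = field(repr=False, default=None)
    chain_p: np.ndarray = field(repr=False, default=None)
    le_loci: np.ndarray = field(repr=False, default=None)

    @property
    def n_loci(self) -> int:
        return self.locus_chrom.size

    @property
    def n_markers(self) -> int:
        return self.marker_loci.size

    @property
    def n_qtl(self) -> int:
        return self.qtl_loci.size


@dataclass
class Population:
    """A cohort of individuals with phased haplotypes over all genome loci.

    ``tbv`` (true breeding values) is filled once a trait architecture is
    attached; row i is the sum over QTL of (allele dosage - 1) times the
    QTL effect, i.e. breeding values are expressed as deviations from the
    all-heterozygote reference.
    """

    cycle_id: int
    haplotypes: np.ndarray        # (g, 2, L) uint8 in {0, 1}
    parent_ids: np.ndarray        # (g, 2) int; -1 for founder-derived F2
    tbv: np.ndarray | None = None  # (g, n_traits)

    @property
    def size(self) -> int:
        return self.haplotypes.shape[0]

    def qtl_dosage(self, genome: Genome) -> np.ndarray:
        """Allele dosage (0/1/2) at every QTL, shape (g, n_qtl)."""
        return self.haplotypes.sum(axis=1, dtype=np.int64)[:, genome.qtl_loci]

    def marker_dosage(self, genome: Genome) -> np.ndarray:
        """Allele dosage (0/1/2) at every marker, shape (g, n_markers)."""
        return self.haplotypes.sum(axis=1, dtype=np.int64)[:, genome.marker_loci]


def build_genome(config: GenomeConfig | None = None, *, seed=None) -> Genome:
    """Construct a genome from ``config``, allocating QTL to random
    inter-marker slots (at most one QTL per slot) and choosing the LE subset
    uniformly at random.  Deterministic given ``seed``.
    """
    cfg = config or GenomeConfig()
    rng = np.random.default_rng(seed)
    mk = cfg.markers_per_chromosome
    slots_per_chrom = mk - 1
    total_slots = cfg.n_chromosomes * slots_per_chrom
    if cfg.n_qtl > total_slots:
        raise ValueError(
            f"{cfg.n_qtl} QTL exceed the {total_slots} available inter-marker slots"
        )

    # Global slot index s on chromosome s // slots_per_chrom, between local
    # markers (s % slots_per_chrom) and (s % slots_per_chrom) + 1.
    qtl_slots = np.sort(rng.choice(total_slots, size=cfg.n_qtl, replace=False))
    # Guard against a chromosome receiving more QTL than it has slots (cannot
    # happen with replace=False, but keep the contract explicit).
    le_ids = np.sort(rng.choice(cfg.n_qtl, size=cfg.n_le_qtl, replace=False))
    is_le = np.zeros(cfg.n_qtl, dtype=bool)
    is_le[le_ids] = True

    chrom_list, qtl_flag, rec_prev = [], [], []
    marker_loci = np.empty(cfg.n_chromosomes * mk, dtype=np.int64)
    qtl_loci = np.empty(cfg.n_qtl, dtype=np.int64)
    qtl_cursor = 0
    locus = 0
    for ch in range(cfg.n_chromosomes):
        lo, hi = ch * slots_per_chrom, (ch + 1) * slots_per_chrom
        sel = (qtl_slots >= lo) & (qtl_slots < hi)
        local_slots = qtl_slots[sel] - lo
        by_slot: dict[int, int] = {int(s): qtl_cursor + j for j, s in enumerate(local_slots)}
        for j in range(mk):
            chrom_list.append(ch)
            qtl_flag.append(False)
            # chromosome starts recombine freely; within a chromosome the
            # locus preceding marker j is either marker j-1 or a QTL sitting
            # on marker j-1, one marker interval away either way
            rec_prev.append(0.5 if j == 0 else cfg.marker_frac)
            marker_loci[ch * mk + j] = locus
            locus += 1
            if j in by_slot:
                q = by_slot[j]
                chrom_list.append(ch)
                qtl_flag.append(True)
                rec_prev.append(0.5 if is_le[q] else cfg.qtl_marker_frac)
                qtl_loci[q] = locus
                locus += 1
        qtl_cursor += local_slots.size

    locus_chrom = np.asarray(chrom_list, dtype=np.int64)
    is_qtl_arr = np.asarray(qtl_flag, dtype=bool)
    rec_prev_arr = np.asarray(rec_prev, dtype=float)
    # The locus following an LE QTL is also 0.5 away from it.
    le_loci = qtl_loci[le_ids]
    nxt = le_loci + 1
    same_chrom = (nxt < locus_chrom.size) & (locus_chrom[np.minimum(nxt, locus_chrom.size - 1)] == locus_chrom[le_loci])
    rec_prev_arr[nxt[same_chrom]] = 0.5

    genome = Genome(
        config=cfg,
        locus_chrom=locus_chrom,
        is_qtl=is_qtl_arr,
        rec_prev=rec_prev_arr,
        marker_loci=marker_loci,
        qtl_loci=qtl_loci,
        le_qtl_ids=le_ids,
    )
    _attach_chain(genome)
    return genome


def _attach_chain(genome: Genome) -> None:
    """Precompute the Markov-chain view: non-LE loci in map order with the
    strand-switch probability applied *before* each locus.  LE QTL segregate
    independently, and their flanking markers stay one marker interval apart.
    """
    L = genome.n_loci
    le_loci = genome.qtl_loci[genome.le_qtl_ids]
    in_chain = np.ones(L, dtype=bool)
    in_chain[le_loci] = False
    chain_loci = np.flatnonzero(in_chain)

    cfg = genome.config
    chain_p = np.empty(chain_loci.size)
    prev_locus = -1
    prev_chrom = -1
    for i, loc in enumerate(chain_loci):
        ch = genome.locus_chrom[loc]
        if ch != prev_chrom:
            chain_p[i] = 0.5
        elif genome.is_qtl[loc]:
            chain_p[i] = genome.rec_prev[loc]
        else:
            # marker: if the skipped stretch contains only an LE QTL the two
            # chain neighbours are adjacent markers one interval apart; a
            # directly preceding non-LE QTL sits on its left marker, so the
            # marker interval fraction applies in every within-chromosome case.
            chain_p[i] = cfg.marker_frac
        prev_locus, prev_chrom = loc, ch
    genome.chain_loci = chain_loci
    genome.chain_p = chain_p
    genome.le_loci = le_loci


def _gametes(haplos: np.ndarray, genome: Genome, rng: np.random.Generator) -> np.ndarray:
    """Draw one gamete per individual.  ``haplos`` is (n, 2, L)."""
    n, two, L = haplos.shape
    if two != 2 or L != genome.n_loci:
        raise ValueError("haplotypes must have shape (n, 2, n_loci)")
    strand = np.empty((n, L), dtype=np.int64)
    switches = rng.random((n, genome.chain_loci.size)) < genome.chain_p[None, :]
    strand[:, genome.chain_loci] = np.cumsum(switches, axis=1) & 1
    if genome.le_loci.size:
        strand[:, genome.le_loci] = rng.integers(0, 2, size=(n, genome.le_loci.size))
    rows = np.arange(n)[:, None]
    cols = np.arange(L)[None, :]
    return haplos[rows, strand, cols]


def meiosis(parent_haplotypes: np.ndarray, genome: Genome, rng: np.random.Generator) -> np.ndarray:
    """Produce a single gamete from one parent's phased haplotypes (2, L).

    The walk starts on a uniformly random strand on each chromosome and
    switches strands between adjacent chain loci with probability equal to
    their recombination fraction; LE QTL are inherited independently.
    """
    parent_haplotypes = np.asarray(parent_haplotypes)
    if parent_haplotypes.shape != (2, genome.n_loci):
        raise ValueError("expected phased haplotypes of shape (2, n_loci)")
    return _gametes(parent_haplotypes[None, :, :], genome, rng)[0]


def make_f2(genome: Genome, n: int = 500, rng: np.random.Generator | None = None) -> Population:
    """Create an F2 population from two fully homozygous complementary
    inbreds (all-1 and all-0), so every locus segregates 1:2:1.
    """
    rng = np.random.default_rng() if rng is None else rng
    L = genome.n_loci
    f1 = np.stack([np.ones(L, dtype=np.uint8), np.zeros(L, dtype=np.uint8)])
    f1_tiled = np.broadcast_to(f1, (n, 2, L))
    g1 = _gametes(f1_tiled, genome, rng)
    g2 = _gametes(f1_tiled, genome, rng)
    haplotypes = np.stack([g1, g2], axis=1).astype(np.uint8)
    parent_ids = np.full((n, 2), -1, dtype=np.int64)
    return Population(cycle_id=0, haplotypes=haplotypes, parent_ids=parent_ids)


def advance_cycle(
    pop: Population,
    selected_ids: np.ndarray,
    genome: Genome,
    n_out: int = 500,
    rng: np.random.Generator | None = None,
) -> Population:
    """Random intercross of the selected individuals.

    Each of the ``n_out`` progeny draws two *distinct* parents uniformly at
    random from ``selected_ids`` (resampled per progeny) and receives one
    meiotic gamete from each.
    """
    rng = np.random.default_rng() if rng is None else rng
    selected_ids = np.asarray(selected_ids, dtype=np.int64)
    s = selected_ids.size
    if s < 2:
        raise ValueError("need at least 2 selected parents to intercross")
    p1 = rng.integers(0, s, size=n_out)
    p2 = (p1 + 1 + rng.integers(0, s - 1, size=n_out)) % s
    mothers = selected_ids[p1]
    fathers = selected_ids[p2]
    g1 = _gametes(pop.haplotypes[mothers], genome, rng)
    g2 = _gametes(pop.haplotypes[fathers], genome, rng)
    haplotypes = np.stack([g1, g2], axis=1).astype(np.uint8)
    parent_ids = np.stack([mothers, fathers], axis=1)
    return Population(cycle_id=pop.cycle_id + 1, haplotypes=haplotypes, parent_ids=parent_ids)


def f2_qtl_dosage_covariance(genome: Genome) -> np.ndarray:
    """Exact covariance matrix of QTL allele dosages in an F2 population.

    For an F2 between complementary inbreds, var(d) = 1/2 at every locus
    and cov(d_i, d_j) = (1/2) * prod(1 - 2 r_k) over the chain steps
    between the loci (zero across chromosomes and for LE QTL, which
    segregate independently of the map).
    """
    nq = genome.n_qtl
    # cumulative (1 - 2r) product along the chain, per chromosome
    chain_factor = 1.0 - 2.0 * genome.chain_p
    cum = np.ones(genome.chain_loci.size)
    running = 1.0
    prev_chrom = -1
    for i, loc in enumerate(genome.chain_loci):
        ch = genome.locus_chrom[loc]
        if ch != prev_chrom:
            running = 1.0
        else:
            running *= chain_factor[i]
        cum[i] = running
        prev_chrom = ch
    chain_pos = {int(loc): i for i, loc in enumerate(genome.chain_loci)}
    is_le = np.zeros(nq, dtype=bool)
    is_le[genome.le_qtl_ids] = True
    v = np.zeros(nq)
    chrom_of = np.empty(nq, dtype=np.int64)
    for q in range(nq):
        loc = genome.qtl_loci[q]
        chrom_of[q] = genome.locus_chrom[loc]
        if not is_le[q]:
            v[q] = cum[chain_pos[int(loc)]]
    S = np.zeros((nq, nq))
    for ch in np.unique(chrom_of):
        idx = np.flatnonzero((chrom_of == ch) & ~is_le)
        if idx.size == 0:
            continue
        vv = v[idx]
        ratio = np.minimum.outer(vv, vv) / np.maximum.outer(vv, vv)
        S[np.ix_(idx, idx)] = 0.5 * ratio
    S[np.diag_indices(nq)] = 0.5
    return S


def compute_tbv(pop: Population, effects: np.ndarray, genome: Genome) -> np.ndarray:
    """True breeding values: (dosage - 1) @ effects, stored on the population."""
    dosage = pop.qtl_dosage(genome)
    tbv = (dosage - 1.0) @ np.asarray(effects, dtype=float)
    pop.tbv = tbv
    return tbv
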