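"""Synthetic BC_n backcross cohort and downstream assay inputs.

Simulates the study design the pipeline assumes: a recessive dwarf line
(recurrent, maternal, allele "M") crossed to a normal tall line (donor,
paternal, allele "P"), advanced by recurrent backcrossing to BC8, with
phenotypically extreme bulks resequenced as pools, a 3-vs-3 RNA-seq count
matrix, hormone replicate panels, and qPCR Ct tables.  Everything is driven
by a single :class:`SimulationConfig` and a seed, and is bit-reproducible.

Haplotypes are boolean vectors over a marker map: ``False`` = recurrent "M",
``True`` = donor "P".  The phenotype follows a single major recessive locus:
an individual is dwarf iff it is homozygous recurrent at the causal marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "Individual",
    "SimulationConfig",
    "default_genome",
    "default_gene_models",
    "simulate_meiosis",
    "advance_backcross",
    "select_bulks",
    "simulate_bulk_depths",
    "simulate_counts",
    "simulate_hormones",
    "simulate_qpcr",
]


# ---------------------------------------------------------------------------
# genome and individuals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeModel:
    """Marker map over one or more chromosomes with a single causal locus.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bp.
    markers
        Mapping chromosome name -> 1-based marker positions (bp), strictly
        increasing.
    rate_cm_per_mb
        Constant recombination rate per chromosome (cM/Mb).
    causal
        ``(chrom, pos)`` of the major dwarfing locus; must be a marker.
    """

    chrom_lengths: dict[str, int]
    markers: dict[str, np.ndarray]
    rate_cm_per_mb: float
    causal: tuple[str, int]

    def __post_init__(self) -> None:
        for chrom, pos in self.markers.items():
            pos = np.asarray(pos, dtype=np.int64)
            if pos.ndim != 1 or len(pos) == 0:
                raise ValueError(f"{chrom}: empty marker vector")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: marker positions must be strictly increasing")
            if pos[0] < 1:
                raise ValueError(f"{chrom}: positions are 1-based")
            object.__setattr__(self, "markers", {**self.markers, chrom: pos})
        cchrom, cpos = self.causal
        if cchrom not in self.markers or cpos not in self.markers[cchrom]:
            raise ValueError("causal locus must coincide with a marker")

    @property
    def chroms(self) -> list[str]:
        return list(self.markers)

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.markers.values())

    def causal_index(self) -> tuple[str, int]:
        """Chromosome name and marker index of the causal locus."""
        chrom, pos = self.causal
        return chrom, int(np.searchsorted(self.markers[chrom], pos))

    def recomb_fractions(self, chrom: str) -> np.ndarray:
        """Per-interval crossover probability under the Haldane map function.

        Map distance between adjacent markers is ``d = Δbp/1e6 * rate`` cM and
        the recombination fraction is ``r = (1 - exp(-2 d / 100)) / 2`` (no
        interference).
        """
        d_cm = np.diff(self.markers[chrom]) / 1e6 * self.rate_cm_per_mb
        return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))

    def marker_table(self) -> pd.DataFrame:
        rows = [(c, int(p)) for c in self.chroms for p in self.markers[c]]
        return pd.DataFrame(rows, columns=["chrom", "pos"])


@dataclass
class Individual:
    """Two haplotypes as parental-origin vectors (False = "M", True = "P")."""

    haplotypes: dict[str, np.ndarray]  # chrom -> (2, n_markers) bool
    genome: GenomeModel

    def __post_init__(self) -> None:
        for chrom, hap in self.haplotypes.items():
            hap = np.asarray(hap, dtype=bool)
            if hap.shape != (2, len(self.genome.markers[chrom])):
                raise ValueError(f"{chrom}: haplotype shape mismatch")
            self.haplotypes[chrom] = hap

    @property
    def phenotype(self) -> str:
        chrom, idx = self.genome.causal_index()
        hap = self.haplotypes[chrom]
        return "dwarf" if (not hap[0, idx] and not hap[1, idx]) else "tall"

    def donor_dosage(self, chrom: str) -> np.ndarray:
        """Per-marker count of donor 'P' alleles (0, 1 or 2)."""
        return self.haplotypes[chrom].sum(axis=0)


def recurrent_parent(genome: GenomeModel) -> Individual:
    """Homozygous recurrent ("M"/"M") at every marker — the dwarf line."""
    return Individual(
        {c: np.zeros((2, len(genome.markers[c])), dtype=bool) for c in genome.chroms},
        genome,
    )


def donor_parent(genome: GenomeModel) -> Individual:
    """Homozygous donor ("P"/"P") at every marker — the tall line."""
    return Individual(
        {c: np.ones((2, len(genome.markers[c])), dtype=bool) for c in genome.chroms},
        genome,
    )


def f1_hybrid(genome: GenomeModel) -> Individual:
    """Heterozygous at every marker."""
    return Individual(
        {
            c: np.vstack(
                [
                    np.zeros(len(genome.markers[c]), dtype=bool),
                    np.ones(len(genome.markers[c]), dtype=bool),
                ]
            )
            for c in genome.chroms
        },
        genome,
    )


def default_genome() -> GenomeModel:
    """Two-chromosome stand-in for the mapped portion of the rapeseed genome.

    A01 carries the causal dwarfing locus at 3.21 Mb (inside the region where
    the scan is expected to peak); A02 is a null chromosome.  Markers every
    15 kb approximate the density of informative SNPs after filtering; the
    constant 2 cM/Mb is a typical genome-wide average for B. napus.
    """
    step = 15_000
    return GenomeModel(
        chrom_lengths={"A01": 24_000_000, "A02": 27_000_000},
        markers={
            "A01": np.arange(step, 24_000_000 + 1, step, dtype=np.int64),
            "A02": np.arange(step, 27_000_000 + 1, step, dtype=np.int64),
        },
        rate_cm_per_mb=2.0,
        causal=("A01", 3_210_000),
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the experimental design the pipeline targets: a BC8
    population of 965 plants, 36-plant tall and 40-plant dwarf pools
    resequenced at ~46x and ~57x, three RNA replicates per group, and
    class-level hormone shifts (IAA up 1.5-fold, GA and ABA down) in dwarf
    plants.
    """

    seed: int
    generations: int = 8
    population_size: int = 965
    n_tall_bulk: int = 36
    n_dwarf_bulk: int = 40
    mean_depth_tall: float = 46.0
    mean_depth_dwarf: float = 57.0
    rna_replicates: int = 3
    n_genes: int = 2_000
    library_size: float = 1_000_000.0
    de_fraction: float = 0.10
    lfc_min: float = 1.0
    lfc_max: float = 3.0
    nb_dispersion: float = 0.05
    up_fraction_region: float = 0.99  # DE direction skew inside the candidate region
    up_fraction_background: float = 0.64
    hormone_ratios: dict[str, float] = field(
        default_factory=lambda: {
            "IAA": 1.5,
            "GA": 0.6,
            "ABA": 0.7,
            "SL": 1.0,
            "CK": 1.0,
            "ETH": 1.0,
            "BR": 1.0,
        }
    )
    hormone_noise_sd: float = 0.10  # log-scale sd of replicate noise
    qpcr_noise_sd: float = 0.15  # sd of Ct noise (cycles)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "generations",
            "population_size",
            "n_tall_bulk",
            "n_dwarf_bulk",
            "rna_replicates",
            "n_genes",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("NB dispersion must be >= 0")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# meiosis and backcrossing
# ---------------------------------------------------------------------------


def _gamete_origins(r: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Origin vectors for ``n`` gametes over one chromosome.

    Returns an (n, m) boolean array; column-wise runs switch between the two
    parental haplotypes with the per-interval recombination fractions ``r``.
    """
    m = len(r) + 1
    start = rng.random(n) < 0.5
    if m == 1:
        return start[:, None]
    xo = rng.random((n, m - 1)) < r
    orig = np.empty((n, m), dtype=bool)
    orig[:, 0] = start
    # cumulative XOR of crossover indicators flips origin at each crossover
    np.not_equal(np.cumsum(xo, axis=1) % 2 == 1, start[:, None], out=orig[:, 1:])
    return orig


def simulate_meiosis(
    parent: Individual, genome: GenomeModel, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """One gamete: per chromosome, a mosaic of the parent's two haplotypes."""
    gamete = {}
    for chrom in genome.chroms:
        hap = parent.haplotypes[chrom]
        if hap.shape[1] != len(genome.markers[chrom]):
            raise ValueError(f"{chrom}: parent not defined on this genome")
        orig = _gamete_origins(genome.recomb_fractions(chrom), 1, rng)[0]
        gamete[chrom] = np.where(orig, hap[1], hap[0])
    return gamete


def advance_backcross(
    f1: Individual,
    recurrent: Individual,
    generations: int,
    genome: GenomeModel,
    rng: np.random.Generator,
    select_carriers: bool = True,
    n_offspring: int = 965,
) -> list[Individual]:
    """Advance ``n_offspring`` independent backcross lineages to BC_n.

    Each lineage runs one plant per generation, always crossed back to the
    recurrent parent.  With ``select_carriers`` the plant carried forward in
    every intermediate generation is heterozygous at the causal locus, so the
    final BC_n offspring segregate ~1:1 tall:dwarf there; the final offspring
    themselves are never selected.  Lineages are independent, so per-individual
    BC_n genotypes are i.i.d. draws from the BC_n distribution.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if recurrent.donor_dosage(genome.chroms[0]).any():
        raise ValueError("recurrent parent must be homozygous recurrent")
    for chrom in genome.chroms:
        if not (f1.haplotypes[chrom][0] != f1.haplotypes[chrom][1]).all():
            raise ValueError("f1 must be heterozygous at every marker")

    cchrom, cidx = genome.causal_index()
    # non-recurrent haplotype of the current parent of each lineage
    hap = {c: np.ones((n_offspring, len(genome.markers[c])), dtype=bool) for c in genome.chroms}
    for gen in range(1, generations + 1):
        gam = {}
        for chrom in genome.chroms:
            r = genome.recomb_fractions(chrom)
            orig = _gamete_origins(r, n_offspring, rng)
            # other haplotype is all-recurrent: gamete is donor only where the
            # origin picks the segregating haplotype and it carries donor
            gam[chrom] = hap[chrom] & orig
        if select_carriers and gen < generations:
            # redraw gametes for lineages whose carried-forward plant would
            # not be heterozygous at the causal locus
            bad = ~gam[cchrom][:, cidx]
            while bad.any():
                idx = np.flatnonzero(bad)
                for chrom in genome.chroms:
                    r = genome.recomb_fractions(chrom)
                    orig = _gamete_origins(r, len(idx), rng)
                    gam[chrom][idx] = hap[chrom][idx] & orig
                bad = ~gam[cchrom][:, cidx]
        hap = gam

    out = []
    for i in range(n_offspring):
        haps = {
            c: np.vstack([hap[c][i], np.zeros(len(genome.markers[c]), dtype=bool)])
            for c in genome.chroms
        }
        out.append(Individual(haps, genome))
    return out


def select_bulks(
    population: list[Individual],
    n_tall: int,
    n_dwarf: int,
    rng: np.random.Generator,
) -> tuple[list[Individual], list[Individual]]:
    """Phenotype-extreme pools: all-heterozygote tall, all-homozygote dwarf."""
    tall = [ind for ind in population if ind.phenotype == "tall"]
    dwarf = [ind for ind in population if ind.phenotype == "dwarf"]
    if len(tall) < n_tall:
        raise ValueError(f"only {len(tall)} tall plants, need {n_tall}")
    if len(dwarf) < n_dwarf:
        raise ValueError(f"only {len(dwarf)} dwarf plants, need {n_dwarf}")
    if n_tall < 1 or n_dwarf < 1:
        raise ValueError("bulk sizes must be positive")
    tsel = rng.choice(len(tall), size=n_tall, replace=False)
    dsel = rng.choice(len(dwarf), size=n_dwarf, replace=False)
    return [tall[i] for i in tsel], [dwarf[i] for i in dsel]


def bulk_allele_frequency(bulk: list[Individual], chrom: str) -> np.ndarray:
    """Per-marker frequency of the recurrent 'M' allele in a pool."""
    dosage = np.sum([ind.donor_dosage(chrom) for ind in bulk], axis=0)
    return 1.0 - dosage / (2 * len(bulk))


def simulate_bulk_depths(
    tall_bulk: list[Individual],
    dwarf_bulk: list[Individual],
    genome: GenomeModel,
    mean_depth_tall: float,
    mean_depth_dwarf: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pooled short-read allele counts at every marker.

    Per marker and pool, total depth ~ Poisson(mean depth) and the
    maternal-allele read count ~ Binomial(depth, pool 'M' frequency).  A row
    is flagged missing when either pool has zero depth.
    """
    frames = []
    for chrom in genome.chroms:
        pos = genome.markers[chrom]
        f_tall = bulk_allele_frequency(tall_bulk, chrom)
        f_dwarf = bulk_allele_frequency(dwarf_bulk, chrom)
        d_tall = rng.poisson(mean_depth_tall, size=len(pos))
        d_dwarf = rng.poisson(mean_depth_dwarf, size=len(pos))
        m_tall = rng.binomial(d_tall, f_tall)
        m_dwarf = rng.binomial(d_dwarf, f_dwarf)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": "A",  # maternal (recurrent) allele mapped to REF
                    "alt": "G",
                    "M_tall": m_tall,
                    "P_tall": d_tall - m_tall,
                    "M_dwarf": m_dwarf,
                    "P_dwarf": d_dwarf - m_dwarf,
                    "missing": (d_tall == 0) | (d_dwarf == 0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# expression, hormones, qPCR
# ---------------------------------------------------------------------------


def default_gene_models(genome: GenomeModel, n_genes: int = 2_000) -> pd.DataFrame:
    """Gene models tiled uniformly along the genome, 2 kb each."""
    total = sum(genome.chrom_lengths.values())
    rows = []
    gid = 0
    for chrom in genome.chroms:
        n_c = max(1, round(n_genes * genome.chrom_lengths[chrom] / total))
        starts = np.linspace(1, genome.chrom_lengths[chrom] - 2_000, n_c).astype(np.int64)
        for s in starts:
            gid += 1
            rows.append((f"gene{gid:05d}", chrom, int(s), int(s) + 1_999, 2_000))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "length"])


def simulate_counts(
    config: SimulationConfig,
    gene_models: pd.DataFrame,
    candidate_region: tuple[str, int, int],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted differential expression.

    Counts are NB with mean = library size x relative abundance and
    dispersion alpha (variance mu + alpha mu^2; alpha = 0 falls back to
    Poisson).  A configured fraction of genes is differentially expressed
    (dwarf vs tall) with |log2FC| uniform on [lfc_min, lfc_max]; DE genes
    inside the candidate region are up-regulated in dwarf with probability
    ``up_fraction_region`` (elsewhere ``up_fraction_background``).

    Returns ``(counts, truth)``: counts indexed by gene with columns
    Tall1..TallR, Dwarf1..DwarfR, and a truth table with the planted log2FC.
    """
    if config.nb_dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    genes = gene_models["gene_id"].to_numpy()
    n = len(genes)
    chrom_r, start_r, end_r = candidate_region
    in_region = (
        (gene_models["chrom"] == chrom_r)
        & (gene_models["start"].to_numpy() <= end_r)
        & (gene_models["end"].to_numpy() >= start_r)
    ).to_numpy()

    # relative abundances: lognormal, normalised to the library size
    abundance = rng.lognormal(mean=0.0, sigma=1.2, size=n)
    abundance /= abundance.sum()
    base_mu = config.library_size * abundance

    is_de = rng.random(n) < config.de_fraction
    mag = rng.uniform(config.lfc_min, config.lfc_max, size=n)
    p_up = np.where(in_region, config.up_fraction_region, config.up_fraction_background)
    sign = np.where(rng.random(n) < p_up, 1.0, -1.0)
    lfc = np.where(is_de, sign * mag, 0.0)

    samples = [f"Tall{i + 1}" for i in range(config.rna_replicates)] + [
        f"Dwarf{i + 1}" for i in range(config.rna_replicates)
    ]
    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        mu = base_mu * (2.0 ** lfc if s.startswith("Dwarf") else 1.0)
        counts[:, j] = _nb_draw(mu, config.nb_dispersion, rng)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "is_de": is_de,
            "true_log2fc": lfc,
            "in_region": in_region,
        }
    )
    return counts_df, truth


def _nb_draw(mu: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    if alpha == 0.0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


# hormone panel composition: class -> (compound count, baseline class total ng/g)
_HORMONE_CLASSES: dict[str, tuple[int, float]] = {
    "IAA": (12, 2600.0),
    "GA": (4, 8.0),
    "ABA": (1, 150.0),
    "SL": (1, 2.0),
    "CK": (8, 5.0),
    "ETH": (1, 20.0),
    "BR": (5, 3.0),
}


def simulate_hormones(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Replicate-level hormone concentrations with class-level group ratios.

    Each class total is split evenly over its member compounds; replicate
    values are lognormal around the group mean.  With zero noise the
    dwarf/tall ratio of every class total is exactly the configured ratio.
    """
    rows = []
    for cls, (n_comp, total) in _HORMONE_CLASSES.items():
        ratio = config.hormone_ratios.get(cls, 1.0)
        base = total / n_comp
        for c in range(n_comp):
            name = f"{cls}_{c + 1}" if n_comp > 1 else cls
            for group, mean in (("tall", base), ("dwarf", base * ratio)):
                noise = rng.normal(0.0, config.hormone_noise_sd, size=3)
                for rep in range(1, 4):
                    rows.append(
                        (name, cls, group, rep, mean * float(np.exp(noise[rep - 1])))
                    )
    return pd.DataFrame(
        rows, columns=["compound", "class", "group", "replicate", "concentration"]
    )


def simulate_qpcr(
    de_truth: pd.DataFrame,
    rng: np.random.Generator,
    n_genes: int = 12,
    noise_sd: float = 0.15,
    ref_ct: float = 20.0,
    base_ct: float = 25.0,
) -> pd.DataFrame:
    """Ct tables for a panel of DE genes against a stable reference gene.

    Target Ct in the dwarf group is shifted by -log2(fold change) relative to
    tall, so with zero noise the 2^-ddCt estimator recovers the simulated
    fold change exactly.
    """
    de = de_truth[de_truth["is_de"]]
    if len(de) < n_genes:
        raise ValueError("not enough DE genes for the qPCR panel")
    pick = de.sample(n=n_genes, random_state=int(rng.integers(2**31)))
    rows = []
    for _, g in pick.iterrows():
        for group in ("tall", "dwarf"):
            shift = g["true_log2fc"] if group == "dwarf" else 0.0
            for rep in range(1, 4):
                rows.append(
                    (
                        g["gene_id"],
                        group,
                        rep,
                        base_ct - shift + float(rng.normal(0.0, noise_sd)),
                        ref_ct + float(rng.normal(0.0, noise_sd)),
                    )
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "group", "replicate", "ct_target", "ct_reference"]
    )
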