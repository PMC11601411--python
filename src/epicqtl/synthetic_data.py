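"""Forward simulation of a fixed-chromosome bulk-segregant experiment.

The simulator emulates the full experimental design at desk scale: a cross
between two divergent yeast-like parents (Oak and Wine) whose genomes
differ at roughly 1 SNP per 200 bp; haploid F2 segregants produced under a
Haldane (no-interference) meiosis model with one chromosome fixed for a
single parent; viability selection with a baseline survival in the 1-10%
range, where planted QTL add to the survival logit — additively, or with a
coefficient whose contribution depends on the fixed chromosome's parent
(epistasis with that chromosome); four bulks (selected/unselected x
Oak/Wine background) in replicate; and pooled sequencing at ~70X mean
per-site depth (Poisson depth, binomial allele sampling).

Genotypes are coded 0 = Oak, 1 = Wine. The interaction coefficient gamma
enters the survival logit as ``gamma * b`` with b = +0.5 (Oak background) /
-0.5 (Wine background), mirroring the contrast coding of the analysis
model, so a planted gamma is what the scan's interaction term estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII",
         "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI"]

#: default desk-scale genome: 16 chromosomes, 300 SNPs each
DEFAULT_N_CHROM = 16
DEFAULT_CHROM_BP = 60_000          # 300 SNPs at 1 SNP / 200 bp
DEFAULT_SNP_DENSITY = 1 / 200      # SNPs per bp (parental divergence)
DEFAULT_MORGANS = 1.0              # genetic length per chromosome

DEFAULT_DEPTH = 70.0
DEFAULT_REPLICATES = 2
DEFAULT_N_SEGREGANTS = 10_000
DEFAULT_SURVIVAL = 0.05            # baseline, inside the 1-10% design range

BACKGROUNDS = ("Oak", "Wine")
_BCODE = {"Oak": 0.5, "Wine": -0.5}


@dataclass
class GenomeMap:
    """Chromosome ids, physical/genetic lengths and SNP positions (bp)."""
    chrom_ids: list[str]
    lengths_bp: dict[str, int]
    lengths_morgan: dict[str, float]
    snp_positions: dict[str, np.ndarray]

    def __post_init__(self):
        for c, pos in self.snp_positions.items():
            pos = np.asarray(pos)
            if len(pos) == 0:
                raise ValueError(f"chromosome {c} has zero SNPs")
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"SNP positions on {c} not strictly increasing")
            if self.lengths_morgan[c] <= 0:
                raise ValueError(f"chromosome {c} genetic length must be > 0")
            self.snp_positions[c] = pos

    @property
    def n_snps(self) -> int:
        return sum(len(p) for p in self.snp_positions.values())


@dataclass
class QTLModel:
    """Planted survival-logit architecture.

    ``additive`` maps a (chrom, pos) SNP to the additive effect a of its
    Wine allele on the survival logit; ``interaction`` maps a SNP to gamma,
    whose contribution to a Wine-allele carrier is gamma * (+0.5) in the
    Oak background and gamma * (-0.5) in the Wine background. Interaction
    QTL may not lie on the fixed chromosome (it does not segregate).
    """
    mu: float = float(logit(DEFAULT_SURVIVAL))
    additive: list[tuple[str, int, float]] = field(default_factory=list)
    interaction: list[tuple[str, int, float]] = field(default_factory=list)
    fixed_chrom: str = "VIII"
    fixed_parent: str | None = None     # per-background experiments set this
    #: per-background baseline override (the "dose knob"); see calibrate_doses
    mu_by_background: dict[str, float] | None = None
    #: survival link: "logit" (odds-multiplicative; default) or "probit"
    #: (Gaussian liability / classical truncation selection). At low survival
    #: the logit link factorizes across loci, so only a thinner-tailed
    #: liability lets fixation of a major QTL boost power at secondary loci.
    liability: str = "logit"

    def validate(self, genome: GenomeMap) -> None:
        for chrom, pos, _ in self.additive + self.interaction:
            if chrom not in genome.snp_positions:
                raise ValueError(f"QTL chromosome {chrom} not in genome")
            if pos not in genome.snp_positions[chrom]:
                raise ValueError(f"QTL position {chrom}:{pos} is not a SNP")
        for chrom, pos, _ in self.interaction:
            if chrom == self.fixed_chrom:
                raise ValueError("interaction QTL may not lie on the fixed chromosome")


@dataclass
class SimConfig:
    """Study conditions of one simulated experiment."""
    n_chrom: int = DEFAULT_N_CHROM
    chrom_bp: int = DEFAULT_CHROM_BP
    snp_density: float = DEFAULT_SNP_DENSITY
    morgans: float = DEFAULT_MORGANS
    snp_mode: str = "grid"             # "grid" | "uniform"
    n_segregants: int = DEFAULT_N_SEGREGANTS
    depth: float = DEFAULT_DEPTH
    replicates: int = DEFAULT_REPLICATES
    unselected_mode: str = "match"     # "match" (drift-matched subsample) | "full"
    #: target expected survival per background (dose tuning); None disables
    calibrate_survival: float | None = DEFAULT_SURVIVAL
    seed: int | None = None

    def __post_init__(self):
        if self.n_segregants < 1 or self.replicates < 1 or self.n_chrom < 1:
            raise ValueError("counts must be positive")


@dataclass
class SimTruth:
    """Ground truth attached to a simulated experiment."""
    model: QTLModel
    realized_survival: dict    # (background, replicate) -> fraction
    seed: int | None

    def to_json(self) -> str:
        d = {
            "mu": self.model.mu,
            "mu_by_background": self.model.mu_by_background,
            "additive": [list(q) for q in self.model.additive],
            "interaction": [list(q) for q in self.model.interaction],
            "fixed_chrom": self.model.fixed_chrom,
            "realized_survival": {f"{bg}:{rep}": v
                                  for (bg, rep), v in self.realized_survival.items()},
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)


def make_genome(config: SimConfig, rng: np.random.Generator | None = None) -> GenomeMap:
    """Build a deterministic desk-scale genome map.

    ``grid`` mode places SNPs every ``1 / snp_density`` bp (200 bp at the
    default divergence); ``uniform`` mode draws Binomial(length, density)
    SNP count with uniformly random positions.
    """
    rng = rng or np.random.default_rng(config.seed)
    ids = [ROMAN[i] if i < len(ROMAN) else f"chr{i + 1}" for i in range(config.n_chrom)]
    step = int(round(1 / config.snp_density))
    positions = {}
    for c in ids:
        if config.snp_mode == "grid":
            pos = np.arange(step, config.chrom_bp + 1, step, dtype=int)
        elif config.snp_mode == "uniform":
            n = rng.binomial(config.chrom_bp, config.snp_density)
            if n == 0:
                raise ValueError(f"zero SNPs drawn on chromosome {c}")
            pos = np.sort(rng.choice(np.arange(1, config.chrom_bp + 1), size=n, replace=False))
        else:
            raise ValueError(f"unknown snp_mode {config.snp_mode!r}")
        positions[c] = pos
    return GenomeMap(
        chrom_ids=ids,
        lengths_bp={c: config.chrom_bp for c in ids},
        lengths_morgan={c: config.morgans for c in ids},
        snp_positions=positions,
    )


def simulate_segregants(genome: GenomeMap, fixed_chrom: str, fixed_parent: str,
                        n: int, rng: np.random.Generator | int | None = None,
                        return_crossovers: bool = False):
    """Simulate haploid F2 segregant genotypes under the Haldane model.

    Per segregant and non-fixed chromosome: the crossover count is
    Poisson(genetic length in Morgans), breakpoints fall uniformly along
    the chromosome (uniform in genetic distance; the bp-to-Morgan map is
    linear), and the starting parental phase is a fair coin. The fixed
    chromosome is uniformly ``fixed_parent`` in every segregant.

    Returns
    -------
    genotypes : dict[str, numpy.ndarray]
        chrom -> (n, n_snp) int8 array, 0 = Oak allele, 1 = Wine allele.
    crossovers : dict[str, numpy.ndarray], optional
        chrom -> (n,) realized crossover counts (only with
        ``return_crossovers=True``; zeros for the fixed chromosome).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if fixed_parent not in BACKGROUNDS:
        raise ValueError("fixed_parent must be 'Oak' or 'Wine'")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    genotypes: dict[str, np.ndarray] = {}
    crossovers: dict[str, np.ndarray] = {}
    for chrom in genome.chrom_ids:
        snp_pos = genome.snp_positions[chrom]
        m = len(snp_pos)
        if chrom == fixed_chrom:
            fill = 1 if fixed_parent == "Wine" else 0
            genotypes[chrom] = np.full((n, m), fill, dtype=np.int8)
            crossovers[chrom] = np.zeros(n, dtype=int)
            continue
        L = genome.lengths_morgan[chrom]
        counts = rng.poisson(L, size=n)
        total = int(counts.sum())
        bp = rng.uniform(0, genome.lengths_bp[chrom], size=total)
        seg_ids = np.repeat(np.arange(n), counts)
        # parity of crossovers left of each SNP decides the phase flip
        snp_idx = np.searchsorted(snp_pos, bp, side="left")
        flips = np.zeros((n, m + 1), dtype=np.int32)
        np.add.at(flips, (seg_ids, snp_idx), 1)
        parity = np.cumsum(flips[:, :m], axis=1) % 2
        start = rng.integers(0, 2, size=n, dtype=np.int8)
        genotypes[chrom] = (start[:, None] ^ parity.astype(np.int8))
        crossovers[chrom] = counts
    if return_crossovers:
        return genotypes, crossovers
    return genotypes


def survival_probability(genotypes: dict[str, np.ndarray], model: QTLModel,
                         background: str, genome: GenomeMap) -> np.ndarray:
    """Per-segregant survival probability under the planted architecture.

    The survival logit is ``mu + sum(a_i * g_i) + sum(gamma_j * b * g_j)``
    with g the Wine-allele indicator and b the background contrast (+0.5
    Oak, -0.5 Wine). With no QTL every probability equals ``expit(mu)``.
    """
    if background not in BACKGROUNDS:
        raise ValueError("background must be 'Oak' or 'Wine'")
    b = _BCODE[background]
    mu = model.mu
    if model.mu_by_background and background in model.mu_by_background:
        mu = model.mu_by_background[background]
    some = next(iter(genotypes.values()))
    eta = np.full(some.shape[0], mu, dtype=float)
    for chrom, pos, a in model.additive:
        eta += a * genotypes[chrom][:, _qtl_column(genome, chrom, pos)]
    for chrom, pos, gamma in model.interaction:
        eta += gamma * b * genotypes[chrom][:, _qtl_column(genome, chrom, pos)]
    return _link(model)(eta)


def _link(model: QTLModel):
    if model.liability == "logit":
        return expit
    if model.liability == "probit":
        from scipy.stats import norm
        return norm.cdf
    raise ValueError(f"unknown liability {model.liability!r}")


def _qtl_column(genome: GenomeMap, chrom: str, pos: int) -> int:
    j = int(np.searchsorted(genome.snp_positions[chrom], pos))
    if j >= len(genome.snp_positions[chrom]) or genome.snp_positions[chrom][j] != pos:
        raise ValueError(f"QTL position {chrom}:{pos} is not a SNP")
    return j


def calibrate_doses(model: QTLModel, genome: GenomeMap,
                    target: float = DEFAULT_SURVIVAL) -> QTLModel:
    """Set per-background baselines so expected survival hits ``target``.

    Emulates the experimental dose determination: because the fixed
    chromosome may carry (or interact with) large-effect alleles, the same
    stress dose yields different survival in the two backgrounds, so the
    dose is adjusted per cross until expected survival matches the target
    (the 1-10% design range). The expectation is taken analytically over
    Mendelian 0.5 allele frequencies at the segregating QTL (QTL on the
    fixed chromosome contribute a constant), and the per-background
    baseline ``mu`` solving it is stored in ``model.mu_by_background``.
    """
    from itertools import product
    from scipy.optimize import brentq

    if not 0 < target < 1:
        raise ValueError("target survival must be in (0, 1)")
    model.validate(genome)
    mu_by_bg: dict[str, float] = {}
    for background in BACKGROUNDS:
        b = _BCODE[background]
        fixed_allele = 1 if background == "Wine" else 0
        constant = 0.0
        segregating: list[float] = []
        for chrom, _pos, a in model.additive:
            if chrom == model.fixed_chrom:
                constant += a * fixed_allele
            else:
                segregating.append(a)
        for chrom, _pos, gamma in model.interaction:
            segregating.append(gamma * b)   # never on the fixed chromosome

        combos = np.array([constant + sum(s) for s in product(*[(0.0, e) for e in segregating])]) \
            if segregating else np.array([constant])
        link = _link(model)

        def mean_survival(mu):
            return float(link(mu + combos).mean()) - target

        mu_by_bg[background] = float(brentq(mean_survival, -40.0, 40.0))
    model.mu_by_background = mu_by_bg
    return model


def make_bulks(genotypes: dict[str, np.ndarray], probs: np.ndarray, config: SimConfig,
               rng: np.random.Generator | int | None = None) -> dict:
    """Draw selected and unselected bulks; return per-SNP Wine frequencies.

    Selected replicate bulks are independent Bernoulli(prob) survivor draws
    from the segregant pool. Each unselected replicate is, by default, an
    independent random subsample of the pool matched in size to its paired
    selected bulk (``unselected_mode="match"``): real unselected cultures
    are deliberately grown to cell numbers comparable to the selected ones,
    so selected and unselected pools carry sampling (drift) noise of the
    same scale — which is also what makes a permutation null built from
    unselected bulks a valid reference for the selected ones.
    ``unselected_mode="full"`` uses the whole pool instead (no drift).
    With survival probabilities of 1 the two modes coincide and selected
    frequencies equal unselected frequencies.

    Returns ``{(selection, replicate): {chrom: freq array}}`` plus
    ``(1, replicate, "n")`` entries recording survivor counts.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = len(probs)
    bulks: dict = {}
    for rep in range(1, config.replicates + 1):
        survivors = rng.random(n) < probs
        n_surv = int(survivors.sum())
        if n_surv == 0:
            raise ValueError("no survivors drawn; increase n_segregants or baseline survival")
        bulks[(1, rep)] = {c: g[survivors].mean(axis=0) for c, g in genotypes.items()}
        bulks[(1, rep, "n")] = n_surv
        if config.unselected_mode == "full" or n_surv == n:
            bulks[(0, rep)] = {c: g.mean(axis=0) for c, g in genotypes.items()}
        elif config.unselected_mode == "match":
            members = rng.choice(n, size=n_surv, replace=False)
            bulks[(0, rep)] = {c: g[members].mean(axis=0) for c, g in genotypes.items()}
        else:
            raise ValueError(f"unknown unselected_mode {config.unselected_mode!r}")
    return bulks


def sequence_bulks(frequencies: dict, genome: GenomeMap, background: str,
                   config: SimConfig,
                   rng: np.random.Generator | int | None = None,
                   constant_depth: bool = False) -> pd.DataFrame:
    """Pooled sequencing of bulk allele frequencies into a variant table.

    Per SNP and bulk replicate, total reads are Poisson(depth) (or exactly
    ``depth`` with ``constant_depth=True``) and Wine reads are
    Binomial(total, freq). Returns rows of the polarized variant table for
    one background.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    frames = []
    for (sel, rep), freqs in ((k, v) for k, v in frequencies.items() if len(k) == 2):
        for chrom in genome.chrom_ids:
            f = np.clip(freqs[chrom], 0.0, 1.0)
            m = len(f)
            if constant_depth:
                total = np.full(m, int(round(config.depth)))
            else:
                total = rng.poisson(config.depth, size=m)
            wine = rng.binomial(total, f)
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": genome.snp_positions[chrom],
                "selection": sel,
                "background": background,
                "replicate": rep,
                "oak_reads": total - wine,
                "wine_reads": wine,
            }))
    table = pd.concat(frames, ignore_index=True)
    return table


# ---------------------------------------------------------------------------
# canonical desk-scale study conditions
#
# Fixed once: 16 chromosomes x 300 SNPs, 10,000 segregants per background,
# ~70X depth, 2 replicates per bulk, 5% target survival. Planted effects:
# additive QTL a = 2 on the survival logit; magnitude-epistasis architecture
# a = 1.5 with gamma = 1.5 (same-direction selection effect in both
# backgrounds, differing in size); sign-epistasis architecture a = 0 with
# gamma = 3 (selection effect of opposite direction per background).

def null_scenario(seed: int | None = None):
    """No planted QTL; chromosome VIII fixed."""
    return SimConfig(seed=seed), QTLModel(fixed_chrom="VIII")


def additive_scenario(seed: int | None = None, effect: float = 2.0):
    """One additive QTL (default a = 2) on chromosome XII; VIII fixed."""
    return SimConfig(seed=seed), QTLModel(
        fixed_chrom="VIII", additive=[("XII", 30_000, effect)])


def magnitude_scenario(seed: int | None = None):
    """Magnitude epistasis on VII: selection slopes 2.25 (Oak) / 0.75 (Wine)."""
    return SimConfig(seed=seed), QTLModel(
        fixed_chrom="VIII",
        additive=[("VII", 30_000, 1.5)],
        interaction=[("VII", 30_000, 1.5)])


def sign_scenario(seed: int | None = None):
    """Sign epistasis on X: selection slopes +1.5 (Oak) / -1.5 (Wine)."""
    return SimConfig(seed=seed), QTLModel(
        fixed_chrom="VIII", interaction=[("X", 30_000, 3.0)])


def power_gain_scenario(seed: int | None = None, fixed_chrom: str = "VIII"):
    """Major QTL on VIII (a = 3) plus secondary QTL on X (a = 1).

    Run once with ``fixed_chrom="VIII"`` (major QTL removed from the
    segregating variance) and once with ``fixed_chrom="I"`` (major QTL
    segregates); compare |z_selection| at the secondary QTL. Uses the
    Gaussian-liability (probit) survival model, under which truncation-type
    selection lets fixation of the major QTL sharpen the selection gradient
    at secondary loci; with the odds-multiplicative logit link the two arms
    are provably equivalent at low survival.
    """
    return SimConfig(seed=seed), QTLModel(
        fixed_chrom=fixed_chrom,
        additive=[("VIII", 30_000, 3.0), ("X", 30_000, 1.0)],
        liability="probit")


def generate_experiment(config: SimConfig, model: QTLModel,
                        rng: np.random.Generator | int | None = None,
                        genome: GenomeMap | None = None):
    """Simulate one full fixed-chromosome experiment (both backgrounds).

    For each background (Oak-fixed and Wine-fixed) the fixed chromosome is
    set to that parent, segregants are simulated, selected for survival and
    sequenced. Returns ``(variant_table, truth, genome)`` where the variant
    table carries all four bulk categories with ``config.replicates``
    replicates each and a per-chromosome ``snp_index``.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        rng if rng is not None else config.seed)
    if genome is None:
        genome = make_genome(config, rng)
    model.validate(genome)
    if config.calibrate_survival is not None and model.mu_by_background is None:
        calibrate_doses(model, genome, config.calibrate_survival)

    tables = []
    realized: dict = {}
    for background in BACKGROUNDS:
        genos = simulate_segregants(genome, model.fixed_chrom, background,
                                    config.n_segregants, rng)
        probs = survival_probability(genos, model, background, genome)
        bulks = make_bulks(genos, probs, config, rng)
        for rep in range(1, config.replicates + 1):
            realized[(background, rep)] = bulks[(1, rep, "n")] / config.n_segregants
        tables.append(sequence_bulks(bulks, genome, background, config, rng))

    table = pd.concat(tables, ignore_index=True)
    table = table.sort_values(["chrom", "pos", "background", "selection", "replicate"],
                              kind="mergesort").reset_index(drop=True)
    from epicqtl.core_io import assign_snp_index
    table["snp_index"] = assign_snp_index(table)
    truth = SimTruth(model=model, realized_survival=realized, seed=config.seed)
    return table, truth, genome
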