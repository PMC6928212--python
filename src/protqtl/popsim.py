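"""Simulators for breeding pedigrees, RIL populations and trait phenotypes.

The generators emulate the statistical structure of a soybean high-protein
breeding study: a diversity panel containing one donor cultivar with rare
alleles; a backcross-derived cultivar whose descendants retain donor genomic
blocks through repeated cycles of selection; F5/F6-derived recombinant inbred
line (RIL) populations from biparental crosses; and multi-trial seed
protein/oil/yield phenotypes driven by additive and epistatic QTLs.

All randomness flows through one ``numpy.random.Generator`` seeded per call;
the seed is recorded in the output object's ``meta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, PanelGenotypes, PhenotypeRecords, RILGenotypes
from .genmap import GeneticMap, haldane_r

__all__ = [
    "Pedigree",
    "QTLLocus",
    "EpistaticPair",
    "QTLModel",
    "simulate_panel",
    "simulate_descent",
    "simulate_ril_population",
    "simulate_phenotypes",
    "demo_pedigree",
    "five_locus_protein_model",
]


# ---------------------------------------------------------------------------
# Pedigree


@dataclass
class Pedigree:
    """Directed breeding pedigree with designated analysis roles.

    ``nodes`` maps each individual to a tuple of its parents (empty for
    founders, otherwise exactly two) and ``operations`` to a breeding
    operation label per node (``cross``, ``backcross``, ``self_k`` or
    ``selection_for_trait``).
    """

    nodes: dict[str, tuple[str, ...]]
    operations: dict[str, str] = field(default_factory=dict)
    donor: str = "donor"
    recurrent_parent: str = "recurrent"
    derivatives: list[str] = field(default_factory=list)
    low_protein_contrast_lines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, parents in self.nodes.items():
            if len(parents) not in (0, 2):
                raise ValueError(f"node {name!r} must have 0 or 2 parents")
            for p in parents:
                if p not in self.nodes:
                    raise ValueError(f"parent {p!r} of {name!r} is not a node")
        self._check_acyclic()
        for role, names in [
            ("donor", [self.donor]),
            ("recurrent_parent", [self.recurrent_parent]),
            ("derivatives", self.derivatives),
            ("low_protein_contrast_lines", self.low_protein_contrast_lines),
        ]:
            for n in names:
                if n not in self.nodes:
                    raise ValueError(f"{role} {n!r} is not a pedigree node")
        if len(self.derivatives) < 1:
            raise ValueError("pedigree needs at least one derivative")

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(n: str, stack: list[str]) -> None:
            if state.get(n) == 1:
                raise ValueError(f"pedigree cycle through {n!r}")
            if state.get(n) == 2:
                return
            state[n] = 1
            for p in self.nodes[n]:
                visit(p, stack + [n])
            state[n] = 2

        for n in self.nodes:
            visit(n, [])

    def breeding_depth(self, name: str) -> int:
        """Number of crossing generations from founders to ``name``."""
        parents = self.nodes[name]
        if not parents:
            return 0
        return 1 + max(self.breeding_depth(p) for p in parents)


def demo_pedigree(n_derivatives: int = 7) -> Pedigree:
    """Canonical demonstration pedigree: a donor introgressed into a
    recurrent parent over two backcrosses with selection, then
    ``n_derivatives`` descendant cultivars bred over up to three further
    cycles of crossing with continued selection for the trait."""
    nodes: dict[str, tuple[str, ...]] = {
        "donor": (),
        "recurrent": (),
        "low1": (),
        "low2": (),
        "F1": ("donor", "recurrent"),
        "BC1": ("F1", "recurrent"),
        "focal": ("BC1", "recurrent"),
    }
    ops = {
        "F1": "cross",
        "BC1": "backcross",
        "focal": "selection_for_trait",
    }
    derivatives = []
    cycle_parents = ["focal"]
    i = 0
    while len(derivatives) < n_derivatives:
        parent = cycle_parents[i % len(cycle_parents)]
        name = f"deriv{len(derivatives) + 1}"
        nodes[name] = (parent, "recurrent")
        ops[name] = "selection_for_trait"
        derivatives.append(name)
        i += 1
        if i % 3 == 0:  # start the next breeding cycle from the new cultivars
            cycle_parents = derivatives[-3:]
            i = 0
    return Pedigree(
        nodes=nodes,
        operations=ops,
        donor="donor",
        recurrent_parent="recurrent",
        derivatives=derivatives,
        low_protein_contrast_lines=["low1", "low2"],
    )


# ---------------------------------------------------------------------------
# QTL model


@dataclass
class QTLLocus:
    chrom: str
    cm: float
    additive_effect: float | None = None  # trait units per dosage unit


@dataclass
class EpistaticPair:
    i: int  # index into QTLModel.loci
    j: int
    interaction_effect: float | None = None
    variance_fraction: float | None = None


@dataclass
class QTLModel:
    """Additive + epistatic trait architecture on a genetic map.

    When ``target_variance_fractions`` (one per locus, fractions of the
    line-mean phenotypic variance) are supplied, additive effects are solved
    at simulation time so each locus realizes its target; epistatic pairs may
    carry their own ``variance_fraction`` and are solved the same way.
    """

    loci: list[QTLLocus]
    epistatic_pairs: list[EpistaticPair] = field(default_factory=list)
    target_variance_fractions: list[float] | None = None
    residual_sd: float = 1.5  # % protein, per plot
    trial_effect_sd: float = 1.0  # % protein, per trial
    population_mean: float = 44.0  # % protein (midparent of ~48 x ~40)

    def __post_init__(self) -> None:
        if self.target_variance_fractions is not None:
            f = self.target_variance_fractions
            if len(f) != len(self.loci):
                raise ValueError("one variance fraction per locus required")
            if any(fi < 0 or fi > 1 for fi in f):
                raise ValueError("variance fractions must lie in [0,1]")
        for p in self.epistatic_pairs:
            if not (0 <= p.i < len(self.loci) and 0 <= p.j < len(self.loci)):
                raise ValueError("epistatic pair indexes a missing locus")
        if self.total_target_fraction() > 1.0:
            raise ValueError("variance fractions sum to more than 1")

    def total_target_fraction(self) -> float:
        tot = sum(self.target_variance_fractions or [])
        tot += sum(p.variance_fraction or 0.0 for p in self.epistatic_pairs)
        return tot


# Relative single-locus weights of the canonical five-locus seed-protein
# architecture (major chr-20 locus, chr-15 locus, two sub-threshold loci on
# chr 1 and 16, and a chr-5 locus acting purely through epistasis with the
# chr-20 locus), with the joint model explaining 70% of line-mean variance.
FIVE_LOCUS_WEIGHTS = {"Gm20": 60.0, "Gm15": 23.0, "Gm01": 14.0, "Gm16": 13.0}
FIVE_LOCUS_INTERACTION_WEIGHT = 1.0  # Gm05 x Gm20
FIVE_LOCUS_TOTAL_FRACTION = 0.70


def five_locus_protein_model(
    gmap: GeneticMap,
    total_fraction: float = FIVE_LOCUS_TOTAL_FRACTION,
) -> QTLModel:
    """The package's canonical five-locus protein model on ``gmap``.

    Additive loci sit at the marker nearest each chromosome midpoint on
    Gm20/Gm15/Gm01/Gm16; a fifth locus on Gm05 contributes only through its
    interaction with the Gm20 locus.  The printed single-locus weights
    (60:23:14:13 plus 1 for the interaction) are scaled so the joint model
    explains ``total_fraction`` of the line-mean variance.
    """
    weight_sum = sum(FIVE_LOCUS_WEIGHTS.values()) + FIVE_LOCUS_INTERACTION_WEIGHT
    scale = total_fraction / weight_sum

    wanted = list(FIVE_LOCUS_WEIGHTS) + ["Gm05"]
    chroms = gmap.chromosomes
    if all(c in chroms for c in wanted):
        additive_chroms, epi_chrom = wanted[:4], wanted[4]
    else:
        # smaller maps: spread the five loci over distinct chromosomes
        if len(chroms) < 5:
            raise ValueError("the five-locus model needs at least 5 chromosomes")
        picks = [chroms[int(k)] for k in np.linspace(0, len(chroms) - 1, 5)]
        additive_chroms, epi_chrom = picks[:4], picks[4]

    def mid_locus(chrom: str) -> QTLLocus:
        pos = gmap.positions(chrom)
        mid = 0.5 * (pos[0] + pos[-1])
        marker = gmap.nearest_marker(chrom, mid)
        row = gmap.table[gmap.table["marker"] == marker].iloc[0]
        return QTLLocus(chrom=chrom, cm=float(row["cm"]))

    loci = [mid_locus(c) for c in additive_chroms] + [mid_locus(epi_chrom)]
    fractions = [w * scale for w in FIVE_LOCUS_WEIGHTS.values()] + [0.0]
    pair = EpistaticPair(
        i=len(loci) - 1, j=0, variance_fraction=FIVE_LOCUS_INTERACTION_WEIGHT * scale
    )
    return QTLModel(
        loci=loci,
        epistatic_pairs=[pair],
        target_variance_fractions=fractions,
    )


# ---------------------------------------------------------------------------
# Diversity panel


def _draw_maf(rng: np.random.Generator, n: int, maf_distribution) -> np.ndarray:
    if callable(maf_distribution):
        maf = np.asarray(maf_distribution(rng, n), dtype=float)
    else:
        kind = maf_distribution[0]
        if kind == "uniform":
            lo, hi = maf_distribution[1], maf_distribution[2]
            maf = rng.uniform(lo, hi, n)
        elif kind == "beta":
            a, b = maf_distribution[1], maf_distribution[2]
            maf = 0.5 * rng.beta(a, b, n)
        else:
            raise ValueError(f"unknown maf distribution {kind!r}")
    if np.any((maf < 0) | (maf > 0.5)):
        raise ValueError("minor allele frequencies must lie in [0, 0.5]")
    return maf


def _sample_positions(rng: np.random.Generator, length_bp: int, n: int) -> np.ndarray:
    """n distinct sorted positions in [1, length_bp] without materializing
    the full coordinate range."""
    if n > length_bp:
        raise ValueError("more SNPs requested than available positions")
    pos = np.unique(rng.integers(1, length_bp + 1, size=n))
    while len(pos) < n:  # top up collisions (rare at realistic densities)
        extra = rng.integers(1, length_bp + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos


def simulate_panel(
    n_lines: int,
    gmap: GeneticMap,
    snp_density: int = 1000,
    maf_distribution=("uniform", 0.01, 0.5),
    donor_rare_config: tuple[int, float] = (100, 1 / 300),
    seed: int | None = None,
    donor: str = "donor",
    het_rate: float = 0.01,
    missing_rate: float = 0.02,
    bp_per_cm: float = 400_000.0,
    rare_snp_indices: np.ndarray | None = None,
    line_names: list[str] | None = None,
) -> PanelGenotypes:
    """Simulate a diversity panel of inbred lines at biallelic SNPs.

    One designated donor line is made homozygous for a minor allele at each
    of ``donor_rare_config[0]`` SNPs whose panel allele frequency equals
    ``donor_rare_config[1]`` in expectation; the remaining SNPs draw their
    alt-allele frequency from ``maf_distribution``.  Lines are inbred
    cultivars: calls are homozygous apart from a small ``het_rate``.

    Parameters
    ----------
    rare_snp_indices:
        Optional explicit SNP column indices to carry the donor rare allele
        (defaults to a random draw without replacement).
    """
    if n_lines < 10:
        raise ValueError("panel needs at least 10 lines")
    n_rare, rare_freq = donor_rare_config
    if n_rare > 0:
        if not (0 < rare_freq < 0.05):
            raise ValueError("rare_frequency must lie in (0, 0.05)")
        if rare_freq * n_lines < 1.0:
            raise ValueError(
                "rare allele cannot exist in less than one line: "
                f"rare_frequency*n_lines = {rare_freq * n_lines:.3f} < 1"
            )
    rng = np.random.default_rng(seed)

    # SNP coordinates per chromosome
    densities = (
        list(snp_density)
        if np.iterable(snp_density)
        else [int(snp_density)] * len(gmap.chromosomes)
    )
    if len(densities) != len(gmap.chromosomes):
        raise ValueError("snp_density list must match the number of chromosomes")
    frames = []
    for chrom, dens in zip(gmap.chromosomes, densities):
        length_bp = int(gmap.positions(chrom)[-1] * bp_per_cm) + int(bp_per_cm)
        bp = _sample_positions(rng, length_bp, dens)
        frames.append(pd.DataFrame({"chrom": chrom, "bp": bp}))
    snps = pd.concat(frames, ignore_index=True)
    snps.insert(0, "snp", [f"S{i + 1:06d}" for i in range(len(snps))])
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, len(snps))
    alt_i = (ref_i + rng.integers(1, 4, len(snps))) % 4
    snps["ref"] = bases[ref_i]
    snps["alt"] = bases[alt_i]

    n_snps = len(snps)
    maf = _draw_maf(rng, n_snps, maf_distribution)
    calls = (rng.random((n_lines, n_snps)) < maf[None, :]).astype(np.int8) * 2

    het = rng.random((n_lines, n_snps)) < het_rate
    calls[het] = 1
    miss = rng.random((n_lines, n_snps)) < missing_rate
    calls[miss] = MISSING

    if line_names is None:
        line_names = [donor] + [f"V{i:03d}" for i in range(1, n_lines)]
    if len(line_names) != n_lines or len(set(line_names)) != n_lines:
        raise ValueError("line_names must be unique and match n_lines")
    donor_idx = line_names.index(donor)

    rare_ids: list[str] = []
    if n_rare > 0:
        if rare_snp_indices is None:
            rare_snp_indices = rng.choice(n_snps, size=n_rare, replace=False)
        rare_snp_indices = np.asarray(rare_snp_indices, dtype=int)
        # carrier probability for non-donor lines so the expected panel
        # frequency of the rare (alt) allele equals rare_freq
        q = (rare_freq * n_lines - 1.0) / (n_lines - 1.0)
        for j in rare_snp_indices:
            col = (rng.random(n_lines) < q).astype(np.int8) * 2
            col[donor_idx] = 2
            miss_col = rng.random(n_lines) < missing_rate
            miss_col[donor_idx] = False
            col[miss_col] = MISSING
            calls[:, j] = col
        rare_ids = list(snps["snp"].iloc[rare_snp_indices])

    return PanelGenotypes(
        calls=calls,
        lines=list(line_names),
        snps=snps,
        meta={"seed": seed, "donor": donor, "rare_snp_ids": rare_ids},
    )


# ---------------------------------------------------------------------------
# Pedigree descent with donor-block retention


def simulate_descent(
    panel: PanelGenotypes,
    pedigree: Pedigree,
    retained_blocks: list[tuple[str, int, int]],
    retention_probability_outside: float = 0.125,
    seed: int | None = None,
    segment_bp: int = 10_000_000,
) -> PanelGenotypes:
    """Append pedigree derivatives that retain donor blocks under selection.

    Each derivative carries the donor genotype at every SNP inside
    ``retained_blocks`` (chrom, start_bp, end_bp; 1-based inclusive) —
    modeling selection for the trait — and, outside the blocks, inherits the
    donor genotype per independently segregating region (contiguous windows
    of ``segment_bp``) with probability ``retention_probability_outside``,
    otherwise the recurrent parent's genotype.
    """
    if not (0.0 <= retention_probability_outside <= 1.0):
        raise ValueError("retention probability must lie in [0,1]")
    chroms = set(panel.snps["chrom"])
    for chrom, start, end in retained_blocks:
        if chrom not in chroms:
            raise ValueError(f"retained block on unknown chromosome {chrom!r}")
        if start > end:
            raise ValueError(f"retained block {chrom}:{start}-{end} has start > end")
    rng = np.random.default_rng(seed)

    donor_calls = panel.line_calls(pedigree.donor)
    recurrent_calls = panel.line_calls(pedigree.recurrent_parent)

    chrom_arr = panel.snps["chrom"].to_numpy()
    bp = panel.snps["bp"].to_numpy()
    in_block = np.zeros(panel.n_snps, dtype=bool)
    for chrom, start, end in retained_blocks:
        in_block |= (chrom_arr == chrom) & (bp >= start) & (bp <= end)

    # independently segregating regions: windows of segment_bp per chromosome
    region_id = np.zeros(panel.n_snps, dtype=int)
    next_region = 0
    for chrom in panel.snps["chrom"].unique():
        m = chrom_arr == chrom
        region_id[m] = next_region + bp[m] // segment_bp
        next_region = region_id[m].max() + 1
    n_regions = next_region

    new_calls = np.empty((len(pedigree.derivatives), panel.n_snps), dtype=np.int8)
    for k, _name in enumerate(pedigree.derivatives):
        donor_region = rng.random(n_regions) < retention_probability_outside
        take_donor = donor_region[region_id]
        take_donor[in_block] = True
        new_calls[k] = np.where(take_donor, donor_calls, recurrent_calls)

    out = panel.with_lines(new_calls, list(pedigree.derivatives))
    out.meta = dict(panel.meta)
    out.meta.update(
        {
            "descent_seed": seed,
            "derivatives": list(pedigree.derivatives),
            "retained_blocks": list(retained_blocks),
            "retention_probability_outside": retention_probability_outside,
        }
    )
    return out


# ---------------------------------------------------------------------------
# RIL populations by single-seed descent


def _meioses(
    rng: np.random.Generator, hap0: np.ndarray, hap1: np.ndarray, r: np.ndarray
) -> np.ndarray:
    """One gamete per line from a diplotype (hap0, hap1) of shape (n, M).

    Crossovers follow the Haldane (no-interference) model: the parental
    origin switches independently between adjacent markers with the
    interval's recombination fraction ``r`` (length M-1), which is
    equivalent in law, at the marker positions, to Poisson(L/100) crossover
    counts with uniform positions.
    """
    n, m = hap0.shape
    start = rng.integers(0, 2, size=n)
    if m > 1:
        switches = rng.random((n, m - 1)) < r[None, :]
        origin = (start[:, None] + np.concatenate(
            [np.zeros((n, 1), dtype=int), np.cumsum(switches, axis=1)], axis=1
        )) % 2
    else:
        origin = start[:, None]
    return np.where(origin == 0, hap0, hap1)


def simulate_ril_population(
    gmap: GeneticMap,
    n_lines: int,
    derived_generation: int = 5,
    seed: int | None = None,
    parents: tuple[str, str] = ("P1", "P2"),
    missing_rate: float = 0.0,
    line_prefix: str = "RIL",
) -> RILGenotypes:
    """Simulate an F_k-derived RIL population by strict single-seed descent.

    Both parents are fully homozygous; the F1 is selfed ``derived_generation
    - 1`` times, advancing one random seed per line per generation, with
    meiosis under the Haldane mapping function.  Residual heterozygosity is
    retained (expected fraction (1/2)^(k-1) per marker).
    """
    if n_lines < 2:
        raise ValueError("a RIL population needs at least 2 lines")
    if not (2 <= derived_generation <= 10):
        raise ValueError("derived_generation must lie in 2..10")
    rng = np.random.default_rng(seed)

    n_markers = gmap.n_markers
    codes = np.empty((n_lines, n_markers), dtype=np.int8)
    col = 0
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        m = len(pos)
        r = haldane_r(np.diff(pos)) if m > 1 else np.empty(0)
        hap0 = np.zeros((n_lines, m), dtype=np.int8)  # parent-1 alleles
        hap1 = np.ones((n_lines, m), dtype=np.int8)  # parent-2 alleles
        for _ in range(derived_generation - 1):
            g0 = _meioses(rng, hap0, hap1, r)
            g1 = _meioses(rng, hap0, hap1, r)
            hap0, hap1 = g0, g1
        codes[:, col:col + m] = hap0 + hap1
        col += m

    if missing_rate > 0:
        miss = rng.random(codes.shape) < missing_rate
        codes[miss] = MISSING

    lines = [f"{line_prefix}{i + 1:03d}" for i in range(n_lines)]
    return RILGenotypes(
        codes=codes,
        lines=lines,
        gmap=gmap,
        generation=derived_generation,
        parents=parents,
        meta={"seed": seed},
    )


# ---------------------------------------------------------------------------
# Phenotypes


def _locus_columns(genotypes: RILGenotypes, model: QTLModel) -> list[int]:
    idx = []
    for locus in model.loci:
        grp = genotypes.gmap.chrom_table(locus.chrom)
        if grp.empty:
            raise ValueError(f"model locus on unknown chromosome {locus.chrom!r}")
        d = (grp["cm"] - locus.cm).abs()
        if d.min() > 1e-6:
            raise ValueError(
                f"model locus {locus.chrom}:{locus.cm} cM does not coincide "
                "with a map marker"
            )
        idx.append(int(grp.index[d.to_numpy().argmin()]))
    return idx


def simulate_phenotypes(
    genotypes: RILGenotypes,
    model: QTLModel,
    n_trials: int = 3,
    seed: int | None = None,
) -> PhenotypeRecords:
    """Simulate balanced multi-trial phenotypes under a QTL model.

    Per plot: trait = mean + sum of additive effects (dosage -1/0/+1) + sum
    of interaction effects + trial effect + residual.  When the model carries
    target variance fractions, effects are solved against the empirical
    dosage variances so each locus's marginal share of the line-mean
    phenotypic variance matches its target in expectation.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed)
    cols = _locus_columns(genotypes, model)
    x = genotypes.dosage()[:, cols]  # (n_lines, n_loci)
    n = genotypes.n_lines

    xx = np.column_stack(
        [x[:, p.i] * x[:, p.j] for p in model.epistatic_pairs]
    ) if model.epistatic_pairs else np.empty((n, 0))

    total = model.total_target_fraction()
    if model.target_variance_fractions is not None:
        if model.residual_sd <= 0:
            raise ValueError("variance-targeted models need residual_sd > 0")
        if total >= 1.0:
            raise ValueError("variance fractions must sum to less than 1")
        sigma_eff2 = model.residual_sd**2 / n_trials
        v_total = sigma_eff2 / (1.0 - total)
        a = np.empty(len(model.loci))
        for i, f in enumerate(model.target_variance_fractions):
            sd = x[:, i].std()
            if f > 0 and sd == 0:
                raise ValueError(f"locus {i} is monomorphic; cannot target variance")
            a[i] = np.sqrt(f * v_total) / sd if f > 0 else 0.0
        w = np.empty(len(model.epistatic_pairs))
        for k, p in enumerate(model.epistatic_pairs):
            g = p.variance_fraction or 0.0
            sd = xx[:, k].std()
            if g > 0 and sd == 0:
                raise ValueError("epistatic product is monomorphic; cannot target variance")
            w[k] = np.sqrt(g * v_total) / sd if g > 0 else 0.0
    else:
        a = np.array([loc.additive_effect or 0.0 for loc in model.loci])
        w = np.array([p.interaction_effect or 0.0 for p in model.epistatic_pairs])

    genetic = x @ a + (xx @ w if xx.size else 0.0)

    trial_effects = rng.normal(0.0, model.trial_effect_sd, n_trials)
    rows = []
    protein_all = np.empty((n, n_trials))
    for t in range(n_trials):
        resid = rng.normal(0.0, model.residual_sd, n)
        protein_all[:, t] = model.population_mean + genetic + trial_effects[t] + resid
    oil_noise = rng.normal(0.0, 0.3, (n, n_trials))
    yield_vals = rng.normal(3000.0, 300.0, (n, n_trials))
    for t in range(n_trials):
        for i, line in enumerate(genotypes.lines):
            prot = float(np.clip(protein_all[i, t], 0.0, 100.0))
            rows.append(
                {
                    "line": line,
                    "trial": f"T{t + 1}",
                    "protein": prot,
                    "oil": float(np.clip(46.6 - 0.6 * prot + oil_noise[i, t], 0.0, 100.0)),
                    "yield": float(max(yield_vals[i, t], 0.0)),
                }
            )
    causal_markers = [genotypes.gmap.marker_names[c] for c in cols]
    return PhenotypeRecords(
        table=pd.DataFrame(rows),
        meta={
            "seed": seed,
            "causal_markers": causal_markers,
            "additive_effects": list(map(float, a)),
            "interaction_effects": list(map(float, w)),
        },
    )
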