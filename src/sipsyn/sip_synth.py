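"""Synthetic DNA-SIP experiment generator with known ground truth.

Emulates the data a 13C-substrate stable-isotope-probing experiment produces:
a mixed community in which a known subset of populations assimilates the
labeled substrate, the GC- and label-dependent distribution of each
population's DNA over a CsCl buoyant-density gradient, per-fraction qPCR
signal for target taxa, and replicated 12C/13C heavy-window read-count
matrices with negative-binomial noise.

Density model: the Schildkraut relation rho = 1.660 + 0.098*GC (g/mL) plus a
+0.036 g/mL shift at full 13C labeling, linear in the 13C atom fraction above
natural abundance (1.1%). DNA spreads around its equilibrium density as a
Gaussian (default sd 0.003 g/mL); an optional uniform "carryover" component
models the low-level smearing of unlabeled DNA into heavy fractions that is
observed in real gradients (and is the reason 12C control gradients are
sequenced at all).

Every simulator is driven by an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import CountMatrix
from .fraction_select import QPCRProfile

__all__ = [
    "NATURAL_13C",
    "DENSITY_INTERCEPT",
    "DENSITY_GC_SLOPE",
    "DENSITY_LABEL_SHIFT",
    "GenomePopulation",
    "GradientProfile",
    "SIPDesign",
    "simulate_community",
    "buoyant_density",
    "default_fraction_edges",
    "simulate_gradient",
    "simulate_qpcr_profile",
    "simulate_counts",
    "random_genome",
    "mutate_genome",
]

#: Natural 13C atom fraction.
NATURAL_13C = 0.011

#: Schildkraut relation: rho = 1.660 + 0.098 * GC (g/mL).
DENSITY_INTERCEPT = 1.660
DENSITY_GC_SLOPE = 0.098

#: Buoyant-density increase of fully 13C-labeled DNA, g/mL.
DENSITY_LABEL_SHIFT = 0.036

#: Default gradient: 24 fractions spanning 1.66-1.78 g/mL.
DEFAULT_N_FRACTIONS = 24
DEFAULT_DENSITY_RANGE = (1.66, 1.78)
DEFAULT_SIGMA_DENSITY = 0.003


@dataclass(frozen=True)
class GenomePopulation:
    """One genome-resolved population in the synthetic community.

    ``atom13c`` is the 13C atom fraction of this population's DNA in the
    13C-substrate condition; in the 12C control every population sits at
    natural abundance.
    """

    id: str
    gc: float
    genome_length: int
    rel_abundance: float
    atom13c: float
    is_labeled: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"{self.id}: gc out of [0, 1]")
        if not NATURAL_13C <= self.atom13c <= 1.0:
            raise ValueError(f"{self.id}: atom13c out of [{NATURAL_13C}, 1]")
        if self.genome_length <= 0 or self.rel_abundance < 0:
            raise ValueError(f"{self.id}: non-positive genome length or abundance")

    def atom13c_in(self, condition: str) -> float:
        """Effective 13C atom fraction in a given condition ('12C'/'13C')."""
        return self.atom13c if condition == "13C" else NATURAL_13C


@dataclass(frozen=True)
class GradientProfile:
    """Per-population DNA mass across buoyant-density fractions.

    ``edges`` are ascending fraction boundaries (len n_fractions + 1);
    ``masses`` has shape (n_populations, n_fractions). ``truncated`` is the
    mass falling outside the covered density range.
    """

    population_ids: tuple[str, ...]
    edges: tuple[float, ...]
    masses: np.ndarray
    total_mass: np.ndarray
    truncated: np.ndarray
    condition: str

    @property
    def centers(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0

    def mass_in_window(self, lo: float, hi: float) -> np.ndarray:
        """Per-population mass in [lo, hi], weighting bins by overlap."""
        if hi <= lo:
            raise ValueError("heavy window must have positive width")
        e = np.asarray(self.edges)
        left, right = e[:-1], e[1:]
        overlap = np.clip(np.minimum(right, hi) - np.maximum(left, lo), 0.0, None)
        weights = overlap / (right - left)
        return self.masses @ weights

    def fraction_totals(self) -> np.ndarray:
        return self.masses.sum(axis=0)


@dataclass(frozen=True)
class SIPDesign:
    """Replication, depth and noise of the sequencing design."""

    replicates: int = 2
    depth: int = 500_000
    dispersion: float = 0.05
    qpcr_targets: tuple[str, ...] = ()
    seed: int = 0
    count_mode: str = "nb"  # "nb" or "multinomial" (exact column sums)

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.count_mode not in ("nb", "multinomial"):
            raise ValueError("count_mode must be 'nb' or 'multinomial'")


def simulate_community(
    n_populations: int,
    n_labeled: int,
    abundance_distribution: str = "lognormal",
    seed: int = 0,
    gc_range: tuple[float, float] = (0.35, 0.65),
    genome_length_range: tuple[int, int] = (2_000_000, 6_000_000),
    lognormal_sigma: float = 1.0,
    labeled_atom13c: float = 1.0,
) -> list[GenomePopulation]:
    """Draw a community with ``n_labeled`` fully 13C-assimilating populations.

    Relative abundances are lognormal (or uniform) and normalized to sum to 1;
    GC contents are uniform over ``gc_range``. Labeled populations carry
    ``labeled_atom13c`` in the 13C condition; everyone else stays at natural
    abundance. Fully reproducible for a fixed seed.
    """
    if not 0 <= n_labeled <= n_populations:
        raise ValueError("need 0 <= n_labeled <= n_populations")
    rng = np.random.default_rng(seed)
    if abundance_distribution == "lognormal":
        raw = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n_populations)
    elif abundance_distribution == "uniform":
        raw = rng.uniform(0.5, 1.5, size=n_populations)
    else:
        raise ValueError(f"unknown abundance distribution {abundance_distribution!r}")
    abund = raw / raw.sum()
    gc = rng.uniform(*gc_range, size=n_populations)
    lengths = rng.integers(genome_length_range[0], genome_length_range[1] + 1, size=n_populations)
    labeled_idx = set(rng.choice(n_populations, size=n_labeled, replace=False).tolist())
    width = len(str(max(n_populations, 1)))
    community = []
    for i in range(n_populations):
        labeled = i in labeled_idx
        community.append(
            GenomePopulation(
                id=f"pop_{i + 1:0{width}d}",
                gc=float(gc[i]),
                genome_length=int(lengths[i]),
                rel_abundance=float(abund[i]),
                atom13c=labeled_atom13c if labeled else NATURAL_13C,
                is_labeled=labeled,
            )
        )
    return community


def buoyant_density(gc: float, atom13c: float) -> float:
    """Equilibrium CsCl buoyant density (g/mL) of DNA.

    rho = 1.660 + 0.098*GC + 0.036*(atom13c - 0.011)/(1 - 0.011); linear in
    both GC content and the 13C atom fraction above natural abundance.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc out of [0, 1]")
    if not NATURAL_13C <= atom13c <= 1.0:
        raise ValueError(f"atom13c out of [{NATURAL_13C}, 1]")
    label_excess = (atom13c - NATURAL_13C) / (1.0 - NATURAL_13C)
    return DENSITY_INTERCEPT + DENSITY_GC_SLOPE * gc + DENSITY_LABEL_SHIFT * label_excess


def default_fraction_edges(
    n_fractions: int = DEFAULT_N_FRACTIONS,
    density_range: tuple[float, float] = DEFAULT_DENSITY_RANGE,
) -> np.ndarray:
    return np.linspace(density_range[0], density_range[1], n_fractions + 1)


def simulate_gradient(
    community: Sequence[GenomePopulation],
    fraction_edges: Sequence[float] | None = None,
    sigma_density: float = DEFAULT_SIGMA_DENSITY,
    seed: int = 0,
    condition: str = "13C",
    carryover: float = 0.0,
) -> GradientProfile:
    """Distribute each population's DNA over buoyant-density fractions.

    DNA mass (proportional to rel_abundance * genome_length) spreads as a
    Gaussian centered at the population's buoyant density with sd
    ``sigma_density``, integrated over the fraction bins; mass outside the
    covered range is truncated and reported. A ``carryover`` fraction of each
    population's mass is spread uniformly over the whole gradient, modeling
    the cross-fraction smearing seen in real gradients. The profile is a
    deterministic function of its inputs (``seed`` is accepted for interface
    symmetry with the stochastic simulators).
    """
    del seed  # deterministic stage
    if sigma_density <= 0:
        raise ValueError("sigma_density must be positive")
    if not 0.0 <= carryover < 1.0:
        raise ValueError("carryover must be in [0, 1)")
    edges = (
        default_fraction_edges() if fraction_edges is None else np.asarray(fraction_edges, float)
    )
    if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("fraction edges must be >= 2 strictly increasing densities")
    span = edges[-1] - edges[0]
    widths = np.diff(edges)
    ids, masses, totals, truncated = [], [], [], []
    for pop in community:
        total = pop.rel_abundance * pop.genome_length
        center = buoyant_density(pop.gc, pop.atom13c_in(condition))
        cdf = stats.norm.cdf(edges, loc=center, scale=sigma_density)
        gauss = (1.0 - carryover) * total * np.diff(cdf)
        smear = carryover * total * widths / span
        ids.append(pop.id)
        masses.append(gauss + smear)
        totals.append(total)
        truncated.append((1.0 - carryover) * total * (1.0 - (cdf[-1] - cdf[0])))
    return GradientProfile(
        population_ids=tuple(ids),
        edges=tuple(edges.tolist()),
        masses=np.asarray(masses),
        total_mass=np.asarray(totals),
        truncated=np.asarray(truncated),
        condition=condition,
    )


def simulate_qpcr_profile(
    profile: GradientProfile,
    target_ids: Sequence[str],
    noise_cv: float = 0.1,
    seed: int = 0,
    replicate: str = "1",
) -> QPCRProfile:
    """Per-fraction qPCR signal for the summed target populations.

    Signal = summed target DNA mass per fraction times multiplicative
    lognormal noise with the stated coefficient of variation (mean 1).
    """
    if not target_ids:
        raise ValueError("need at least one target population id")
    unknown = set(target_ids) - set(profile.population_ids)
    if unknown:
        raise KeyError(f"target ids not in profile: {sorted(unknown)}")
    idx = [profile.population_ids.index(t) for t in target_ids]
    signal = profile.masses[idx].sum(axis=0)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=signal.size)
        signal = signal * noise
    return QPCRProfile(
        densities=tuple(profile.centers.tolist()),
        signals=tuple(signal.tolist()),
        condition=profile.condition,
        replicate=replicate,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.clip(mean, 0.0, None)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + np.where(mean > 0, mean, 1.0))
    out = rng.negative_binomial(size, p)
    return np.where(mean > 0, out, 0)


def simulate_counts(
    profile_12c: GradientProfile,
    profile_13c: GradientProfile,
    design: SIPDesign,
    heavy_window: tuple[float, float],
) -> CountMatrix:
    """Replicated heavy-window read counts for both conditions.

    For each replicate, a population's expected read share is its DNA mass
    inside the heavy window divided by the total window mass of its gradient;
    counts are negative-binomial around depth*share with the design
    dispersion ('nb' mode), or exactly multinomial(depth, shares)
    ('multinomial' mode). Populations assimilating 13C have systematically
    higher shares in the 13C-gradient window.
    """
    lo, hi = min(heavy_window), max(heavy_window)
    if hi <= lo:
        raise ValueError("heavy window must have positive width")
    if profile_12c.population_ids != profile_13c.population_ids:
        raise ValueError("12C and 13C profiles must cover the same populations")
    shares = {}
    for cond, prof in (("12C", profile_12c), ("13C", profile_13c)):
        w = prof.mass_in_window(lo, hi)
        total = w.sum()
        if total <= 0:
            raise ValueError(f"heavy window contains no DNA mass in the {cond} gradient")
        shares[cond] = w / total
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(2 * design.replicates)
    cols, conditions, replicates = {}, {}, {}
    k = 0
    for cond in ("12C", "13C"):
        for rep in range(1, design.replicates + 1):
            rng = np.random.default_rng(children[k])
            k += 1
            if design.count_mode == "multinomial":
                counts = rng.multinomial(design.depth, shares[cond])
            else:
                counts = _nb_draw(rng, design.depth * shares[cond], design.dispersion)
            name = f"{cond}_rep{rep}"
            cols[name] = counts
            conditions[name] = cond
            replicates[name] = str(rep)
    df = pd.DataFrame(cols, index=list(profile_12c.population_ids))
    return CountMatrix(counts=df, conditions=conditions, replicates=replicates)


# ---------------------------------------------------------------------------
# Synthetic genome sequences (for ANI-based population delineation tests)
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_genome(length: int, gc: float, seed: int | np.random.Generator = 0) -> str:
    """An i.i.d. random nucleotide sequence with the given GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc out of [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def mutate_genome(sequence: str, rate: float, seed: int | np.random.Generator = 0) -> str:
    """Substitute each position i.i.d. with probability ``rate``.

    Substitutions always change the base, so the expected per-site identity to
    the parent is exactly 1 - rate.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate out of [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        current = arr[hit]
        # draw a replacement uniformly from the three other bases
        offsets = rng.integers(1, 4, size=n_hit)
        cur_idx = np.searchsorted(_BASES, current)  # A<C<G<T sorted order
        arr[hit] = _BASES[(cur_idx + offsets) % 4]
    return arr.tobytes().decode()
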