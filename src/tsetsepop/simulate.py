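"""Synthetic data with the statistical structure the analyses assume.

Three generators emulate the Senegal tsetse study design so the whole
pipeline is testable without any field data:

* :func:`simulate_microsat_panel` — a hierarchical F-model: ancestral allele
  frequencies per locus are Dirichlet; region frequencies are Dirichlet
  centred on the ancestral vector with concentration (1-F_RT)/F_RT;
  population frequencies likewise with (1-F_SR)/F_SR; genotypes are binomial
  draws (two per female, one per male at X-linked loci). Null alleles are a
  hidden allele class producing blanks (two copies) or apparent homozygotes
  (one copy). An optional bottleneck applies extra Wright-Fisher drift to one
  population.
* :func:`simulate_coi_panel` — haplotypes placed on a random mutation tree
  over L sites with region-exclusive haplotype pools.
* :func:`simulate_landmarks` — group mean shapes = base decagon + small
  group offsets; individuals add isotropic landmark noise and a random
  similarity (rotation/translation/scale) nuisance transform.

The Dirichlet hierarchy is used instead of a coalescent island model because
the study reports F-statistics, not migration rates: it gives direct control
of the F targets. Same seed means bit-identical output everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .panels import MISSING, GenotypePanel, LandmarkPanel, SequencePanel

__all__ = [
    "PopulationSpec", "LocusSpec", "CoiPopSpec", "SimConfig",
    "study_config", "simulate_microsat_panel", "simulate_wright_fisher_locus",
    "simulate_coi_panel", "simulate_landmarks", "tpm_multistep_q",
]


@dataclass
class PopulationSpec:
    name: str
    region: str
    n_females: int
    n_males: int


@dataclass
class LocusSpec:
    name: str
    x_linked: bool = False
    mutation_model: str = "SMM"          # IAM | SMM | TPM (WF simulator only)
    null_freq: float = 0.0
    n_alleles: int = 8                   # ancestral allele classes
    base_size: int = 150                 # smallest allele size (bp)


@dataclass
class CoiPopSpec:
    name: str
    region: str
    counts: list[int]                    # per regional haplotype, in order


@dataclass
class SimConfig:
    populations: list[PopulationSpec]
    loci: list[LocusSpec]
    f_sr: float = 0.05                   # subsamples within regions
    f_rt: float = 0.05                   # regions within total
    bottleneck: tuple[str, int, int] | None = None   # (pop, Ne_pb, gens ago)
    coi: list[CoiPopSpec] = field(default_factory=list)
    coi_sites: int = 738
    coi_divergence_steps: int = 12       # steps separating region pools
    landmark_groups: list[tuple[str, int]] = field(default_factory=list)
    landmark_k: int = 10
    landmark_noise_sd: float = 0.02
    landmark_offset_scale: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.f_sr < 1 and 0 <= self.f_rt < 1):
            raise ValueError("F targets must lie in [0, 1)")
        for l in self.loci:
            if not 0 <= l.null_freq <= 1:
                raise ValueError(f"null frequency out of [0,1] at {l.name}")
        for p in self.populations:
            if p.n_females + p.n_males < 1:
                raise ValueError(f"empty population {p.name}")

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["populations"] = [PopulationSpec(**p) for p in d["populations"]]
        d["loci"] = [LocusSpec(**l) for l in d["loci"]]
        d["coi"] = [CoiPopSpec(**c) for c in d.get("coi", [])]
        d["landmark_groups"] = [tuple(g) for g in d.get("landmark_groups", [])]
        if d.get("bottleneck"):
            d["bottleneck"] = tuple(d["bottleneck"])
        return cls(**d)


def study_config(seed: int = 0) -> SimConfig:
    """The Senegal study emulation: 5 sites in 2 regions, 153 flies,
    10 microsatellite loci (5 X-linked), COI haplotype structure with no
    sharing between regions, and 5 wing-landmark groups."""
    pops = [
        PopulationSpec("DiacsawPeul", "Niayes", 22, 8),
        PopulationSpec("DakarHann", "Niayes", 23, 6),
        PopulationSpec("Sebikotan", "Niayes", 21, 11),
        PopulationSpec("Missira", "Missira", 23, 12),
        PopulationSpec("Pout", "Niayes", 13, 14),
    ]
    loci = [
        LocusSpec("X55.3", True), LocusSpec("XPgp11", True),
        LocusSpec("Pgp1", False, null_freq=0.20),
        LocusSpec("XPgp13", True),
        LocusSpec("Pgp24", False, null_freq=0.20),
        LocusSpec("A10", False), LocusSpec("XB104", True),
        LocusSpec("XB110", True, n_alleles=2),
        LocusSpec("C102", False), LocusSpec("GPCAG", False),
    ]
    coi = [
        CoiPopSpec("DiacsawPeul", "Niayes", [30, 0]),
        CoiPopSpec("DakarHann", "Niayes", [25, 2]),
        CoiPopSpec("Sebikotan", "Niayes", [31, 1]),
        CoiPopSpec("Missira", "Missira", [14, 6, 4, 3, 2, 2, 1, 1, 1]),
        CoiPopSpec("Pout", "Niayes", [19, 6]),
    ]
    groups = [("DiacsawPeul", 20), ("DakarHann", 21), ("Sebikotan", 18),
              ("Missira", 34), ("Pout", 18)]
    return SimConfig(populations=pops, loci=loci, f_sr=0.069, f_rt=0.12,
                     bottleneck=("DakarHann", 16, 10), coi=coi,
                     landmark_groups=groups, seed=seed)


# --------------------------------------------------------------------------
# microsatellite panel
# --------------------------------------------------------------------------

def _dirichlet_around(rng, mean: np.ndarray, f: float) -> np.ndarray:
    """Dirichlet draw centred on ``mean`` with target fixation ``f``."""
    if f <= 0:
        return mean.copy()
    conc = (1.0 - f) / f
    alpha = np.maximum(conc * mean, 1e-9)
    return rng.dirichlet(alpha)


def _wf_drift(rng, freqs: np.ndarray, n_genes: int, gens: int) -> np.ndarray:
    p = freqs.copy()
    for _ in range(gens):
        counts = rng.multinomial(n_genes, p)
        p = counts / n_genes
    return p


def simulate_microsat_panel(config: SimConfig,
                            seed: int | None = None) -> GenotypePanel:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    regions_order: list[str] = []
    for p in config.populations:
        if p.region not in regions_order:
            regions_order.append(p.region)

    L = len(config.loci)
    pop_freqs: dict[str, list[np.ndarray]] = {p.name: [] for p in
                                              config.populations}
    allele_sizes: list[np.ndarray] = []
    for spec in config.loci:
        k = spec.n_alleles
        sizes = spec.base_size + 2 * np.arange(k)
        allele_sizes.append(sizes)
        ancestral = rng.dirichlet(np.ones(k))
        region_freq = {r: _dirichlet_around(rng, ancestral, config.f_rt)
                       for r in regions_order}
        for p in config.populations:
            pop_freqs[p.name].append(
                _dirichlet_around(rng, region_freq[p.region], config.f_sr))

    if config.bottleneck is not None:
        bpop, ne_pb, gens = config.bottleneck
        if bpop not in pop_freqs:
            raise ValueError(f"unknown bottleneck population {bpop}")
        for l in range(L):
            pop_freqs[bpop][l] = _wf_drift(rng, pop_freqs[bpop][l],
                                           2 * ne_pb, gens)

    ids, sexes, pops, calls = [], [], [], []
    for p in config.populations:
        n = p.n_females + p.n_males
        sex_vec = ["F"] * p.n_females + ["M"] * p.n_males
        for i in range(n):
            ids.append(f"{p.name}_{i + 1:03d}")
            sexes.append(sex_vec[i])
            pops.append(p.name)
            row = []
            for l, spec in enumerate(config.loci):
                freqs = pop_freqs[p.name][l]
                pn = spec.null_freq
                full = np.concatenate([(1 - pn) * freqs, [pn]])
                sizes = allele_sizes[l]
                hemizygous = spec.x_linked and sex_vec[i] == "M"
                if hemizygous:
                    a = rng.choice(len(full), p=full)
                    if a == len(sizes):                 # null -> blank male
                        row.append((MISSING, MISSING))
                    else:
                        row.append((int(sizes[a]), MISSING))
                else:
                    a, b = rng.choice(len(full), size=2, p=full)
                    a_null, b_null = a == len(sizes), b == len(sizes)
                    if a_null and b_null:
                        row.append((MISSING, MISSING))
                    elif a_null:
                        row.append((int(sizes[b]), int(sizes[b])))
                    elif b_null:
                        row.append((int(sizes[a]), int(sizes[a])))
                    else:
                        lo, hi = sorted((int(sizes[a]), int(sizes[b])))
                        row.append((lo, hi))
            calls.append(row)
    return GenotypePanel(
        ids=ids, sex=np.array(sexes), populations=pops,
        regions={p.name: p.region for p in config.populations},
        loci=[s.name for s in config.loci],
        x_linked=np.array([s.x_linked for s in config.loci]),
        calls=np.array(calls, dtype=np.int64))


# --------------------------------------------------------------------------
# forward Wright-Fisher locus
# --------------------------------------------------------------------------

def tpm_multistep_q(variance: float = 30.0) -> float:
    """Geometric parameter q so the signed multistep size has the requested
    variance: |step| ~ Geometric, P(|step|=j) = (1-q) q^(j-1), sign fair,
    Var = E[step^2] = (1+q)/(1-q)^2."""
    t = (np.sqrt(1 + 8 * variance) - 1) / (2 * variance)  # t = 1-q
    return 1.0 - t


def _mutate(rng, sizes: np.ndarray, model: str, p_single: float = 0.7,
            variance: float = 30.0, next_label: int | None = None):
    """Mutate one gene copy; returns (new allele value, next_label)."""
    if model == "IAM":
        return next_label, next_label + 1
    if model == "SMM":
        return int(sizes + rng.choice((-1, 1))), next_label
    if model == "TPM":
        if rng.random() < p_single:
            step = 1
        else:
            q = tpm_multistep_q(variance)
            step = int(rng.geometric(1 - q))
        return int(sizes + rng.choice((-1, 1)) * step), next_label
    raise ValueError(f"unknown mutation model {model!r}")


def simulate_wright_fisher_locus(N: int, mu: float, model: str,
                                 generations: int,
                                 bottleneck_spec: tuple[int, int] | None = None,
                                 sample_n: int = 30, seed: int = 0,
                                 p_single: float = 0.7,
                                 variance: float = 30.0) -> np.ndarray:
    """Forward Wright-Fisher simulation of one locus; returns sampled allele
    counts (a vector over the alleles present in the sample).

    ``N`` is the diploid population size (2N genes). ``bottleneck_spec`` is
    ``(gens_before_sampling, N_new)`` for an instantaneous crash.
    """
    if N < 2 or sample_n < 2:
        raise ValueError("N and sample_n must be >= 2")
    rng = np.random.default_rng(seed)
    genes = 2 * N
    # state: allele value -> count; IAM alleles are opaque labels
    values = np.array([100], dtype=np.int64)
    counts = np.array([genes], dtype=np.int64)
    next_label = 101 if model == "IAM" else None
    crash_at = None
    if bottleneck_spec is not None:
        gens_before, n_new = bottleneck_spec
        if gens_before > generations:
            raise ValueError("bottleneck earlier than the simulation start")
        crash_at = generations - gens_before

    for g in range(generations):
        if crash_at is not None and g == crash_at:
            genes = 2 * bottleneck_spec[1]
        p = counts / counts.sum()
        counts = rng.multinomial(genes, p)
        keep = counts > 0
        values, counts = values[keep], counts[keep]
        n_mut = rng.binomial(genes, mu)
        for _ in range(n_mut):
            src = rng.choice(len(values), p=counts / counts.sum())
            counts[src] -= 1
            new_val, next_label = _mutate(rng, values[src], model,
                                          p_single, variance, next_label)
            if new_val in values:
                counts[values == new_val] += 1
            else:
                values = np.append(values, new_val)
                counts = np.append(counts, 1)
        keep = counts > 0
        values, counts = values[keep], counts[keep]

    take = min(2 * sample_n, int(counts.sum()))
    sampled = rng.multivariate_hypergeometric(counts, take)
    return sampled[sampled > 0]


def panel_from_allele_counts(counts_per_locus: list[np.ndarray],
                             population: str = "sample", seed: int = 0,
                             ) -> GenotypePanel:
    """Assemble a one-population diploid panel from per-locus allele-count
    vectors (genes paired at random into individuals; odd gene counts drop
    one gene). Useful for turning gene-level simulations into panels."""
    rng = np.random.default_rng(seed)
    n_ind = min(int(np.asarray(c).sum()) // 2 for c in counts_per_locus)
    calls = np.zeros((n_ind, len(counts_per_locus), 2), dtype=np.int64)
    for l, counts in enumerate(counts_per_locus):
        counts = np.asarray(counts)
        genes = np.repeat(150 + 2 * np.arange(len(counts)), counts)
        rng.shuffle(genes)
        pairs = genes[:2 * n_ind].reshape(n_ind, 2)
        calls[:, l, :] = np.sort(pairs, axis=1)
    return GenotypePanel(
        ids=[f"{population}_{i + 1:03d}" for i in range(n_ind)],
        sex=np.array(["F"] * n_ind), populations=[population] * n_ind,
        regions={population: population},
        loci=[f"L{j + 1}" for j in range(len(counts_per_locus))],
        x_linked=np.zeros(len(counts_per_locus), dtype=bool),
        calls=calls)


def simulate_isolated_population(N: int, n_loci: int = 10, mu: float = 5e-3,
                                 generations: int | None = None,
                                 sample_n: int = 30, seed: int = 0,
                                 name: str = "isolate") -> GenotypePanel:
    """Multilocus diploid Wright-Fisher simulation of one isolated population.

    Unlinked loci recombine freely; the linkage disequilibrium among them is
    therefore pure drift signal, which is what the LD effective-size method
    measures. Mutation is stepwise (SMM). The default burn-in of 10 N
    generations from a monomorphic start comfortably exceeds the ~4 N
    coalescent depth of the sample.
    """
    rng = np.random.default_rng(seed)
    if generations is None:
        generations = 10 * N
    pop = np.full((N, n_loci, 2), 150, dtype=np.int64)
    for _ in range(generations):
        mothers = rng.integers(0, N, size=N)
        fathers = rng.integers(0, N, size=N)
        pick_m = rng.integers(0, 2, size=(N, n_loci, 1))
        pick_f = rng.integers(0, 2, size=(N, n_loci, 1))
        gam_m = np.take_along_axis(pop[mothers], pick_m, axis=2)[:, :, 0]
        gam_f = np.take_along_axis(pop[fathers], pick_f, axis=2)[:, :, 0]
        pop = np.stack([gam_m, gam_f], axis=2)
        mut = rng.random(pop.shape) < mu
        if mut.any():
            pop[mut] += rng.choice((-1, 1), size=int(mut.sum()))
    take = rng.choice(N, size=min(sample_n, N), replace=False)
    sample = np.sort(pop[take], axis=2)
    n = sample.shape[0]
    return GenotypePanel(
        ids=[f"{name}_{i + 1:03d}" for i in range(n)],
        sex=np.array(["F"] * n), populations=[name] * n,
        regions={name: name},
        loci=[f"L{j + 1}" for j in range(n_loci)],
        x_linked=np.zeros(n_loci, dtype=bool),
        calls=sample)


# --------------------------------------------------------------------------
# COI sequence panel
# --------------------------------------------------------------------------

def simulate_coi_panel(config: SimConfig,
                       seed: int | None = None) -> SequencePanel:
    if not config.coi:
        raise ValueError("config has no COI block")
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 7)
    L = config.coi_sites
    regions_order: list[str] = []
    pool_size: dict[str, int] = {}
    for c in config.coi:
        if c.region not in regions_order:
            regions_order.append(c.region)
        pool_size[c.region] = max(pool_size.get(c.region, 0), len(c.counts))

    total_haps = sum(pool_size.values())
    needed = (total_haps - 1) + (len(regions_order) - 1) * \
        max(config.coi_divergence_steps - 1, 0)
    if needed > L:
        raise ValueError(
            f"{total_haps} haplotypes with divergence "
            f"{config.coi_divergence_steps} need more than {L} sites")

    site_pool = rng.permutation(L)
    site_cursor = 0

    def fresh_sites(k):
        nonlocal site_cursor
        out = site_pool[site_cursor:site_cursor + k]
        site_cursor += k
        return out

    bases = np.array(list("ACGT"))
    root = bases[rng.integers(0, 4, size=L)].copy()

    def mutate(seq, sites):
        s = seq.copy()
        for pos in sites:
            cur = s[pos]
            s[pos] = rng.choice([b for b in "ACGT" if b != cur])
        return s

    pools: dict[str, list[np.ndarray]] = {}
    anchor = root
    for ri, region in enumerate(regions_order):
        base = anchor if ri == 0 else mutate(
            anchor, fresh_sites(config.coi_divergence_steps))
        haps = [base]
        while len(haps) < pool_size[region]:
            parent = haps[rng.integers(0, len(haps))]
            haps.append(mutate(parent, fresh_sites(1)))
        pools[region] = haps

    ids, pops, seqs = [], [], []
    regions = {}
    for c in config.coi:
        regions[c.name] = c.region
        k = 0
        for hi, count in enumerate(c.counts):
            for _ in range(count):
                k += 1
                ids.append(f"{c.name}_{k:03d}")
                pops.append(c.name)
                seqs.append("".join(pools[c.region][hi]))
    return SequencePanel(ids=ids, populations=pops, regions=regions,
                         sequences=seqs)


# --------------------------------------------------------------------------
# wing landmarks
# --------------------------------------------------------------------------

def simulate_landmarks(config: SimConfig,
                       seed: int | None = None) -> LandmarkPanel:
    if not config.landmark_groups:
        raise ValueError("config has no landmark groups")
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 13)
    k = config.landmark_k
    angles = 2 * np.pi * np.arange(k) / k
    base = np.stack([np.cos(angles), np.sin(angles)], axis=1)

    ids, groups, configs = [], [], []
    for name, n in config.landmark_groups:
        offset = config.landmark_offset_scale * rng.standard_normal((k, 2))
        mean_shape = base + offset
        for i in range(n):
            shape = mean_shape + config.landmark_noise_sd * \
                rng.standard_normal((k, 2))
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
            scale = rng.uniform(0.5, 2.0)
            shift = rng.uniform(-5, 5, size=2)
            configs.append(scale * shape @ rot.T + shift)
            ids.append(f"{name}_{i + 1:03d}")
            groups.append(name)
    return LandmarkPanel(ids=ids, groups=groups, configs=np.array(configs))
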