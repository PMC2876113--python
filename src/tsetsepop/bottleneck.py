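"""Heterozygosity-excess bottleneck detection.

For each polymorphic locus the sample expected heterozygosity ``H_E`` is
compared with the heterozygosity ``H_EQ`` expected for a sample of the same
gene count ``n`` carrying the same allele number ``k`` in a population at
mutation-drift equilibrium. Allele number is lost faster than heterozygosity
in a shrinking population, so a recent bottleneck shows up as H_E > H_EQ
across loci; a one-tailed Wilcoxon signed-rank test summarizes the loci. The
signed-rank input is the centred quantile of each locus's H_E within the
simulated equilibrium distribution (symmetric about zero under the null,
unlike the raw, skewed H_E - H_EQ differences), with H_EQ itself reported as
the median of the retained replicates.

``H_EQ`` is estimated by conditional coalescent simulation: the scaled
mutation rate theta is tuned so that E[k | theta, n] = k, equilibrium samples
are drawn, and replicates with exactly k alleles are retained. Under the
infinite-allele model the sample follows the Ewens sampling distribution, so
a Hoppe-urn (Chinese-restaurant) sampler is used directly — no genealogy is
needed, and the retained configuration distribution is theta-free. Under SMM
and TPM an explicit coalescent tree is simulated with stepwise mutations
(TPM: single step with probability 0.7, otherwise a signed geometric
multistep calibrated to variance 30).

A detectable bottleneck must lie between tau1*2*Ne-pb and tau2*2*Ne-pb
generations before sampling (tau1 = 0.1, tau2 = 2.5 for ~10 loci and samples
of 10-30 individuals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panels import GenotypePanel
from .simulate import tpm_multistep_q

__all__ = [
    "BottleneckTestResult", "DetectionWindow", "HeqResult",
    "heq_simulate", "bottleneck_test", "detection_window",
    "ewens_sample_counts", "expected_k_iam", "theta_for_k",
]


@dataclass
class HeqResult:
    k: int
    n: int
    model: str
    heq: float               # median equilibrium heterozygosity (test anchor)
    heq_mean: float          # mean over retained replicates
    n_retained: int
    theta: float
    seed: int
    retained: np.ndarray | None = None   # retained replicate H values


@dataclass
class BottleneckTestResult:
    population: str
    model: str
    per_locus: pd.DataFrame   # locus, k, n, he, heq, diff
    p_value: float            # one-tailed Wilcoxon, H1: H_E > H_EQ
    n_reps: int
    seed: int


@dataclass
class DetectionWindow:
    ne_pb: float
    tau1: float
    tau2: float
    lower: float
    upper: float


class HeqSimulationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# equilibrium samplers
# --------------------------------------------------------------------------

def ewens_sample_counts(n: int, theta: float, n_reps: int, rng
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Hoppe-urn samples under the infinite-allele model.

    Returns ``(k, sum_p2)`` arrays of length ``n_reps``: allele number and
    sum of squared sample frequencies per replicate.
    """
    i = np.arange(n, dtype=float)
    p_new = theta / (theta + i)                  # i = 0 -> always new
    new = rng.random((n_reps, n)) < p_new
    labels = np.zeros((n_reps, n), dtype=np.int32)
    rows = np.arange(n_reps)
    for j in range(1, n):
        pick = rng.integers(0, j, size=n_reps)
        labels[:, j] = np.where(new[:, j], j, labels[rows, pick])
    offs = labels + (rows[:, None] * n).astype(np.int32)
    counts = np.bincount(offs.ravel(), minlength=n_reps * n)
    counts = counts.reshape(n_reps, n)
    k = (counts > 0).sum(axis=1)
    sum_p2 = ((counts / n) ** 2).sum(axis=1)
    return k, sum_p2


def _coalescent_stepwise_counts(n: int, theta: float, model: str, rng,
                                p_single: float = 0.7,
                                variance: float = 30.0
                                ) -> tuple[int, float]:
    """One coalescent sample under SMM/TPM; returns (k, sum_p2)."""
    total = 2 * n - 1
    parent = np.empty(total, dtype=np.int64)
    time = np.zeros(total)
    active = np.arange(n)
    n_active = n
    t = 0.0
    # pre-draw the exponential waiting times for j = n..2 lineages
    js = np.arange(n, 1, -1, dtype=float)
    waits = rng.exponential(2.0 / (js * (js - 1)))
    for step_i, nxt in enumerate(range(n, total)):
        t += waits[step_i]
        i1 = rng.integers(0, n_active)
        i2 = rng.integers(0, n_active - 1)
        if i2 >= i1:
            i2 += 1
        a, b = active[i1], active[i2]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        # swap-pop the two merged lineages, append the new one
        lo, hi = (i1, i2) if i1 < i2 else (i2, i1)
        active[hi] = active[n_active - 1]
        active[lo] = nxt
        n_active -= 1
    root = total - 1
    # mutations per branch, drawn in one shot
    nodes = np.arange(total - 1)                       # all but the root
    blen = time[parent[nodes]] - time[nodes]
    muts = rng.poisson(theta / 2.0 * blen)
    steps = np.zeros(total, dtype=np.int64)
    m_total = int(muts.sum())
    if m_total:
        signs = rng.choice((-1, 1), size=m_total)
        if model == "SMM":
            mags = signs
        else:                                          # TPM
            q = tpm_multistep_q(variance)
            single = rng.random(m_total) < p_single
            mags = signs * np.where(single, 1,
                                    rng.geometric(1 - q, size=m_total))
        owner = np.repeat(nodes, muts)
        np.add.at(steps, owner, mags)
    state = np.zeros(total, dtype=np.int64)
    for node in range(total - 2, -1, -1):              # parents have larger ids
        state[node] = state[parent[node]] + steps[node]
    leaves = state[:n]
    _, counts = np.unique(leaves, return_counts=True)
    return len(counts), float(((counts / n) ** 2).sum())


def expected_k_iam(theta: float, n: int) -> float:
    return float((theta / (theta + np.arange(n))).sum())


_theta_cache: dict[tuple, float] = {}


def theta_for_k(k: int, n: int, model: str, p_single: float = 0.7,
                variance: float = 30.0) -> float:
    """Scaled mutation rate with E[allele number] = k for a sample of n genes.

    Exact bisection under IAM; pilot-simulation bisection (deterministic
    internal seeds) under SMM/TPM.
    """
    key = (k, n, model, p_single, variance)
    if key in _theta_cache:
        return _theta_cache[key]
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    lo, hi = 1e-4, 1e4
    if model == "IAM":
        f = lambda th: expected_k_iam(th, n) - k
    else:
        pilot = 120

        def f(th, _n=n):
            rng = np.random.default_rng(
                abs(hash((round(np.log(th), 6), _n, model))) % (2 ** 31))
            ks = [_coalescent_stepwise_counts(_n, th, model, rng, p_single,
                                              variance)[0]
                  for _ in range(pilot)]
            return float(np.mean(ks)) - k
    if f(lo) > 0:
        theta = lo
    elif f(hi) < 0:
        theta = hi
    else:
        for _ in range(40 if model == "IAM" else 14):
            mid = np.sqrt(lo * hi)
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        theta = np.sqrt(lo * hi)
    _theta_cache[key] = float(theta)
    return float(theta)


def heq_simulate(k: int, n: int, model: str = "IAM", n_reps: int = 1000,
                 seed: int = 0, p_single: float = 0.7,
                 variance: float = 30.0, max_iter: int = 400_000) -> HeqResult:
    """Equilibrium heterozygosity for samples of n genes with exactly k
    alleles (unbiased estimator n/(n-1) (1 - sum p^2) over retained
    replicates).

    The reference value ``heq`` anchoring the one-tailed Wilcoxon is the
    median of the retained replicates: the conditional heterozygosity
    distribution is left-skewed, so anchoring at the mean would make
    P(H_E > H_EQ) exceed one half at equilibrium and inflate the test's
    type-I error; the replicate mean is reported alongside as ``heq_mean``.
    """
    if not 2 <= k <= n or n < 4:
        raise ValueError(f"invalid (k={k}, n={n})")
    theta = theta_for_k(k, n, model, p_single, variance)
    rng = np.random.default_rng(seed)
    retained: list[float] = []
    simulated = 0
    while len(retained) < n_reps and simulated < max_iter:
        if model == "IAM":
            batch = max(4 * n_reps, 512)
            ks, sp2 = ewens_sample_counts(n, theta, batch, rng)
            hit = ks == k
            retained.extend((n / (n - 1) * (1.0 - sp2[hit])).tolist())
            simulated += batch
        else:
            ks, sp2 = _coalescent_stepwise_counts(n, theta, model, rng,
                                                  p_single, variance)
            if ks == k:
                retained.append(n / (n - 1) * (1.0 - sp2))
            simulated += 1
    if len(retained) < n_reps:
        raise HeqSimulationError(
            f"could not retain {n_reps} equilibrium samples with k={k}, "
            f"n={n} under {model} within {max_iter} simulations")
    retained = np.asarray(retained[:n_reps])
    return HeqResult(k=k, n=n, model=model, heq=float(np.median(retained)),
                     heq_mean=float(retained.mean()),
                     n_retained=len(retained), theta=theta, seed=seed,
                     retained=retained)


# --------------------------------------------------------------------------
# the test
# --------------------------------------------------------------------------

def _locus_kn_he(panel: GenotypePanel, locus: int, idx: np.ndarray
                 ) -> tuple[int, int, float]:
    counts = panel.allele_counts(locus, individuals=idx)
    n = sum(counts.values())
    k = len(counts)
    if n < 2 or k < 2:
        return k, n, np.nan
    p = np.array(list(counts.values()), dtype=float) / n
    he = n / (n - 1) * (1.0 - (p ** 2).sum())
    return k, n, float(he)


def bottleneck_test(panel: GenotypePanel, population: str,
                    model: str = "IAM", n_reps: int = 1000, seed: int = 0,
                    p_single: float = 0.7, variance: float = 30.0
                    ) -> BottleneckTestResult:
    """One-tailed Wilcoxon heterozygosity-excess test for one population.

    Loci with fewer than 2 alleles are excluded; at least 4 polymorphic loci
    are required for the signed-rank test to have resolution. Gene counts at
    X-linked loci count hemizygous males once.
    """
    idx = panel.individuals_in(population)
    if idx.size == 0:
        raise ValueError(f"unknown population {population!r}")
    rng = np.random.default_rng(seed)
    heq_cache: dict[tuple[int, int], HeqResult] = {}
    rows = []
    for l, name in enumerate(panel.loci):
        k, n, he = _locus_kn_he(panel, l, idx)
        if not np.isfinite(he) or k < 2 or n < 4:
            continue
        key = (k, n)
        if key not in heq_cache:
            heq_cache[key] = heq_simulate(
                k, n, model, n_reps, seed=int(rng.integers(2 ** 31)),
                p_single=p_single, variance=variance)
        hr = heq_cache[key]
        # probability-integral position of H_E in the equilibrium
        # distribution (midranks for ties): symmetric about 1/2 under H0
        ret = hr.retained
        u = ((ret < he).sum() + 0.5 * (ret == he).sum() + 0.5) \
            / (len(ret) + 1)
        rows.append({"locus": name, "k": k, "n": n, "he": he, "heq": hr.heq,
                     "diff": he - hr.heq, "u": u})
    if len(rows) < 4:
        raise ValueError("need >= 4 polymorphic loci for the Wilcoxon test")
    table = pd.DataFrame(rows).set_index("locus")
    d = table["u"].to_numpy() - 0.5
    method = "exact" if len(d) <= 25 and (d != 0).all() else "approx"
    res = stats.wilcoxon(d, alternative="greater", method=method)
    return BottleneckTestResult(population=population, model=model,
                                per_locus=table, p_value=float(res.pvalue),
                                n_reps=n_reps, seed=seed)


def detection_window(ne_pb: float, tau1: float = 0.1, tau2: float = 2.5
                     ) -> DetectionWindow:
    """Generations-before-sampling window in which a crash to ``ne_pb`` is
    detectable by the heterozygosity-excess signal."""
    if ne_pb <= 0:
        raise ValueError("Ne must be positive")
    return DetectionWindow(ne_pb=ne_pb, tau1=tau1, tau2=tau2,
                           lower=tau1 * 2 * ne_pb, upper=tau2 * 2 * ne_pb)
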