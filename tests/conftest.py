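import numpy as np
import pytest

from tsetsepop.panels import GenotypePanel, SequencePanel
from tsetsepop.simulate import (LocusSpec, PopulationSpec, SimConfig,
                                simulate_microsat_panel, study_config)


def make_panel(calls, pops, sex=None, x_linked=None, loci=None, regions=None):
    """Small helper: build a GenotypePanel from nested call lists."""
    calls = np.asarray(calls, dtype=np.int64)
    n, L = calls.shape[:2]
    if loci is None:
        loci = [f"L{i + 1}" for i in range(L)]
    if x_linked is None:
        x_linked = [False] * L
    if sex is None:
        sex = ["F"] * n
    if regions is None:
        regions = {p: p for p in set(pops)}
    return GenotypePanel(
        ids=[f"i{k + 1}" for k in range(n)], sex=np.array(sex),
        populations=list(pops), regions=regions, loci=list(loci),
        x_linked=np.array(x_linked), calls=calls)


@pytest.fixture(scope="session")
def study_panel():
    return simulate_microsat_panel(study_config(11), seed=11)


@pytest.fixture(scope="session")
def flat_config():
    """Two regions x two populations, no structure, no nulls."""
    pops = [PopulationSpec("P1", "A", 15, 15), PopulationSpec("P2", "A", 15, 15),
            PopulationSpec("P3", "B", 15, 15), PopulationSpec("P4", "B", 15, 15)]
    loci = [LocusSpec(f"L{i}") for i in range(8)]
    return SimConfig(populations=pops, loci=loci, f_sr=0.0, f_rt=0.0, seed=0)


def random_panel(seed: int) -> GenotypePanel:
    """Randomized valid panel for round-trip property tests."""
    rng = np.random.default_rng(seed)
    n_pops = rng.integers(1, 4)
    L = rng.integers(1, 5)
    x_linked = rng.random(L) < 0.4
    ids, sexes, pops, calls = [], [], [], []
    for p in range(n_pops):
        for i in range(rng.integers(2, 6)):
            sex = "M" if rng.random() < 0.4 else "F"
            ids.append(f"p{p}i{i}")
            sexes.append(sex)
            pops.append(f"pop{p}")
            row = []
            for l in range(L):
                if rng.random() < 0.1:
                    row.append((0, 0))
                elif x_linked[l] and sex == "M":
                    row.append((int(rng.integers(100, 120)), 0))
                else:
                    a, b = sorted(rng.integers(100, 120, size=2))
                    row.append((int(a), int(b)))
            calls.append(row)
    return GenotypePanel(
        ids=ids, sex=np.array(sexes), populations=pops,
        regions={f"pop{p}": ("north" if p % 2 else "south")
                 for p in range(n_pops)},
        loci=[("X" if x else "") + f"loc{l}" for l, x in enumerate(x_linked)],
        x_linked=x_linked, calls=np.array(calls, dtype=np.int64))


def two_haplotype_panel(count_a: int, count_b: int, length: int = 738,
                        pop: str = "Pout") -> SequencePanel:
    """count_a + count_b sequences of two haplotypes one step apart."""
    base = ("ACGT" * (length // 4 + 1))[:length]
    variant = "T" + base[1:] if base[0] != "T" else "G" + base[1:]
    seqs = [base] * count_a + [variant] * count_b
    n = count_a + count_b
    return SequencePanel(ids=[f"s{i}" for i in range(n)],
                         populations=[pop] * n, regions={pop: pop},
                         sequences=seqs)
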