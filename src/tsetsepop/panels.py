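"""Core data containers for the multi-marker pipeline.

Four containers cover the three marker systems and their derived matrices:

* :class:`GenotypePanel` — diploid/hemizygous microsatellite calls with sex,
  population and region labels and per-locus X-linkage flags,
* :class:`SequencePanel` — an aligned mtDNA haplotype panel,
* :class:`LandmarkPanel` — 2-D wing landmark configurations with group labels,
* :class:`DistanceMatrix` — a labelled symmetric matrix tagged with the
  statistic it holds (chord, Kst*, Mahalanobis, ...).

Allele calls are stored as integer allele sizes in an ``(n, L, 2)`` array with
0 meaning "no allele in this slot": ``(0, 0)`` is a missing genotype and
``(a, 0)`` with ``a > 0`` is a hemizygous male call at an X-linked locus.
Storing sizes (not indices) keeps stepwise mutation distances meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = 0

__all__ = [
    "GenotypePanel",
    "SequencePanel",
    "LandmarkPanel",
    "DistanceMatrix",
    "PanelValidationError",
    "MISSING",
]


class PanelValidationError(ValueError):
    """An input violates a container invariant (named in the message)."""


@dataclass
class GenotypePanel:
    ids: list[str]
    sex: np.ndarray            # (n,) array of 'F'/'M'
    populations: list[str]     # per individual
    regions: dict[str, str]    # population -> region
    loci: list[str]
    x_linked: np.ndarray       # (L,) bool
    calls: np.ndarray          # (n, L, 2) int, 0 = empty slot

    def __post_init__(self) -> None:
        self.sex = np.asarray(self.sex, dtype="U1")
        self.x_linked = np.asarray(self.x_linked, dtype=bool)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n, L = len(self.ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise PanelValidationError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)")
        if len(self.populations) != n or self.sex.shape != (n,):
            raise PanelValidationError("per-individual labels mismatch n")
        if self.x_linked.shape != (L,):
            raise PanelValidationError("x_linked flags mismatch locus count")
        missing_regions = set(self.populations) - set(self.regions)
        if missing_regions:
            raise PanelValidationError(
                f"populations without region: {sorted(missing_regions)}")
        if not np.isin(self.sex, ("F", "M")).all():
            raise PanelValidationError("sex must be 'F' or 'M'")
        if (self.calls < 0).any():
            raise PanelValidationError("allele codes must be >= 0")
        # a call (0, a) with a > 0 is malformed: the filled slot comes first
        bad = (self.calls[:, :, 0] == MISSING) & (self.calls[:, :, 1] != MISSING)
        if bad.any():
            i, l = np.argwhere(bad)[0]
            raise PanelValidationError(
                f"half-filled call for {self.ids[i]} at {self.loci[l]}")
        # males never carry two distinct alleles at an X-linked locus; they are
        # stored as single-slot hemizygotes
        males = self.sex == "M"
        if males.any() and self.x_linked.any():
            xcalls = self.calls[np.ix_(males, self.x_linked)]
            two = xcalls[:, :, 1] != MISSING
            if two.any():
                midx = np.where(males)[0]
                lidx = np.where(self.x_linked)[0]
                i, l = np.argwhere(two)[0]
                raise PanelValidationError(
                    "male with diploid call at X-linked locus: "
                    f"{self.ids[midx[i]]} at {self.loci[lidx[l]]}")
        # females are diploid wherever scored
        females = ~males
        if females.any():
            fcalls = self.calls[females]
            hemi = (fcalls[:, :, 0] != MISSING) & (fcalls[:, :, 1] == MISSING)
            if hemi.any():
                fidx = np.where(females)[0]
                i, l = np.argwhere(hemi)[0]
                raise PanelValidationError(
                    f"female single-allele call: {self.ids[fidx[i]]} "
                    f"at {self.loci[l]}")

    # -- basic accessors -----------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    @property
    def region_of_individual(self) -> list[str]:
        return [self.regions[p] for p in self.populations]

    def individuals_in(self, population: str) -> np.ndarray:
        return np.array([i for i, p in enumerate(self.populations)
                         if p == population], dtype=int)

    def subset(self, individuals=None, loci=None) -> "GenotypePanel":
        individuals = (np.arange(self.n_individuals) if individuals is None
                       else np.asarray(individuals))
        if loci is None:
            lidx = np.arange(self.n_loci)
        else:
            name_to_i = {nm: i for i, nm in enumerate(self.loci)}
            lidx = np.array([name_to_i[nm] if isinstance(nm, str) else nm
                             for nm in loci], dtype=int)
        pops = [self.populations[i] for i in individuals]
        return GenotypePanel(
            ids=[self.ids[i] for i in individuals],
            sex=self.sex[individuals],
            populations=pops,
            regions={p: self.regions[p] for p in set(pops)},
            loci=[self.loci[i] for i in lidx],
            x_linked=self.x_linked[lidx],
            calls=self.calls[np.ix_(individuals, lidx)],
        )

    def drop_loci(self, names) -> "GenotypePanel":
        keep = [nm for nm in self.loci if nm not in set(names)]
        return self.subset(loci=keep)

    # -- analysis views ------------------------------------------------
    # X-linked handling follows the study's conventions and differs by
    # analysis: hemizygous males are excluded for inbreeding (f) analyses and
    # coded as homozygous diploids for differentiation/LD analyses.
    def fis_view(self) -> "GenotypePanel":
        """Males set to missing at X-linked loci (for F_IS-based analyses)."""
        calls = self.calls.copy()
        males = self.sex == "M"
        calls[np.ix_(males, self.x_linked)] = MISSING
        out = object.__new__(GenotypePanel)
        out.__dict__.update(self.__dict__)
        out.calls = calls
        return out

    def diff_view(self) -> "GenotypePanel":
        """Hemizygous males coded homozygous (differentiation/LD analyses)."""
        calls = self.calls.copy()
        males = self.sex == "M"
        sub = calls[np.ix_(males, self.x_linked)]
        hemi = (sub[:, :, 0] != MISSING) & (sub[:, :, 1] == MISSING)
        sub[:, :, 1] = np.where(hemi, sub[:, :, 0], sub[:, :, 1])
        calls[np.ix_(males, self.x_linked)] = sub
        out = object.__new__(GenotypePanel)
        out.__dict__.update(self.__dict__)
        out.calls = calls
        return out

    def allele_counts(self, locus: int, individuals=None) -> dict[int, int]:
        """Gene counts per allele (hemizygous males count once)."""
        calls = self.calls[:, locus, :] if individuals is None \
            else self.calls[individuals, locus, :]
        vals = calls[calls != MISSING]
        alleles, counts = np.unique(vals, return_counts=True)
        return dict(zip(alleles.tolist(), counts.tolist()))

    def __eq__(self, other) -> bool:  # content equality, used by round-trips
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (self.ids == other.ids
                and self.populations == other.populations
                and self.regions == other.regions
                and self.loci == other.loci
                and bool((self.sex == other.sex).all())
                and bool((self.x_linked == other.x_linked).all())
                and bool((self.calls == other.calls).all()))


@dataclass
class SequencePanel:
    """Aligned sequences with population/region labels."""

    ids: list[str]
    populations: list[str]
    regions: dict[str, str]
    sequences: list[str]       # uppercase, over A/C/G/T/N/-
    length: int = field(init=False)

    def __post_init__(self) -> None:
        self.sequences = [s.upper() for s in self.sequences]
        if not self.sequences:
            raise PanelValidationError("empty sequence panel")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise PanelValidationError(
                f"ragged alignment: lengths {sorted(lengths)}")
        self.length = lengths.pop()
        if len(self.ids) != len(self.sequences) or \
                len(self.populations) != len(self.sequences):
            raise PanelValidationError("label/sequence count mismatch")
        missing = set(self.populations) - set(self.regions)
        if missing:
            raise PanelValidationError(
                f"populations without region: {sorted(missing)}")
        alphabet = set("ACGTN-")
        for i, s in enumerate(self.sequences):
            extra = set(s) - alphabet
            if extra:
                raise PanelValidationError(
                    f"bad characters {sorted(extra)} in {self.ids[i]}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def subset_populations(self, pops) -> "SequencePanel":
        keep = [i for i, p in enumerate(self.populations) if p in set(pops)]
        return SequencePanel(
            ids=[self.ids[i] for i in keep],
            populations=[self.populations[i] for i in keep],
            regions={p: self.regions[p] for p in pops},
            sequences=[self.sequences[i] for i in keep],
        )

    def complete_sites(self) -> "SequencePanel":
        """Drop every column containing N or a gap in any sequence."""
        arr = np.array([list(s) for s in self.sequences])
        ok = ~np.isin(arr, ("N", "-")).any(axis=0)
        seqs = ["".join(row) for row in arr[:, ok]]
        out = object.__new__(SequencePanel)
        out.ids = list(self.ids)
        out.populations = list(self.populations)
        out.regions = dict(self.regions)
        out.sequences = seqs
        out.length = int(ok.sum())
        return out


@dataclass
class LandmarkPanel:
    """Per-individual k x 2 landmark configurations with group labels."""

    ids: list[str]
    groups: list[str]
    configs: np.ndarray        # (n, k, 2) float

    def __post_init__(self) -> None:
        self.configs = np.asarray(self.configs, dtype=float)
        if self.configs.ndim != 3 or self.configs.shape[2] != 2:
            raise PanelValidationError("configs must be (n, k, 2)")
        n, k, _ = self.configs.shape
        if k < 4:
            raise PanelValidationError("need k >= 4 landmarks")
        if len(self.ids) != n or len(self.groups) != n:
            raise PanelValidationError("label/config count mismatch")
        if not np.isfinite(self.configs).all():
            raise PanelValidationError("non-finite landmark coordinates")

    @property
    def n(self) -> int:
        return self.configs.shape[0]

    @property
    def k(self) -> int:
        return self.configs.shape[1]

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g)
        return list(seen)


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix tagged with the statistic it holds."""

    labels: list[str]
    values: np.ndarray
    statistic: str = "generic"   # chord | kst | mahalanobis | generic

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.labels)
        if self.values.shape != (m, m):
            raise PanelValidationError("matrix size does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise PanelValidationError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise PanelValidationError("diagonal not zero")

    def reorder(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)],
                              self.statistic)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), 1)
        return self.values[iu]
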