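"""Genepop file I/O and allele-frequency summaries.

The Genepop text format stores diploid genotypes for one or more
populations.  Layout: a free-text title line; locus names (one per line,
or comma-separated); populations separated by a line consisting of
``pop`` (any case); individual lines ``id , g1 g2 ...`` where each
genotype concatenates two fixed-width allele codes (2- or 3-digit
dialect).  Allele code ``00``/``000`` marks a missing allele.

This module reduces genotypes to per-population allele counts, sample
sizes and observed-heterozygote tallies — the sufficient statistics for
the allele-matching F_ST moment estimators.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "AlleleFreqTable",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "allele_frequencies",
    "expected_heterozygosity",
]


class GenepopParseError(ValueError):
    """Raised when a file does not follow the Genepop layout."""


@dataclass
class GenotypeTable:
    """Diploid genotypes for an ordered set of populations.

    ``genotypes`` has shape ``(n_individuals, n_loci, 2)`` with positive
    integer allele codes; ``(0, 0)`` marks a missing genotype.  Each
    individual belongs to exactly one population; ``pop_index`` maps
    individual row -> population index.
    """

    populations: list[str]
    individuals: list[list[str]]
    loci: list[str]
    genotypes: np.ndarray
    pop_index: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int32)
        self.pop_index = np.asarray(self.pop_index, dtype=np.int64)
        n_ind = sum(len(ids) for ids in self.individuals)
        if self.genotypes.shape != (n_ind, len(self.loci), 2):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} does not match "
                f"{n_ind} individuals x {len(self.loci)} loci x 2"
            )
        half = (self.genotypes == 0).sum(axis=2) == 1
        if half.any():
            raise ValueError("genotypes must be fully observed or fully missing")

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def population_rows(self, k: int) -> np.ndarray:
        return np.nonzero(self.pop_index == k)[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.populations == other.populations
            and self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.pop_index, other.pop_index)
        )


@dataclass
class AlleleFreqTable:
    """Per-locus, per-population allele counts and sample sizes.

    ``counts[l, k, u]`` is the number of observed copies of allele
    ``allele_codes[u]`` at locus ``l`` in population ``k``; ``n[l, k]``
    is the number of fully typed individuals (2n allele copies).
    ``het[l, k]``, when available, counts observed heterozygotes.
    """

    populations: list[str]
    loci: list[str]
    allele_codes: np.ndarray
    counts: np.ndarray
    n: np.ndarray
    het: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        L, K = len(self.loci), len(self.populations)
        if self.counts.shape != (L, K, len(self.allele_codes)):
            raise ValueError("counts shape mismatch")
        if self.n.shape != (L, K):
            raise ValueError("n shape mismatch")
        if (self.counts.sum(axis=2) != 2 * self.n).any():
            raise ValueError("allele counts do not sum to 2n")

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def frequencies(self) -> np.ndarray:
        """Sample allele frequencies p̃, NaN where a cell is untyped."""
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / (2.0 * self.n[:, :, None])
        p[self.n == 0] = np.nan
        return p


_POP_RE = re.compile(r"^pop\s*$", re.IGNORECASE)


def read_genepop(path, labels: Optional[Sequence[str]] = None) -> GenotypeTable:
    """Read a Genepop file into a :class:`GenotypeTable`.

    The 2- vs 3-digit allele dialect is auto-detected from the genotype
    field width; mixed widths raise :class:`GenepopParseError`.  A
    genotype with any missing allele (code 0) is treated as wholly
    missing.  Population labels default to the Genepop convention (the
    ID of each population's last individual) unless ``labels`` is given.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("empty file")

    # locus names: lines 2.. until the first "pop" delimiter
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        for name in lines[i].split(","):
            name = name.strip()
            if name:
                loci.append(name)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no population delimiter ('pop') found")
    if not loci:
        raise GenepopParseError("no locus names declared")

    pops: list[list[tuple[str, list[str]]]] = []
    current: Optional[list] = None
    digit_width: Optional[int] = None
    for lineno0 in range(i, len(lines)):
        line = lines[lineno0]
        lineno = lineno0 + 1
        if _POP_RE.match(line):
            current = []
            pops.append(current)
            continue
        if not line.strip():
            continue
        if current is None:
            raise GenepopParseError(f"line {lineno}: genotype data before 'pop'")
        if "," not in line:
            raise GenepopParseError(f"line {lineno}: missing ',' after individual ID")
        ind_id, _, geno_part = line.partition(",")
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise GenepopParseError(
                f"line {lineno}: expected {len(loci)} genotypes, found {len(fields)}"
            )
        for f in fields:
            if len(f) not in (4, 6) or not f.isdigit():
                raise GenepopParseError(f"line {lineno}: malformed genotype field {f!r}")
            w = len(f) // 2
            if digit_width is None:
                digit_width = w
            elif w != digit_width:
                raise GenepopParseError(
                    f"line {lineno}: mixed {2 * digit_width}- and {2 * w}-digit "
                    "genotype fields"
                )
        current.append((ind_id.strip(), fields))
    if not pops:
        raise GenepopParseError("zero populations")

    w = digit_width if digit_width is not None else 2
    individuals = [[ind for ind, _ in p] for p in pops]
    n_ind = sum(len(p) for p in pops)
    genotypes = np.zeros((n_ind, len(loci), 2), dtype=np.int32)
    pop_index = np.zeros(n_ind, dtype=np.int64)
    row = 0
    for k, p in enumerate(pops):
        for _, fields in p:
            for l, f in enumerate(fields):
                a1, a2 = int(f[:w]), int(f[w:])
                if a1 == 0 or a2 == 0:
                    a1 = a2 = 0  # partially missing -> wholly missing
                genotypes[row, l] = (a1, a2)
            pop_index[row] = k
            row += 1

    if labels is not None:
        if len(labels) != len(pops):
            raise ValueError("label list length does not match population count")
        pop_labels = list(labels)
    else:
        pop_labels = [p[-1][0] if p else f"pop{k + 1}" for k, p in enumerate(pops)]
    return GenotypeTable(pop_labels, individuals, list(loci), genotypes, pop_index)


def write_genepop(gt: GenotypeTable, path, title: str = "fsttrace export",
                  digits: Optional[int] = None) -> None:
    """Write a :class:`GenotypeTable` as a Genepop file.

    The digit dialect defaults to 2 unless any allele code needs 3.
    """
    max_code = int(gt.genotypes.max(initial=0))
    if digits is None:
        digits = 3 if max_code > 99 else 2
    if max_code >= 10 ** digits:
        raise ValueError(f"allele code {max_code} does not fit {digits} digits")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for name in gt.loci:
            fh.write(name + "\n")
        row = 0
        for k in range(gt.n_populations):
            fh.write("pop\n")
            for ind in gt.individuals[k]:
                gs = (
                    f"{a1:0{digits}d}{a2:0{digits}d}"
                    for a1, a2 in gt.genotypes[row]
                )
                fh.write(f"{ind} , " + " ".join(gs) + "\n")
                row += 1


def allele_frequencies(gt: GenotypeTable) -> AlleleFreqTable:
    """Tally observed allele copies per locus and population.

    Missing genotypes reduce ``n`` for their locus x population cell;
    observed-heterozygote tallies are recorded for the full NC83
    correction.
    """
    if gt.n_loci == 0 or gt.n_populations == 0:
        raise ValueError("empty genotype table")
    codes = np.unique(gt.genotypes)
    codes = codes[codes > 0]
    U = len(codes)
    L, K = gt.n_loci, gt.n_populations
    remap = np.zeros(int(codes.max(initial=0)) + 1, dtype=np.int64)
    remap[codes] = np.arange(U)

    counts = np.zeros((L, K, U), dtype=np.int64)
    n = np.zeros((L, K), dtype=np.int64)
    het = np.zeros((L, K), dtype=np.int64)
    locus_ids = np.arange(L)
    for k in range(K):
        rows = gt.population_rows(k)
        g = gt.genotypes[rows]  # (n_k, L, 2)
        typed = g[:, :, 0] > 0
        n[:, k] = typed.sum(axis=0)
        het[:, k] = (typed & (g[:, :, 0] != g[:, :, 1])).sum(axis=0)
        if typed.any():
            sel = np.broadcast_to(typed[:, :, None], g.shape)
            alleles = remap[g[sel]]
            loci_of = np.broadcast_to(locus_ids[None, :, None], g.shape)[sel]
            flat = np.bincount(loci_of * U + alleles, minlength=L * U)
            counts[:, k, :] = flat.reshape(L, U)
    return AlleleFreqTable(list(gt.populations), list(gt.loci), codes, counts, n, het)


def expected_heterozygosity(af: AlleleFreqTable, unbiased: bool = True) -> pd.Series:
    """Per-population expected heterozygosity (gene diversity).

    He_i averages, over the loci typed in population i, the small-sample
    unbiased gene diversity ``(2n/(2n-1)) * (1 - sum_u p̃_iu^2)``; set
    ``unbiased=False`` for the raw ``1 - sum p̃^2`` form.  A population
    typed at zero loci yields NaN.
    """
    p = af.frequencies()
    with np.errstate(invalid="ignore"):
        h = 1.0 - np.nansum(p**2, axis=2)
    typed = af.n > 0
    if unbiased:
        with np.errstate(invalid="ignore", divide="ignore"):
            h = h * (2.0 * af.n) / (2.0 * af.n - 1.0)
    h = np.where(typed, h, 0.0)
    n_typed = typed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        he = h.sum(axis=0) / n_typed
    he = np.where(n_typed > 0, he, np.nan)
    return pd.Series(he, index=af.populations, name="He")


def heterozygosity_table(af: AlleleFreqTable, unbiased: bool = True) -> pd.DataFrame:
    """TSV-ready table: population, mean typed sample size, He."""
    he = expected_heterozygosity(af, unbiased=unbiased)
    typed = af.n > 0
    with np.errstate(invalid="ignore"):
        n_mean = np.where(
            typed.any(axis=0),
            af.n.sum(axis=0) / np.maximum(typed.sum(axis=0), 1),
            np.nan,
        )
    return pd.DataFrame(
        {"population": af.populations, "n_mean": n_mean, "He": he.values}
    )
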