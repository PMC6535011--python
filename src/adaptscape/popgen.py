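"""Genotype containers, Genepop I/O, locus filtering and F-statistics.

Genotypes are stored as counts of the minor allele (0, 1, 2) per individual
and locus, with ``-1`` marking missing calls — the natural encoding for
biallelic SNPs from reduced-representation sequencing.  Population
differentiation is estimated with the Weir & Cockerham (1984) theta,
combining loci as a ratio of summed variance components, which is the stable
choice for sparse RAD-style data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "FstMatrix",
    "GenepopParseError",
    "MISSING",
    "read_genepop",
    "write_genepop",
    "filter_loci",
    "impute_missing",
    "pairwise_fst",
    "weir_cockerham_theta",
]

MISSING = -1


class GenepopParseError(ValueError):
    """Malformed Genepop input; message carries the offending line number."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid minor-allele counts.

    ``values[i, j]`` in {0, 1, 2} or ``MISSING`` (-1).
    """

    values: np.ndarray
    sample_ids: list[str]
    locus_ids: list[str]
    populations: list[str] | None = None
    coordinates: np.ndarray | None = None  # (n, 2) lon/lat, optional
    imputed_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        n, L = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match genotype rows")
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length does not match genotype columns")
        if len(set(self.locus_ids)) != L:
            raise ValueError("locus_ids must be unique")
        if self.populations is not None and len(self.populations) != n:
            raise ValueError("populations length does not match genotype rows")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    @property
    def genotyping_rate(self) -> float:
        return float(1.0 - self.missing_mask.mean())

    def allele_frequencies(self) -> np.ndarray:
        """Per-locus frequency of the counted (minor) allele, missing excluded."""
        vals = np.ma.masked_equal(self.values, MISSING)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            freq = vals.sum(axis=0) / (2.0 * vals.count(axis=0))
        return np.asarray(freq.filled(np.nan), dtype=float)

    def subset_loci(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:  # locus ids
            pos = {l: i for i, l in enumerate(self.locus_ids)}
            idx = np.array([pos[l] for l in keep], dtype=int)
        return replace(
            self,
            values=self.values[:, idx],
            locus_ids=[self.locus_ids[i] for i in idx],
            imputed_mask=None if self.imputed_mask is None else self.imputed_mask[:, idx],
        )

    def population_sizes(self) -> dict[str, int]:
        if self.populations is None:
            raise ValueError("no population labels")
        out: dict[str, int] = {}
        for p in self.populations:
            out[p] = out.get(p, 0) + 1
        return out


@dataclass
class FstMatrix:
    """Pairwise Weir-Cockerham theta between populations."""

    theta: np.ndarray
    population_ids: list[str]
    per_locus_components: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        k = len(self.population_ids)
        if self.theta.shape != (k, k):
            raise ValueError("theta must be square over populations")
        if not np.allclose(self.theta, self.theta.T, equal_nan=True):
            raise ValueError("theta must be symmetric")

    @property
    def linearized(self) -> np.ndarray:
        """Rousset's theta/(1-theta); denominator clamped at 1e-6."""
        denom = np.maximum(1.0 - self.theta, 1e-6)
        out = self.theta / denom
        np.fill_diagonal(out, 0.0)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=self.population_ids, columns=self.population_ids)


# ---------------------------------------------------------------------------
# Genepop I/O
# ---------------------------------------------------------------------------

def _parse_genotype_token(token: str, lineno: int) -> tuple[int, int]:
    if len(token) == 4:
        w = 2
    elif len(token) == 6:
        w = 3
    else:
        raise GenepopParseError(f"line {lineno}: genotype token {token!r} is not 4 or 6 digits")
    if not token.isdigit():
        raise GenepopParseError(f"line {lineno}: non-numeric genotype token {token!r}")
    return int(token[:w]), int(token[w:])


def read_genepop(path) -> GenotypeMatrix:
    """Read a Genepop file into a :class:`GenotypeMatrix`.

    Accepts 2- and 3-digit allele codes; allele code 0 means missing.
    Biallelic loci are recoded to counts of the minor allele (global
    frequency; ties broken toward the larger allele code).  Loci with more
    than two alleles are excluded with a warning.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("empty Genepop file")
    # title line, then locus names until the first "Pop"
    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        for name in lines[i].replace(",", " ").split():
            locus_ids.append(name)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no 'Pop' separator found")

    sample_ids: list[str] = []
    populations: list[str] = []
    allele_rows: list[list[tuple[int, int]]] = []
    pop_counter = 0
    for lineno, line in enumerate(lines[i:], start=i + 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            pop_counter += 1
            continue
        if "," not in stripped:
            raise GenepopParseError(f"line {lineno}: expected 'name , genotypes'")
        name, geno_part = stripped.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(locus_ids):
            raise GenepopParseError(
                f"line {lineno}: {len(tokens)} genotypes for {len(locus_ids)} loci"
            )
        sample_ids.append(name.strip())
        populations.append(f"pop{pop_counter}")
        allele_rows.append([_parse_genotype_token(t, lineno) for t in tokens])

    if not sample_ids:
        raise GenepopParseError("no individuals found")

    n, L = len(sample_ids), len(locus_ids)
    a1 = np.array([[g[0] for g in row] for row in allele_rows], dtype=int)
    a2 = np.array([[g[1] for g in row] for row in allele_rows], dtype=int)

    values = np.full((n, L), MISSING, dtype=np.int16)
    keep = np.ones(L, dtype=bool)
    for j in range(L):
        called = (a1[:, j] > 0) & (a2[:, j] > 0)
        alleles = np.unique(np.concatenate([a1[called, j], a2[called, j]]))
        if alleles.size > 2:
            warnings.warn(
                f"locus {locus_ids[j]!r} has {alleles.size} alleles; excluded", stacklevel=2
            )
            keep[j] = False
            continue
        if alleles.size == 0:
            continue  # all missing; stays MISSING
        # count the globally rarer allele; tie -> larger code
        counts = {
            a: int((a1[called, j] == a).sum() + (a2[called, j] == a).sum()) for a in alleles
        }
        minor = min(sorted(alleles, reverse=True), key=lambda a: counts[a])
        values[called, j] = (a1[called, j] == minor).astype(int) + (a2[called, j] == minor)

    gm = GenotypeMatrix(values, sample_ids, locus_ids, populations)
    return gm.subset_loci(keep) if not keep.all() else gm


def write_genepop(gm: GenotypeMatrix, path, title: str = "adaptscape export") -> None:
    """Write canonical Genepop with 3-digit allele codes.

    Counts are encoded against alleles 001 (reference) and 002 (counted
    minor allele); missing genotypes become ``000000``.
    """
    if gm.populations is None:
        pops = ["pop1"] * gm.n_individuals
    else:
        pops = list(gm.populations)
    order = sorted(range(gm.n_individuals), key=lambda i: (pops[i],))
    code = {MISSING: "000000", 0: "001001", 1: "001002", 2: "002002"}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in gm.locus_ids:
            fh.write(locus + "\n")
        current = None
        wrote_any = False
        for i in order:
            if pops[i] != current:
                fh.write("Pop\n")
                current = pops[i]
                wrote_any = True
            genos = " ".join(code[int(v)] for v in gm.values[i])
            fh.write(f"{gm.sample_ids[i]} , {genos}\n")
        if not wrote_any:
            raise ValueError("cannot write Genepop with no individuals")


# ---------------------------------------------------------------------------
# Filtering & imputation
# ---------------------------------------------------------------------------

def filter_loci(
    gm: GenotypeMatrix, maf_min: float = 0.0, max_missing: float = 1.0
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Drop loci by minor-allele frequency and missingness.

    Returns the filtered matrix and per-rule drop counts. A locus fails the
    MAF rule when ``min(f, 1-f) < maf_min`` (monomorphic loci fail at any
    ``maf_min > 0``); it fails the missingness rule when the proportion of
    missing calls exceeds ``max_missing``.
    """
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    freq = gm.allele_frequencies()
    maf = np.fmin(freq, 1.0 - freq)
    missingness = gm.missing_mask.mean(axis=0)
    fail_maf = np.isnan(maf) | (maf < maf_min)
    fail_miss = missingness > max_missing
    if maf_min == 0.0:
        fail_maf = np.zeros_like(fail_maf)
    keep = ~(fail_maf | fail_miss)
    report = {
        "n_input": gm.n_loci,
        "dropped_maf": int(fail_maf.sum()),
        "dropped_missing": int(fail_miss.sum()),
        "n_kept": int(keep.sum()),
    }
    return gm.subset_loci(keep), report


def impute_missing(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing genotypes by the per-locus modal genotype.

    Ties are broken toward the lower genotype count, deterministically. The
    returned matrix carries a boolean ``imputed_mask`` flagging filled cells.
    """
    values = gm.values.copy()
    imputed = np.zeros_like(values, dtype=bool)
    for j in range(gm.n_loci):
        col = values[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        called = col[~miss]
        if called.size == 0:
            mode = 0  # fully missing locus: fill with reference genotype
        else:
            counts = np.bincount(called, minlength=3)
            mode = int(np.argmax(counts))  # argmax takes the lowest on ties
        col[miss] = mode
        imputed[:, j] = miss
    return replace(gm, values=values, imputed_mask=imputed)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(
    values: np.ndarray, pop_index: np.ndarray, n_pops: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components (a, b, c).

    ``values`` is individuals x loci with MISSING = -1; ``pop_index`` maps
    individuals to 0..n_pops-1.  Vectorized over loci.
    """
    L = values.shape[1]
    called = values != MISSING
    het = values == 1

    n_ij = np.zeros((n_pops, L))      # genotyped individuals per pop/locus
    p_ij = np.zeros((n_pops, L))      # minor-allele frequency per pop/locus
    h_ij = np.zeros((n_pops, L))      # observed het proportion per pop/locus
    for k in range(n_pops):
        rows = pop_index == k
        c = called[rows]
        n_ij[k] = c.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_ij[k] = np.where(c, values[rows], 0).sum(axis=0) / (2.0 * n_ij[k])
            h_ij[k] = (het[rows] & c).sum(axis=0) / n_ij[k]

    r = n_pops
    n_tot = n_ij.sum(axis=0)
    nbar = n_tot / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_tot - (n_ij**2).sum(axis=0) / n_tot) / (r - 1)
        pbar = (n_ij * p_ij).sum(axis=0) / n_tot
        s2 = (n_ij * (p_ij - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_ij * h_ij).sum(axis=0) / n_tot

        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0)) * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c_comp = hbar / 2.0

    # loci unusable for this comparison (monomorphic across pops, or a pop
    # with <2 genotyped individuals) get NaN components and are skipped
    bad = (nbar < 2) | (n_ij < 2).any(axis=0) | np.isnan(pbar)
    mono = (pbar <= 0) | (pbar >= 1)
    for arr in (a, b, c_comp):
        arr[bad | mono] = np.nan
    return a, b, c_comp


def weir_cockerham_theta(gm: GenotypeMatrix) -> float:
    """Multilocus Weir-Cockerham theta over all populations.

    Ratio of summed variance components: sum(a) / sum(a + b + c) over loci
    with defined components.
    """
    if gm.populations is None:
        raise ValueError("population labels required")
    pop_ids = sorted(set(gm.populations))
    if len(pop_ids) < 2:
        raise ValueError("need at least two populations")
    pop_index = np.array([pop_ids.index(p) for p in gm.populations])
    a, b, c = _wc_components(gm.values, pop_index, len(pop_ids))
    ok = ~np.isnan(a)
    if not ok.any():
        raise ValueError("no polymorphic loci with sufficient data")
    denom = (a + b + c)[ok].sum()
    return float(a[ok].sum() / denom)


def pairwise_fst(gm: GenotypeMatrix) -> FstMatrix:
    """Pairwise multilocus Weir-Cockerham theta between all populations.

    Each pair is estimated from its own two-population variance components;
    negative estimates are preserved (no truncation at zero).
    """
    if gm.populations is None:
        raise ValueError("population labels required")
    pop_ids = sorted(set(gm.populations))
    if len(pop_ids) < 2:
        raise ValueError("need at least two populations")
    sizes = gm.population_sizes()
    for p in pop_ids:
        if sizes[p] < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")
    pops = np.array(gm.populations)
    k = len(pop_ids)
    theta = np.zeros((k, k))
    components: dict[tuple[str, str], np.ndarray] = {}
    for i in range(k):
        for j in range(i + 1, k):
            rows = (pops == pop_ids[i]) | (pops == pop_ids[j])
            sub_index = (pops[rows] == pop_ids[j]).astype(int)
            a, b, c = _wc_components(gm.values[rows], sub_index, 2)
            ok = ~np.isnan(a)
            if not ok.any():
                raise ValueError(
                    f"no usable loci for pair ({pop_ids[i]}, {pop_ids[j]})"
                )
            t = a[ok].sum() / (a + b + c)[ok].sum()
            theta[i, j] = theta[j, i] = t
            components[(pop_ids[i], pop_ids[j])] = np.column_stack([a, b, c])
    return FstMatrix(theta, pop_ids, components)
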