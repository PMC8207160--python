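"""Microsatellite summary statistics.

Observed heterozygosity per individual and population, the Weir & Cockerham
(1984) within-population inbreeding estimator f (F_is), exact
Hardy-Weinberg tests (full enumeration of genotype arrays conditional on
allele counts, or Monte-Carlo shuffling of the allele vector for large
tables), and genotypic linkage-disequilibrium permutation tests.

Genotypes are unordered pairs of positive integer allele sizes; 0 denotes a
missing call.  Missing data are handled by pairwise deletion per locus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeTable",
    "observed_heterozygosity",
    "fis_weir_cockerham",
    "fis_nei",
    "hwe_exact",
    "ld_permutation",
    "HWEResult",
    "HetResult",
]

_LOG_TOL = 1e-9  # tolerance for comparing conditional log-probabilities


class GenotypeTable:
    """Individuals x loci table of unordered allele pairs.

    ``alleles`` is an (n, L, 2) integer array; 0 encodes a missing allele
    (both alleles of a call are missing together).
    """

    def __init__(self, individuals: pd.DataFrame, loci: list[str], alleles: np.ndarray):
        alleles = np.asarray(alleles, dtype=int)
        if alleles.shape != (len(individuals), len(loci), 2):
            raise ValueError("alleles must be (n_individuals, n_loci, 2)")
        if np.any(alleles < 0):
            raise ValueError("allele values must be positive (0 = missing)")
        half_missing = (alleles == 0).sum(axis=2) == 1
        if np.any(half_missing):
            raise ValueError("a call must have both alleles present or both missing")
        if "individual_id" not in individuals or "population" not in individuals:
            raise ValueError("individuals frame needs individual_id and population columns")
        if individuals["population"].isna().any() or (individuals["population"] == "").any():
            raise ValueError("populations must be non-empty")
        self.individuals = individuals.reset_index(drop=True)
        self.loci = list(loci)
        self.alleles = np.sort(alleles, axis=2)  # canonical unordered pairs

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def populations(self) -> list[str]:
        return sorted(self.individuals["population"].unique())

    def subset_population(self, population: str) -> "GenotypeTable":
        mask = (self.individuals["population"] == population).to_numpy()
        return GenotypeTable(self.individuals[mask], self.loci, self.alleles[mask])

    def locus_calls(self, locus: str) -> np.ndarray:
        """(n_typed, 2) allele pairs at a locus, missing individuals dropped."""
        j = self.loci.index(locus)
        calls = self.alleles[:, j, :]
        return calls[calls[:, 0] > 0]

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        out = self.individuals.copy()
        for j, locus in enumerate(self.loci):
            out[f"{locus}_a"] = self.alleles[:, j, 0]
            out[f"{locus}_b"] = self.alleles[:, j, 1]
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeTable":
        loci = [c[:-2] for c in frame.columns if c.endswith("_a")]
        alleles = np.zeros((len(frame), len(loci), 2), dtype=int)
        for j, locus in enumerate(loci):
            alleles[:, j, 0] = frame[f"{locus}_a"].to_numpy()
            alleles[:, j, 1] = frame[f"{locus}_b"].to_numpy()
        return cls(frame[["individual_id", "population"]].copy(), loci, alleles)

    @classmethod
    def from_csv(cls, path) -> "GenotypeTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class HetResult:
    """Observed heterozygosity at individual and population level."""

    individual: pd.DataFrame      # individual_id, population, ho, n_typed
    population: pd.Series         # mean over loci of per-locus Ho
    population_by_locus: pd.DataFrame
    excluded: list[str]           # individuals with no typed locus


def observed_heterozygosity(table: GenotypeTable) -> HetResult:
    """Ho per individual (heterozygous loci / typed loci) and per population
    (mean over loci of heterozygote proportion among typed individuals)."""
    typed = table.alleles[:, :, 0] > 0
    het = typed & (table.alleles[:, :, 0] != table.alleles[:, :, 1])
    n_typed = typed.sum(axis=1)
    excluded = table.individuals.loc[n_typed == 0, "individual_id"].tolist()
    keep = n_typed > 0
    ind = table.individuals.loc[keep, ["individual_id", "population"]].copy()
    ind["ho"] = het[keep].sum(axis=1) / n_typed[keep]
    ind["n_typed"] = n_typed[keep]

    pops = table.populations
    by_locus = pd.DataFrame(index=pops, columns=table.loci, dtype=float)
    for pop in pops:
        mask = (table.individuals["population"] == pop).to_numpy()
        t = typed[mask]
        h = het[mask]
        with np.errstate(invalid="ignore"):
            by_locus.loc[pop] = np.where(t.sum(axis=0) > 0,
                                         h.sum(axis=0) / np.maximum(t.sum(axis=0), 1),
                                         np.nan)
    pop_ho = by_locus.mean(axis=1, skipna=True)
    return HetResult(
        individual=ind.reset_index(drop=True),
        population=pop_ho,
        population_by_locus=by_locus,
        excluded=excluded,
    )


def _wc_components(calls: np.ndarray) -> tuple[float, float] | None:
    """Weir & Cockerham (1984) single-population variance components for one
    locus: returns (sum_b, sum_c) over alleles, or None if monomorphic or
    fewer than two typed individuals."""
    n = calls.shape[0]
    if n < 2:
        return None
    alleles = np.unique(calls)
    if alleles.size < 2:
        return None
    sum_b = sum_c = 0.0
    for a in alleles:
        count = (calls == a).sum()
        p = count / (2.0 * n)
        h = ((calls[:, 0] == a) ^ (calls[:, 1] == a)).mean()  # het prop. for allele a
        b = n / (n - 1.0) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * h)
        c = h / 2.0
        sum_b += b
        sum_c += c
    return sum_b, sum_c


def fis_weir_cockerham(table: GenotypeTable, by_population: bool = True) -> pd.DataFrame:
    """Weir & Cockerham (1984) f estimator of F_is.

    Per locus f = 1 - c/(b+c); the multilocus value combines variance
    components summed over loci and alleles.  Monomorphic population x locus
    combinations are undefined and skipped (NaN in the per-locus column).
    """
    groups = table.populations if by_population else ["_all"]
    rows = []
    for pop in groups:
        sub = table.subset_population(pop) if by_population else table
        per_locus = {}
        tot_b = tot_c = 0.0
        for locus in table.loci:
            comp = _wc_components(sub.locus_calls(locus))
            if comp is None:
                per_locus[locus] = np.nan
                continue
            b, c = comp
            per_locus[locus] = 1.0 - c / (b + c) if (b + c) != 0 else np.nan
            tot_b += b
            tot_c += c
        multi = 1.0 - tot_c / (tot_b + tot_c) if (tot_b + tot_c) != 0 else np.nan
        rows.append({"population": pop, "fis": multi, **per_locus})
    return pd.DataFrame(rows).set_index("population")


def fis_nei(table: GenotypeTable, by_population: bool = True) -> pd.DataFrame:
    """Nei-style 1 - Ho/He per population (multilocus, He with the 2n/(2n-1)
    small-sample correction).  Exposed for comparison with the W&C f."""
    groups = table.populations if by_population else ["_all"]
    rows = []
    for pop in groups:
        sub = table.subset_population(pop) if by_population else table
        ho_sum = he_sum = 0.0
        n_loci = 0
        for locus in table.loci:
            calls = sub.locus_calls(locus)
            n = calls.shape[0]
            if n < 2 or np.unique(calls).size < 2:
                continue
            ho = (calls[:, 0] != calls[:, 1]).mean()
            _, counts = np.unique(calls, return_counts=True)
            p = counts / (2.0 * n)
            he = (2 * n) / (2 * n - 1.0) * (1.0 - (p**2).sum())
            ho_sum += ho
            he_sum += he
            n_loci += 1
        fis = 1.0 - ho_sum / he_sum if he_sum > 0 else np.nan
        rows.append({"population": pop, "fis_nei": fis, "n_loci": n_loci})
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def genotype_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Condense calls to (allele values, symmetric genotype count matrix)."""
    alleles = np.unique(calls)
    idx = {a: i for i, a in enumerate(alleles)}
    g = len(alleles)
    counts = np.zeros((g, g), dtype=int)
    for a, b in calls:
        i, j = sorted((idx[a], idx[b]))
        counts[j, i] += 1  # lower triangle
    return alleles, counts


def _log_conditional_prob(counts: np.ndarray) -> float:
    """Log of the conditional probability of a genotype array given its
    allele counts (the exact-test null distribution)."""
    n = counts.sum()
    het = counts.sum() - np.trace(counts)
    allele_counts = counts.sum(axis=0) + counts.sum(axis=1)  # lower-tri: row+col
    return float(
        gammaln(n + 1)
        + gammaln(allele_counts + 1).sum()
        + het * np.log(2.0)
        - gammaln(2 * n + 1)
        - gammaln(counts[np.tril_indices_from(counts)] + 1).sum()
    )


def _enumerate_arrays(allele_counts: np.ndarray, limit: int | None = None):
    """Yield all symmetric genotype count matrices with the given allele
    counts.  Raises OverflowError when more than ``limit`` arrays exist."""
    g = len(allele_counts)
    pairs = [(j, i) for j in range(g) for i in range(j, -1, -1)]  # (row>=col)
    counts = np.zeros((g, g), dtype=int)
    produced = 0

    def rec(pi: int, rem: np.ndarray):
        nonlocal produced
        if pi == len(pairs):
            if rem.sum() == 0:
                produced += 1
                if limit is not None and produced > limit:
                    raise OverflowError("enumeration limit exceeded")
                yield counts.copy()
            return
        j, i = pairs[pi]
        if i == j:
            # homozygote consumes 2 alleles j; last pair touching allele j in
            # this ordering for row j? allele j also appears in later rows.
            max_n = rem[j] // 2
            for nij in range(max_n + 1):
                counts[j, i] = nij
                rem[j] -= 2 * nij
                yield from rec(pi + 1, rem)
                rem[j] += 2 * nij
            counts[j, i] = 0
        else:
            max_n = min(rem[i], rem[j])
            for nij in range(max_n + 1):
                counts[j, i] = nij
                rem[i] -= nij
                rem[j] -= nij
                yield from rec(pi + 1, rem)
                rem[i] += nij
                rem[j] += nij
            counts[j, i] = 0

    yield from rec(0, allele_counts.copy())


@dataclass
class HWEResult:
    p: float
    method: str            # "enumeration" | "monte-carlo" | "monomorphic"
    n_arrays: int          # arrays enumerated or shuffles performed
    monomorphic: bool = False


def hwe_exact(
    table: GenotypeTable,
    locus: str,
    population: str | None = None,
    method: str = "auto",
    reps: int = 10000,
    seed: int | None = None,
    enumeration_limit: int = 1_000_000,
) -> HWEResult:
    """Exact conditional Hardy-Weinberg test at one locus.

    The p-value is the probability, under the conditional (Levene)
    distribution of genotype arrays given the observed allele counts, of
    arrays no more probable than the observed one.  Full enumeration is used
    when the number of arrays does not exceed ``enumeration_limit``
    (``method="auto"``); otherwise ``reps`` Monte-Carlo shuffles of the
    allele vector are used (Guo-Thompson style).
    """
    sub = table.subset_population(population) if population else table
    calls = sub.locus_calls(locus)
    if calls.shape[0] == 0:
        raise ValueError(f"no typed individuals at {locus}")
    alleles, counts = genotype_counts(calls)
    if len(alleles) < 2:
        return HWEResult(p=1.0, method="monomorphic", n_arrays=0, monomorphic=True)
    allele_counts = counts.sum(axis=0) + counts.sum(axis=1)
    log_obs = _log_conditional_prob(counts)

    if method in ("auto", "enumeration"):
        try:
            limit = None if method == "enumeration" else enumeration_limit
            total = 0.0
            p_mass = 0.0
            n_arrays = 0
            for arr in _enumerate_arrays(allele_counts, limit=limit):
                lp = _log_conditional_prob(arr)
                prob = np.exp(lp)
                total += prob
                if lp <= log_obs + _LOG_TOL:
                    p_mass += prob
                n_arrays += 1
            return HWEResult(p=min(p_mass / total, 1.0), method="enumeration", n_arrays=n_arrays)
        except OverflowError:
            if method == "enumeration":
                raise

    rng = np.random.default_rng(seed)
    allele_vector = np.repeat(np.arange(len(alleles)), allele_counts)
    hits = 0
    g = len(alleles)
    for _ in range(reps):
        perm = rng.permutation(allele_vector)
        a = perm[0::2]
        b = perm[1::2]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        arr = np.zeros((g, g), dtype=int)
        np.add.at(arr, (hi, lo), 1)
        if _log_conditional_prob(arr) <= log_obs + _LOG_TOL:
            hits += 1
    return HWEResult(p=(hits + 1.0) / (reps + 1.0), method="monte-carlo", n_arrays=reps)


# ---------------------------------------------------------------------------
# Linkage disequilibrium


def _g_statistic(codes_a: np.ndarray, codes_b: np.ndarray, na: int, nb: int) -> float:
    """G-type log-likelihood-ratio statistic of the two-locus genotypic
    contingency table."""
    obs = np.zeros(na * nb)
    np.add.at(obs, codes_a * nb + codes_b, 1.0)
    obs = obs.reshape(na, nb)
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    mask = obs > 0
    return float(2.0 * (obs[mask] * np.log(obs[mask] / expected[mask])).sum())


def ld_permutation(
    table: GenotypeTable,
    locus_a: str,
    locus_b: str,
    population: str | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
) -> float:
    """Genotypic linkage-disequilibrium permutation test for a pair of loci.

    The statistic is the G log-likelihood ratio of the two-locus genotype
    contingency table; the null is built by permuting one locus's genotypes
    across individuals.  p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    sub = table.subset_population(population) if population else table
    ja = sub.loci.index(locus_a)
    jb = sub.loci.index(locus_b)
    a = sub.alleles[:, ja, :]
    b = sub.alleles[:, jb, :]
    joint = (a[:, 0] > 0) & (b[:, 0] > 0)
    if joint.sum() < 5:
        raise ValueError("fewer than 5 individuals typed at both loci")
    a = a[joint]
    b = b[joint]
    base = int(max(a.max(), b.max())) + 1
    codes_a, ua = pd.factorize(a[:, 0].astype(np.int64) * base + a[:, 1])
    codes_b, ub = pd.factorize(b[:, 0].astype(np.int64) * base + b[:, 1])
    na, nb = len(ua), len(ub)
    obs = _g_statistic(codes_a, codes_b, na, nb)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes_b)
        if _g_statistic(codes_a, perm, na, nb) >= obs - 1e-12:
            hits += 1
    return (hits + 1.0) / (n_perm + 1.0)


def ld_matrix(
    table: GenotypeTable,
    population: str | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise LD permutation p-values for all locus pairs."""
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(np.nan, index=table.loci, columns=table.loci)
    for la, lb in itertools.combinations(table.loci, 2):
        try:
            p = ld_permutation(
                table, la, lb, population=population, n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
            )
        except ValueError:
            p = np.nan
        out.loc[la, lb] = out.loc[lb, la] = p
    return out
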