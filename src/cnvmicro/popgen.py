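"""Per-individual nucleotide-diversity estimators.

Two estimators computed from a biallelic genotype matrix over a region
of effective length L:

* ``atajima`` — the count of variant sites the focal individual carries
  (dosage >= 1), per nucleotide.
* ``rtajima`` — Tajima's pi restricted to the sites the individual
  carries, with each frequency class inverse-weighted by the
  hypergeometric probability that a diploid individual samples an allele
  segregating at population count i:

      theta_hat = C(n,2)^-1 * sum_i i (n - i) xi_i
                  * [1 - C(n-i,2)/C(n,2)]^-1  / L

  where n is the number of chromosomes (2 x individuals) and xi_i the
  number of carried sites whose population alternate-allele count is i.
  The correction exactly inverts the per-site carry probability
  1 - C(n-i,2)/C(n,2), so averaging rtajima over individuals is an
  unbiased estimate of the population nucleotide diversity pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IndividualSpectrum",
    "individual_spectrum",
    "atajima",
    "rtajima",
    "population_pi",
    "popgen_table",
]


@dataclass
class IndividualSpectrum:
    """Individual-conditioned site-frequency spectrum.

    ``xi[i - 1]`` counts the sites at population alternate-allele count i
    (i = 1..n-1) that the focal individual carries with dosage >= 1.
    """

    individual: str
    n: int                  # chromosomes in the population (2 x individuals)
    xi: np.ndarray          # length n - 1
    L: float                # effective length in bp

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("effective length L must be positive")
        if len(self.xi) != self.n - 1:
            raise ValueError("xi must have one entry per count 1..n-1")


def _alt_counts(genotypes: pd.DataFrame, folded: bool) -> np.ndarray:
    counts = genotypes.sum(axis=0).to_numpy(dtype=int)
    if folded:
        n = 2 * genotypes.shape[0]
        counts = np.minimum(counts, n - counts)
    return counts


def individual_spectrum(genotypes: pd.DataFrame, individual: str, L: float,
                        folded: bool = False) -> IndividualSpectrum:
    """Build the carried site-frequency spectrum of one individual.

    Sites monomorphic in the population (count 0 or n) are ignored.  With
    ``folded=True`` counts use the minor allele instead of the alternate.
    """
    n = 2 * genotypes.shape[0]
    if n < 4:
        raise ValueError("need at least two individuals (n >= 4 chromosomes)")
    if L <= 0:
        raise ValueError("effective length L must be positive")
    counts = _alt_counts(genotypes, folded)
    carried = genotypes.loc[individual].to_numpy(dtype=int) >= 1
    xi = np.zeros(n - 1, dtype=int)
    seg = (counts >= 1) & (counts <= n - 1) & carried
    np.add.at(xi, counts[seg] - 1, 1)
    return IndividualSpectrum(individual=str(individual), n=n, xi=xi, L=float(L))


def atajima(spectrum: IndividualSpectrum) -> float:
    """Variants carried by the individual, per nucleotide."""
    return float(spectrum.xi.sum() / spectrum.L)


def _choose2(m: np.ndarray | int) -> np.ndarray | float:
    m = np.asarray(m, dtype=float)
    return np.where(m >= 2, m * (m - 1) / 2.0, 0.0)


def rtajima(spectrum: IndividualSpectrum) -> float:
    """Hypergeometric-corrected per-individual nucleotide diversity."""
    n = spectrum.n
    if n < 4:
        raise ValueError("estimator requires n >= 4 chromosomes")
    i = np.arange(1, n, dtype=float)
    cn2 = n * (n - 1) / 2.0
    carry_prob = 1.0 - _choose2(n - i) / cn2
    # a carried site always has carry probability > 0 (i >= 1)
    weights = i * (n - i) / carry_prob
    return float(np.sum(weights * spectrum.xi) / cn2 / spectrum.L)


def population_pi(genotypes: pd.DataFrame, L: float,
                  folded: bool = False) -> float:
    """Population nucleotide diversity pi per nucleotide.

    pi = C(n,2)^-1 sum_sites i (n - i) over segregating sites with
    alternate count i; equal to the mean pairwise difference between
    chromosomes, divided by L.
    """
    if L <= 0:
        raise ValueError("effective length L must be positive")
    n = 2 * genotypes.shape[0]
    counts = _alt_counts(genotypes, folded).astype(float)
    seg = (counts >= 1) & (counts <= n - 1)
    cn2 = n * (n - 1) / 2.0
    return float(np.sum(counts[seg] * (n - counts[seg])) / cn2 / L)


def popgen_table(genotypes: pd.DataFrame, L: float,
                 folded: bool = False) -> pd.DataFrame:
    """ATajima and RTajima for every individual, plus n and L columns."""
    rows = {}
    for ind in genotypes.index:
        spec = individual_spectrum(genotypes, ind, L, folded=folded)
        rows[ind] = {"atajima": atajima(spec), "rtajima": rtajima(spec),
                     "n": spec.n, "L": L}
    return pd.DataFrame.from_dict(rows, orient="index")
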