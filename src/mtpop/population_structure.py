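"""Pairwise population differentiation (Fst) for haplotype samples.

Two estimators:

* ``PHI_ST`` — the molecular-variance (AMOVA) form for one pair of
  populations.  Pairwise haplotype difference counts d_ij act as squared
  distances; sums of squared deviations are decomposed into among- and
  within-population components,

      SSD(total)  = sum_{i<j over all N individuals} d_ij / N
      SSD(within) = sum over groups of (within-group pair sum / group size)
      sigma2_w    = SSD(within) / (N - 2)
      sigma2_a    = (SSD(among)/1 - sigma2_w) / n_c,
                    n_c = N - (n1^2 + n2^2)/N
      Phi_st      = sigma2_a / (sigma2_a + sigma2_w)

  The estimate may be negative (an under-dispersed pair); raw values are
  retained, and only the distance-matrix export floors them at zero.

* ``FREQUENCY`` — the haplotype-frequency (Hudson/Nei-style) form
  1 - Hw/Hb, with Hw the mean unbiased within-population heterozygosity
  (n/(n-1) corrected) and Hb the between-population heterozygosity
  1 - sum_h p1(h) p2(h).  Unbiased near the null (a sample against an exact
  copy of itself gives the small negative -1/(n-1)); under a
  Dirichlet-multinomial (Balding–Nichols) divergence model the estimator
  recovers the divergence parameter F in expectation.

Significance comes from the standard permutation null: individuals are
reassigned to the two populations holding sample sizes fixed, and
p = (1 + #{permuted Fst >= observed}) / (n_perm + 1), never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import NumericError, ValidationError
from .haplotype_model import LocusPanel, Mode, PopulationSample, haplotype_distance
from .tree_and_ordination import DistanceMatrix, SignificanceMatrix

logger = logging.getLogger("mtpop.fst")

PHI_ST = "phist"
FREQUENCY = "frequency"


@dataclass(frozen=True)
class FstEstimate:
    value: float
    method: str
    pair: tuple[str, str]


@dataclass(frozen=True)
class PermutationResult:
    p: float
    n_perm: int
    seed: int
    observed: FstEstimate


def _pooled_setup(a: PopulationSample, b: PopulationSample, panel: LocusPanel):
    """Distinct base haplotypes over both samples, their count vectors and
    pairwise difference-count matrix."""
    keyed: dict = {}
    for sample in (a, b):
        for hap, _ in sample.collapse(Mode.BASE):
            keyed.setdefault(hap.key(Mode.BASE), hap)
    haps = list(keyed.values())
    index = {k: i for i, k in enumerate(keyed)}
    K = len(haps)
    D = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            D[i, j] = D[j, i] = haplotype_distance(haps[i], haps[j], panel)
    counts = []
    for sample in (a, b):
        c = np.zeros(K)
        for hap, count in sample.collapse(Mode.BASE):
            c[index[hap.key(Mode.BASE)]] = count
        counts.append(c)
    return haps, counts[0], counts[1], D


def _phist_from_counts(ca: np.ndarray, cb: np.ndarray, D: np.ndarray) -> float:
    n1, n2 = ca.sum(), cb.sum()
    N = n1 + n2
    ct = ca + cb
    ssd_total = ct @ D @ ct / (2 * N)
    ssd_within = ca @ D @ ca / (2 * n1) + cb @ D @ cb / (2 * n2)
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (N - 2)
    n_c = N - (n1 * n1 + n2 * n2) / N  # df_among = 1
    sigma_a = (ssd_among - sigma_w) / n_c
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0  # no molecular variance at all: identical monomorphic pool
    return float(sigma_a / denom)


def _frequency_fst_from_counts(ca: np.ndarray, cb: np.ndarray) -> float:
    n1, n2 = ca.sum(), cb.sum()
    p1, p2 = ca / n1, cb / n2
    # unbiased within-population heterozygosities (n/(n-1) correction)
    h1 = (1.0 - float(p1 @ p1)) * n1 / (n1 - 1)
    h2 = (1.0 - float(p2 @ p2)) * n2 / (n2 - 1)
    hb = 1.0 - float(p1 @ p2)  # unbiased across independent samples
    if hb == 0.0:
        return 0.0  # both populations fixed for the same haplotype
    return float(1.0 - 0.5 * (h1 + h2) / hb)


def _estimate(ca, cb, D, method: str) -> float:
    if method == PHI_ST:
        return _phist_from_counts(ca, cb, D)
    if method == FREQUENCY:
        return _frequency_fst_from_counts(ca, cb)
    raise ValidationError(f"unknown Fst method {method!r}")


def pairwise_fst(
    a: PopulationSample,
    b: PopulationSample,
    panel: LocusPanel,
    method: str = PHI_ST,
) -> FstEstimate:
    """Pairwise Fst between two samples typed on the same panel."""
    if a.n < 2 or b.n < 2:
        raise NumericError("each sample needs n >= 2 for pairwise Fst")
    _, ca, cb, D = _pooled_setup(a, b, panel)
    return FstEstimate(_estimate(ca, cb, D, method), method, (a.name, b.name))


def fst_permutation_p(
    a: PopulationSample,
    b: PopulationSample,
    panel: LocusPanel,
    method: str = PHI_ST,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of population differentiation.

    Individuals are pooled and reassigned at random to two groups of the
    original sizes; p = (1 + #{Fst_perm >= Fst_obs}) / (n_perm + 1).
    Bit-reproducible given (seed, n_perm).
    """
    if n_perm < 1:
        raise NumericError("n_perm must be >= 1")
    _, ca, cb, D = _pooled_setup(a, b, panel)
    observed = _estimate(ca, cb, D, method)
    n1 = int(ca.sum())
    individuals = np.repeat(np.arange(len(ca)), (ca + cb).astype(int))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    K = len(ca)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(individuals)
        ca_p = np.bincount(individuals[:n1], minlength=K).astype(float)
        cb_p = np.bincount(individuals[n1:], minlength=K).astype(float)
        if _estimate(ca_p, cb_p, D, method) >= observed:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PermutationResult(
        p, n_perm, seed, FstEstimate(observed, method, (a.name, b.name))
    )


def fst_matrix(
    samples: Sequence[PopulationSample],
    panel: LocusPanel,
    method: str = PHI_ST,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[DistanceMatrix, SignificanceMatrix]:
    """All pairwise Fst values and permutation p-values.

    Returns the distance matrix with negative estimates floored at zero
    (the raw per-pair values are logged at DEBUG) and the aligned p-value
    matrix.  Each unordered pair gets its own deterministic permutation
    substream derived from ``seed``.
    """
    names = [s.name for s in samples]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate sample names in Fst matrix input")
    if len(samples) < 2:
        raise ValidationError("need at least two samples")
    k = len(samples)
    fst = np.zeros((k, k))
    pval = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            sub_seed = int(
                np.random.SeedSequence(seed, spawn_key=(i, j)).generate_state(1)[0]
                % (2**31)
            )
            res = fst_permutation_p(
                samples[i], samples[j], panel, method, n_perm, sub_seed
            )
            logger.debug(
                "fst(%s, %s) = %.6f, p = %.4f", names[i], names[j], res.observed.value, res.p
            )
            fst[i, j] = fst[j, i] = res.observed.value
            pval[i, j] = pval[j, i] = res.p
    return DistanceMatrix(tuple(names), fst).floored(), SignificanceMatrix(
        tuple(names), pval
    )
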