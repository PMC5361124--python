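"""Synthetic population samples with known statistical structure.

Every estimator in the package is testable without external data through
three generators:

* multinomial sampling of haplotypes from a known frequency spectrum;
* a two-population divergence model at a target fixation index F
  (Balding–Nichols: each population's haplotype frequencies are drawn from
  a Dirichlet with mean p and concentration (1-F)/F, then individuals are
  sampled multinomially);
* additive leaf-to-leaf distance matrices from known trees, the standard
  harness for Neighbor-Joining recovery.

Synthetic haplotype k carries a single variant at generated panel position
k+1, so distinct haplotypes sit at a uniform pairwise distance of 2 and
frequency- and distance-based estimators coincide in expectation.  An
optional tree-structured mode instead assigns variants along a random
genealogy, giving heterogeneous distances for Phi_st-specific tests.

All generators are pure functions of (parameters, seed): a global integer
seed is split into named substreams, so replays are bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .errors import NumericError, ParseError, ValidationError
from .haplotype_model import (
    Haplotype,
    LocusDef,
    LocusPanel,
    NineBp,
    PopulationSample,
    VariantCall,
)
from .tree_and_ordination import DistanceMatrix

_SIMPLEX_TOL = 1e-12


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),))
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Two-population divergence scenario.

    K distinct haplotypes with ancestral frequencies ``ancestral_freqs``
    (uniform when omitted), divergence ``F`` in (0,1), per-population sample
    sizes, and a panel of ``panel_loci`` generated positions (defaults to K,
    one variant site per haplotype).
    """

    K: int
    F: float
    sample_sizes: tuple[int, int] = (500, 500)
    ancestral_freqs: tuple[float, ...] | None = None
    seed: int = 0
    panel_loci: int | None = None

    def __post_init__(self):
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        if not 0.0 < self.F < 1.0:
            raise ValidationError(f"divergence F must lie in (0, 1), got {self.F}")
        if any(n < 1 for n in self.sample_sizes):
            raise ValidationError("sample sizes must be positive")
        if self.ancestral_freqs is not None:
            p = np.asarray(self.ancestral_freqs, dtype=float)
            if len(p) != self.K:
                raise ValidationError("ancestral_freqs length must equal K")
            _check_simplex(p)

    @property
    def p(self) -> np.ndarray:
        if self.ancestral_freqs is None:
            return np.full(self.K, 1.0 / self.K)
        return np.asarray(self.ancestral_freqs, dtype=float)


def _check_simplex(p: np.ndarray) -> None:
    if np.any(p < 0) or abs(float(p.sum()) - 1.0) > _SIMPLEX_TOL:
        raise ValidationError(
            f"frequencies must be a probability simplex (sum {float(p.sum())!r})"
        )


def synthetic_panel(n_loci: int) -> LocusPanel:
    """A generated substitution panel: positions 1..n_loci, ref A, alt G."""
    return LocusPanel(
        tuple(LocusDef(i + 1, "A", ("A", "G")) for i in range(n_loci))
    )


def synthetic_haplotypes(K: int, panel: LocusPanel | None = None) -> list[Haplotype]:
    """K haplotypes, the k-th carrying the single variant at position k+1."""
    panel = panel or synthetic_panel(K)
    if panel.site_count < K:
        raise ValidationError("panel has fewer loci than haplotypes")
    out = []
    for k in range(K):
        pos = panel.positions[k]
        alt = panel.locus(pos).alt_alleles[0]
        out.append(Haplotype(frozenset({VariantCall(pos, alt)}), NineBp.UNSPECIFIED, None))
    return out


def tree_structured_haplotypes(
    K: int, seed: int = 0
) -> tuple[list[Haplotype], LocusPanel]:
    """K haplotypes whose variant sets accumulate along a random genealogy.

    A random binary coalescent-style topology over K tips is built; every
    edge contributes one unique variant position, and each haplotype carries
    the variants on its root path, so pairwise distances equal tree path
    lengths (heterogeneous, unlike the flat default encoding).
    """
    rng = substream(seed, "tree-haplotypes")
    nodes = [{i} for i in range(K)]  # tip sets
    edges: list[tuple[frozenset, int]] = []  # (tips below edge, position)
    pos = 1
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = nodes[i] | nodes[j]
        for part in (nodes[i], nodes[j]):
            edges.append((frozenset(part), pos))
            pos += 1
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    panel = synthetic_panel(pos - 1)
    haps = []
    for tip in range(K):
        calls = frozenset(
            VariantCall(p, panel.locus(p).alt_alleles[0])
            for part, p in edges
            if tip in part
        )
        haps.append(Haplotype(calls, NineBp.UNSPECIFIED, None))
    return haps, panel


def multinomial_sample(
    p: Sequence[float],
    n: int,
    seed: int = 0,
    name: str = "sim",
    haplotypes: Sequence[Haplotype] | None = None,
) -> PopulationSample:
    """Multinomial draw of ``n`` individuals from spectrum ``p``.

    Haplotypes are materialised as distinct single-variant sets on the
    generated panel (``synthetic_panel(len(p))``) unless supplied.
    Zero-count haplotypes are dropped from the sample (a sample is a
    multiset of observed carriers).
    """
    if n < 1:
        raise NumericError("sample size must be >= 1")
    p = np.asarray(p, dtype=float)
    _check_simplex(p)
    haps = list(haplotypes) if haplotypes is not None else synthetic_haplotypes(len(p))
    if len(haps) != len(p):
        raise ValidationError("haplotype list length must match spectrum length")
    rng = substream(seed, f"multinomial:{name}")
    counts = rng.multinomial(n, p)
    records = tuple(
        (hap, int(c)) for hap, c in zip(haps, counts) if c > 0
    )
    return PopulationSample(name, records)


def divergent_pair(
    config: SimulationConfig,
    haplotypes: Sequence[Haplotype] | None = None,
) -> tuple[PopulationSample, PopulationSample]:
    """Two populations diverged at target F from a shared ancestral spectrum.

    Population-specific haplotype frequencies are Dirichlet draws with mean
    ``config.p`` and concentration (1-F)/F (so the expected
    frequency-method Fst is approximately F), then each population is
    sampled multinomially at its configured size.
    """
    p = config.p
    conc = (1.0 - config.F) / config.F
    alpha = np.maximum(p * conc, 1e-300)  # zero-frequency classes stay (almost) zero
    rng = substream(config.seed, "divergent-pair")
    haps = (
        list(haplotypes) if haplotypes is not None else synthetic_haplotypes(config.K)
    )
    out = []
    for which, n in zip(("A", "B"), config.sample_sizes):
        freqs = rng.dirichlet(alpha)
        counts = rng.multinomial(n, freqs)
        records = tuple((hap, int(c)) for hap, c in zip(haps, counts) if c > 0)
        out.append(PopulationSample(f"pop{which}", records))
    return out[0], out[1]


def random_additive_tree(
    n_leaves: int, seed: int = 0, min_length: float = 0.1, max_length: float = 1.0
) -> str:
    """Random binary tree over leaves L1..Ln with uniform branch lengths,
    as a Newick string — a ground truth for Neighbor-Joining recovery."""
    if n_leaves < 3:
        raise ValidationError("need at least 3 leaves")
    rng = substream(seed, "random-tree")
    nodes = [f"L{i + 1}" for i in range(n_leaves)]

    def bl() -> str:
        return f"{rng.uniform(min_length, max_length):.6f}"

    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        joined = f"({nodes[i]}:{bl()},{nodes[j]}:{bl()})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [joined]
    return f"({nodes[0]}:{bl()},{nodes[1]}:{bl()});"


def additive_matrix_from_tree(
    newick: str, jitter: float = 0.0, seed: int = 0
) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a Newick tree, with optional
    symmetric uniform noise of magnitude ``jitter`` on off-diagonal entries."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise ParseError(f"malformed Newick: {exc}") from None
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = tuple(t.label for t in taxa)
    k = len(labels)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            values[i, j] = values[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    if jitter:
        rng = substream(seed, "matrix-jitter")
        noise = rng.uniform(-jitter, jitter, size=(k, k))
        noise = np.triu(noise, 1)
        values = values + noise + noise.T
        values = np.maximum(values, 0.0)
    return DistanceMatrix(labels, values)
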