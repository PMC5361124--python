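"""Forensic diversity statistics for mtDNA haplotype samples.

Implements the standard summary set reported for forensic mtDNA SNP panels:

* random match probability  P = sum x_i^2, the chance two randomly drawn
  individuals share a haplotype;
* discrimination power      DP = 1 - P;
* haplotype diversity       H = n/(n-1) * (1 - sum x_i^2)  (unbiased form;
  the plug-in form 1 - sum x_i^2 is available via ``unbiased=False``), with
  the usual large-sample variance for its standard error;
* nucleotide diversity      pi = n/(n-1) * sum_{i<j} 2 x_i x_j d_ij / L,
  the average number of differing panel sites between two randomly drawn
  individuals, per site.

All spectrum statistics are computed from exact integer counts (rational
arithmetic) before any rounding, so identities such as P + DP = 1 hold
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from .errors import NumericError, ValidationError
from .haplotype_model import (
    Haplotype,
    LocusPanel,
    Mode,
    PopulationSample,
    Substitution,
    classify_substitution,
    haplotype_distance,
    round_half_up,
)


@dataclass(frozen=True)
class HaplotypeSpectrum:
    """Counts of the distinct haplotypes in a sample (order irrelevant)."""

    counts: tuple[int, ...]

    def __post_init__(self):
        if not self.counts:
            raise ValidationError("empty haplotype spectrum")
        if any(c < 1 for c in self.counts):
            raise ValidationError("spectrum counts must be positive integers")

    @classmethod
    def from_sample(cls, sample: PopulationSample, mode: Mode | str = Mode.BASE):
        return cls(tuple(sample.counts(mode)))

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def frequencies(self) -> tuple[Fraction, ...]:
        n = self.n
        return tuple(Fraction(c, n) for c in self.counts)


def match_probability(spectrum: HaplotypeSpectrum, exact: bool = False):
    """Random match probability P = sum x_i^2 = (sum c_i^2) / n^2."""
    p = Fraction(sum(c * c for c in spectrum.counts), spectrum.n ** 2)
    return p if exact else float(p)


def discrimination_power(spectrum: HaplotypeSpectrum, exact: bool = False):
    """Discrimination power DP = 1 - P; complements match_probability exactly."""
    dp = 1 - match_probability(spectrum, exact=True)
    return dp if exact else float(dp)


def haplotype_diversity(
    spectrum: HaplotypeSpectrum, unbiased: bool = True
) -> tuple[float, float]:
    """Haplotype (gene) diversity H and its standard error.

    H = n/(n-1) * (1 - sum x_i^2) when ``unbiased`` (the convention of
    forensic mtDNA reports), else the plug-in 1 - sum x_i^2.  The standard
    error uses the standard diversity variance

        V(H) = 2/(n(n-1)) * [2(n-2)(S3 - S2^2) + S2 - S2^2]

    with S2 = sum x_i^2, S3 = sum x_i^3.
    """
    n = spectrum.n
    if n < 2:
        raise NumericError("haplotype diversity requires n >= 2")
    s2 = sum(x * x for x in spectrum.frequencies)
    s3 = sum(x ** 3 for x in spectrum.frequencies)
    h = (1 - s2) * (Fraction(n, n - 1) if unbiased else 1)
    var = Fraction(2, n * (n - 1)) * (2 * (n - 2) * (s3 - s2 * s2) + s2 - s2 * s2)
    return float(h), math.sqrt(max(float(var), 0.0))


def mean_pairwise_differences(
    sample: PopulationSample, panel: LocusPanel, unbiased: bool = True
) -> Fraction:
    """Frequency-weighted average count of differing panel sites between two
    randomly drawn individuals: (n/(n-1)) * sum_{i<j} 2 x_i x_j d_ij.

    Exact rational value; base-mode haplotype identity (the 9-bp and (CA)n
    extensions never enter d_ij).
    """
    n = sample.n
    if n < 2:
        raise NumericError("pairwise differences require n >= 2")
    haps = sample.collapse(Mode.BASE)
    total = Fraction(0)
    for i in range(len(haps)):
        hi, ci = haps[i]
        for j in range(i + 1, len(haps)):
            hj, cj = haps[j]
            d = haplotype_distance(hi, hj, panel)
            if d:
                total += 2 * Fraction(ci, n) * Fraction(cj, n) * d
    if unbiased:
        total *= Fraction(n, n - 1)
    return total


def nucleotide_diversity(
    sample: PopulationSample,
    panel: LocusPanel,
    sites: int | str = "panel",
    unbiased: bool = True,
) -> float:
    """Nucleotide diversity pi over the assayed panel.

    ``sites`` selects the per-site denominator L: ``"panel"`` (all assayed
    loci, monomorphic included — the default), ``"polymorphic"`` (segregating
    loci only), or an explicit integer.  The estimator variant used by the
    source software of any given printed table is rarely stated, hence the
    switch.
    """
    if isinstance(sites, str):
        if sites == "panel":
            length = panel.site_count
        elif sites == "polymorphic":
            length = len(polymorphic_positions(sample, panel))
        else:
            raise ValidationError(f"unknown site-count choice {sites!r}")
    else:
        length = int(sites)
    if length < 1:
        raise NumericError("site count for pi must be >= 1")
    return float(mean_pairwise_differences(sample, panel, unbiased) / length)


def polymorphic_positions(sample: PopulationSample, panel: LocusPanel) -> list[int]:
    """Panel positions at which the sample carries more than one allele."""
    out = []
    for locus in panel.loci:
        seen = set()
        for hap, _ in sample.records:
            seen.add(hap.allele_at(locus.position, panel))
            if len(seen) > 1:
                out.append(locus.position)
                break
    return out


def observed_substitutions(
    sample: PopulationSample, panel: LocusPanel
) -> list[tuple[int, str, str, Substitution]]:
    """Distinct (position, ref, alt) substitutions observed in the sample,
    with their transition/transversion class."""
    seen: set[tuple[int, str]] = set()
    for hap, _ in sample.records:
        for v in hap.variants:
            seen.add((v.position, v.allele))
    out = []
    for position, alt in sorted(seen):
        ref = panel.locus(position).ref_allele
        out.append((position, ref, alt, classify_substitution(ref, alt)))
    return out


@dataclass(frozen=True)
class GeneticSummary:
    """The printed-table genetic parameter set for one population sample."""

    name: str
    mode: Mode
    n: int
    n_haplotypes: int
    n_polymorphic_sites: int
    n_indels: int
    haplotype_diversity: float
    haplotype_diversity_se: float
    nucleotide_diversity: float
    match_probability: float
    discrimination_power: float
    singleton_count: int
    modal_count: int
    transition_fraction: float


def summarize(
    sample: PopulationSample,
    panel: LocusPanel,
    mode: Mode | str = Mode.BASE,
    pi_sites: int | str = "panel",
    unbiased: bool = True,
) -> GeneticSummary:
    """Full genetic-parameter summary of a sample on its panel.

    Haplotype counting honours ``mode`` (base = SNP variants only; extended
    additionally separates 9-bp and (CA)n states).  Site-level quantities
    (polymorphic sites, pi, transitions) are substitution-based and identical
    across modes.  ``n_indels`` is 0 by construction: the panel is
    substitution-only and the length polymorphisms are carried as opaque
    extensions, not as sites.
    """
    mode = Mode(mode)
    spectrum = HaplotypeSpectrum.from_sample(sample, mode)
    if spectrum.n >= 2:
        h, se = haplotype_diversity(spectrum, unbiased=unbiased)
        pi = nucleotide_diversity(sample, panel, pi_sites, unbiased)
    else:  # a sample of one individual carries no pairwise information
        h, se, pi = 0.0, 0.0, 0.0
    subs = observed_substitutions(sample, panel)
    n_ts = sum(1 for *_, cls in subs if cls is Substitution.TRANSITION)
    return GeneticSummary(
        name=sample.name,
        mode=mode,
        n=sample.n,
        n_haplotypes=len(spectrum.counts),
        n_polymorphic_sites=len(polymorphic_positions(sample, panel)),
        n_indels=0,
        haplotype_diversity=h,
        haplotype_diversity_se=se,
        nucleotide_diversity=pi,
        match_probability=match_probability(spectrum),
        discrimination_power=discrimination_power(spectrum),
        singleton_count=sum(1 for c in spectrum.counts if c == 1),
        modal_count=max(spectrum.counts),
        transition_fraction=(n_ts / len(subs)) if subs else float("nan"),
    )


def write_summary_table(summary: GeneticSummary) -> str:
    """Serialize a summary in the printed Indexes/Value dialect (4 decimals)."""
    rows = [
        ("No. of haplotypes", str(summary.n_haplotypes)),
        ("No. of polymorphic sites", str(summary.n_polymorphic_sites)),
        ("No. of indels", str(summary.n_indels)),
        (
            "Haplotype diversity",
            f"{round_half_up(summary.haplotype_diversity, 4):.4f} "
            f"± {round_half_up(summary.haplotype_diversity_se, 4):.4f}",
        ),
        ("Nucleotide diversity", f"{round_half_up(summary.nucleotide_diversity, 4):.4f}"),
        ("Random match probability (P)", f"{round_half_up(summary.match_probability, 4):.4f}"),
        ("Discrimination power (DP)", f"{round_half_up(summary.discrimination_power, 4):.4f}"),
    ]
    lines = ["Indexes\tValue"] + [f"{k}\t{v}" for k, v in rows]
    return "\n".join(lines) + "\n"
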