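"""Haplotype data model for an mtDNA SNP panel typed against the rCRS.

A haplotype is represented as the set of positions at which it differs from
the revised Cambridge Reference Sequence (rCRS), written in the conventional
``<position><base>`` notation (e.g. ``16362C``).  Two length polymorphisms
commonly co-typed with such panels — the COII/tRNA-Lys 9-bp deletion and the
D-loop (CA)n dinucleotide repeat — are carried as opaque extensions: they
never enter substitution-based distances but can distinguish otherwise
identical haplotypes ("extended" identity mode).

Coordinates are 1-based rCRS positions throughout.
"""

from __future__ import annotations

import enum
import io
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ParseError, ValidationError

RCRS_LENGTH = 16569
_BASES = frozenset("ACGT")
_PURINES = frozenset("AG")

_TOKEN_RE = re.compile(r"^(\d+)([ACGT])$")


def round_half_up(value, ndigits: int) -> float:
    """Round with ties away from zero, the convention of printed forensic tables.

    Accepts floats or exact :class:`fractions.Fraction` values; the latter are
    rounded without an intermediate binary-float step.
    """
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    exp = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(exp, rounding=ROUND_HALF_UP))


class NineBp(enum.Enum):
    """9-bp deletion state, copied verbatim from input (no interpretation)."""

    NORM = "NORM"
    DEL = "DEL"
    UNSPECIFIED = "NA"


class Substitution(enum.Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"


class Mode(str, enum.Enum):
    """Haplotype identity mode: SNP variants only, or with 9-bp/(CA)n."""

    BASE = "base"
    EXTENDED = "extended"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class VariantCall:
    """A single difference to the rCRS: 1-based position plus observed base."""

    position: int
    allele: str

    def __post_init__(self):
        if not 1 <= self.position <= RCRS_LENGTH:
            raise ValidationError(
                f"position {self.position} outside rCRS coordinates 1..{RCRS_LENGTH}"
            )
        if self.allele not in _BASES:
            raise ValidationError(f"allele {self.allele!r} is not one of A/C/G/T")

    def __str__(self) -> str:
        return f"{self.position}{self.allele}"


@dataclass(frozen=True)
class LocusDef:
    """One assayed rCRS position with its reference and observed alleles."""

    position: int
    ref_allele: str
    observed_alleles: tuple[str, ...]

    def __post_init__(self):
        if not 1 <= self.position <= RCRS_LENGTH:
            raise ValidationError(f"locus position {self.position} outside rCRS")
        if self.ref_allele not in _BASES:
            raise ValidationError(f"bad reference allele {self.ref_allele!r}")
        if self.ref_allele not in self.observed_alleles:
            raise ValidationError(
                f"locus {self.position}: observed alleles must include the reference"
            )
        for a in self.observed_alleles:
            if a not in _BASES:
                raise ValidationError(f"locus {self.position}: bad allele {a!r}")
        if len(set(self.observed_alleles)) != len(self.observed_alleles):
            raise ValidationError(f"locus {self.position}: duplicate alleles")

    @property
    def alt_alleles(self) -> tuple[str, ...]:
        return tuple(a for a in self.observed_alleles if a != self.ref_allele)

    @property
    def is_monomorphic(self) -> bool:
        return len(self.observed_alleles) == 1


@dataclass(frozen=True)
class LocusPanel:
    """Ordered collection of assayed loci (strictly increasing positions)."""

    loci: tuple[LocusDef, ...]
    _by_position: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        positions = [l.position for l in self.loci]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValidationError("panel positions must be strictly increasing")
        object.__setattr__(self, "_by_position", {l.position: l for l in self.loci})

    @property
    def site_count(self) -> int:
        return len(self.loci)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(l.position for l in self.loci)

    def __contains__(self, position: int) -> bool:
        return position in self._by_position

    def locus(self, position: int) -> LocusDef:
        try:
            return self._by_position[position]
        except KeyError:
            raise ValidationError(f"position {position} is not on the panel") from None

    def validate_call(self, call: VariantCall) -> None:
        locus = self.locus(call.position)
        if call.allele == locus.ref_allele:
            raise ValidationError(
                f"{call}: allele equals the panel reference at {call.position}"
            )
        if call.allele not in locus.observed_alleles:
            raise ValidationError(
                f"{call}: allele not among observed alleles "
                f"{'/'.join(locus.observed_alleles)} at {call.position}"
            )


@dataclass(frozen=True)
class Haplotype:
    """A variant-set haplotype with optional 9-bp and (CA)n extensions.

    ``variants`` empty means the rCRS state over the panel.  ``ca_repeats``
    is ``None`` when unspecified.
    """

    variants: frozenset[VariantCall] = frozenset()
    nine_bp: NineBp = NineBp.UNSPECIFIED
    ca_repeats: int | None = None

    def __post_init__(self):
        positions = [v.position for v in self.variants]
        if len(set(positions)) != len(positions):
            raise ValidationError("haplotype carries two alleles at one position")
        if self.ca_repeats is not None and self.ca_repeats < 0:
            raise ValidationError("(CA)n repeat count must be non-negative")

    def allele_at(self, position: int, panel: LocusPanel) -> str:
        """The implied allele at a panel position (reference unless varied)."""
        for v in self.variants:
            if v.position == position:
                return v.allele
        return panel.locus(position).ref_allele

    def allele_map(self) -> dict[int, str]:
        return {v.position: v.allele for v in self.variants}

    def key(self, mode: Mode | str = Mode.BASE):
        """Identity key under the chosen mode (hashable)."""
        if Mode(mode) is Mode.BASE:
            return self.variants
        return (self.variants, self.nine_bp, self.ca_repeats)

    def __str__(self) -> str:
        if not self.variants:
            return "rCRS"
        return ", ".join(str(v) for v in sorted(self.variants))


@dataclass(frozen=True)
class PopulationSample:
    """A named multiset of haplotypes: (haplotype, carrier count) records."""

    name: str
    records: tuple[tuple[Haplotype, int], ...]

    def __post_init__(self):
        if not self.records:
            raise ValidationError(f"sample {self.name!r} has no records")
        seen = set()
        for hap, count in self.records:
            if count < 1:
                raise ValidationError(f"sample {self.name!r}: count {count} < 1")
            k = hap.key(Mode.EXTENDED)
            if k in seen:
                raise ValidationError(
                    f"sample {self.name!r}: duplicate extended haplotype {hap}"
                )
            seen.add(k)

    @property
    def n(self) -> int:
        return sum(c for _, c in self.records)

    def counts(self, mode: Mode | str = Mode.BASE) -> list[int]:
        """Carrier counts of the distinct haplotypes under ``mode``."""
        return [c for _, c in self.collapse(mode)]

    def collapse(self, mode: Mode | str = Mode.BASE) -> list[tuple[Haplotype, int]]:
        """Distinct haplotypes under ``mode``, counts merged, input order kept."""
        merged: dict = {}
        for hap, count in self.records:
            k = hap.key(mode)
            if k in merged:
                merged[k] = (merged[k][0], merged[k][1] + count)
            else:
                merged[k] = (hap, count)
        return list(merged.values())


# ---------------------------------------------------------------------------
# parsing & writing
# ---------------------------------------------------------------------------

def parse_variant_token(token: str) -> VariantCall:
    """Parse a ``<position><base>`` token such as ``16362C``.

    Panel membership is not checked here; that is a separate validation step.
    """
    m = _TOKEN_RE.match(token.strip())
    if not m:
        raise ParseError(f"malformed variant token {token!r}")
    position, allele = int(m.group(1)), m.group(2)
    if position == 0:
        raise ParseError(f"malformed variant token {token!r}: position 0")
    try:
        return VariantCall(position, allele)
    except ValidationError as exc:
        raise ParseError(f"malformed variant token {token!r}: {exc}") from None


def _read_text(source) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str) and "\n" not in source and Path(source).is_file():
        return Path(source).read_text()
    return source


def parse_panel(source) -> LocusPanel:
    """Read a locus panel TSV: columns ``position, ref, alts`` (alts ``/``-joined,
    ``.`` when the locus is monomorphic)."""
    text = _read_text(source)
    try:
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read panel table: {exc}") from None
    required = {"position", "ref", "alts"}
    if not required.issubset(df.columns):
        raise ParseError(f"panel table must have columns {sorted(required)}")
    loci = []
    for _, row in df.iterrows():
        try:
            position = int(row["position"])
        except (TypeError, ValueError):
            raise ParseError(f"bad panel position {row['position']!r}") from None
        alts = () if row["alts"] in (".", "", None) else tuple(str(row["alts"]).split("/"))
        loci.append(LocusDef(position, str(row["ref"]), (str(row["ref"]),) + alts))
    return LocusPanel(tuple(loci))


def parse_haplotype_table(source, panel: LocusPanel, name: str = "sample") -> PopulationSample:
    """Read a haplotype table TSV into a :class:`PopulationSample`.

    Columns: ``haplotype_id, count, variants, nine_bp, ca_repeats``;
    ``variants`` is a comma-separated token list or the literal ``rCRS``;
    ``nine_bp`` one of NORM/DEL/NA; ``ca_repeats`` an integer or NA.
    Variants at positions absent from the panel are rejected.
    """
    text = _read_text(source)
    try:
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, comment="#")
    except Exception as exc:
        raise ParseError(f"cannot read haplotype table: {exc}") from None
    required = {"haplotype_id", "count", "variants", "nine_bp", "ca_repeats"}
    if not required.issubset(df.columns):
        raise ParseError(f"haplotype table must have columns {sorted(required)}")
    if df.empty:
        raise ParseError("haplotype table has no rows")
    records = []
    for idx, row in df.iterrows():
        where = f"row {idx + 2} (haplotype {row['haplotype_id']})"
        try:
            count = int(row["count"])
        except (TypeError, ValueError):
            raise ParseError(f"{where}: bad count {row['count']!r}") from None
        raw = str(row["variants"]).strip()
        if raw == "rCRS":
            variants = frozenset()
        else:
            calls = [parse_variant_token(t) for t in raw.split(",")]
            for call in calls:
                if call.position not in panel:
                    raise ValidationError(
                        f"{where}: position {call.position} is not on the panel"
                    )
                panel.validate_call(call)
            variants = frozenset(calls)
        nine_raw = str(row["nine_bp"]).strip()
        try:
            nine = NineBp(nine_raw) if nine_raw not in ("NA", "nan") else NineBp.UNSPECIFIED
        except ValueError:
            raise ParseError(f"{where}: bad nine_bp state {nine_raw!r}") from None
        ca_raw = str(row["ca_repeats"]).strip()
        if ca_raw in ("NA", "nan", ""):
            ca = None
        else:
            try:
                ca = int(ca_raw)
            except ValueError:
                raise ParseError(f"{where}: bad ca_repeats {ca_raw!r}") from None
        records.append((Haplotype(variants, nine, ca), count))
    try:
        return PopulationSample(name, tuple(records))
    except ValidationError as exc:
        raise ValidationError(f"haplotype table: {exc}") from None


def write_haplotype_table(sample: PopulationSample) -> str:
    """Serialize a sample back to the haplotype-table TSV dialect."""
    lines = ["haplotype_id\tcount\tvariants\tnine_bp\tca_repeats"]
    for i, (hap, count) in enumerate(sample.records, start=1):
        ca = "NA" if hap.ca_repeats is None else str(hap.ca_repeats)
        lines.append(f"{i}\t{count}\t{hap}\t{hap.nine_bp.value}\t{ca}")
    return "\n".join(lines) + "\n"


def write_panel(panel: LocusPanel) -> str:
    lines = ["position\tref\talts"]
    for locus in panel.loci:
        alts = "/".join(locus.alt_alleles) or "."
        lines.append(f"{locus.position}\t{locus.ref_allele}\t{alts}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def classify_substitution(ref: str, alt: str) -> Substitution:
    """Transition (purine<->purine or pyrimidine<->pyrimidine) vs transversion."""
    if ref not in _BASES or alt not in _BASES:
        raise ValidationError(f"bases must be A/C/G/T, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValidationError("reference and alternate allele are identical")
    if (ref in _PURINES) == (alt in _PURINES):
        return Substitution.TRANSITION
    return Substitution.TRANSVERSION


def haplotype_distance(h1: Haplotype, h2: Haplotype, panel: LocusPanel) -> int:
    """Number of panel positions at which two haplotypes' implied alleles differ.

    The 9-bp and (CA)n extensions are excluded.  Because unvaried positions
    share the reference allele, this is the size of the symmetric difference
    of the variant sets, counting positions (not calls) where both haplotypes
    carry different alternate alleles once.
    """
    m1, m2 = h1.allele_map(), h2.allele_map()
    for pos in set(m1) | set(m2):
        if pos not in panel:
            raise ValidationError(f"variant position {pos} is not on the panel")
    return sum(1 for pos in set(m1) | set(m2) if m1.get(pos) != m2.get(pos))


def allele_frequencies(sample: PopulationSample, panel: LocusPanel) -> pd.DataFrame:
    """Per-locus allele counts and frequencies over the sample.

    Returns a tidy frame with columns ``position, allele, count, frequency,
    frequency_rounded`` (half-up, 2 decimals, the printed-table convention).
    Unrounded frequencies at each locus sum to exactly 1.
    """
    n = sample.n
    rows = []
    for locus in panel.loci:
        counts = {a: 0 for a in locus.observed_alleles}
        for hap, count in sample.records:
            counts[hap.allele_at(locus.position, panel)] += count
        for allele, c in counts.items():
            freq = Fraction(c, n)
            rows.append(
                {
                    "position": locus.position,
                    "allele": allele,
                    "count": c,
                    "frequency": float(freq),
                    "frequency_rounded": round_half_up(freq, 2),
                }
            )
    return pd.DataFrame(rows)


def write_frequency_table(freqs: pd.DataFrame) -> str:
    """Serialize allele frequencies in the printed-table dialect
    (``position, alleles, freqs`` with ``/``-joined fields, 2 decimals)."""
    lines = ["position\talleles\tfreqs"]
    for position, group in freqs.groupby("position", sort=True):
        group = group.sort_values("count", ascending=False, kind="stable")
        alleles = "/".join(group["allele"])
        if len(group) == 1:
            vals = "1"
        else:
            vals = "/".join(f"{v:.2f}" for v in group["frequency_rounded"])
        lines.append(f"{position}\t{alleles}\t{vals}")
    return "\n".join(lines) + "\n"


def parse_frequency_table(source) -> pd.DataFrame:
    """Read the printed-dialect frequency table into tidy (position, allele,
    frequency) rows."""
    text = _read_text(source)
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, comment="#")
    rows = []
    for _, row in df.iterrows():
        alleles = str(row["alleles"]).split("/")
        freqs = str(row["freqs"]).split("/")
        if len(alleles) != len(freqs):
            raise ParseError(f"frequency row {row['position']}: allele/freq mismatch")
        for a, f in zip(alleles, freqs):
            rows.append(
                {"position": int(row["position"]), "allele": a, "frequency": float(f)}
            )
    return pd.DataFrame(rows)


def frequency_mismatches(
    computed: pd.DataFrame, reference: pd.DataFrame, decimals: int = 2
) -> list[tuple[int, str, float, float]]:
    """Cross-table consistency check: compare recomputed allele frequencies
    against a reference (printed) table at ``decimals`` places.

    Returns the list of (position, allele, computed, reference) mismatches;
    empty means full agreement.  Mismatches are reported, never silently
    accepted or repaired.
    """
    ref = {
        (int(r.position), r.allele): float(r.frequency)
        for r in reference.itertuples()
    }
    out = []
    for r in computed.itertuples():
        key = (int(r.position), r.allele)
        expected = ref.get(key)
        got = float(r.frequency_rounded)
        if expected is None:
            if r.count > 0:
                out.append((key[0], key[1], got, float("nan")))
            continue
        if got != expected:
            out.append((key[0], key[1], got, expected))
    return out


# ---------------------------------------------------------------------------
# packaged study fixtures
# ---------------------------------------------------------------------------

def _data_text(filename: str) -> str:
    return (resources.files("mtpop") / "data" / filename).read_text()


def load_xibe_panel() -> LocusPanel:
    """The packaged 54-locus Xibe study panel."""
    return parse_panel(_data_text("xibe_panel.tsv"))


def load_xibe_sample(panel: LocusPanel | None = None) -> PopulationSample:
    """The packaged Xibe haplotype table (137 individuals)."""
    panel = panel or load_xibe_panel()
    return parse_haplotype_table(_data_text("xibe_haplotypes.tsv"), panel, name="Xibe")


def load_xibe_reference_frequencies() -> pd.DataFrame:
    """The published per-locus allele frequencies (2-decimal reference table)."""
    return parse_frequency_table(_data_text("xibe_allele_freqs.tsv"))


def xibe_fst_table_text() -> str:
    """Raw text of the packaged 19-population Fst / p-value matrix."""
    return _data_text("fst_table4.tsv")
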