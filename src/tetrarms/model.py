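"""Core domain objects for tetra-primer ARMS-PCR modelling.

Conventions used throughout the package:

* Template coordinates are 1-based and inclusive, always on the top strand.
* Primer sequences are written 5'->3'.
* A *forward* primer is identical to the top strand over its annealing site
  (it anneals to the bottom strand); a *reverse* primer is identical to the
  bottom strand (it anneals to the top strand) and its site is reported by
  top-strand coordinates, with the primer's 3' terminus at ``anneal_left``.
* Mismatch pairs are ordered ``(primer_base, template_base)`` where the
  template base is read from the strand the primer anneals to.
* Positions inside a primer are counted from the 3' end starting at 1
  (the 3'-terminal base is position 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional

from .errors import TetrarmsError

IUPAC_BASES = frozenset("ACGTRYSWKMBDHVN")
#: characters legal in a SequenceRecord (IUPAC nucleotides plus alignment gap)
SEQUENCE_ALPHABET = IUPAC_BASES | {"-"}
CONCRETE_BASES = ("A", "C", "G", "T")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")

#: the four Watson-Crick (primer_base, template_base) pairs
WATSON_CRICK_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


def complement(seq: str) -> str:
    """Base-wise complement of an IUPAC nucleotide string (keeps orientation)."""
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


@dataclass
class SequenceRecord:
    """One named nucleotide sequence (uppercase IUPAC, gaps allowed)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


Strength = Literal["match", "weak", "medium", "strong"]
Role = Literal["outer", "inner"]
Orientation = Literal["forward", "reverse"]


@dataclass(frozen=True)
class DesignedMismatch:
    """A deliberate mispair engineered into a primer.

    ``template_base`` is the base on the strand the primer anneals to, so the
    pair (primer_base, template_base) is never Watson-Crick complementary.
    """

    pos_from_3prime: int
    primer_base: str
    template_base: str

    def __post_init__(self) -> None:
        if self.pos_from_3prime < 1:
            raise ValueError("pos_from_3prime counts from 1 at the 3' terminus")
        for b in (self.primer_base, self.template_base):
            if b not in CONCRETE_BASES:
                raise ValueError(f"mismatch bases must be concrete, got {b!r}")
        if (self.primer_base, self.template_base) in WATSON_CRICK_PAIRS:
            raise ValueError(
                f"{self.primer_base}-{self.template_base} is a Watson-Crick match, "
                "not a designed mismatch"
            )


@dataclass
class PrimerSpec:
    """One oligo of a tetra-primer set.

    ``anneal_left``/``anneal_right`` are filled once the primer is placed on a
    template; until then they are ``None``.
    """

    name: str
    sequence: str
    role: Role
    orientation: Orientation
    anneal_left: Optional[int] = None
    anneal_right: Optional[int] = None
    designed_mismatches: list[DesignedMismatch] = field(default_factory=list)
    tm_c: Optional[float] = None
    target_allele: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(CONCRETE_BASES)
        if bad:
            raise ValueError(
                f"primer {self.name!r} contains non-DNA characters: {sorted(bad)}"
            )
        if self.role not in ("outer", "inner"):
            raise ValueError(f"bad role {self.role!r}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if (self.anneal_left is None) != (self.anneal_right is None):
            raise ValueError("anneal_left/anneal_right must be set together")
        if self.anneal_left is not None:
            if self.anneal_right - self.anneal_left + 1 != len(self.sequence):
                raise ValueError(
                    f"primer {self.name!r}: annealing interval does not match length"
                )
        for mm in self.designed_mismatches:
            if mm.pos_from_3prime > len(self.sequence):
                raise ValueError(
                    f"primer {self.name!r}: mismatch position beyond primer length"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def three_prime_base(self) -> str:
        return self.sequence[-1]

    @property
    def allele(self) -> Optional[str]:
        """Top-strand allele this primer extends on (inner primers only)."""
        if self.role != "inner":
            return None
        if self.orientation == "forward":
            return self.three_prime_base
        return complement(self.three_prime_base)


@dataclass
class DiagnosticSnp:
    """A fixed inter-species difference at one alignment column."""

    position: int
    allele_group1: str
    allele_group2: str
    hybrid_support: Optional[float] = None

    def __post_init__(self) -> None:
        for a in (self.allele_group1, self.allele_group2):
            if a not in CONCRETE_BASES:
                raise ValueError(f"alleles must be concrete bases, got {a!r}")
        if self.allele_group1 == self.allele_group2:
            raise ValueError("diagnostic SNP alleles must differ")
        if self.hybrid_support is not None and not 0.0 <= self.hybrid_support <= 1.0:
            raise ValueError("hybrid_support must lie in [0, 1]")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_group1, self.allele_group2)


@dataclass
class TetraPrimerAssay:
    """Four primers genotyping one SNP locus.

    ``product_o``/``product_a1``/``product_a2`` are the expected sizes of the
    outer-outer control band, the inner-forward x outer-reverse band (allele 1,
    the inner-forward primer's target) and the outer-forward x inner-reverse
    band (allele 2). They may be given directly (e.g. parsed from a published
    table) or derived from primer coordinates.
    """

    locus_id: str
    primers: list[PrimerSpec]
    snp: Optional[DiagnosticSnp] = None
    product_o: Optional[int] = None
    product_a1: Optional[int] = None
    product_a2: Optional[int] = None
    species1: str = "sika"
    species2: str = "red"

    def __post_init__(self) -> None:
        if len(self.primers) != 4:
            raise ValueError(
                f"assay {self.locus_id!r}: expected 4 primers, got {len(self.primers)}"
            )
        roles = {(p.role, p.orientation) for p in self.primers}
        want = {
            ("outer", "forward"),
            ("inner", "forward"),
            ("inner", "reverse"),
            ("outer", "reverse"),
        }
        if roles != want:
            raise ValueError(
                f"assay {self.locus_id!r}: need one primer per role/orientation, "
                f"got {sorted(roles)}"
            )

    def _get(self, role: Role, orientation: Orientation) -> PrimerSpec:
        for p in self.primers:
            if p.role == role and p.orientation == orientation:
                return p
        raise TetrarmsError("unreachable: assay validated at construction")

    @property
    def outer_f(self) -> PrimerSpec:
        return self._get("outer", "forward")

    @property
    def inner_f(self) -> PrimerSpec:
        return self._get("inner", "forward")

    @property
    def inner_r(self) -> PrimerSpec:
        return self._get("inner", "reverse")

    @property
    def outer_r(self) -> PrimerSpec:
        return self._get("outer", "reverse")

    @property
    def allele1(self) -> str:
        """Top-strand allele detected by the inner forward primer."""
        if self.snp is not None:
            return self.snp.allele_group1
        return self.inner_f.three_prime_base

    @property
    def allele2(self) -> str:
        """Top-strand allele detected by the inner reverse primer."""
        if self.snp is not None:
            return self.snp.allele_group2
        return complement(self.inner_r.three_prime_base)

    def sizes(self) -> dict[str, int]:
        """Expected band sizes keyed ``O``/``A1``/``A2``.

        Falls back to primer coordinates when explicit sizes are absent.
        """
        o, a1, a2 = self.product_o, self.product_a1, self.product_a2
        if o is None or a1 is None or a2 is None:
            of, inf = self.outer_f, self.inner_f
            inr, orv = self.inner_r, self.outer_r
            placed = all(
                p.anneal_left is not None for p in (of, inf, inr, orv)
            )
            if not placed:
                raise TetrarmsError(
                    f"assay {self.locus_id!r}: product sizes unknown and primers "
                    "are not placed on a template"
                )
            o = orv.anneal_right - of.anneal_left + 1
            a1 = orv.anneal_right - inf.anneal_left + 1
            a2 = inr.anneal_right - of.anneal_left + 1
        return {"O": int(o), "A1": int(a1), "A2": int(a2)}


@dataclass
class DesignConstraints:
    """Tunable envelope for assay design.

    Sizes are in bp, temperatures in deg C, GC bounds as fractions. Scoring
    weights rank otherwise-valid candidates and need not sum to one.
    """

    product_min: int = 150
    product_max: int = 600
    min_band_separation: int = 60
    inner_len_min: int = 18
    inner_len_max: int = 28
    outer_len_min: int = 18
    outer_len_max: int = 26
    tm_target_c: float = 64.0
    tm_tolerance_c: float = 3.0
    gc_min: float = 0.30
    gc_max: float = 0.70
    scoring: Mapping[str, float] = field(
        default_factory=lambda: {
            "tm_uniformity": 0.4,
            "size_spread": 0.3,
            "gc": 0.2,
            "homopolymer": 0.1,
        }
    )

    def __post_init__(self) -> None:
        if not self.product_min < self.product_max:
            raise ValueError("product_min must be < product_max")
        if self.min_band_separation <= 0:
            raise ValueError("min_band_separation must be positive")


@dataclass(frozen=True)
class SiteMismatch:
    pos_from_3prime: int
    primer_base: str
    template_base: str
    strength: Strength


@dataclass
class BindingSite:
    """One ungapped alignment of a primer against a template.

    ``strand`` is the strand the primer's own sequence matches ("top" means a
    forward-style hit: the primer reads as the top strand and anneals to the
    bottom strand; "bottom" means the reverse-style hit annealing to the top
    strand). Coordinates are top-strand, 1-based, inclusive.
    """

    primer: PrimerSpec
    strand: Literal["top", "bottom"]
    anneal_left: int
    anneal_right: int
    mismatches: list[SiteMismatch]
    effective_tm_c: float
    perfect_tm_c: float

    @property
    def terminal_matched(self) -> bool:
        return all(m.pos_from_3prime != 1 for m in self.mismatches)

    @property
    def n_internal_mismatches(self) -> int:
        return sum(1 for m in self.mismatches if m.pos_from_3prime > 1)


@dataclass(frozen=True)
class Amplicon:
    size: int
    forward_primer: str
    reverse_primer: str
    left: int
    right: int


@dataclass
class AmpliconSet:
    """Predicted products per haplotype plus the merged diploid band set."""

    per_haplotype: dict[str, list[Amplicon]]

    @property
    def band_sizes(self) -> set[int]:
        return {a.size for amps in self.per_haplotype.values() for a in amps}

    def amplicons(self) -> list[Amplicon]:
        return [a for amps in self.per_haplotype.values() for a in amps]


@dataclass
class PcrPolicy:
    """Stringency knobs of the in-silico PCR model.

    ``anneal_margin_c`` sets how far a site's mismatch-penalised effective Tm
    may fall below the programmed annealing temperature before the site is
    considered unable to prime: primers routinely prime below their Tm, so the
    filter targets grossly destabilised sites, not every sub-Tm one.
    ``permissive_temp_threshold_c`` is the temperature below which a weak
    3'-terminal mismatch reads through under the permissive extension rule.
    """

    annealing_temp_c: float = 62.0
    extension_rule: Literal["stringent", "permissive"] = "stringent"
    max_internal_mismatches: int = 3
    tm_penalty_per_mismatch_c: float = 5.0
    min_3prime_exact_run: int = 1
    max_product_bp: int = 2000
    anneal_margin_c: float = 12.0
    permissive_temp_threshold_c: float = 60.0
    # salt/oligo conditions for the effective-Tm model (PCR buffer)
    na_mm: float = 50.0
    mg_mm: float = 2.5
    oligo_nm: float = 200.0

    def __post_init__(self) -> None:
        for name in (
            "max_internal_mismatches",
            "tm_penalty_per_mismatch_c",
            "min_3prime_exact_run",
            "max_product_bp",
            "anneal_margin_c",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.extension_rule not in ("stringent", "permissive"):
            raise ValueError(f"bad extension_rule {self.extension_rule!r}")


GenotypeCategory = Literal[
    "hom_allele1", "hom_allele2", "het", "control_only", "no_amplification"
]
SpeciesReading = Literal["sika", "red", "hybrid", "other_cervid", "invalid"]
Sex = Literal["male", "female", "unknown"]


@dataclass
class GenotypeCall:
    """Genotype of one sample at one locus, read off a gel band pattern."""

    locus_id: str
    bands_present: frozenset[str]
    genotype: GenotypeCategory
    genotype_label: str
    species_reading: str
    unexpected_bands: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "locus_id": self.locus_id,
            "bands_present": sorted(self.bands_present),
            "genotype": self.genotype,
            "genotype_label": self.genotype_label,
            "species_reading": self.species_reading,
            "unexpected_bands": list(self.unexpected_bands),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenotypeCall":
        return cls(
            locus_id=d["locus_id"],
            bands_present=frozenset(d["bands_present"]),
            genotype=d["genotype"],
            genotype_label=d["genotype_label"],
            species_reading=d["species_reading"],
            unexpected_bands=tuple(d.get("unexpected_bands", ())),
        )


@dataclass
class SampleVerdict:
    """Species verdict for one sample across all assayed loci."""

    sample_id: str
    sex: Sex
    calls: dict[str, GenotypeCall]
    concordant: bool
    species_verdict: str
    maternal_lineage: Optional[str] = None
    declared_label: Optional[str] = None
    label_concordant: Optional[bool] = None

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "sex": self.sex,
            "locus_calls": {k: v.to_dict() for k, v in sorted(self.calls.items())},
            "concordant": self.concordant,
            "species_verdict": self.species_verdict,
            "maternal_lineage": self.maternal_lineage,
            "declared_label": self.declared_label,
            "label_concordance": self.label_concordant,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SampleVerdict":
        return cls(
            sample_id=d["sample_id"],
            sex=d["sex"],
            calls={
                k: GenotypeCall.from_dict(v) for k, v in d["locus_calls"].items()
            },
            concordant=d["concordant"],
            species_verdict=d["species_verdict"],
            maternal_lineage=d.get("maternal_lineage"),
            declared_label=d.get("declared_label"),
            label_concordant=d.get("label_concordance"),
        )
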