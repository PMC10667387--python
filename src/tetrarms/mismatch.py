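"""Ordinal mismatch-strength model for allele-specific (ARMS) primers.

ARMS primers discriminate alleles because Taq polymerase cannot extend a
primer whose 3'-terminal base mispairs the template. How refractory extension
is depends on the identity of the mispair: a purine-purine clash like C.C
destabilises the duplex far more than a wobble-prone G.T. The model here is
deliberately ordinal (weak / medium / strong), not thermodynamic: assay
design needs a rank to pick compensating mismatches, not a free energy.

Pairs are ordered ``(primer_base, template_base)`` with the template base read
from the strand the primer anneals to, matching the conventional "C-A",
"G-T", "G-G" notation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping

from .model import CONCRETE_BASES, WATSON_CRICK_PAIRS, Strength

_DEFAULT: dict[tuple[str, str], str] = {}
for _pair in [("G", "T"), ("T", "G"), ("C", "A"), ("A", "C"), ("G", "G")]:
    _DEFAULT[_pair] = "weak"
for _pair in [("A", "A"), ("T", "T"), ("C", "T"), ("T", "C")]:
    _DEFAULT[_pair] = "medium"
for _pair in [("C", "C"), ("G", "A"), ("A", "G")]:
    _DEFAULT[_pair] = "strong"


@dataclass(frozen=True)
class StrengthTable:
    """Total classification of the 12 non-complementary ordered base pairs.

    The default ranks wobble-like pairs (G.T/T.G, C.A/A.C) and the
    self-stacking G.G as weak, pyrimidine-pyrimidine and A.A pairs as medium,
    and C.C plus the purine-purine G.A/A.G clashes as strong. Individual
    entries can be overridden (e.g. from a config file) without touching the
    rest of the table.
    """

    entries: Mapping[tuple[str, str], str]

    def __post_init__(self) -> None:
        expected = {
            p
            for p in product(CONCRETE_BASES, repeat=2)
            if p not in WATSON_CRICK_PAIRS
        }
        got = set(self.entries)
        if got != expected:
            missing = expected - got
            extra = got - expected
            raise ValueError(
                f"strength table must cover exactly the 12 non-complementary "
                f"pairs (missing {sorted(missing)}, extra {sorted(extra)})"
            )
        for pair, s in self.entries.items():
            if s not in ("weak", "medium", "strong"):
                raise ValueError(f"bad strength {s!r} for pair {pair}")

    @classmethod
    def default(cls) -> "StrengthTable":
        return cls(dict(_DEFAULT))

    def override(
        self, triples: Iterable[tuple[str, str, str]]
    ) -> "StrengthTable":
        """Return a new table with the given (primer, template, strength)
        entries replaced; all other pairs keep their classification."""
        entries = dict(self.entries)
        for primer_base, template_base, strength in triples:
            pair = (primer_base.upper(), template_base.upper())
            if pair in WATSON_CRICK_PAIRS:
                raise ValueError(f"{pair} is complementary; cannot assign a strength")
            if pair[0] not in CONCRETE_BASES or pair[1] not in CONCRETE_BASES:
                raise ValueError(f"non-concrete bases in override {pair}")
            entries[pair] = strength
        return StrengthTable(entries)

    def pairs_with_strength(self, strength: str) -> list[tuple[str, str]]:
        return sorted(p for p, s in self.entries.items() if s == strength)


def classify_mismatch(
    primer_base: str,
    template_base: str,
    table: StrengthTable | None = None,
) -> Strength:
    """Classify a primer.template base pairing.

    Returns ``"match"`` for the four Watson-Crick pairs, otherwise the
    table's ordinal strength. Defined on concrete bases only: diploid
    ambiguity codes have no single pairing geometry.
    """
    pb, tb = primer_base.upper(), template_base.upper()
    for b in (pb, tb):
        if b not in CONCRETE_BASES:
            raise ValueError(
                f"classification requires concrete bases, got {b!r}"
            )
    if (pb, tb) in WATSON_CRICK_PAIRS:
        return "match"
    return (table or StrengthTable.default()).entries[(pb, tb)]


@dataclass(frozen=True)
class CompensationPlan:
    """How to reinforce an allele-discriminating 3' mismatch.

    ``secondary_strength`` is the rank of the extra mispair to engineer at a
    3'-proximal position (``positions``, counted from the 3' end); when
    ``allow_5prime_escalation`` is set the design may additionally place a
    weak mismatch at position 5 or 6 from the 5' end to kill residual
    read-through.
    """

    secondary_strength: Strength
    positions: tuple[int, ...] = (2, 3, 4)
    allow_5prime_escalation: bool = False


def required_compensation(allele_mismatch: str) -> CompensationPlan:
    """Compensation rule for a given 3'-terminal allele-mismatch strength.

    A strong terminal clash already blocks well, so only a weak secondary is
    added to curb residual extension; a medium clash gets a medium secondary;
    a weak clash needs a 3'-proximal secondary and may escalate with an extra
    5'-region weak mismatch.
    """
    if allele_mismatch == "strong":
        return CompensationPlan("weak")
    if allele_mismatch == "medium":
        return CompensationPlan("medium")
    if allele_mismatch == "weak":
        return CompensationPlan("weak", allow_5prime_escalation=True)
    raise ValueError(
        f"no compensation defined for allele mismatch {allele_mismatch!r} "
        "(a matched 3' terminus does not discriminate alleles)"
    )
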