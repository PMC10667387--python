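"""Diagnostic-SNP discovery from a two-species multiple alignment.

A column is species-diagnostic when the two species groups are each fixed
for a different concrete base, with no gaps or ambiguity codes inside either
group at that column. Hybrid consensus sequences (Sanger double peaks coded
as IUPAC two-base ambiguities, e.g. Y for C/T) never disqualify a column;
they only contribute to ``hybrid_support``, the fraction of hybrids carrying
exactly the two-base code matching the two species alleles.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values

from .model import CONCRETE_BASES, DiagnosticSnp, SequenceRecord

#: map a frozenset of concrete bases to its IUPAC one-letter code
_CODE_BY_BASESET = {
    frozenset(expansion): code
    for code, expansion in ambiguous_dna_values.items()
    if code != "X"
}

GroupLabel = str  # "group1" | "group2" | "hybrid"


def expand_iupac(code: str) -> set[str]:
    """Concrete bases denoted by one IUPAC nucleotide code (A -> {A})."""
    code = code.upper()
    if len(code) != 1 or code not in ambiguous_dna_values or code == "X":
        raise ValueError(f"invalid IUPAC nucleotide code {code!r}")
    return set(ambiguous_dna_values[code])


def iupac_code_for(bases: set[str] | frozenset[str]) -> str:
    """IUPAC code for a set of concrete bases (inverse of expand_iupac)."""
    key = frozenset(b.upper() for b in bases)
    try:
        return _CODE_BY_BASESET[key]
    except KeyError as exc:
        raise ValueError(f"no IUPAC code for base set {sorted(key)}") from exc


def find_diagnostic_snps(
    alignment: Sequence[SequenceRecord],
    groups: Mapping[str, GroupLabel],
) -> list[DiagnosticSnp]:
    """Scan an alignment for fixed inter-group differences.

    ``groups`` maps sequence id to ``"group1"``, ``"group2"`` or ``"hybrid"``.
    Sequences absent from the mapping are ignored. Returns SNPs sorted by
    position (1-based alignment column). ``hybrid_support`` is ``None`` when
    the alignment contains no hybrid sequences.
    """
    if not alignment:
        raise ValueError("alignment is empty")
    lengths = {len(rec) for rec in alignment}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    (aln_len,) = lengths

    by_label: dict[str, list[SequenceRecord]] = {"group1": [], "group2": [], "hybrid": []}
    for rec in alignment:
        label = groups.get(rec.id)
        if label is None:
            continue
        if label not in by_label:
            raise ValueError(
                f"unknown group label {label!r} for sequence {rec.id!r} "
                "(expected group1/group2/hybrid)"
            )
        by_label[label].append(rec)
    for label in ("group1", "group2"):
        if not by_label[label]:
            raise ValueError(f"no sequences assigned to {label}")

    g1 = [rec.seq for rec in by_label["group1"]]
    g2 = [rec.seq for rec in by_label["group2"]]
    hyb = [rec.seq for rec in by_label["hybrid"]]
    concrete = set(CONCRETE_BASES)

    snps: list[DiagnosticSnp] = []
    for col in range(aln_len):
        b1 = {s[col] for s in g1}
        b2 = {s[col] for s in g2}
        if len(b1) != 1 or len(b2) != 1:
            continue
        (a1,) = b1
        (a2,) = b2
        if a1 not in concrete or a2 not in concrete or a1 == a2:
            continue
        support = None
        if hyb:
            het_code = iupac_code_for({a1, a2})
            support = sum(1 for s in hyb if s[col] == het_code) / len(hyb)
        snps.append(
            DiagnosticSnp(
                position=col + 1,
                allele_group1=a1,
                allele_group2=a2,
                hybrid_support=support,
            )
        )
    return snps
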