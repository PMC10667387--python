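"""Tetra-primer ARMS assay design.

The tetra-primer layout places two allele-specific *inner* primers in
opposite orientations with their 3' termini on the SNP itself, flanked by two
exact-match *outer* control primers. Three products can then form:

* ``O``  — outer-F x outer-R, the allele-independent control band;
* ``A1`` — inner-F x outer-R, present when allele 1 is in the template;
* ``A2`` — outer-F x inner-R, present when allele 2 is in the template.

Because both inner 3' termini coincide at the SNP, the sizes obey the
identity ``A1 + A2 = O + lf + lr - 1`` (lf, lr the inner primer lengths).

Allele specificity comes from the 3'-terminal base (matched on the target
allele, mismatched on the other) reinforced by deliberate secondary
mismatches chosen by strength via :func:`tetrarms.mismatch.required_compensation`.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import DesignError
from .mismatch import StrengthTable, classify_mismatch, required_compensation
from .model import (
    CONCRETE_BASES,
    DesignConstraints,
    DesignedMismatch,
    DiagnosticSnp,
    PcrPolicy,
    PrimerSpec,
    SequenceRecord,
    TetraPrimerAssay,
    complement,
    gc_fraction,
    max_homopolymer_run,
    reverse_complement,
)
from .pcr import simulate_pcr
from .thermo import PCR_BUFFER, melting_temperature


def _tm(seq: str) -> float:
    return melting_temperature(seq, **PCR_BUFFER)


def melting_temperature_c(seq: str) -> float:
    """Design-time Tm (PCR-buffer salt profile)."""
    return _tm(seq)


def _pick_mismatch_base(
    template_base: str, strength: str, table: StrengthTable, avoid: str | None = None
) -> str | None:
    """First base (fixed A<C<G<T order) mispairing ``template_base`` at the
    requested strength; ``avoid`` excludes the base already in the primer."""
    for b in CONCRETE_BASES:
        if b == avoid:
            continue
        if classify_mismatch(b, template_base, table) == strength:
            return b
    return None


def design_inner_primer(
    template: SequenceRecord,
    snp: DiagnosticSnp,
    allele: str,
    orientation: str,
    constraints: DesignConstraints | None = None,
    table: StrengthTable | None = None,
    escalate: bool = False,
) -> PrimerSpec:
    """Design one allele-specific inner primer.

    The 3'-terminal base anneals exactly on the SNP and pairs the target
    ``allele``; against the other allele the terminus mispairs, blocking
    extension. A secondary mismatch is engineered at a 3'-proximal position
    (default 3rd-from-3' for forward primers, 2nd for reverse, falling back
    to any of positions 2-4), with strength given by the compensation rule
    for the terminal allele-mismatch. With ``escalate`` (allowed for weak
    allele mismatches, optional otherwise) an extra weak mismatch is placed
    at position 5 from the 5' end.
    """
    constraints = constraints or DesignConstraints()
    table = table or StrengthTable.default()
    if allele not in snp.alleles:
        raise ValueError(f"allele {allele!r} is not one of the SNP alleles {snp.alleles}")
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"bad orientation {orientation!r}")
    p = snp.position
    top = template.seq
    if not 1 <= p <= len(top):
        raise ValueError(f"SNP position {p} outside template (len {len(top)})")
    other = snp.allele_group2 if allele == snp.allele_group1 else snp.allele_group1

    # strength of the 3'-terminal mispair on the NON-target allele
    if orientation == "forward":
        allele_mm = classify_mismatch(allele, complement(other), table)
    else:
        allele_mm = classify_mismatch(complement(allele), other, table)
    plan = required_compensation(allele_mm)
    preferred = (3, 2, 4) if orientation == "forward" else (2, 3, 4)
    positions = [k for k in preferred if k in plan.positions] or list(plan.positions)

    violations: list[str] = []
    candidates: list[tuple[float, int, PrimerSpec]] = []
    for L in range(constraints.inner_len_min, constraints.inner_len_max + 1):
        if orientation == "forward":
            left, right = p - L + 1, p
        else:
            left, right = p, p + L - 1
        if left < 1 or right > len(top):
            violations.append(f"length {L}: no room to anneal on the template")
            continue
        region = top[left - 1 : right]
        if orientation == "forward":
            bases = list(region)
            bases[-1] = allele
        else:
            bases = list(reverse_complement(region))
            bases[-1] = complement(allele)
        designed: list[DesignedMismatch] = []

        placed = False
        for k in positions:
            idx = L - k  # 0-based primer index of pos k from 3'
            if orientation == "forward":
                tmpl_base = complement(top[(right - k + 1) - 1])
            else:
                tmpl_base = top[(left + k - 1) - 1]
            pb = _pick_mismatch_base(
                tmpl_base, plan.secondary_strength, table, avoid=bases[idx]
            )
            if pb is None:
                continue
            bases[idx] = pb
            designed.append(DesignedMismatch(k, pb, tmpl_base))
            placed = True
            break
        if not placed:
            violations.append(
                f"length {L}: no secondary mismatch of strength "
                f"{plan.secondary_strength!r} placeable at positions {positions}"
            )
            continue

        if escalate:
            k5 = L - 4  # position 5 from the 5' end, counted from 3'
            if k5 <= max(positions) + 1:
                violations.append(f"length {L}: too short for 5' escalation")
                continue
            idx = L - k5
            if orientation == "forward":
                tmpl_base = complement(top[(right - k5 + 1) - 1])
            else:
                tmpl_base = top[(left + k5 - 1) - 1]
            pb = _pick_mismatch_base(tmpl_base, "weak", table, avoid=bases[idx])
            if pb is None:
                violations.append(f"length {L}: no weak 5'-region mismatch available")
                continue
            bases[idx] = pb
            designed.append(DesignedMismatch(k5, pb, tmpl_base))

        seq = "".join(bases)
        tm = _tm(seq)
        gc = gc_fraction(seq)
        if abs(tm - constraints.tm_target_c) > constraints.tm_tolerance_c:
            violations.append(f"length {L}: Tm {tm:.1f} C outside target band")
            continue
        if not constraints.gc_min <= gc <= constraints.gc_max:
            violations.append(f"length {L}: GC {gc:.2f} outside bounds")
            continue
        primer = PrimerSpec(
            name=f"In-{'F' if orientation == 'forward' else 'R'}{left if orientation == 'forward' else right}",
            sequence=seq,
            role="inner",
            orientation=orientation,
            anneal_left=left,
            anneal_right=right,
            designed_mismatches=designed,
            tm_c=tm,
            target_allele=allele,
        )
        candidates.append((abs(tm - constraints.tm_target_c), L, primer))

    if not candidates:
        raise DesignError(
            f"no inner {orientation} primer satisfies the constraints at "
            f"position {p}",
            violations=violations,
        )
    candidates.sort(key=lambda t: (t[0], t[1]))
    return candidates[0][2]


def _best_outer_at(
    top: str,
    anchor: int,
    orientation: str,
    constraints: DesignConstraints,
) -> PrimerSpec | None:
    """Best exact-match outer primer with its 5' end (forward) or 3'-to-5'
    span chosen so the primer's *outer* coordinate is ``anchor``.

    For forward primers ``anchor`` is the left (5') coordinate; for reverse
    primers it is the right (5') top-strand coordinate. Length is chosen to
    bring the Tm closest to target within tolerance and GC bounds."""
    best: tuple[float, int, PrimerSpec] | None = None
    for L in range(constraints.outer_len_min, constraints.outer_len_max + 1):
        if orientation == "forward":
            left, right = anchor, anchor + L - 1
        else:
            left, right = anchor - L + 1, anchor
        if left < 1 or right > len(top):
            continue
        region = top[left - 1 : right]
        seq = region if orientation == "forward" else reverse_complement(region)
        tm = _tm(seq)
        gc = gc_fraction(seq)
        if abs(tm - constraints.tm_target_c) > constraints.tm_tolerance_c:
            continue
        if not constraints.gc_min <= gc <= constraints.gc_max:
            continue
        cand = PrimerSpec(
            name=f"Out-{'F' if orientation == 'forward' else 'R'}{anchor}",
            sequence=seq,
            role="outer",
            orientation=orientation,
            anneal_left=left,
            anneal_right=right,
            tm_c=tm,
        )
        key = (abs(tm - constraints.tm_target_c), L)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], cand)
    return best[2] if best else None


def design_outer_primers(
    template: SequenceRecord,
    snp: DiagnosticSnp,
    inner_f: PrimerSpec,
    inner_r: PrimerSpec,
    constraints: DesignConstraints | None = None,
) -> tuple[PrimerSpec, PrimerSpec]:
    """Place the exact-match outer control pair around the inner primers so
    that all three products (O, A1, A2) fit the size window and the allele
    bands are separable on a gel."""
    pairs = _outer_candidates(template, snp, inner_f, inner_r, constraints)
    if not pairs:
        raise _outer_failure(template, snp, inner_f, inner_r, constraints)
    return pairs[0][1], pairs[0][2]


def _outer_candidates(
    template: SequenceRecord,
    snp: DiagnosticSnp,
    inner_f: PrimerSpec,
    inner_r: PrimerSpec,
    constraints: DesignConstraints | None,
) -> list[tuple[float, PrimerSpec, PrimerSpec]]:
    constraints = constraints or DesignConstraints()
    top = template.seq
    n = len(top)
    ifl = inner_f.anneal_left
    irr = inner_r.anneal_right
    if ifl is None or irr is None:
        raise ValueError("inner primers must be placed before outer design")

    # candidate anchors, pruned by the size window before Tm evaluation
    fwd: dict[int, PrimerSpec] = {}
    f_lo = max(1, irr - constraints.product_max + 1)
    f_hi = min(ifl - constraints.outer_len_min, irr - constraints.product_min + 1)
    for f in range(f_lo, max(f_lo, f_hi) + 1):
        cand = _best_outer_at(top, f, "forward", constraints)
        if cand is not None and cand.anneal_right < ifl:
            fwd[f] = cand
    rev: dict[int, PrimerSpec] = {}
    r_lo = max(irr + constraints.outer_len_min, ifl + constraints.product_min - 1)
    r_hi = min(n, ifl + constraints.product_max - 1)
    for r in range(r_lo, r_hi + 1):
        cand = _best_outer_at(top, r, "reverse", constraints)
        if cand is not None and cand.anneal_left > irr:
            rev[r] = cand

    scored: list[tuple[float, PrimerSpec, PrimerSpec]] = []
    for f, pf in fwd.items():
        a2 = irr - f + 1
        if not constraints.product_min <= a2 <= constraints.product_max:
            continue
        for r, pr in rev.items():
            a1 = r - ifl + 1
            o = r - f + 1
            if not constraints.product_min <= a1 <= constraints.product_max:
                continue
            if not constraints.product_min <= o <= constraints.product_max:
                continue
            if abs(a1 - a2) < constraints.min_band_separation:
                continue
            if min(abs(o - a1), abs(o - a2)) < constraints.min_band_separation:
                continue
            score = abs(pf.tm_c - constraints.tm_target_c) + abs(
                pr.tm_c - constraints.tm_target_c
            )
            scored.append((score, pf, pr))
    scored.sort(key=lambda t: (t[0], t[1].anneal_left, t[2].anneal_right))
    return scored


def _outer_failure(template, snp, inner_f, inner_r, constraints) -> DesignError:
    constraints = constraints or DesignConstraints()
    n = len(template.seq)
    violations = []
    if n < constraints.product_min:
        violations.append(
            f"template ({n} bp) shorter than the minimum product size "
            f"{constraints.product_min} bp"
        )
    violations.append(
        f"no outer placement gives O, A1, A2 within "
        f"[{constraints.product_min}, {constraints.product_max}] bp with "
        f"band separation >= {constraints.min_band_separation} bp and "
        f"Tm within {constraints.tm_target_c} +/- {constraints.tm_tolerance_c} C"
    )
    return DesignError(
        f"outer primer design failed for SNP at {snp.position}", violations
    )


def design_assay(
    template: SequenceRecord,
    snp: DiagnosticSnp,
    constraints: DesignConstraints | None = None,
    table: StrengthTable | None = None,
    seed: int | None = None,
    n_candidates: int = 5,
) -> list[TetraPrimerAssay]:
    """Design ranked tetra-primer assays for one SNP.

    Both allele-to-orientation assignments are explored; candidates are
    scored by Tm uniformity across the four primers, product-size spread,
    GC deviation and homopolymer runs (weights in ``constraints.scoring``).
    The result is deterministic; the seed only shuffles candidates that tie
    on score."""
    constraints = constraints or DesignConstraints()
    table = table or StrengthTable.default()
    failures: list[str] = []
    raw: list[tuple[float, TetraPrimerAssay]] = []

    for a1, a2 in ((snp.allele_group1, snp.allele_group2),
                   (snp.allele_group2, snp.allele_group1)):
        oriented_snp = DiagnosticSnp(
            position=snp.position,
            allele_group1=a1,
            allele_group2=a2,
            hybrid_support=snp.hybrid_support,
        )
        try:
            inner_f = design_inner_primer(
                template, oriented_snp, a1, "forward", constraints, table
            )
            inner_r = design_inner_primer(
                template, oriented_snp, a2, "reverse", constraints, table
            )
        except DesignError as exc:
            failures.extend(exc.violations or [str(exc)])
            continue
        pairs = _outer_candidates(template, oriented_snp, inner_f, inner_r, constraints)
        if not pairs:
            failures.append(
                f"no valid outer pair for assignment {a1}->forward/{a2}->reverse"
            )
            continue
        for score_outer, pf, pr in pairs[: max(n_candidates * 4, 20)]:
            assay = TetraPrimerAssay(
                locus_id=f"snp{snp.position}_{a1}{a2}",
                primers=[pf, inner_f, inner_r, pr],
                snp=oriented_snp,
            )
            raw.append((_score_assay(assay, constraints), assay))

    if not raw:
        raise DesignError(
            f"no tetra-primer assay satisfies the constraints at position "
            f"{snp.position}",
            violations=failures,
        )
    rng = random.Random(seed)
    rng.shuffle(raw)  # only reorders equal-score ties; sort below is stable
    raw.sort(key=lambda t: t[0])
    return [assay for _, assay in raw[:n_candidates]]


def _score_assay(assay: TetraPrimerAssay, constraints: DesignConstraints) -> float:
    w = constraints.scoring
    tms = [p.tm_c if p.tm_c is not None else _tm(p.sequence) for p in assay.primers]
    mean_tm = sum(tms) / 4
    tm_spread = math.sqrt(sum((t - mean_tm) ** 2 for t in tms) / 4)
    sizes = assay.sizes()
    gaps = [
        abs(sizes["A1"] - sizes["A2"]),
        abs(sizes["O"] - sizes["A1"]),
        abs(sizes["O"] - sizes["A2"]),
    ]
    # larger minimum gap is better; normalise by the size window
    window = constraints.product_max - constraints.product_min
    spread_penalty = 1.0 - min(min(gaps) / window, 1.0)
    gc_penalty = sum(abs(gc_fraction(p.sequence) - 0.5) for p in assay.primers) / 4
    homo_penalty = max(
        0, max(max_homopolymer_run(p.sequence) for p in assay.primers) - 4
    ) / 10.0
    return (
        w.get("tm_uniformity", 0.4) * tm_spread
        + w.get("size_spread", 0.3) * spread_penalty
        + w.get("gc", 0.2) * gc_penalty
        + w.get("homopolymer", 0.1) * homo_penalty
    )


def expected_products(
    assay: TetraPrimerAssay, genotype: str | Sequence[str]
) -> set[int]:
    """Band sizes expected for an unordered diploid genotype.

    ``genotype`` is a two-allele string ("CT") or pair ("C", "T"). The
    control band O is always present; each allele contributes its band.
    """
    if isinstance(genotype, str):
        alleles = tuple(genotype.upper())
    else:
        alleles = tuple(a.upper() for a in genotype)
    if len(alleles) != 2:
        raise ValueError(f"genotype must have exactly two alleles, got {alleles}")
    valid = {assay.allele1, assay.allele2}
    foreign = set(alleles) - valid
    if foreign:
        raise ValueError(
            f"allele(s) {sorted(foreign)} not part of assay {assay.locus_id!r} "
            f"(expects {sorted(valid)})"
        )
    sizes = assay.sizes()
    out = {sizes["O"]}
    for a in set(alleles):
        out.add(sizes["A1"] if a == assay.allele1 else sizes["A2"])
    return out


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    checks: list[ValidationCheck] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[ValidationCheck]:
        return [c for c in self.checks if not c.passed]


def validate_assay(
    assay: TetraPrimerAssay,
    templates: Mapping[str, Sequence[SequenceRecord]] | None = None,
    constraints: DesignConstraints | None = None,
    policy: PcrPolicy | None = None,
) -> ValidationReport:
    """Consistency harness for a tetra-primer assay.

    Checks the geometric invariants (inner 3' termini on the SNP when
    coordinates are known, the size identity A1+A2 = O+lf+lr-1, sizes within
    the design window, distinguishable allele bands) and, when per-genotype
    ``templates`` are supplied (genotype string -> 1-2 haplotypes), that
    in-silico PCR reproduces :func:`expected_products`. Never raises; the
    report lists failures.
    """
    constraints = constraints or DesignConstraints()
    report = ValidationReport()

    try:
        sizes = assay.sizes()
    except Exception as exc:
        report.checks.append(ValidationCheck("sizes_known", False, str(exc)))
        return report
    lf, lr = len(assay.inner_f), len(assay.inner_r)
    identity_lhs = sizes["A1"] + sizes["A2"]
    identity_rhs = sizes["O"] + lf + lr - 1
    report.checks.append(
        ValidationCheck(
            "size_identity",
            identity_lhs == identity_rhs,
            f"A1+A2={identity_lhs}, O+lf+lr-1={identity_rhs}",
        )
    )
    in_window = all(
        constraints.product_min <= sizes[k] <= constraints.product_max
        for k in ("O", "A1", "A2")
    )
    report.checks.append(
        ValidationCheck(
            "sizes_within_constraints", in_window, f"sizes={sizes}"
        )
    )
    report.checks.append(
        ValidationCheck(
            "allele_bands_distinct",
            sizes["A1"] != sizes["A2"],
            f"A1={sizes['A1']}, A2={sizes['A2']}",
        )
    )
    if assay.snp is not None and assay.inner_f.anneal_right is not None:
        ok_f = assay.inner_f.anneal_right == assay.snp.position
        ok_r = assay.inner_r.anneal_left == assay.snp.position
        report.checks.append(
            ValidationCheck(
                "inner_termini_on_snp",
                ok_f and ok_r,
                f"inner-F 3'={assay.inner_f.anneal_right}, "
                f"inner-R 3'={assay.inner_r.anneal_left}, snp={assay.snp.position}",
            )
        )

    if templates:
        for genotype, haps in templates.items():
            try:
                want = expected_products(assay, genotype)
            except ValueError as exc:
                report.checks.append(
                    ValidationCheck(f"simulation_{genotype}", False, str(exc))
                )
                continue
            got = simulate_pcr(assay, list(haps), policy).band_sizes
            report.checks.append(
                ValidationCheck(
                    f"simulation_{genotype}",
                    got == want,
                    f"expected {sorted(want)}, simulated {sorted(got)}",
                )
            )
    return report
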