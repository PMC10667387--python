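"""In-silico PCR under an ARMS extension-blocking model.

The simulator is qualitative (presence/absence of products, no yields) and
has three stages:

1. **Site search** — every ungapped alignment of a primer against either
   strand of the template with at most ``max_internal_mismatches`` internal
   (non-3'-terminal) mismatches, annotated with each mispair's ordinal
   strength and an effective Tm: the perfect-duplex nearest-neighbor Tm minus
   a fixed penalty per mismatch. Sites whose effective Tm falls more than
   ``anneal_margin_c`` below the programmed annealing temperature are
   considered unable to prime and are dropped.
2. **Extension test** — the ARMS rule. Under the stringent rule a primer
   extends only when its 3'-terminal ``min_3prime_exact_run`` bases are all
   matched. The permissive rule additionally lets a *weak* 3'-terminal
   mismatch read through when the annealing temperature is below the
   permissive threshold (default 60 C), modelling the loss of allele
   specificity observed at low annealing temperatures.
3. **Pairing** — every extendable forward-style site paired with every
   extendable reverse-style site downstream of it yields an amplicon of size
   ``rev.anneal_right - fwd.anneal_left + 1`` (capped at ``max_product_bp``).
   For a diploid sample the band set is the union over the two haplotypes.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .errors import TetrarmsError
from .mismatch import StrengthTable, classify_mismatch
from .model import (
    Amplicon,
    AmpliconSet,
    BindingSite,
    PcrPolicy,
    PrimerSpec,
    SequenceRecord,
    SiteMismatch,
    TetraPrimerAssay,
    complement,
)
from .thermo import melting_temperature


def _perfect_tm(primer: PrimerSpec, policy: PcrPolicy) -> float:
    return melting_temperature(
        primer.sequence,
        na_mm=policy.na_mm,
        mg_mm=policy.mg_mm,
        oligo_nm=policy.oligo_nm,
    )


def find_binding_sites(
    primer: PrimerSpec,
    template: SequenceRecord,
    policy: PcrPolicy | None = None,
    table: StrengthTable | None = None,
) -> list[BindingSite]:
    """All retained ungapped alignments of ``primer`` on ``template``.

    Both strands are scanned regardless of the primer's nominal orientation.
    The 3'-terminal base may mismatch (that is what ARMS blocking detects);
    only *internal* mismatches count against ``max_internal_mismatches``.
    Returns an empty list when nothing anneals.
    """
    policy = policy or PcrPolicy()
    table = table or StrengthTable.default()
    top = template.seq
    bad = set(top) - set("ACGT")
    if bad:
        raise ValueError(
            f"template {template.id!r} must be concrete bases for site search, "
            f"found {sorted(bad)}"
        )
    seq = primer.sequence
    L = len(seq)
    n = len(top)
    if L > n:
        return []
    max_internal = policy.max_internal_mismatches
    tm_perfect = _perfect_tm(primer, policy)
    tm_floor = policy.annealing_temp_c - policy.anneal_margin_c
    sites: list[BindingSite] = []

    # forward-style hits: primer sequence equals the top strand, anneals to
    # the bottom strand. Internal positions are 0..L-2; terminal is L-1.
    for i in range(n - L + 1):
        window = top[i : i + L]
        internal = 0
        mism_idx: list[int] = []
        ok = True
        for j in range(L):
            if seq[j] != window[j]:
                mism_idx.append(j)
                if j != L - 1:
                    internal += 1
                    if internal > max_internal:
                        ok = False
                        break
        if not ok:
            continue
        eff = tm_perfect - policy.tm_penalty_per_mismatch_c * len(mism_idx)
        if eff < tm_floor:
            continue
        mms = [
            SiteMismatch(
                pos_from_3prime=L - j,
                primer_base=seq[j],
                template_base=complement(window[j]),
                strength=classify_mismatch(seq[j], complement(window[j]), table),
            )
            for j in mism_idx
        ]
        sites.append(
            BindingSite(
                primer=primer,
                strand="top",
                anneal_left=i + 1,
                anneal_right=i + L,
                mismatches=mms,
                effective_tm_c=eff,
                perfect_tm_c=tm_perfect,
            )
        )

    # reverse-style hits: primer equals the bottom strand and anneals to the
    # top strand; primer position m (0-based from 5') pairs top coordinate
    # i+L-1-m, so the 3' terminus sits at the window's left edge.
    for i in range(n - L + 1):
        window = top[i : i + L]
        internal = 0
        mism_idx = []
        ok = True
        for m in range(L):
            t = window[L - 1 - m]
            if seq[m] != complement(t):
                mism_idx.append(m)
                if m != L - 1:
                    internal += 1
                    if internal > max_internal:
                        ok = False
                        break
        if not ok:
            continue
        eff = tm_perfect - policy.tm_penalty_per_mismatch_c * len(mism_idx)
        if eff < tm_floor:
            continue
        mms = [
            SiteMismatch(
                pos_from_3prime=L - m,
                primer_base=seq[m],
                template_base=window[L - 1 - m],
                strength=classify_mismatch(seq[m], window[L - 1 - m], table),
            )
            for m in mism_idx
        ]
        sites.append(
            BindingSite(
                primer=primer,
                strand="bottom",
                anneal_left=i + 1,
                anneal_right=i + L,
                mismatches=mms,
                effective_tm_c=eff,
                perfect_tm_c=tm_perfect,
            )
        )
    return sites


def can_extend(site: BindingSite, policy: PcrPolicy | None = None) -> bool:
    """ARMS extension rule for one binding site.

    Stringent: the 3'-terminal ``min_3prime_exact_run`` bases must all match
    (Taq cannot proofread a 3' mispair away). Permissive additionally lets a
    weak terminal mismatch extend when the annealing temperature is below the
    permissive threshold — the low-stringency mis-amplification regime.
    """
    policy = policy or PcrPolicy()
    run = max(1, policy.min_3prime_exact_run)
    blocked = [m for m in site.mismatches if m.pos_from_3prime <= run]
    if not blocked:
        return True
    if policy.extension_rule == "permissive":
        terminal = next(
            (m for m in site.mismatches if m.pos_from_3prime == 1), None
        )
        if (
            terminal is not None
            and terminal.strength == "weak"
            and policy.annealing_temp_c < policy.permissive_temp_threshold_c
            and all(m.pos_from_3prime == 1 for m in blocked)
        ):
            return True
    return False


def simulate_pcr(
    primers: TetraPrimerAssay | Iterable[PrimerSpec],
    haplotypes: SequenceRecord | Sequence[SequenceRecord],
    policy: PcrPolicy | None = None,
    table: StrengthTable | None = None,
) -> AmpliconSet:
    """Predict the band set for a primer collection on 1 or 2 haplotypes.

    ``primers`` may be a :class:`TetraPrimerAssay` or any iterable of
    :class:`PrimerSpec`. The diploid band set is the union of the per-
    haplotype products; an empty result means no amplification.
    """
    policy = policy or PcrPolicy()
    table = table or StrengthTable.default()
    if isinstance(primers, TetraPrimerAssay):
        primer_list = list(primers.primers)
    else:
        primer_list = list(primers)
    if isinstance(haplotypes, SequenceRecord):
        haplotypes = [haplotypes]
    if not 1 <= len(haplotypes) <= 2:
        raise ValueError("simulate_pcr expects 1 or 2 haplotypes")
    if len({len(h) for h in haplotypes}) != 1:
        raise ValueError("haplotypes must have equal length")

    per_hap: dict[str, list[Amplicon]] = {}
    for hap in haplotypes:
        fwd_sites: list[BindingSite] = []
        rev_sites: list[BindingSite] = []
        for primer in primer_list:
            for site in find_binding_sites(primer, hap, policy, table):
                if not can_extend(site, policy):
                    continue
                (fwd_sites if site.strand == "top" else rev_sites).append(site)
        amps = []
        for f in fwd_sites:
            for r in rev_sites:
                if r.anneal_left < f.anneal_left or r.anneal_right < f.anneal_right:
                    continue
                size = r.anneal_right - f.anneal_left + 1
                if size > policy.max_product_bp:
                    continue
                if size < max(len(f.primer), len(r.primer)):
                    continue
                amps.append(
                    Amplicon(
                        size=size,
                        forward_primer=f.primer.name,
                        reverse_primer=r.primer.name,
                        left=f.anneal_left,
                        right=r.anneal_right,
                    )
                )
        key = hap.id if hap.id not in per_hap else f"{hap.id}_2"
        per_hap[key] = sorted(amps, key=lambda a: (a.size, a.forward_primer))
    return AmpliconSet(per_haplotype=per_hap)
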