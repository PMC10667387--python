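"""Genotype and species calling from gel band patterns.

The gel readout is qualitative: which of the three expected bands (control
O, allele bands A1/A2) are present. Band sizing on agarose is imprecise, so
observed sizes are matched to expectations within a relative tolerance
(default 5 %, appropriate for 2 % agarose against a 100-1200 bp ladder).

The control band gates every call: allele bands without the control are
reported as invalid rather than a species, because the outer-outer product
is the assay's internal positive control.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import (
    GenotypeCall,
    SampleVerdict,
    Sex,
    TetraPrimerAssay,
)

logger = logging.getLogger(__name__)

BAND_KEYS = ("O", "A1", "A2")


@dataclass
class BandMatch:
    """Result of matching observed sizes against the expected band set."""

    presence: dict[str, bool]
    assigned: dict[str, float] = field(default_factory=dict)
    unexpected: tuple[float, ...] = ()

    @property
    def present_keys(self) -> frozenset[str]:
        return frozenset(k for k, v in self.presence.items() if v)


def match_bands(
    observed: Sequence[float],
    expected: Mapping[str, float],
    rel_tolerance: float = 0.05,
) -> BandMatch:
    """Assign observed band sizes to expected bands, nearest first.

    Each expected band is present iff some observed size lies within
    ``rel_tolerance * expected``; each observed band is consumed by at most
    one expected band. Leftover observed bands are flagged as unexpected.
    """
    if not 0.0 < rel_tolerance <= 0.2:
        raise ValueError("rel_tolerance must lie in (0, 0.2]")
    candidates = []
    for key, exp in expected.items():
        for i, obs in enumerate(observed):
            dist = abs(obs - exp) / exp
            if dist <= rel_tolerance:
                candidates.append((dist, key, i))
    candidates.sort()
    presence = {k: False for k in expected}
    assigned: dict[str, float] = {}
    used: set[int] = set()
    for dist, key, i in candidates:
        if presence[key] or i in used:
            continue
        presence[key] = True
        assigned[key] = float(observed[i])
        used.add(i)
    unexpected = tuple(
        float(obs) for i, obs in enumerate(observed) if i not in used
    )
    return BandMatch(presence=presence, assigned=assigned, unexpected=unexpected)


def call_locus_genotype(
    match: BandMatch,
    assay: TetraPrimerAssay,
) -> GenotypeCall:
    """Map a band presence pattern to a genotype and species reading.

    Truth table over {O, A1, A2} (8/8 subsets covered): with the control
    present, A1 alone is the allele-1 homozygote (species 1), A2 alone the
    allele-2 homozygote (species 2), both the heterozygote (hybrid), neither
    the control-only pattern of a related non-target species. Without the
    control every pattern is invalid.
    """
    present = match.present_keys
    a1, a2 = assay.allele1, assay.allele2
    if "O" not in present:
        genotype, label, reading = "no_amplification", "no_amplification", "invalid"
    elif present == {"O", "A1"}:
        genotype, label, reading = "hom_allele1", a1 + a1, assay.species1
    elif present == {"O", "A2"}:
        genotype, label, reading = "hom_allele2", a2 + a2, assay.species2
    elif present == {"O", "A1", "A2"}:
        genotype, label, reading = "het", "".join(sorted(a1 + a2)), "hybrid"
    else:  # exactly {O}
        genotype, label, reading = "control_only", "control_only", "other_cervid"
    return GenotypeCall(
        locus_id=assay.locus_id,
        bands_present=frozenset(present),
        genotype=genotype,
        genotype_label=label,
        species_reading=reading,
        unexpected_bands=match.unexpected,
    )


def interpret_sample(
    sample_id: str,
    calls: Mapping[str, GenotypeCall] | Sequence[GenotypeCall],
    sex: Sex = "female",
) -> SampleVerdict:
    """Combine per-locus calls into a species verdict, sex-aware.

    Females inherit one X per parent, so a concordant heterozygote is a
    hybrid and a concordant homozygote the corresponding pure species. A
    male carries a single maternally inherited X: a homozygous pattern only
    fixes the maternal lineage (verdict ``maternal_only`` with the lineage
    recorded), and a heterozygous pattern is biologically inconsistent
    (conflict). Discordant loci always conflict.
    """
    if not isinstance(calls, Mapping):
        calls = {c.locus_id: c for c in calls}
    if not calls:
        raise ValueError("interpret_sample needs at least one locus call")
    readings = {c.species_reading for c in calls.values()}
    concordant = len(readings) == 1
    maternal = None
    if not concordant:
        verdict = "conflict"
    else:
        (reading,) = readings
        if reading == "invalid":
            verdict = "invalid"
        elif reading == "other_cervid":
            verdict = "other_cervid"
        elif reading == "hybrid":
            verdict = "hybrid" if sex != "male" else "conflict"
        else:  # a pure-species reading
            if sex == "male":
                verdict = "maternal_only"
                maternal = reading
            else:
                verdict = reading
    return SampleVerdict(
        sample_id=sample_id,
        sex=sex,
        calls=dict(calls),
        concordant=concordant,
        species_verdict=verdict,
        maternal_lineage=maternal,
    )


def route_assay(sex: Sex) -> str:
    """Sex-based assay routing.

    The X-linked tetra-primer panel is fully informative only for females;
    males go to an external barcode panel (COI/SRY, outside this package).
    Unknown sex routes to the tetra-primer panel (still reports maternal
    lineage) with a warning.
    """
    if sex == "male":
        return "male_barcode_panel"
    if sex == "unknown":
        warnings.warn(
            "sex unknown: routing to the tetra-primer panel; a heterozygous "
            "call assumes the sample is female",
            stacklevel=2,
        )
    return "tarms_female_panel"


def label_matches(declared_label: str, verdict: SampleVerdict) -> bool:
    """Does a declared product label agree with the species verdict?

    Labels are species names; the composite label "sika/red deer product"
    accepts either pure species. For a maternal-only verdict the maternal
    lineage is compared.
    """
    label = declared_label.strip().lower()
    effective = verdict.species_verdict
    if effective == "maternal_only" and verdict.maternal_lineage:
        effective = verdict.maternal_lineage
    if "/" in label or label in ("deer", "sika/red deer product"):
        return effective in ("sika", "red")
    return effective == label


@dataclass
class AuditSummary:
    counts: Counter
    mislabels: list[tuple[str, str, str]]  # (sample_id, declared, verdict)
    n_samples: int

    def count(self, verdict: str) -> int:
        return self.counts.get(verdict, 0)


def audit_panel(
    verdicts: Sequence[SampleVerdict],
    declared_labels: Mapping[str, str] | None = None,
) -> AuditSummary:
    """Tally species verdicts and list label disagreements.

    ``declared_labels`` (sample_id -> label) overrides/supplies labels not
    already attached to the verdicts. Deterministic.
    """
    counts: Counter = Counter()
    mislabels = []
    for v in verdicts:
        counts[v.species_verdict] += 1
        label = None
        if declared_labels and v.sample_id in declared_labels:
            label = declared_labels[v.sample_id]
        elif v.declared_label:
            label = v.declared_label
        if label is None:
            raise ValueError(f"sample {v.sample_id!r} has no declared label")
        ok = label_matches(label, v)
        v.declared_label = label
        v.label_concordant = ok
        if not ok:
            mislabels.append((v.sample_id, label, v.species_verdict))
    return AuditSummary(counts=counts, mislabels=mislabels, n_samples=len(verdicts))


def call_panel(
    bands: pd.DataFrame,
    assays: Iterable[TetraPrimerAssay],
    rel_tolerance: float = 0.05,
    sex_map: Mapping[str, Sex] | None = None,
) -> tuple[list[SampleVerdict], list[str]]:
    """End-to-end calling of a band table over one or more loci.

    ``bands`` follows the band-table schema (lane_id, locus_id, size_bp,
    optional declared_label/declared_sex). Lanes routed to the external male
    panel are *not* genotyped; their lane ids are returned separately.
    Returns (verdicts for tetra-primer lanes, male-routed lane ids).
    """
    assay_by_locus = {a.locus_id: a for a in assays}
    verdicts: list[SampleVerdict] = []
    routed_out: list[str] = []
    for lane_id, lane_rows in bands.groupby("lane_id", sort=False):
        sex: Sex = "unknown"
        if sex_map and lane_id in sex_map:
            sex = sex_map[lane_id]
        elif "declared_sex" in lane_rows.columns:
            declared = [s for s in lane_rows["declared_sex"].unique() if s]
            if declared:
                sex = declared[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            route = route_assay(sex)
        if route == "male_barcode_panel":
            routed_out.append(str(lane_id))
            continue
        calls = {}
        for locus_id, locus_rows in lane_rows.groupby("locus_id", sort=False):
            assay = assay_by_locus.get(str(locus_id))
            if assay is None:
                logger.warning("lane %s: unknown locus %s skipped", lane_id, locus_id)
                continue
            sizes = assay.sizes()
            observed = [s for s in locus_rows["size_bp"].tolist() if s > 0]
            m = match_bands(observed, sizes, rel_tolerance)
            calls[str(locus_id)] = call_locus_genotype(m, assay)
        if not calls:
            continue
        verdict = interpret_sample(str(lane_id), calls, sex)
        labels = [
            s for s in lane_rows.get("declared_label", pd.Series(dtype=str)).unique() if s
        ]
        if labels:
            verdict.declared_label = labels[0]
            verdict.label_concordant = label_matches(labels[0], verdict)
        verdicts.append(verdict)
    return verdicts, routed_out
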