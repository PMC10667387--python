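"""Synthetic test data: ZFX-like templates, alignments and market panels.

No real deer sequence ships with the package. Instead a ~730 bp synthetic
top-strand template is *reconstructed from the published assay geometry*:
with the shared outer-forward site anchored at position 67, the printed
product sizes force the outer-reverse 3' coordinates to 552 and 615, the
inner-forward 5' coordinates to 201 and 403 and the SNP columns to 221 and
428 — exactly the numbers embedded in the primer and locus names. Primer
annealing sites carry the primer sequences (with each deliberate mismatch
position holding the documented template base); everything between sites is
seeded random filler. The fidelity target is the assay geometry, not the
true ZFX sequence.

Species presets: sika = C/G homozygote, red = T/T, hybrid = C/T + G/T
heterozygote. The reindeer preset keeps the outer control sites intact but
scrambles four bases in the 3' half of each inner site, so only the control
band amplifies — the control-only pattern of a non-target cervid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import read_primer_table
from .model import (
    DiagnosticSnp,
    PcrPolicy,
    PrimerSpec,
    SequenceRecord,
    TetraPrimerAssay,
    complement,
    reverse_complement,
)
from .pcr import simulate_pcr

TEMPLATE_LENGTH = 730
OUT_F_LEFT = 67
DEFAULT_SEED = 42

#: per-locus optimised annealing temperatures (deg C)
ASSAY_ANNEALING_C = {"X221": 62.0, "X428": 61.0}

#: species -> per-locus diploid genotypes on the top strand
SPECIES_GENOTYPES: dict[str, dict[str, tuple[str, str]]] = {
    "sika": {"X221": ("C", "C"), "X428": ("G", "G")},
    "red": {"X221": ("T", "T"), "X428": ("T", "T")},
    "hybrid": {"X221": ("C", "T"), "X428": ("G", "T")},
}

#: primer names as printed elsewhere in the source publication that refer to
#: the same oligos (label drift between table and text)
PUBLISHED_NAME_ALIASES = {
    "In-F210w1": "In-F201w1",
    "In-F201w": "In-F201w1",
    "Out-615": "Out-R615",
}

#: the discovery primer pair used to amplify the full fragment
ZFX1F = PrimerSpec(
    name="ZFX1F", sequence="CCACAAGAACCAAACTCATT", role="outer",
    orientation="forward", anneal_left=1, anneal_right=20,
)
ZFX1R = PrimerSpec(
    name="ZFX1R", sequence="TTGATAACTTCAGGGCAAG", role="outer",
    orientation="reverse", anneal_left=712, anneal_right=730,
)


def published_assays(placed: bool = True) -> list[TetraPrimerAssay]:
    """The packaged published primer sets (X221, X428).

    With ``placed=True`` primer coordinates and the SNP are derived from the
    printed product sizes via :func:`place_assay`.
    """
    ref = resources.files("tetrarms").joinpath("data/published_primers.tsv")
    with resources.as_file(ref) as path:
        assays = read_primer_table(path)
    if placed:
        assays = [place_assay(a) for a in assays]
    return assays


def place_assay(
    assay: TetraPrimerAssay, out_f_left: int = OUT_F_LEFT
) -> TetraPrimerAssay:
    """Derive top-strand coordinates for a four-primer set from its product
    sizes, anchoring the outer-forward 5' end.

    Geometry: outer-R right = out_f_left + O - 1; inner-F left =
    outer-R right - A1 + 1; the SNP sits at inner-F left + lf - 1; inner-R
    right = out_f_left + A2 - 1 with its 3' terminus on the SNP.
    """
    sizes = assay.sizes()
    o, a1, a2 = sizes["O"], sizes["A1"], sizes["A2"]
    of, inf, inr, orv = assay.outer_f, assay.inner_f, assay.inner_r, assay.outer_r
    or_right = out_f_left + o - 1
    if_left = or_right - a1 + 1
    snp_pos = if_left + len(inf) - 1
    ir_right = out_f_left + a2 - 1
    ir_left = ir_right - len(inr) + 1
    if ir_left != snp_pos:
        raise ValueError(
            f"assay {assay.locus_id!r}: size identity violated — inner 3' "
            f"termini do not coincide ({ir_left} vs {snp_pos})"
        )
    placed = [
        replace(of, anneal_left=out_f_left, anneal_right=out_f_left + len(of) - 1),
        replace(inf, anneal_left=if_left, anneal_right=snp_pos),
        replace(inr, anneal_left=snp_pos, anneal_right=ir_right),
        replace(orv, anneal_left=or_right - len(orv) + 1, anneal_right=or_right),
    ]
    allele1 = inf.target_allele or inf.three_prime_base
    allele2 = inr.target_allele or complement(inr.three_prime_base)
    snp = DiagnosticSnp(position=snp_pos, allele_group1=allele1, allele_group2=allele2)
    return TetraPrimerAssay(
        locus_id=assay.locus_id,
        primers=placed,
        snp=snp,
        product_o=o,
        product_a1=a1,
        product_a2=a2,
        species1=assay.species1,
        species2=assay.species2,
    )


@dataclass(frozen=True)
class TemplateModel:
    """Coordinate layout of the synthetic top-strand template."""

    length: int
    snp_positions: Mapping[str, int]
    sites: Mapping[str, tuple[int, int]]  # primer name -> (left, right)

    @classmethod
    def default(cls) -> "TemplateModel":
        sites = {ZFX1F.name: (1, 20), ZFX1R.name: (712, 730)}
        snps = {}
        for assay in published_assays(placed=True):
            snps[assay.locus_id] = assay.snp.position
            for p in assay.primers:
                sites[p.name] = (p.anneal_left, p.anneal_right)
        return cls(length=TEMPLATE_LENGTH, snp_positions=dict(snps), sites=sites)


def _paint(top: list[str], primer: PrimerSpec) -> None:
    """Write a primer's matched site into the top strand, then restore the
    documented template base at each designed-mismatch position."""
    left, right = primer.anneal_left, primer.anneal_right
    if primer.orientation == "forward":
        top[left - 1 : right] = list(primer.sequence)
        for mm in primer.designed_mismatches:
            # forward primers anneal to the bottom strand: the top strand
            # carries the complement of the mismatched template base
            top[(right - mm.pos_from_3prime + 1) - 1] = complement(mm.template_base)
    else:
        top[left - 1 : right] = list(reverse_complement(primer.sequence))
        for mm in primer.designed_mismatches:
            # reverse primers anneal to the top strand directly
            top[(left + mm.pos_from_3prime - 1) - 1] = mm.template_base


def _normalise_genotype(
    genotype: str | Mapping[str, str | tuple[str, str]],
) -> tuple[str, dict[str, tuple[str, str]], bool]:
    """Return (name, per-locus allele pairs, is_reindeer)."""
    if isinstance(genotype, str):
        if genotype == "reindeer":
            return "reindeer", SPECIES_GENOTYPES["sika"], True
        if genotype not in SPECIES_GENOTYPES:
            raise ValueError(
                f"unknown genotype preset {genotype!r} "
                f"(expected {sorted(SPECIES_GENOTYPES)} or 'reindeer')"
            )
        return genotype, SPECIES_GENOTYPES[genotype], False
    pairs: dict[str, tuple[str, str]] = {}
    for locus, alleles in genotype.items():
        if isinstance(alleles, str):
            pair = tuple(alleles) if len(alleles) == 2 else (alleles, alleles)
        else:
            pair = tuple(alleles)
        if len(pair) != 2:
            raise ValueError(f"locus {locus}: need 1 or 2 alleles, got {alleles!r}")
        pairs[locus] = pair  # type: ignore[assignment]
    name = "custom"
    return name, pairs, False


_VALID_ALLELES = {"X221": {"C", "T"}, "X428": {"G", "T"}}
_SCRAMBLE = {"A": "C", "C": "G", "G": "T", "T": "A"}


def build_haplotype(
    alleles: Mapping[str, str],
    seed: int = DEFAULT_SEED,
    reindeer: bool = False,
    hap_id: str = "hap",
) -> SequenceRecord:
    """One synthetic top-strand haplotype with the given SNP alleles.

    Filler bases are reproducible from the seed and independent of genotype,
    so haplotypes from the same seed differ only at the SNP columns (and, for
    the reindeer preset, at the scrambled inner-site positions).
    """
    rng = np.random.default_rng(seed)
    top = list(rng.choice(list("ACGT"), size=TEMPLATE_LENGTH))
    assays = published_assays(placed=True)
    _paint(top, ZFX1F)
    _paint(top, ZFX1R)
    for assay in assays:
        for primer in assay.primers:
            _paint(top, primer)
    for assay in assays:
        locus = assay.locus_id
        allele = alleles.get(locus, assay.snp.allele_group1).upper()
        if allele not in _VALID_ALLELES.get(locus, {"A", "C", "G", "T"}):
            raise ValueError(
                f"invalid allele {allele!r} at {locus} "
                f"(expected one of {sorted(_VALID_ALLELES[locus])})"
            )
        top[assay.snp.position - 1] = allele
    if reindeer:
        for assay in assays:
            snp_pos = assay.snp.position
            for inner in (assay.inner_f, assay.inner_r):
                left, right = inner.anneal_left, inner.anneal_right
                # 3' half of the primer's footprint, SNP column excluded
                if inner.orientation == "forward":
                    half = range(right - len(inner) // 2, right + 1)
                else:
                    half = range(left, left + len(inner) // 2 + 1)
                coords = [c for c in half if c != snp_pos]
                picks = rng.choice(len(coords), size=4, replace=False)
                for k in sorted(picks):
                    c = coords[k]
                    top[c - 1] = _SCRAMBLE[top[c - 1]]
    return SequenceRecord(id=hap_id, seq="".join(top))


def build_template(
    genotype: str | Mapping[str, str | tuple[str, str]] = "sika",
    seed: int = DEFAULT_SEED,
) -> list[SequenceRecord]:
    """Diploid (or haploid) synthetic template for a genotype or preset.

    ``genotype`` is a species preset ("sika", "red", "hybrid", "reindeer")
    or a per-locus allele assignment such as ``{"X221": ("C", "T"),
    "X428": ("G", "T")}`` (single bases mean homozygous). Returns the two
    haplotypes of the diploid; use :func:`build_haplotype` for one strand.
    """
    name, pairs, reindeer = _normalise_genotype(genotype)
    hap1 = {locus: p[0] for locus, p in pairs.items()}
    hap2 = {locus: p[1] for locus, p in pairs.items()}
    recs = [
        build_haplotype(hap1, seed=seed, reindeer=reindeer, hap_id=f"{name}_hap1"),
        build_haplotype(hap2, seed=seed, reindeer=reindeer, hap_id=f"{name}_hap2"),
    ]
    return recs


def build_alignment(
    n_sika: int = 5,
    n_red: int = 5,
    n_hybrid: int = 5,
    seed: int = DEFAULT_SEED,
) -> list[SequenceRecord]:
    """Species panel of consensus sequences for SNP discovery.

    Within-species sequences are byte-identical; hybrids carry the IUPAC
    heterozygote codes Y (C/T) at the X221 column and K (G/T) at X428, the
    way a diploid Sanger consensus encodes double peaks.
    """
    if n_sika < 1 or n_red < 1 or n_hybrid < 0:
        raise ValueError("need at least one sika and one red sequence")
    sika = build_haplotype({"X221": "C", "X428": "G"}, seed=seed)
    red = build_haplotype({"X221": "T", "X428": "T"}, seed=seed)
    model = TemplateModel.default()
    hyb_seq = list(sika.seq)
    hyb_seq[model.snp_positions["X221"] - 1] = "Y"
    hyb_seq[model.snp_positions["X428"] - 1] = "K"
    hybrid = "".join(hyb_seq)
    records = []
    for i in range(n_sika):
        records.append(SequenceRecord(id=f"sika_{i + 1}", seq=sika.seq))
    for i in range(n_red):
        records.append(SequenceRecord(id=f"red_{i + 1}", seq=red.seq))
    for i in range(n_hybrid):
        records.append(SequenceRecord(id=f"hybrid_{i + 1}", seq=hybrid))
    return records


def alignment_groups(records: Sequence[SequenceRecord]) -> dict[str, str]:
    """Group labels (group1=sika, group2=red) inferred from fixture ids."""
    out = {}
    for rec in records:
        if rec.id.startswith("sika"):
            out[rec.id] = "group1"
        elif rec.id.startswith("red"):
            out[rec.id] = "group2"
        elif rec.id.startswith("hybrid"):
            out[rec.id] = "hybrid"
    return out


@dataclass(frozen=True)
class PanelLane:
    lane_id: str
    species: str  # true source: sika/red/hybrid/reindeer
    declared_label: str
    sex: str = "female"
    sample_type: str = "product"


@dataclass(frozen=True)
class PanelSpec:
    name: str
    lanes: tuple[PanelLane, ...]

    def __post_init__(self) -> None:
        ids = [lane.lane_id for lane in self.lanes]
        if len(ids) != len(set(ids)):
            raise ValueError("lane ids must be unique")


def _fig5_lanes() -> list[PanelLane]:
    # 24-lane composition as printed in the source gel legend: hybrids sold
    # under a pure-sika label, reindeer counterfeits under a generic deer
    # label, everything else labelled truthfully
    species_by_lane: dict[int, str] = {}
    for i in (1, 2, 3, 4, 10, 11, 13, 22):
        species_by_lane[i] = "red"
    for i in (5, 6, 12, 19):
        species_by_lane[i] = "hybrid"
    for i in (7, 8, 9, 14, 15, 16, 17, 18, 20, 24):
        species_by_lane[i] = "sika"
    for i in (21, 23):
        species_by_lane[i] = "reindeer"
    lanes = []
    for i in range(1, 25):
        sp = species_by_lane[i]
        if sp == "hybrid":
            label = "sika"
        elif sp == "reindeer":
            label = "sika/red deer product"
        else:
            label = sp
        lanes.append(PanelLane(lane_id=f"L{i:02d}", species=sp, declared_label=label))
    return lanes


def _full40_lanes() -> list[PanelLane]:
    lanes = _fig5_lanes()
    extra = ["sika"] * 6 + ["red"] * 4 + ["hybrid"] * 2
    for j, sp in enumerate(extra, start=25):
        lanes.append(
            PanelLane(lane_id=f"L{j:02d}", species=sp, declared_label=sp)
        )
    # four male samples (three blood, one meat) caught by sex identification
    for j, stype in zip(range(37, 41), ("blood", "blood", "blood", "meat")):
        sp = "sika" if j != 40 else "red"
        lanes.append(
            PanelLane(
                lane_id=f"L{j:02d}",
                species=sp,
                declared_label=sp,
                sex="male",
                sample_type=stype,
            )
        )
    return lanes


def build_market_panel(
    spec: str = "fig5_24",
    seed: int = DEFAULT_SEED,
    noise_cv: float = 0.0,
) -> tuple[PanelSpec, pd.DataFrame]:
    """Simulate a market-survey panel into a band table.

    ``spec`` is ``"fig5_24"`` (the 24-lane published panel composition) or
    ``"full_40"`` (those 24 plus 12 label-concordant female lanes and 4 male
    lanes). Band sizes come from in-silico PCR of each lane's template with
    both primer sets at their optimised annealing temperatures; noise-free by
    default (``noise_cv`` adds multiplicative gel sizing error).
    """
    if spec == "fig5_24":
        lanes = _fig5_lanes()
    elif spec == "full_40":
        lanes = _full40_lanes()
    else:
        raise ValueError(f"unknown panel spec {spec!r}")
    panel = PanelSpec(name=spec, lanes=tuple(lanes))

    assays = published_assays(placed=True)
    bands_by_species: dict[str, dict[str, list[int]]] = {}
    for species in {lane.species for lane in lanes}:
        haps = build_template(species, seed=seed)
        per_locus = {}
        for assay in assays:
            policy = PcrPolicy(annealing_temp_c=ASSAY_ANNEALING_C[assay.locus_id])
            per_locus[assay.locus_id] = sorted(
                simulate_pcr(assay, haps, policy).band_sizes
            )
        bands_by_species[species] = per_locus

    rows = []
    for lane in lanes:
        for locus_id, sizes in bands_by_species[lane.species].items():
            for size in sizes:
                rows.append(
                    {
                        "lane_id": lane.lane_id,
                        "locus_id": locus_id,
                        "size_bp": float(size),
                        "declared_label": lane.declared_label,
                        "declared_sex": lane.sex,
                    }
                )
    bands = pd.DataFrame(rows)
    if noise_cv:
        bands = add_gel_noise(bands, cv=noise_cv, seed=seed)
    return panel, bands


def add_gel_noise(
    bands: pd.DataFrame, cv: float, seed: int = DEFAULT_SEED
) -> pd.DataFrame:
    """Multiplicative gel sizing error: size *= (1 + eps), eps ~ N(0, cv).

    cv = 0 returns an identical table; sizes are kept positive.
    """
    if not 0.0 <= cv <= 0.2:
        raise ValueError("cv must lie in [0, 0.2]")
    out = bands.copy()
    if cv == 0.0 or out.empty:
        return out
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, cv, size=len(out))
    out["size_bp"] = np.maximum(out["size_bp"].to_numpy() * (1.0 + eps), 1.0)
    return out
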