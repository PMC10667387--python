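"""Melting-temperature models.

Short oligos (< 14 nt) use the Wallace rule 2(A+T) + 4(G+C); everything else
uses the unified nearest-neighbor model (SantaLucia) as implemented in
Biopython, with Owczarzy-style salt correction so divalent Mg2+ in a PCR
buffer can be accounted for. Defaults: 50 mM monovalent, 200 nM oligo, no Mg.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.SeqUtils import MeltingTemp as _mt

from .model import CONCRETE_BASES

#: salt/oligo profile matching the assay's PCR buffer (2.5 mM MgCl2)
PCR_BUFFER = {"na_mm": 50.0, "mg_mm": 2.5, "oligo_nm": 200.0}

_WALLACE_MAX_LEN = 13


def melting_temperature(
    seq: str,
    *,
    na_mm: float = 50.0,
    mg_mm: float = 0.0,
    oligo_nm: float = 200.0,
) -> float:
    """Tm in deg C of a concrete-base oligo.

    Deterministic: nearest-neighbor for length >= 14, Wallace rule below.
    Ambiguity codes are rejected (their pairing is not a single duplex).
    """
    seq = seq.upper()
    if len(seq) < 4:
        raise ValueError("Tm undefined for oligos shorter than 4 nt")
    bad = set(seq) - set(CONCRETE_BASES)
    if bad:
        raise ValueError(f"Tm requires concrete bases, got {sorted(bad)}")
    return _tm_cached(seq, float(na_mm), float(mg_mm), float(oligo_nm))


@lru_cache(maxsize=4096)
def _tm_cached(seq: str, na_mm: float, mg_mm: float, oligo_nm: float) -> float:
    if len(seq) <= _WALLACE_MAX_LEN:
        return float(_mt.Tm_Wallace(seq))
    # saltcorr=7 (Owczarzy 2008) handles both monovalent-only and Mg2+ cases
    return float(
        _mt.Tm_NN(
            seq,
            Na=na_mm,
            Mg=mg_mm,
            dnac1=oligo_nm,
            dnac2=0,
            saltcorr=7,
        )
    )
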