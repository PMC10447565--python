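"""Microbial biomass and necromass carbon from fumigation extracts and amino sugars.

Living microbial biomass C (MBC, g/kg) comes from chloroform
fumigation-extraction: the extra organic C released by fumigation, divided by
the extraction-efficiency factor kEC = 0.45.

Dead microbial residues (necromass C) are estimated from amino-sugar
biomarkers.  Muramic acid (MurA) occurs only in bacterial cell walls, so
bacterial necromass C (BNC) = 45 x MurA.  Glucosamine (GluN) is of mixed
origin; the fungal share is the molar excess of GluN over twice the MurA
molarity, converted back to mass and scaled by the fungal factor 9:

    FNC = (GluN/179.17 - 2 x MurA/251.23) x 179.17 x 9

with 179.17 and 251.23 the molecular masses (g/mol) of glucosamine and
muramic acid.  Total necromass C (MNC) = BNC + FNC.  Galactosamine is
measured alongside but enters no formula.

Units: amino sugars and necromass in mg/g dry soil, extract TOC in mg C/g,
MBC and SOC in g/kg.  mg/g and g/kg are numerically identical, so the
MNC/SOC ratio needs no unit conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: molecular masses (g/mol)
MW_GLUCOSAMINE = 179.17
MW_MURAMIC_ACID = 251.23

#: fumigation-extraction efficiency (kEC); extractable flush / kEC = MBC
MBC_CONVERSION_FACTOR = 0.45

#: mg bacterial necromass C per mg muramic acid
BNC_FACTOR = 45.0

#: fungal glucosamine-to-necromass-C factor
FNC_FACTOR = 9.0


@dataclass(frozen=True)
class AminoSugarProfile:
    """Amino-sugar concentrations (mg/g dry soil)."""

    glun: float
    galn: float
    mura: float

    def __post_init__(self) -> None:
        for name in ("glun", "galn", "mura"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class CarbonPools:
    """Derived microbial carbon pools for one site.

    ``mnc == bnc + fnc`` holds exactly; ``fnc_clamped`` records that the raw
    fungal formula went negative (MurA large relative to GluN) and was
    floored at zero, ``mbc_clamped`` likewise for a negative fumigation flush.
    """

    mbc: float
    bnc: float
    fnc: float
    mnc: float
    mnc_soc_ratio: float
    fnc_clamped: bool = False
    mbc_clamped: bool = False


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


def microbial_biomass_c(toc_fum: float, toc_unfum: float) -> tuple[float, bool]:
    """MBC (g/kg) from fumigated and unfumigated extract TOC (mg C/g).

    Returns ``(mbc, clamped)``; a negative flush (fumigated below
    unfumigated, a measurement artifact) is floored at zero and flagged.
    """
    _require_finite(toc_fum=toc_fum, toc_unfum=toc_unfum)
    if toc_fum < 0 or toc_unfum < 0:
        raise ValueError("extract TOC concentrations must be >= 0")
    flush = toc_fum - toc_unfum
    if flush < 0:
        return 0.0, True
    return flush / MBC_CONVERSION_FACTOR, False


def bacterial_necromass_c(mura: float) -> float:
    """Bacterial necromass C (mg/g) = 45 x muramic acid (mg/g)."""
    _require_finite(mura=mura)
    if mura < 0:
        raise ValueError(f"mura must be >= 0, got {mura!r}")
    return BNC_FACTOR * mura


def fungal_necromass_c(glun: float, mura: float) -> tuple[float, bool]:
    """Fungal necromass C (mg/g) from glucosamine after the bacterial correction.

    Raw value = (GluN/179.17 - 2*MurA/251.23) x 179.17 x 9.  Returns
    ``(fnc, clamped)``; a negative raw value is floored at zero and flagged.
    """
    _require_finite(glun=glun, mura=mura)
    if glun < 0 or mura < 0:
        raise ValueError("amino-sugar concentrations must be >= 0")
    raw = (glun / MW_GLUCOSAMINE - 2.0 * mura / MW_MURAMIC_ACID) * MW_GLUCOSAMINE * FNC_FACTOR
    if raw < 0:
        return 0.0, True
    return raw, False


def total_necromass_c(bnc: float, fnc: float) -> float:
    """Total microbial necromass C (mg/g) = bacterial + fungal."""
    _require_finite(bnc=bnc, fnc=fnc)
    if bnc < 0 or fnc < 0:
        raise ValueError("necromass components must be >= 0")
    return bnc + fnc


def necromass_fraction_of_soc(mnc: float, soc: float) -> float:
    """MNC as a percentage of SOC (mg/g over g/kg: same scale, no conversion)."""
    _require_finite(mnc=mnc, soc=soc)
    if soc <= 0:
        raise ValueError(f"soc must be > 0, got {soc!r}")
    if mnc < 0:
        raise ValueError(f"mnc must be >= 0, got {mnc!r}")
    return 100.0 * mnc / soc


def compute_pools(
    toc_fum: float,
    toc_unfum: float,
    glun: float,
    mura: float,
    soc: float,
) -> CarbonPools:
    """All carbon pools for one site; ``mnc = bnc + fnc`` bit-exactly."""
    mbc, mbc_clamped = microbial_biomass_c(toc_fum, toc_unfum)
    bnc = bacterial_necromass_c(mura)
    fnc, fnc_clamped = fungal_necromass_c(glun, mura)
    mnc = total_necromass_c(bnc, fnc)
    ratio = necromass_fraction_of_soc(mnc, soc)
    return CarbonPools(
        mbc=mbc,
        bnc=bnc,
        fnc=fnc,
        mnc=mnc,
        mnc_soc_ratio=ratio,
        fnc_clamped=fnc_clamped,
        mbc_clamped=mbc_clamped,
    )


def pools_table(sites: pd.DataFrame) -> pd.DataFrame:
    """Vectorized carbon pools for a site table.

    ``sites`` must carry columns ``toc_fum, toc_unfum, glun, mura, soc``
    (the site TSV written by :mod:`micronet.synthetic_data` qualifies).
    Returns a copy with ``mbc, bnc, fnc, mnc, mnc_soc_ratio, fnc_clamped,
    mbc_clamped`` appended.  Per-site MNC/SOC ratios are computed first and
    averaged by the caller if a summary is wanted (mean of per-site ratios,
    not ratio of means).
    """
    required = {"toc_fum", "toc_unfum", "glun", "mura", "soc"}
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"site table is missing columns: {sorted(missing)}")
    out = sites.copy()
    flush = out["toc_fum"].to_numpy(float) - out["toc_unfum"].to_numpy(float)
    out["mbc_clamped"] = flush < 0
    out["mbc"] = np.clip(flush, 0.0, None) / MBC_CONVERSION_FACTOR
    out["bnc"] = BNC_FACTOR * out["mura"].to_numpy(float)
    raw_fnc = (
        out["glun"].to_numpy(float) / MW_GLUCOSAMINE
        - 2.0 * out["mura"].to_numpy(float) / MW_MURAMIC_ACID
    ) * MW_GLUCOSAMINE * FNC_FACTOR
    out["fnc_clamped"] = raw_fnc < 0
    out["fnc"] = np.clip(raw_fnc, 0.0, None)
    out["mnc"] = out["bnc"] + out["fnc"]
    soc = out["soc"].to_numpy(float)
    if np.any(soc <= 0):
        raise ValueError("soc must be > 0 for every site")
    out["mnc_soc_ratio"] = 100.0 * out["mnc"] / soc
    return out
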