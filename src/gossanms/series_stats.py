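"""Homologous fatty-acid series detection and distributional statistics.

Deprotonated fatty acids appear as carboxylate anions CnH(2n-1-2u)O2-
(u = number of double bonds; one extra O for hydroxylated chains).  The
carbon-number parity profile of the series is a classic biogenicity
indicator: membrane lipids of most organisms are built from C2 units, so
even-carbon chains dominate; a strong even-over-odd excess on the short
(<= C20) side of the distribution, together with the short/long partition,
fingerprints a microbial (fungal-like) rather than higher-plant source.

"Even/odd" refers to the total carbon number including the carboxyl carbon
(standard n-Cx:y lipidomics notation).  Hydroxylated chains enter the parity
and partition sums but are also reported as their own saturation class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .formula_assign import AssignedPeak
from .masschem import IonSpecies, MolecularFormula

__all__ = ["FattyAcidIon", "SeriesSummary", "detect_fa_series", "summarize_series"]

CARBON_RANGE = (11, 30)
UNSAT_RANGE = (0, 5)


@dataclass(frozen=True)
class FattyAcidIon:
    carbons: int
    unsaturation: int
    hydroxylation: int  # 0 or 1
    intensity: float

    def __post_init__(self):
        if not (CARBON_RANGE[0] <= self.carbons <= CARBON_RANGE[1]):
            raise ValueError(f"carbon number {self.carbons} outside {CARBON_RANGE}")
        if not (UNSAT_RANGE[0] <= self.unsaturation <= UNSAT_RANGE[1]):
            raise ValueError(f"unsaturation {self.unsaturation} outside {UNSAT_RANGE}")
        if self.hydroxylation not in (0, 1):
            raise ValueError("hydroxylation must be 0 or 1")

    @property
    def label(self) -> str:
        oh = "-OH" if self.hydroxylation else ""
        return f"C{self.carbons}:{self.unsaturation}{oh}"

    @property
    def saturation_class(self) -> str:
        if self.hydroxylation:
            return "hydroxylated"
        if self.unsaturation == 0:
            return "saturated"
        if self.unsaturation == 1:
            return "monounsaturated"
        return "polyunsaturated"

    @property
    def ion(self) -> IonSpecies:
        """The carboxylate anion CnH(2n-1-2u)O(2+oh)-."""
        n, u = self.carbons, self.unsaturation
        return IonSpecies(
            MolecularFormula(
                {"C": n, "H": 2 * n - 1 - 2 * u, "O": 2 + self.hydroxylation}
            ),
            -1,
        )

    @property
    def neutral(self) -> MolecularFormula:
        """The neutral free acid CnH(2n-2u)O(2+oh)."""
        n, u = self.carbons, self.unsaturation
        return MolecularFormula(
            {"C": n, "H": 2 * n - 2 * u, "O": 2 + self.hydroxylation}
        )


def _fa_from_formula(f: MolecularFormula, intensity: float) -> Optional[FattyAcidIon]:
    d = f.as_dict()
    if set(d) - {"C", "H", "O"}:
        return None
    n, h, o = d.get("C", 0), d.get("H", 0), d.get("O", 0)
    if not (CARBON_RANGE[0] <= n <= CARBON_RANGE[1]):
        return None
    if o not in (2, 3):
        return None
    # h = 2n - 1 - 2u  =>  u = (2n - 1 - h) / 2
    twice_u = 2 * n - 1 - h
    if twice_u < 0 or twice_u % 2:
        return None
    u = twice_u // 2
    if not (UNSAT_RANGE[0] <= u <= UNSAT_RANGE[1]):
        return None
    return FattyAcidIon(n, u, o - 2, intensity)


def detect_fa_series(assigned: Sequence[AssignedPeak]) -> List[FattyAcidIon]:
    """Extract fatty-acid carboxylates from negative-mode assignments.

    Every best formula matching CnH(2n-1-2u)O2..3- with 11 <= n <= 30 and
    0 <= u <= 5 is emitted; anything else is ignored.
    """
    out = []
    for pk in assigned:
        if pk.best is None or pk.best.ion.charge >= 0:
            continue
        fa = _fa_from_formula(pk.best.ion.formula, pk.intensity)
        if fa is not None:
            out.append(fa)
    return out


@dataclass
class SeriesSummary:
    """Intensity sums by parity, chain-length partition and saturation class."""

    cutoff: int = 20
    total_intensity: float = 0.0
    even_intensity: float = 0.0
    odd_intensity: float = 0.0
    short_intensity: float = 0.0  # <= cutoff carbons
    long_intensity: float = 0.0  # > cutoff
    short_even_intensity: float = 0.0
    short_odd_intensity: float = 0.0
    saturation_intensity: Dict[str, float] = field(default_factory=dict)
    #: even:odd intensity ratio on the <= cutoff side; inf when odd sum is 0
    even_odd_ratio_short: float = float("nan")
    has_20_5: bool = False  # eicosapentaenoic-type PUFA present
    has_20_4: bool = False  # arachidonic-type PUFA present
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("cutoff_carbons", self.cutoff),
            ("total_intensity", self.total_intensity),
            ("even_intensity", self.even_intensity),
            ("odd_intensity", self.odd_intensity),
            ("short_intensity", self.short_intensity),
            ("long_intensity", self.long_intensity),
            ("short_even_intensity", self.short_even_intensity),
            ("short_odd_intensity", self.short_odd_intensity),
            ("even_odd_ratio_short", self.even_odd_ratio_short),
            ("has_20_5", self.has_20_5),
            ("has_20_4", self.has_20_4),
        ]
        for k, v in sorted(self.saturation_intensity.items()):
            rows.append((f"intensity[{k}]", v))
        return pd.DataFrame(rows, columns=["quantity", "value"])


def summarize_series(
    fas: Sequence[FattyAcidIon], cutoff: int = 20
) -> SeriesSummary:
    """Deterministic parity / partition / saturation sums over an FA list."""
    out = SeriesSummary(cutoff=cutoff)
    if not fas:
        out.empty = True
        return out
    for fa in fas:
        i = fa.intensity
        out.total_intensity += i
        if fa.carbons % 2 == 0:
            out.even_intensity += i
        else:
            out.odd_intensity += i
        short = fa.carbons <= cutoff
        if short:
            out.short_intensity += i
            if fa.carbons % 2 == 0:
                out.short_even_intensity += i
            else:
                out.short_odd_intensity += i
        else:
            out.long_intensity += i
        cls = fa.saturation_class
        out.saturation_intensity[cls] = out.saturation_intensity.get(cls, 0.0) + i
        if fa.carbons == 20 and fa.unsaturation == 5 and not fa.hydroxylation:
            out.has_20_5 = True
        if fa.carbons == 20 and fa.unsaturation == 4 and not fa.hydroxylation:
            out.has_20_4 = True
    if out.short_odd_intensity > 0:
        out.even_odd_ratio_short = out.short_even_intensity / out.short_odd_intensity
    elif out.short_even_intensity > 0:
        out.even_odd_ratio_short = math.inf
    return out


def series_bins(fas: Sequence[FattyAcidIon]) -> pd.DataFrame:
    """Carbon number x saturation class intensity table (plot-ready bins)."""
    acc: Dict[tuple, float] = {}
    for fa in fas:
        key = (fa.carbons, fa.saturation_class)
        acc[key] = acc.get(key, 0.0) + fa.intensity
    rows = [
        dict(carbons=c, saturation=s, intensity=v)
        for (c, s), v in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["carbons", "saturation", "intensity"])
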