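"""Diagnostic-fragment annotation for ToF-SIMS-style peak lists.

A curated library of marker ions — inorganic matrix species, NH4+-bearing
hydrocarbon adducts, fatty-acid carboxylates, sulfate/sulfonate adducts,
sphingolipid dehydration fragments, amino-acid immonium-type ions,
phytochemical fragments, PAH cations, sterol fragments — maps secondary-ion
peaks onto nine morphological marker groups (G1..G9) plus cross-cutting
chemical tags (matrix, PAH, FA, sterol, aminoacid, phytochemical).

The library ships as a delimited text resource.  Each entry records the
two-decimal m/z value as printed in its source alongside the elemental
formula; the theoretical m/z is always recomputed from the formula with the
electron-mass correction, never copied.  Entries whose printed value does
not round-trip against theory are flagged ``discrepant`` (instrument
calibration offsets of 0.01-0.03 Da are common in time-of-flight surface
spectra) and are enumerated by :func:`discrepancy_report`.
"""

from __future__ import annotations

import csv

import numpy as np
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import pandas as pd

from .masschem import (
    FormulaError,
    IonSpecies,
    MolecularFormula,
    parse_formula,
    round_half_even,
)
from .peaklist import PeakList

__all__ = [
    "FragmentLibraryEntry",
    "SphingoidBase",
    "SPHINGOID_BASES",
    "AnnotationResult",
    "load_library",
    "annotate",
    "pah_sum",
    "dehydration_series",
    "nh4_adduct",
    "discrepancy_report",
]

GROUP_TAGS = frozenset(
    {f"G{i}" for i in range(1, 10)}
    | {"matrix", "PAH", "FA", "sterol", "aminoacid", "phytochemical"}
)

#: Default match tolerance (Da); two-decimal printed masses imply ~5 mDa.
DEFAULT_TOL_DA = 0.005


@dataclass(frozen=True)
class FragmentLibraryEntry:
    ion: IonSpecies
    printed_mz: Optional[float]
    group_tags: FrozenSet[str]
    provenance: str
    discrepant: bool

    def __post_init__(self):
        if not self.group_tags:
            raise ValueError(f"entry {self.ion} carries no group tag")
        bad = self.group_tags - GROUP_TAGS
        if bad:
            raise ValueError(f"unknown group tags {bad} on {self.ion}")

    @property
    def theoretical_mz(self) -> float:
        return self.ion.mz


@dataclass(frozen=True)
class SphingoidBase:
    """A long-chain amino-alcohol backbone (neutral formula)."""

    name: str
    formula: MolecularFormula


#: The shipped sphingoid-base set.
SPHINGOID_BASES: Tuple[SphingoidBase, ...] = (
    SphingoidBase("sphingenine", parse_formula("C18H37NO2")),
    SphingoidBase("sphinganine", parse_formula("C18H39NO2")),
    SphingoidBase("aminomethyl-nonadecane-triol", parse_formula("C20H41NO3")),
    SphingoidBase("phytosphingosine", parse_formula("C20H43NO3")),
)

_H = parse_formula("H")
_H2O = parse_formula("H2O")
_NH4 = parse_formula("NH4")


def dehydration_series(base: SphingoidBase, n: int) -> IonSpecies:
    """[M+H-nH2O]+ dehydration cation of a sphingoid base, n in {1, 2}.

    Long-chain amino alcohols ionize predominantly through loss of one or
    two of their hydroxyls as water from the protonated molecule, yielding
    diagnostic N-bearing even-mass cations.
    """
    if n not in (1, 2):
        raise ValueError(f"dehydration count must be 1 or 2, got {n}")
    if base.formula["O"] < n:
        raise ValueError(
            f"{base.name} has only {base.formula['O']} oxygens; cannot lose {n} waters"
        )
    f = base.formula + _H
    for _ in range(n):
        f = f - _H2O
    return IonSpecies(f, +1)


def nh4_adduct(alkyl: MolecularFormula) -> IonSpecies:
    """Ammonium-bearing cation CxH(y+4)N+ of a hydrocarbon CxHy.

    Only unsaturated chains form the observed adduct series; a saturation
    sanity check rejects compositions whose adduct would exceed the maximum
    hydrogen count of an even-electron amine-type cation (H <= 2C + 4).
    """
    d = alkyl.as_dict()
    if set(d) != {"C", "H"}:
        raise FormulaError(f"{alkyl} is not a pure hydrocarbon")
    c, h = d["C"], d["H"]
    if h + 4 > 2 * c + 4:
        raise FormulaError(
            f"adduct C{c}H{h + 4}N+ fails the valence sanity check (H > 2C + 4)"
        )
    return IonSpecies(alkyl + _NH4, +1)


# -- library I/O --------------------------------------------------------------

def _parse_entry(row: Dict[str, str]) -> FragmentLibraryEntry:
    formula = parse_formula(row["formula"])
    charge = int(row["charge"])
    printed = row.get("printed_mz", "").strip()
    printed_mz = float(printed) if printed else None
    tags = frozenset(t for t in row["groups"].split("|") if t)
    discrepant = row.get("discrepant", "").strip().lower() in ("1", "true", "yes")
    entry = FragmentLibraryEntry(
        IonSpecies(formula, charge), printed_mz, tags, row.get("provenance", ""), discrepant
    )
    pol = row.get("polarity", "").strip()
    if pol and pol != entry.ion.polarity:
        raise ValueError(f"polarity column disagrees with charge for {formula}")
    return entry


def load_library(path=None) -> List[FragmentLibraryEntry]:
    """Load the fragment library (the shipped resource when ``path`` is None)."""
    if path is None:
        ref = resources.files("gossanms.data") / "fragment_library.csv"
        with ref.open() as fh:
            rows = list(csv.DictReader(fh))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    return [_parse_entry(r) for r in rows]


def save_library(entries: Sequence[FragmentLibraryEntry], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["formula", "charge", "polarity", "printed_mz", "groups", "provenance", "discrepant"]
        )
        for e in entries:
            w.writerow(
                [
                    str(e.ion.formula),
                    e.ion.charge,
                    e.ion.polarity,
                    "" if e.printed_mz is None else f"{e.printed_mz:.2f}",
                    "|".join(sorted(e.group_tags)),
                    e.provenance,
                    "true" if e.discrepant else "false",
                ]
            )


def discrepancy_report(entries: Sequence[FragmentLibraryEntry]) -> pd.DataFrame:
    """Entries whose printed m/z does not equal the 2-dp rounded theory."""
    rows = []
    for e in entries:
        if e.printed_mz is None:
            continue
        theo = e.ion.mz_rounded(2)
        if theo != round_half_even(e.printed_mz, 2):
            rows.append(
                dict(
                    ion=str(e.ion),
                    printed_mz=e.printed_mz,
                    theoretical_mz=round(e.ion.mz, 4),
                    offset=round(e.printed_mz - e.ion.mz, 4),
                    provenance=e.provenance,
                )
            )
    return pd.DataFrame(
        rows, columns=["ion", "printed_mz", "theoretical_mz", "offset", "provenance"]
    )


# -- annotation ---------------------------------------------------------------

@dataclass
class AnnotationResult:
    """Per-peak matches plus per-group intensity and entry-count summaries."""

    matches: List[Tuple[int, FragmentLibraryEntry, float]]  # (peak idx, entry, dm)
    group_intensity: Dict[str, float] = field(default_factory=dict)
    group_entry_count: Dict[str, int] = field(default_factory=dict)

    def top_group(self, tags: Optional[Sequence[str]] = None) -> Optional[str]:
        """Group with the largest summed intensity (restricted to ``tags``)."""
        items = self.group_intensity.items()
        if tags is not None:
            items = [(k, v) for k, v in items if k in tags]
        items = sorted(items, key=lambda kv: (-kv[1], kv[0]))
        return items[0][0] if items else None

    def to_frame(self, peaks: PeakList) -> pd.DataFrame:
        rows = [
            dict(
                mz=peaks.mz[i],
                intensity=peaks.intensity[i],
                ion=str(e.ion),
                delta_mda=round(dm * 1e3, 3),
                groups="|".join(sorted(e.group_tags)),
            )
            for i, e, dm in self.matches
        ]
        return pd.DataFrame(rows, columns=["mz", "intensity", "ion", "delta_mda", "groups"])

    def group_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                group=g,
                summed_intensity=self.group_intensity[g],
                matched_entries=self.group_entry_count.get(g, 0),
            )
            for g in sorted(self.group_intensity)
        ]
        return pd.DataFrame(rows, columns=["group", "summed_intensity", "matched_entries"])


def annotate(
    peaks: PeakList,
    library: Sequence[FragmentLibraryEntry],
    tol: float = DEFAULT_TOL_DA,
) -> AnnotationResult:
    """Match peaks against library entries within ``tol`` Da.

    Only entries whose polarity agrees with the peak list's polarity are
    considered (a peak list without declared polarity matches both).  For
    the per-group intensity sum a peak is counted once per group even when
    several entries of that group match it (isobar guard).
    """
    if not library:
        raise ValueError("empty fragment library")
    if tol < 0:
        raise ValueError("tolerance must be nonnegative")
    matches: List[Tuple[int, FragmentLibraryEntry, float]] = []
    group_intensity: Dict[str, float] = {}
    group_entry_count: Dict[str, int] = {}
    counted: set = set()  # (peak index, group) pairs already summed
    for entry in library:
        if peaks.polarity is not None and entry.ion.polarity != peaks.polarity:
            continue
        theo = entry.ion.mz
        lo = np.searchsorted(peaks.mz, theo - tol, side="left")
        hi = np.searchsorted(peaks.mz, theo + tol, side="right")
        matched_any = False
        for i in range(lo, hi):
            dm = peaks.mz[i] - theo
            matches.append((i, entry, float(dm)))
            matched_any = True
            for g in entry.group_tags:
                if (i, g) not in counted:
                    counted.add((i, g))
                    group_intensity[g] = group_intensity.get(g, 0.0) + float(
                        peaks.intensity[i]
                    )
        if matched_any:
            for g in entry.group_tags:
                group_entry_count[g] = group_entry_count.get(g, 0) + 1
    return AnnotationResult(matches, group_intensity, group_entry_count)


def pah_sum(
    peaks: PeakList,
    library: Sequence[FragmentLibraryEntry],
    tol: float = DEFAULT_TOL_DA,
) -> float:
    """Summed intensity of peaks matching the PAH cation set (each peak once)."""
    if peaks.polarity == "negative":
        raise ValueError("PAH summation expects positive polarity")
    hit = set()
    for entry in library:
        if "PAH" not in entry.group_tags or entry.ion.charge <= 0:
            continue
        theo = entry.ion.mz
        lo = np.searchsorted(peaks.mz, theo - tol, side="left")
        hi = np.searchsorted(peaks.mz, theo + tol, side="right")
        hit.update(range(lo, hi))
    return float(sum(peaks.intensity[i] for i in hit))
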