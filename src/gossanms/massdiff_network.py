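"""Exact-mass-difference histograms and homologous-series motif networks.

A complex organic mixture carries strong internal structure: members of a
homologous series differ by exact multiples of small neutral motifs (CH2 for
alkylation, H2 for (de)saturation, O for oxygenation, NH for amination, SO
for sulfonation).  Counting peak pairs whose exact mass difference matches a
motif within a tight ppm window therefore fingerprints the chemistry of the
mixture without assigning a single formula.

The shipped motif set is CH2, H2, O1..O5, NH1..NH3 and SO1..SO4.  The ppm
residual of a pair is referenced to the mean of the two masses (the
reference mass is configurable to absolute-Da mode); pair search slides a
window over the sorted mass list and is checked against an all-pairs brute
force in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .formula_assign import AssignedPeak
from .masschem import MolecularFormula, parse_formula

__all__ = [
    "MassMotif",
    "DiffEdge",
    "default_motifs",
    "diff_histogram",
    "build_network",
]


@dataclass(frozen=True)
class MassMotif:
    """A named formula delta; ``delta_mass`` is derived, never stored."""

    name: str
    delta: MolecularFormula

    @property
    def delta_mass(self) -> float:
        return self.delta.monoisotopic_mass


def default_motifs() -> List[MassMotif]:
    """CH2, H2, O1-O5, NH1-NH3, SO1-SO4."""
    motifs = [
        MassMotif("CH2", parse_formula("CH2")),
        MassMotif("H2", parse_formula("H2")),
    ]
    motifs += [MassMotif(f"O{n}", parse_formula(f"O{n}")) for n in range(1, 6)]
    motifs += [MassMotif(f"NH{n}", parse_formula(f"NH{n}")) for n in range(1, 4)]
    motifs += [MassMotif(f"SO{n}", parse_formula(f"SO{n}")) for n in range(1, 5)]
    return motifs


def _pair_tolerance_da(m_lo: float, m_hi: float, tol_ppm: float) -> float:
    # residual referenced to the mean of the two pair masses
    return tol_ppm * 1e-6 * 0.5 * (m_lo + m_hi)


def _match_pairs(
    masses: np.ndarray, delta: float, tol_ppm: float, tol_da: Optional[float]
) -> List[Tuple[int, int, float]]:
    """(i_lo, i_hi, residual_ppm or residual_da) for all matching pairs."""
    out = []
    n = masses.size
    for i in range(n):
        target = masses[i] + delta
        if tol_da is not None:
            win = tol_da
        else:
            # conservative window; exact per-pair check below
            win = tol_ppm * 1e-6 * (target + delta)
        j0 = np.searchsorted(masses, target - win, side="left")
        j1 = np.searchsorted(masses, target + win, side="right")
        for j in range(max(j0, i + 1), j1):
            mismatch = masses[j] - masses[i] - delta
            if tol_da is not None:
                if abs(mismatch) <= tol_da:
                    out.append((i, j, mismatch))
            else:
                ref = 0.5 * (masses[i] + masses[j])
                residual_ppm = mismatch / ref * 1e6
                if abs(residual_ppm) <= tol_ppm:
                    out.append((i, j, residual_ppm))
    return out


def diff_histogram(
    masses: Sequence[float],
    motifs: Optional[Sequence[MassMotif]] = None,
    tol_ppm: float = 0.1,
    tol_da: Optional[float] = None,
) -> Dict[str, int]:
    """Count peak pairs separated by each motif's exact mass.

    ``masses`` must be sorted ascending and deduplicated; each unordered
    pair is counted at most once per motif.  Passing ``tol_da`` switches to
    an absolute-Da window instead of ppm-on-mean-mass.
    """
    if tol_ppm < 0 or (tol_da is not None and tol_da < 0):
        raise ValueError("tolerance must be nonnegative")
    arr = np.asarray(list(masses), dtype=float)
    if arr.size and np.any(np.diff(arr) <= 0):
        raise ValueError("masses must be sorted ascending and deduplicated")
    if motifs is None:
        motifs = default_motifs()
    return {
        m.name: len(_match_pairs(arr, m.delta_mass, tol_ppm, tol_da))
        for m in motifs
    }


@dataclass(frozen=True)
class DiffEdge:
    lower: int  # index of lower-mass peak
    upper: int
    motif: str
    residual_ppm: float  # exactly 0.0 for formula-mode edges
    mode: str  # "formula" | "mass"


def build_network(
    assigned: Sequence[AssignedPeak],
    motifs: Optional[Sequence[MassMotif]] = None,
    tol_ppm: float = 0.1,
    mode: str = "auto",
) -> List[DiffEdge]:
    """Motif edges between assigned peaks.

    ``mode="formula"`` links peaks whose best formulas differ exactly by the
    motif's element counts (residual 0 by construction); ``mode="mass"``
    links on observed mass difference within the ppm tolerance;
    ``mode="auto"`` uses formula edges wherever both peaks carry a best
    formula and falls back to mass edges elsewhere.
    """
    if mode not in ("formula", "mass", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if motifs is None:
        motifs = default_motifs()
    edges: List[DiffEdge] = []

    order = sorted(range(len(assigned)), key=lambda i: assigned[i].mz)
    masses = np.array([assigned[i].mz for i in order])

    if mode in ("formula", "auto"):
        by_counts: Dict[Tuple[Tuple[str, int], ...], List[int]] = {}
        for rank, idx in enumerate(order):
            pk = assigned[idx]
            if pk.best is not None:
                by_counts.setdefault(pk.best.ion.formula.counts, []).append(rank)
        for motif in motifs:
            delta = motif.delta.as_dict()
            for counts, ranks_lo in by_counts.items():
                hi = dict(counts)
                for el, n in delta.items():
                    hi[el] = hi.get(el, 0) + n
                key = MolecularFormula(hi).counts
                for r_lo in ranks_lo:
                    for r_hi in by_counts.get(key, ()):
                        edges.append(
                            DiffEdge(order[r_lo], order[r_hi], motif.name, 0.0, "formula")
                        )

    if mode in ("mass", "auto"):
        has_formula = {
            i for i, pk in enumerate(assigned) if pk.best is not None
        }
        for motif in motifs:
            for r_lo, r_hi, res in _match_pairs(masses, motif.delta_mass, tol_ppm, None):
                i_lo, i_hi = order[r_lo], order[r_hi]
                if mode == "auto" and i_lo in has_formula and i_hi in has_formula:
                    continue  # covered (or excluded) by the formula route
                edges.append(DiffEdge(i_lo, i_hi, motif.name, res, "mass"))
    return edges


def histogram_frame(counts: Dict[str, int]) -> pd.DataFrame:
    return pd.DataFrame(sorted(counts.items()), columns=["motif", "count"])


def edges_frame(edges: Sequence[DiffEdge], assigned: Sequence[AssignedPeak]) -> pd.DataFrame:
    rows = [
        dict(
            source_mz=assigned[e.lower].mz,
            target_mz=assigned[e.upper].mz,
            motif=e.motif,
            residual_ppm=e.residual_ppm,
            mode=e.mode,
        )
        for e in edges
    ]
    return pd.DataFrame(
        rows, columns=["source_mz", "target_mz", "motif", "residual_ppm", "mode"]
    )
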