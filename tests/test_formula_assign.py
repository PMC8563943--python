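"""Formula enumeration against a brute-force oracle, plus assignment checks."""

import numpy as np
import pytest

from gossanms.formula_assign import (
    AssignmentConfig,
    assign_peaklist,
    class_counts,
    enumerate_candidates,
    heteroatom_class,
)
from gossanms.masschem import ELECTRON_MASS, ELEMENTS, parse_formula
from gossanms.peaklist import PeakList
from gossanms.synthetic import FticrSimConfig, gen_fticr_peaklist

M = {s: ELEMENTS[s].monoisotopic_mass for s in "CHNOS"}


def brute_force_formulas(mz, config):
    """Independent oracle: full numpy grid over C,H,N,O,S plus inline filters."""
    b = config.element_bounds
    rng = {el: np.arange(b.get(el, (0, 0))[0], b.get(el, (0, 0))[1] + 1)
           for el in "CHNOS"}
    C, H, N, O, S = np.meshgrid(*(rng[el] for el in "CHNOS"), indexing="ij")
    mass = (C * M["C"] + H * M["H"] + N * M["N"] + O * M["O"] + S * M["S"])
    target = mz + config.charge * ELECTRON_MASS
    tol_da = config.tol_ppm * 1e-6 * mz
    hit = np.abs(mass - target) <= tol_da
    out = set()
    h_shift = {"deprotonated": 1, "protonated": -1}.get(config.ion_hypothesis, 0)
    for c, h, n, o, s in zip(C[hit], H[hit], N[hit], O[hit], S[hit]):
        if not (c or h or n or o or s):
            continue
        hn = h + h_shift
        if hn < 0:
            continue
        dbe = c - hn / 2 + n / 2 + 1
        if config.ion_hypothesis in ("deprotonated", "protonated", "radical"):
            if dbe != int(dbe):
                continue
        if not (config.dbe_range[0] <= dbe <= config.dbe_range[1]):
            continue
        if c > 0:
            if not (config.hc_range[0] <= hn / c <= config.hc_range[1]):
                continue
            if not (config.oc_range[0] <= o / c <= config.oc_range[1]):
                continue
        out.add((int(c), int(h), int(n), int(o), int(s)))
    return out


def as_tuple(cand):
    d = cand.ion.formula.as_dict()
    return tuple(d.get(el, 0) for el in "CHNOS")


def test_oracle_equivalence_on_random_masses():
    """Enumeration equals the exhaustive grid oracle for 100 random inputs."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        mz = float(rng.uniform(100, 500))
        bounds = {
            "C": (1, int(rng.integers(20, 41))),
            "H": (1, int(rng.integers(30, 61))),
            "N": (0, int(rng.integers(0, 4))),
            "O": (0, int(rng.integers(5, 13))),
            "S": (0, int(rng.integers(0, 3))),
        }
        config = AssignmentConfig(
            tol_ppm=float(rng.uniform(0.5, 20.0)), element_bounds=bounds
        )
        cands, _ = enumerate_candidates(mz, config)
        got = {as_tuple(c) for c in cands}
        assert len(got) == len(cands)  # each formula appears exactly once
        assert got == brute_force_formulas(mz, config)


def test_tolerance_and_bounds_monotonicity():
    """Enlarging the window or the bounds never removes a candidate."""
    mz = 465.3044
    base = AssignmentConfig(
        tol_ppm=2.0,
        element_bounds={"C": (1, 30), "H": (1, 60), "N": (0, 2), "O": (0, 8), "S": (0, 1)},
    )
    small = {as_tuple(c) for c in enumerate_candidates(mz, base)[0]}
    wider = AssignmentConfig(tol_ppm=8.0, element_bounds=base.element_bounds)
    bigger = AssignmentConfig(
        tol_ppm=2.0,
        element_bounds={"C": (1, 40), "H": (1, 90), "N": (0, 4), "O": (0, 12), "S": (0, 2)},
    )
    assert small <= {as_tuple(c) for c in enumerate_candidates(mz, wider)[0]}
    assert small <= {as_tuple(c) for c in enumerate_candidates(mz, bigger)[0]}


def test_known_ions_recovered():
    cands, _ = enumerate_candidates(
        465.3044,
        AssignmentConfig(
            tol_ppm=1.0,
            element_bounds={"C": (1, 40), "H": (1, 100), "N": (0, 3), "O": (0, 10), "S": (0, 2)},
        ),
    )
    assert "C27H45O4S" in {str(c.ion.formula) for c in cands}

    cands, _ = enumerate_candidates(
        255.2330,
        AssignmentConfig(
            tol_ppm=0.5,
            element_bounds={"C": (1, 30), "H": (1, 60), "N": (0, 0), "O": (0, 10), "S": (0, 0)},
        ),
    )
    assert [str(c.ion.formula) for c in cands] == ["C16H31O2"]


def test_bounds_excluding_everything_yield_empty_list():
    config = AssignmentConfig(
        tol_ppm=5.0,
        element_bounds={"C": (0, 0), "H": (0, 0), "N": (0, 0), "O": (0, 0), "S": (0, 0)},
    )
    cands, _ = enumerate_candidates(18.0106, config)
    assert cands == []


def test_empty_bounds_raise_configuration_error():
    with pytest.raises(ValueError):
        AssignmentConfig(element_bounds={})


def test_rejection_reasons_are_retrievable():
    cands, rejected = enumerate_candidates(
        255.2330,
        AssignmentConfig(
            tol_ppm=40.0,
            element_bounds={"C": (1, 30), "H": (1, 60), "N": (0, 2), "O": (0, 8), "S": (0, 1)},
        ),
        collect_rejections=True,
    )
    assert rejected and all(reason for _, reason in rejected)


@pytest.mark.parametrize(
    "formula, label",
    [
        ("C16H31O2", "CHO"),
        ("C20H40NO", "CHNO"),
        ("C27H45SO4", "CHOS"),
        ("C10H15NO2S", "CHNOS"),
        ("Na3SO4", "other"),
        ("SO2", "other"),
    ],
)
def test_heteroatom_class(formula, label):
    assert heteroatom_class(parse_formula(formula)) == label


def test_assign_peaklist_keeps_unassigned_and_orders_output():
    peaks = PeakList(
        np.array([255.2330, 300.0001]), np.array([5.0, 1.0]), "negative"
    )
    assigned = assign_peaklist(peaks, AssignmentConfig(tol_ppm=0.5))
    assert len(assigned) == 2
    assert assigned[0].class_label == "CHO"
    assert str(assigned[0].best.ion.formula) == "C16H31O2"
    counts = class_counts(assigned)
    assert counts["CHO"] == 1


def test_assign_empty_peaklist():
    peaks = PeakList(np.empty(0), np.empty(0), "negative")
    assert assign_peaklist(peaks, AssignmentConfig()) == []


def test_polarity_mismatch_rejected():
    peaks = PeakList(np.array([255.233]), np.array([1.0]), "positive")
    with pytest.raises(ValueError):
        assign_peaklist(peaks, AssignmentConfig(polarity="negative"))


def test_unsorted_peaklist_rejected():
    with pytest.raises(ValueError):
        PeakList(np.array([300.0, 255.0]), np.array([1.0, 1.0]), "negative")


def test_synthetic_recovery_and_tolerance_binding():
    """0.1 ppm-noise spectra assign >=99% correctly; the same pipeline at
    5 ppm noise assigns far fewer peaks (tolerance binds)."""
    peaks, truth = gen_fticr_peaklist(FticrSimConfig(n_peaks=300, seed=7))
    assigned = assign_peaklist(peaks, AssignmentConfig(tol_ppm=0.5))
    correct = sum(
        1
        for pk, tf in zip(assigned, truth["ion_formula"])
        if pk.best is not None and str(pk.best.ion.formula) == tf
    )
    assert correct / len(assigned) >= 0.99

    noisy, noisy_truth = gen_fticr_peaklist(
        FticrSimConfig(n_peaks=300, seed=7, ppm_sigma=5.0)
    )
    noisy_assigned = assign_peaklist(noisy, AssignmentConfig(tol_ppm=0.5))
    noisy_correct = sum(
        1
        for pk, tf in zip(noisy_assigned, noisy_truth["ion_formula"])
        if pk.best is not None and str(pk.best.ion.formula) == tf
    )
    assert noisy_correct / len(noisy_assigned) < 0.5
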