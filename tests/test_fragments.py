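"""Fragment enumeration, diagnostic ions, spectrum matching, isomer assignment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycolda.fragments import (
    Spectrum,
    assign_isomer_features,
    diagnostic_sialic_ions,
    enumerate_fragments,
    match_spectrum,
)
from glycolda.masses import (
    CO2,
    CROSS_RING_C2H4O2,
    HYDROGEN,
    RESIDUE_MASSES,
    IonSpec,
    mz,
    neutral_mass,
    parse_composition,
    round_half_away,
)
from glycolda.simulate import generate_spectrum
from glycolda.topology import build_topology


def _topo(comp_text, s=None, f=None):
    return build_topology(
        parse_composition(comp_text, labeled=True), sialic_linkages=s, fucose_positions=f
    )


def _y_mzs(topo, max_cleavages=3):
    frags = enumerate_fragments(topo, ion_types={"Y"}, max_cleavages=max_cleavages)
    return {round_half_away(f.mz) for f in frags}


def test_core_fucose_y_series():
    """Core-fucosylated N4H5SF keeps fucose on the small Y ions."""
    mzs = _y_mzs(_topo("N4H5SF", s=["a23"], f=["core"]))
    assert {487.19, 690.27, 1176.43} <= mzs
    # the third member of the printed series; theory places it at 1014.38
    assert 1014.38 in mzs


def test_antenna_fucose_y_series():
    """Antenna-fucosylated N4H5SF loses fucose, giving the fucose-free series."""
    mzs = _y_mzs(_topo("N4H5SF", s=["a26"], f=["antenna"]))
    assert {341.13, 544.21, 1233.45} <= mzs
    # the printed 1395.51 ion; theory places it at 1395.50
    assert 1395.50 in mzs


def test_diagnostic_ion_values_from_residue_arithmetic():
    ions = {i.diagnostic_for: i for i in diagnostic_sialic_ions()}
    a26 = RESIDUE_MASSES["S"] + CROSS_RING_C2H4O2 - HYDROGEN - CO2
    a23 = RESIDUE_MASSES["S"] + RESIDUE_MASSES["H"] - HYDROGEN - CO2
    assert ions["a26"].mz == pytest.approx(a26, abs=1e-9)
    assert ions["a23"].mz == pytest.approx(a23, abs=1e-9)
    assert round_half_away(ions["a26"].mz) == 306.12
    assert round_half_away(ions["a23"].mz) == 408.15


@st.composite
def random_topologies(draw):
    n_ant = draw(st.integers(1, 4))
    n_ng = draw(st.integers(0, 1))
    n_s = draw(st.integers(1, n_ant))
    n_f = draw(st.integers(0, min(3, n_ant + n_ng)))
    comp = parse_composition(
        f"N{2 + n_ant + n_ng}H{3 + n_ant + n_ng}S{n_s}" + (f"F{n_f}" if n_f else "")
        .replace("F1", "F"),
        labeled=True,
    )
    core_first = draw(st.booleans())
    if n_f:
        tags = (["core"] if core_first else ["antenna"]) + ["antenna"] * (n_f - 1)
        tags = tags[:n_f]
    else:
        tags = []
    return build_topology(comp, fucose_positions=tags)


@given(topo=random_topologies())
def test_by_pair_mass_conservation(topo):
    """Every single-cleavage B has a complementary Y; masses sum to the precursor."""
    precursor = neutral_mass(topo.composition())
    b_ions = enumerate_fragments(topo, ion_types={"B"}, max_cleavages=1)
    y_ions = enumerate_fragments(topo, ion_types={"Y"}, max_cleavages=1)
    y_neutrals = sorted(f.neutral for f in y_ions)
    for b in b_ions:
        complement = precursor - b.neutral
        assert any(abs(yn - complement) < 1e-6 for yn in y_neutrals)


@given(topo=random_topologies())
def test_cz_shifted_by_water(topo):
    c_ions = {f.label: f for f in enumerate_fragments(topo, ion_types={"C"})}
    b_ions = {f.label.replace("B", "C"): f for f in enumerate_fragments(topo, ion_types={"B"})}
    for label, c in c_ions.items():
        assert c.neutral == pytest.approx(b_ions[label].neutral + 18.01056, abs=1e-6)


def test_single_cleavage_count_on_asymmetric_chain():
    """A topology with all-distinct subtrees yields 2E B+Y fragments (E edges)."""
    topo = _topo("N3H4S")  # monoantennary: a linear chain, no mirror duplicates
    n_edges = len(topo.edges())
    frags = enumerate_fragments(topo, ion_types={"B", "Y"}, max_cleavages=1)
    assert len(frags) == 2 * n_edges


def test_max_cleavages_validated():
    with pytest.raises(ValueError):
        enumerate_fragments(_topo("N4H5S"), max_cleavages=4)


def test_match_spectrum_basics():
    cands = diagnostic_sialic_ions()
    spec = Spectrum(1000.0, 2, np.array([306.12, 306.50]), np.array([10.0, 5.0]))
    matches = match_spectrum(spec, cands, tol_ppm=10)
    assert len(matches) == 1 and matches[0].fragment.diagnostic_for == "a26"
    assert match_spectrum(Spectrum(1000.0, 2, np.array([]), np.array([])), cands) == []


def test_match_monotone_in_tolerance():
    topo = _topo("N4H5S2", s=["a23", "a26"])
    frags = enumerate_fragments(topo, ion_types={"Y", "B"}, max_cleavages=2)
    rng = np.random.default_rng(0)
    true_mz = np.array([f.mz for f in frags])
    obs = true_mz * (1 + rng.uniform(-15e-6, 15e-6, len(true_mz)))
    spec = Spectrum(1100.0, 2, obs, np.ones(len(obs)))
    sets = []
    for tol in (2, 5, 10, 20):
        matched = match_spectrum(spec, frags, tol_ppm=tol)
        sets.append({(m.peak_mz, m.fragment.label) for m in matched})
    for smaller, larger in zip(sets, sets[1:]):
        assert smaller <= larger


def _printed_spectrum(comp, peaks):
    precursor = mz(neutral_mass(comp), IonSpec(2))
    return Spectrum(precursor, 2, np.array(peaks), np.ones(len(peaks)))


def test_assign_core_fucose_alpha23():
    """Spectrum with the core-fucose Y series plus the 408.15 ion."""
    comp = parse_composition("N4H5SF", labeled=True)
    spec = _printed_spectrum(comp, [487.19, 690.27, 1014.38, 1176.43, 408.15])
    ev = assign_isomer_features(spec, comp, tol_ppm=20)
    assert ev.a23_evidence and not ev.a26_evidence
    assert ev.core_fucose_evidence and ev.core_fucose_confidence == "high"
    assert not ev.antenna_fucose_evidence
    assert all(ev.supporting[k] for k in ("a23", "core_fucose"))


def test_assign_core_fucose_low_confidence():
    """Only the small core-fucose Y ions present (a low-intensity isomer)."""
    comp = parse_composition("N4H5SF", labeled=True)
    spec = _printed_spectrum(comp, [487.19, 306.12])
    ev = assign_isomer_features(spec, comp, tol_ppm=20)
    assert ev.core_fucose_evidence and ev.core_fucose_confidence == "low"
    assert ev.a26_evidence


def test_assign_antenna_fucose_alpha26():
    comp = parse_composition("N4H5SF", labeled=True)
    spec = _printed_spectrum(comp, [341.13, 544.21, 1233.45, 1395.50, 306.12])
    ev = assign_isomer_features(spec, comp, tol_ppm=20)
    assert ev.a26_evidence and not ev.a23_evidence
    assert ev.antenna_fucose_evidence and not ev.core_fucose_evidence


def test_assign_mixed_linkages():
    comp = parse_composition("N4H5S2", labeled=True)
    spec = _printed_spectrum(comp, [306.12, 408.15])
    ev = assign_isomer_features(spec, comp, tol_ppm=20)
    assert ev.a23_evidence and ev.a26_evidence


def test_assign_rejects_precursor_mismatch():
    comp = parse_composition("N4H5SF", labeled=True)
    spec = Spectrum(900.0, 2, np.array([487.19]), np.array([1.0]))
    with pytest.raises(ValueError, match="precursor"):
        assign_isomer_features(spec, comp)


@pytest.mark.parametrize(
    "s_tag, f_tag, core, antenna",
    [("a23", "core", True, False), ("a26", "antenna", False, True)],
)
def test_generated_spectra_round_trip(s_tag, f_tag, core, antenna):
    """Synthetic spectra are assigned the tags their topology carries."""
    comp = parse_composition("N4H5SF", labeled=True)
    topo = build_topology(comp, sialic_linkages=[s_tag], fucose_positions=[f_tag])
    spec = generate_spectrum(topo, n_noise_peaks=15, seed=9)
    ev = assign_isomer_features(spec, comp)
    assert ev.core_fucose_evidence == core
    assert ev.antenna_fucose_evidence == antenna
    assert ev.a23_evidence == (s_tag == "a23")
    assert ev.a26_evidence == (s_tag == "a26")
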