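"""Domon–Costello fragment enumeration, spectrum matching, and isomer diagnostics.

Glycosidic cleavages of a rooted glycan tree give B/C ions (non-reducing
side retained) and Y/Z ions (reducing side retained, label kept).  Neutral
fragment masses follow the usual conventions:

    Y = retained residue sum + water (+ label)      Z = Y − water
    B = cleaved-off residue sum                     C = B + water

Two hard-coded cross-ring diagnostics identify sialic-acid linkage in
negative mode: the 0,4A2−CO2 ion at m/z 306.12 (α-2,6) and the B2−CO2 ion
at m/z 408.15 (α-2,3).  Fucose position is read from the small Y ions: a
fucose-retaining Y1 marks core fucosylation, while fucose-free Y1/Y2
together with larger fucose-free Y ions mark antenna fucosylation (antenna
fucose is bound more weakly and is lost preferentially on fragmentation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .masses import (
    CO2,
    CROSS_RING_C2H4O2,
    HYDROGEN,
    RESIDUE_MASSES,
    WATER,
    GlycanComposition,
    IonSpec,
    format_composition,
    mz,
    neutral_mass,
)
from .topology import GlycanTopology, Residue, build_topology

__all__ = [
    "FragmentIon",
    "Spectrum",
    "Match",
    "IsomerEvidence",
    "enumerate_fragments",
    "diagnostic_sialic_ions",
    "match_spectrum",
    "assign_isomer_features",
]


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical fragment ion."""

    ion_type: str  # B, C, Y, Z, A
    label: str  # Domon-Costello style label, e.g. "Y4/Y4" or "B2-CO2"
    composition: GlycanComposition  # residues retained (partial for A ions)
    neutral: float  # neutral fragment mass before deprotonation, Da
    charge: int = 1
    n_co2_losses: int = 0
    diagnostic_for: Optional[str] = None  # "a23" / "a26" for the two A/B diagnostics

    @property
    def mz(self) -> float:
        return mz(self.neutral, IonSpec(self.charge, self.n_co2_losses))


@dataclass
class Spectrum:
    """A negative-mode MS/MS peak list."""

    precursor_mz: float
    charge: int
    mz_array: np.ndarray
    intensity_array: np.ndarray
    source_id: str = ""
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz_array = np.asarray(self.mz_array, dtype=float)
        self.intensity_array = np.asarray(self.intensity_array, dtype=float)
        if self.mz_array.shape != self.intensity_array.shape:
            raise ValueError("m/z and intensity arrays must have equal length")
        if np.any(self.intensity_array < 0):
            raise ValueError("intensities must be >= 0")
        order = np.argsort(self.mz_array, kind="stable")
        self.mz_array = self.mz_array[order]
        self.intensity_array = self.intensity_array[order]

    def __len__(self) -> int:
        return len(self.mz_array)


@dataclass(frozen=True)
class Match:
    peak_mz: float
    intensity: float
    fragment: FragmentIon
    ppm_error: float
    ambiguous: bool = False


@dataclass
class IsomerEvidence:
    """Diagnostic-ion evidence for one isomer's linkage/fucose features.

    Flags are evidence, not verdicts: each True flag is backed by at least
    one matched ion listed in ``supporting``; absence of a flag means the
    diagnostic ions were not observed, which (as for low-intensity isomers)
    does not prove absence of the feature.
    """

    a23_evidence: bool = False
    a26_evidence: bool = False
    core_fucose_evidence: bool = False
    antenna_fucose_evidence: bool = False
    core_fucose_confidence: Optional[str] = None  # "high" (Y1+Y2) or "low" (Y1 only)
    supporting: dict[str, list[Match]] = field(default_factory=dict)


def _subtree_composition(node: Residue) -> GlycanComposition:
    counts = {"N": 0, "H": 0, "S": 0, "F": 0}
    for n in node.walk():
        counts[n.residue] += 1
    return GlycanComposition(counts["N"], counts["H"], counts["S"], counts["F"], False)


def _depths(topology: GlycanTopology) -> dict[int, int]:
    """Residue depth from the reducing end (root = 1), keyed by id(node)."""
    depths: dict[int, int] = {}

    def visit(node: Residue, d: int) -> None:
        depths[id(node)] = d
        for child in node.children:
            visit(child, d + 1)

    visit(topology.root, 1)
    return depths


def _subtree_height(node: Residue) -> int:
    if not node.children:
        return 1
    return 1 + max(_subtree_height(c) for c in node.children)


def diagnostic_sialic_ions() -> list[FragmentIon]:
    """The two sialic-acid linkage diagnostics (singly charged, one CO2 loss).

    0,4A2−CO2 (m/z 306.12): NeuAc residue plus the C2H4O2 remnant of the 0,4
    cross-ring cleavage of the adjacent galactose — formed by α-2,6-linked
    sialic acids.  B2−CO2 (m/z 408.15): NeuAc-Gal B2 ion after CO2 loss —
    formed by α-2,3-linked sialic acids.
    """
    a_ion = FragmentIon(
        ion_type="A",
        label="0,4A2-CO2",
        composition=GlycanComposition(n_neuac=1),
        neutral=RESIDUE_MASSES["S"] + CROSS_RING_C2H4O2,
        charge=1,
        n_co2_losses=1,
        diagnostic_for="a26",
    )
    b_ion = FragmentIon(
        ion_type="B",
        label="B2-CO2",
        composition=GlycanComposition(n_hex=1, n_neuac=1),
        neutral=RESIDUE_MASSES["S"] + RESIDUE_MASSES["H"],
        charge=1,
        n_co2_losses=1,
        diagnostic_for="a23",
    )
    return [a_ion, b_ion]


def enumerate_fragments(
    topology: GlycanTopology,
    ion_types: Iterable[str] = ("B", "Y"),
    max_cleavages: int = 1,
    charges: Iterable[int] = (1,),
) -> list[FragmentIon]:
    """Enumerate glycosidic-cleavage fragments up to ``max_cleavages`` cuts.

    Y/Z ions retain the reducing-end component after removing 1..max
    pairwise-independent subtrees; B/C ions are single-cleavage ions
    retaining one cleaved-off subtree.  If the topology is sialylated and
    "A" is among the requested ion types, the two hard-coded linkage
    diagnostics are appended.  The result is deduplicated by (label, m/z).
    """
    if max_cleavages not in (1, 2, 3):
        raise ValueError("max_cleavages must be 1, 2 or 3")
    ion_types = set(ion_types)
    unknown = ion_types - {"B", "C", "Y", "Z", "A"}
    if unknown:
        raise ValueError(f"unknown ion types: {sorted(unknown)}")
    charges = sorted(set(charges))
    depths = _depths(topology)
    edges = topology.edges()
    precursor = topology.composition()

    fragments: list[FragmentIon] = []

    def add(ion_type: str, label: str, comp: GlycanComposition, neutral: float) -> None:
        for z in charges:
            frag = FragmentIon(ion_type, label, comp, neutral, charge=z)
            try:
                frag.mz
            except ValueError:
                continue
            fragments.append(frag)

    if ion_types & {"B", "C"}:
        for parent, child in edges:
            comp = _subtree_composition(child)
            residue_sum = neutral_mass(comp) - WATER
            k = _subtree_height(child)
            if "B" in ion_types:
                add("B", f"B{k}", comp, residue_sum)
            if "C" in ion_types:
                add("C", f"C{k}", comp, residue_sum + WATER)

    if ion_types & {"Y", "Z"}:
        edge_nodes = {id(child) for _, child in edges}
        # an edge is "inside" another cut's removed subtree if its child lies there
        removed_sets = {
            id(child): {id(n) for n in child.walk()} for _, child in edges
        }
        for r in range(1, max_cleavages + 1):
            for combo in itertools.combinations(edges, r):
                ids = [id(child) for _, child in combo]
                # require pairwise independence (no cut inside another removed subtree)
                if any(
                    i != j and ids[j] in removed_sets[ids[i]]
                    for i in range(r)
                    for j in range(r)
                ):
                    continue
                removed = GlycanComposition()
                for _, child in combo:
                    removed = removed.merge(_subtree_composition(child))
                retained = precursor.subtract(removed)
                subscripts = sorted(depths[id(parent)] for parent, _ in combo)
                stem = "/".join(f"Y{s}" for s in subscripts)
                y_neutral = neutral_mass(retained)
                if "Y" in ion_types:
                    add("Y", stem, retained, y_neutral)
                if "Z" in ion_types:
                    add("Z", stem.replace("Y", "Z"), retained, y_neutral - WATER)

    if "A" in ion_types and precursor.n_neuac >= 1:
        fragments.extend(diagnostic_sialic_ions())

    seen: set[tuple[str, int, float]] = set()
    unique: list[FragmentIon] = []
    for frag in fragments:
        key = (frag.label, frag.charge, round(frag.mz, 4))
        if key not in seen:
            seen.add(key)
            unique.append(frag)
    return unique


def match_spectrum(
    spectrum: Spectrum, candidates: Sequence[FragmentIon], tol_ppm: float = 10.0
) -> list[Match]:
    """Match observed peaks to candidate ions within a ppm tolerance.

    Every (peak, candidate) pair within tolerance is reported; peaks with
    several candidates in tolerance have all their matches flagged
    ambiguous.  Matches are sorted by peak m/z.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if len(spectrum) == 0 or not candidates:
        return []
    matches: list[Match] = []
    per_peak: dict[int, list[int]] = {}
    cand_mz = np.array([c.mz for c in candidates])
    for i, (obs, inten) in enumerate(zip(spectrum.mz_array, spectrum.intensity_array)):
        ppm = (obs - cand_mz) / cand_mz * 1e6
        hits = np.flatnonzero(np.abs(ppm) <= tol_ppm)
        if len(hits):
            per_peak[i] = list(hits)
    for i, hits in per_peak.items():
        ambiguous = len(hits) > 1
        for j in hits:
            obs = spectrum.mz_array[i]
            matches.append(
                Match(
                    peak_mz=float(obs),
                    intensity=float(spectrum.intensity_array[i]),
                    fragment=candidates[j],
                    ppm_error=float((obs - cand_mz[j]) / cand_mz[j] * 1e6),
                    ambiguous=ambiguous,
                )
            )
    matches.sort(key=lambda m: (m.peak_mz, m.fragment.mz))
    return matches


def _is_retained(frag: FragmentIon, n_hexnac: int, n_fuc: int) -> bool:
    c = frag.composition
    return (
        frag.ion_type == "Y"
        and c.n_hexnac == n_hexnac
        and c.n_hex == 0
        and c.n_neuac == 0
        and c.n_fuc == n_fuc
    )


def assign_isomer_features(
    spectrum: Spectrum,
    comp: GlycanComposition,
    tol_ppm: float = 10.0,
    min_intensity: float = 0.0,
) -> IsomerEvidence:
    """Derive linkage and fucose-position evidence for one isomer's spectrum.

    The candidate set is the union of Y fragments from the canonical
    core-fucosylated and antenna-fucosylated variants of ``comp`` (up to
    triple cleavage) plus the two linkage diagnostics.  ``min_intensity``
    optionally ignores peaks below an absolute intensity floor.
    """
    comp = GlycanComposition(comp.n_hexnac, comp.n_hex, comp.n_neuac, comp.n_fuc, True)
    theo_precursor = mz(neutral_mass(comp), IonSpec(max(spectrum.charge, 1)))
    ppm_off = abs(spectrum.precursor_mz - theo_precursor) / theo_precursor * 1e6
    if ppm_off > tol_ppm:
        raise ValueError(
            f"precursor m/z {spectrum.precursor_mz:.4f} does not match composition "
            f"{format_composition(comp)} (theoretical {theo_precursor:.4f}, "
            f"{ppm_off:.1f} ppm off at tolerance {tol_ppm} ppm)"
        )

    candidates: list[FragmentIon] = list(diagnostic_sialic_ions())
    if comp.n_fuc >= 1:
        variants = [
            ["core"] + ["antenna"] * (comp.n_fuc - 1),
            ["antenna"] * comp.n_fuc,
        ]
    else:
        variants = [[]]
    for fuc_tags in variants:
        topo = build_topology(comp, fucose_positions=fuc_tags)
        candidates.extend(enumerate_fragments(topo, ion_types={"Y"}, max_cleavages=3))
    # dedupe across variants
    seen: set[tuple[str, int, float]] = set()
    unique: list[FragmentIon] = []
    for frag in candidates:
        key = (frag.label, frag.charge, round(frag.mz, 4))
        if key not in seen:
            seen.add(key)
            unique.append(frag)

    if min_intensity > 0:
        keep = spectrum.intensity_array >= min_intensity
        spectrum = Spectrum(
            spectrum.precursor_mz,
            spectrum.charge,
            spectrum.mz_array[keep],
            spectrum.intensity_array[keep],
            spectrum.source_id,
        )
    matches = match_spectrum(spectrum, unique, tol_ppm)

    evidence = IsomerEvidence()
    y1_fuc = [m for m in matches if _is_retained(m.fragment, 1, 1)]
    y2_fuc = [m for m in matches if _is_retained(m.fragment, 2, 1)]
    y1_plain = [m for m in matches if _is_retained(m.fragment, 1, 0)]
    y2_plain = [m for m in matches if _is_retained(m.fragment, 2, 0)]
    larger_defuc = [
        m
        for m in matches
        if m.fragment.ion_type == "Y"
        and m.fragment.composition.n_fuc == 0
        and m.fragment.composition.n_residues >= 5
    ]
    a23 = [m for m in matches if m.fragment.diagnostic_for == "a23"]
    a26 = [m for m in matches if m.fragment.diagnostic_for == "a26"]

    if a23:
        evidence.a23_evidence = True
        evidence.supporting["a23"] = a23
    if a26:
        evidence.a26_evidence = True
        evidence.supporting["a26"] = a26
    if comp.n_fuc >= 1:
        if y1_fuc:
            evidence.core_fucose_evidence = True
            evidence.core_fucose_confidence = "high" if y2_fuc else "low"
            evidence.supporting["core_fucose"] = y1_fuc + y2_fuc
        if y1_plain and y2_plain and larger_defuc:
            evidence.antenna_fucose_evidence = True
            evidence.supporting["antenna_fucose"] = y1_plain + y2_plain + larger_defuc
    return evidence
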