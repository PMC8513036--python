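"""Rooted residue trees for complex-type N-glycans.

A :class:`GlycanTopology` is a rooted tree whose root is the (optionally
AA-labeled) reducing-end GlcNAc.  The tree always contains the canonical
Man3GlcNAc2 core; antennae (GlcNAc–Gal, optionally sialylated and optionally
N-acetyllactosamine-extended) hang off the two branch mannoses.  Sialic
acids carry a linkage tag (``a23`` / ``a26`` / ``unknown``) and fucoses a
position tag (``core`` for fucose on the reducing-end GlcNAc, ``antenna``
for fucose on an antenna GlcNAc).

The exact branch placement of antennae in tri- and tetraantennary glycans
(2+1 and 2+2 on the two core-mannose arms) is a canonical template
assumption: chromatography can leave such assignments ambiguous, and
nothing downstream depends on which arm carries the extra antenna.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .masses import CompositionError, GlycanComposition, format_composition

__all__ = ["Residue", "GlycanTopology", "build_topology"]

SIALIC_TAGS = ("a23", "a26", "unknown")
FUCOSE_TAGS = ("core", "antenna", "unknown")


@dataclass
class Residue:
    """One monosaccharide node; ``residue`` is a class letter N/H/S/F."""

    residue: str
    children: list["Residue"] = field(default_factory=list)
    sialic_linkage: Optional[str] = None  # set on S residues
    fucose_position: Optional[str] = None  # set on F residues

    def add(self, child: "Residue") -> "Residue":
        self.children.append(child)
        return child

    def walk(self) -> Iterator["Residue"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class GlycanTopology:
    """Rooted residue tree; root is the reducing-end GlcNAc."""

    root: Residue
    labeled: bool = True

    def residues(self) -> Iterator[Residue]:
        return self.root.walk()

    def edges(self) -> list[tuple[Residue, Residue]]:
        """All glycosidic bonds as (parent, child) pairs, preorder."""
        out = []
        for parent in self.residues():
            for child in parent.children:
                out.append((parent, child))
        return out

    def composition(self) -> GlycanComposition:
        counts = {"N": 0, "H": 0, "S": 0, "F": 0}
        for node in self.residues():
            counts[node.residue] += 1
        return GlycanComposition(
            counts["N"], counts["H"], counts["S"], counts["F"], self.labeled
        )

    @property
    def sialic_linkages(self) -> list[str]:
        return [n.sialic_linkage or "unknown" for n in self.residues() if n.residue == "S"]

    @property
    def fucose_positions(self) -> list[str]:
        return [n.fucose_position or "unknown" for n in self.residues() if n.residue == "F"]

    def validate(self) -> None:
        if self.root.residue != "N":
            raise CompositionError("root must be the reducing-end GlcNAc")
        for node in self.residues():
            if node.residue == "F" and node.children:
                raise CompositionError("fucose must be a leaf")
            if node.residue == "S" and node.sialic_linkage not in SIALIC_TAGS:
                raise CompositionError("sialic acid missing a linkage tag")
            if node.residue == "F" and node.fucose_position not in FUCOSE_TAGS:
                raise CompositionError("fucose missing a position tag")
        # core fucose tag must match attachment to the root
        for child in self.root.children:
            if child.residue == "F" and child.fucose_position != "core":
                raise CompositionError("fucose on the reducing-end GlcNAc must be tagged core")


def _antenna_counts(n_antennae: int) -> tuple[int, int]:
    # canonical 1+1 / 2+1 / 2+2 arm placement
    upper = (n_antennae + 1) // 2
    return upper, n_antennae - upper


def build_topology(
    comp: GlycanComposition,
    sialic_linkages: Optional[Sequence[str]] = None,
    fucose_positions: Optional[Sequence[str]] = None,
) -> GlycanTopology:
    """Build the canonical complex-type topology for a composition.

    The antenna count is inferred as ``n_hex − 3`` (three core mannoses plus
    one galactose per antenna); any surplus HexNAc beyond ``2 + antennae`` is
    treated as N-acetyllactosamine extension of the last antenna (each unit
    consuming one HexNAc and one Hex, so an NG-extended glycan has equal
    surplus in both).  Sialic acids cap the first ``n_neuac`` antennae.

    Parameters
    ----------
    sialic_linkages : optional sequence of {"a23", "a26", "unknown"}, one per
        sialic acid (default all "unknown").
    fucose_positions : optional sequence of {"core", "antenna"}, one per
        fucose.  Default: first fucose core, the rest antenna.
    """
    if comp.n_hexnac < 2:
        raise CompositionError(f"{comp}: need at least the chitobiose core (2 HexNAc)")
    # Each antenna and each NG unit carries 1 HexNAc + 1 Hex, over the
    # Man3GlcNAc2 core, so a complex-type composition has n_hexnac = n_hex - 1.
    if comp.n_hexnac - 2 != comp.n_hex - 3:
        raise CompositionError(
            f"{comp}: not a complex-type composition (HexNAc/Hex counts inconsistent "
            "with a Man3GlcNAc2 core plus GlcNAc-Gal antennae)"
        )
    n_units = comp.n_hex - 3
    # N-glycans carry at most four antennae; surplus units are NG extensions.
    n_ant = min(n_units, 4)
    n_ng = n_units - n_ant
    if n_ant < 1:
        raise CompositionError(f"{comp}: at least one antenna required")
    if comp.n_neuac > n_ant:
        raise CompositionError(f"{comp}: more sialic acids than antenna termini")

    s_tags = list(sialic_linkages) if sialic_linkages is not None else ["unknown"] * comp.n_neuac
    if len(s_tags) != comp.n_neuac:
        raise CompositionError("one sialic linkage tag required per NeuAc")
    if fucose_positions is not None:
        f_tags = list(fucose_positions)
    else:
        f_tags = ["core"] + ["antenna"] * (comp.n_fuc - 1) if comp.n_fuc else []
    if len(f_tags) != comp.n_fuc:
        raise CompositionError("one fucose position tag required per fucose")
    if f_tags.count("core") > 1:
        raise CompositionError("at most one core fucose")

    root = Residue("N")
    glcnac2 = root.add(Residue("N"))
    core_man = glcnac2.add(Residue("H"))
    arm_a = core_man.add(Residue("H"))
    arm_b = core_man.add(Residue("H"))

    n_upper, n_lower = _antenna_counts(n_ant)
    antenna_terminals: list[Residue] = []  # galactose termini, in antenna order
    antenna_glcnacs: list[Residue] = []
    for arm, count in ((arm_a, n_upper), (arm_b, n_lower)):
        for _ in range(count):
            gn = arm.add(Residue("N"))
            gal = gn.add(Residue("H"))
            antenna_glcnacs.append(gn)
            antenna_terminals.append(gal)
    # NG extension: Gal-GlcNAc repeats on the last antenna
    tip = antenna_terminals[-1]
    for _ in range(n_ng):
        gn = tip.add(Residue("N"))
        tip = gn.add(Residue("H"))
        antenna_glcnacs.append(gn)
        antenna_terminals[-1] = tip

    for i, tag in enumerate(s_tags):
        if tag not in SIALIC_TAGS:
            raise CompositionError(f"unknown sialic linkage tag {tag!r}")
        antenna_terminals[i].add(Residue("S", sialic_linkage=tag))

    next_antenna = 0
    for tag in f_tags:
        if tag == "core":
            root.add(Residue("F", fucose_position="core"))
        elif tag == "antenna":
            if next_antenna >= len(antenna_glcnacs):
                raise CompositionError(f"{comp}: more antenna fucoses than antennae")
            antenna_glcnacs[next_antenna].add(Residue("F", fucose_position="antenna"))
            next_antenna += 1
        else:
            raise CompositionError(f"unknown fucose position tag {tag!r}")

    topo = GlycanTopology(root, labeled=comp.labeled)
    built = topo.composition()
    if built.counts != comp.counts:
        raise CompositionError(
            f"template mismatch: built {format_composition(built)}, wanted {format_composition(comp)}"
        )
    topo.validate()
    return topo
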