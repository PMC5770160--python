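"""PyMOL script emission for SIPRIS clusters.

Pattern residues are shown as sidechain sticks colored by hierarchy level
(0 superfamily yellow, 1 family red, 2 subfamily orange, 3 sub-subfamily
green); glycines, having no sidechain, are shown as CA spheres.  Pattern
residues outside the optimal cluster are rendered semi-transparent to
distinguish them from cluster members.  Scripts are plain text, one command
per line, and are validated by parsing rather than by running a viewer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .engine import SiprisResult
from .pattern_io import PatternSet
from .structure import ResidueKey

logger = logging.getLogger("sipris.viz")

__all__ = ["VizSpec", "pymol_script", "parse_selections"]

DEFAULT_LEVEL_COLORS = {0: "yellow", 1: "red", 2: "orange", 3: "green"}


@dataclass(frozen=True)
class VizSpec:
    structure_id: str
    level_colors: Optional[Dict[int, str]] = None
    glycine_as_spheres: bool = True

    def colors(self) -> Dict[int, str]:
        return dict(DEFAULT_LEVEL_COLORS if self.level_colors is None
                    else self.level_colors)


def _sel_expr(keys: Sequence[ResidueKey]) -> str:
    by_chain: Dict[str, List[str]] = {}
    for k in keys:
        by_chain.setdefault(k.chain, []).append(f"{k.seqnum}{k.icode}")
    parts = [f"(chain {ch} and resi {'+'.join(nums)})"
             for ch, nums in sorted(by_chain.items())]
    return " or ".join(parts)


def pymol_script(result: SiprisResult, pattern: PatternSet,
                 spec: VizSpec) -> str:
    """Emit a PyMOL command script displaying the cluster and pattern.

    Selections use author chain + residue numbers.  Selection names encode
    hierarchy level and cluster membership (``pat_lvl<k>_in`` /
    ``pat_lvl<k>_out``); a ``cluster`` selection covers the whole optimal
    cluster.
    """
    colors = spec.colors()
    lines = [f"load {spec.structure_id}",
             "hide everything",
             "show cartoon",
             "color gray80"]
    if result.cluster_members:
        lines.append(f"select cluster, {_sel_expr(result.cluster_members)}")
        lines.append("color skyblue, cluster")
    in_cluster = set(result.cluster_members)
    if not pattern.entries:
        logger.warning("empty pattern set: emitting structure-only script")
        lines.append("deselect")
        return "\n".join(lines) + "\n"
    gly: List[ResidueKey] = []
    by_level_in: Dict[int, List[ResidueKey]] = {}
    by_level_out: Dict[int, List[ResidueKey]] = {}
    for e in pattern.entries:
        if not isinstance(e.residue, ResidueKey):
            raise ValueError("pattern must be in structure space for viz")
        if spec.glycine_as_spheres and e.name.upper() == "GLY":
            gly.append(e.residue)
        target = by_level_in if e.residue in in_cluster else by_level_out
        target.setdefault(e.level, []).append(e.residue)
    gly_set = set(gly)
    for level in sorted(set(by_level_in) | set(by_level_out)):
        color = colors.get(level, "magenta")
        for tag, group in (("in", by_level_in.get(level, [])),
                           ("out", by_level_out.get(level, []))):
            sticks = [k for k in group if k not in gly_set]
            if not sticks:
                continue
            name = f"pat_lvl{level}_{tag}"
            lines.append(f"select {name}, {_sel_expr(sticks)}")
            lines.append(f"show sticks, {name} and sidechain")
            lines.append(f"color {color}, {name}")
            if tag == "out":
                lines.append(f"set stick_transparency, 0.5, {name}")
    if gly:
        lines.append(f"select pat_gly, ({_sel_expr(gly)}) and name CA")
        lines.append("show spheres, pat_gly")
        for e in pattern.entries:
            if e.residue in gly_set:
                lines.append(f"color {colors.get(e.level, 'magenta')}, "
                             f"pat_gly and {_sel_expr([e.residue])}")
    lines.append("deselect")
    return "\n".join(lines) + "\n"


def parse_selections(script: str) -> Dict[str, List[Tuple[str, str]]]:
    """Parse ``select`` lines back into {name: [(chain, resi), ...]}.

    Used to verify that emitted selections reproduce the intended residue
    sets exactly.
    """
    import re
    out: Dict[str, List[Tuple[str, str]]] = {}
    rx = re.compile(r"chain (\S+) and resi ([\w+]+)")
    for line in script.splitlines():
        if not line.startswith("select "):
            continue
        name, expr = line[len("select "):].split(",", 1)
        sels = []
        for m in rx.finditer(expr):
            for num in m.group(2).split("+"):
                sels.append((m.group(1), num))
        out[name.strip()] = sels
    return out
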