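"""Full SIPRIS runs: pattern + structure (or DCA scores) + mode -> ordering
-> binary profile -> ICA statistics -> best Bonferroni-adjusted result.

A run either scores a *predefined* cluster with the exact cumulative
hypergeometric tail, or *optimizes* over nested clusters grown from one or
more start residues.  Without a focal point every pattern residue serves as
a start in turn and the most significant result is returned, Bonferroni-
adjusted by the number of starts actually scanned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from . import ica
from .expansion import (DcaScores, ResidueOrdering, core_ordering,
                        dca_core_ordering, dca_spherical_ordering,
                        hbond_ordering, predefined_counts, spherical_ordering)
from .ica import BinaryProfile, CutResult
from .pattern_io import PatternSet
from .structure import HydrogenBond, ResidueKey, StructureModel

logger = logging.getLogger("sipris.engine")

__all__ = ["SiprisResult", "StartResult", "run_predefined", "run_optimized",
           "make_profile", "report"]

MODE_BUILDERS = {"S": "spherical", "C": "core", "H": "hbond-H",
                 "B": "hbond-B", "DS": "dca-spherical", "DC": "dca-core"}


@dataclass(frozen=True)
class StartResult:
    start: ResidueKey
    cut: CutResult
    p_raw: float


@dataclass(frozen=True)
class SiprisResult:
    """One SIPRIS analysis: the optimal cluster and its significance.

    ``dist``/``init``/``term`` follow the report convention: pattern
    residues inside the cluster, cluster size, and residues outside it
    (init + term = L).
    """

    mode: str
    start: Union[ResidueKey, str]
    dist: int
    init: int
    term: int
    p_raw: float
    p_adjusted: float
    starts_tried: int
    cluster_members: Tuple[ResidueKey, ...]
    pattern_in_cluster: Tuple[ResidueKey, ...]
    L: int
    D: int
    per_start: Tuple[StartResult, ...] = ()

    def __post_init__(self):
        if self.init + self.term != self.L:
            raise ValueError("init + term must equal L")
        if self.dist > min(self.init, self.D):
            raise ValueError("dist cannot exceed cluster size or pattern size")
        if self.p_adjusted < self.p_raw - 1e-15:
            raise ValueError("adjusted p cannot be smaller than raw p")
        if len(self.cluster_members) != self.init:
            raise ValueError("cluster_members must have init elements")


def _pattern_keys_in_model(pattern: PatternSet,
                           model_keys: Sequence[ResidueKey]) -> Set[ResidueKey]:
    keys = set(model_keys)
    pat = {e.residue for e in pattern.entries}
    missing = pat - keys
    if missing:
        logger.warning("%d pattern residue(s) not in structure, dropped "
                       "from D: %s", len(missing), sorted(missing))
    return pat & keys


def make_profile(ordering: ResidueOrdering, pattern: PatternSet) -> BinaryProfile:
    """Binary profile along an ordering: bit i is 1 iff residue i is a
    pattern residue."""
    pat = {e.residue for e in pattern.entries}
    unknown = pat - set(ordering.order)
    if unknown:
        raise ValueError(f"pattern residues not in ordering: {sorted(unknown)}")
    bits = tuple(1 if k in pat else 0 for k in ordering.order)
    return BinaryProfile(bits=bits,
                         ordering_id=f"{ordering.mode}@{ordering.start}")


def run_predefined(model: StructureModel, pattern: PatternSet,
                   cluster: Set[ResidueKey]) -> SiprisResult:
    """Score a predefined cluster with the exact hypergeometric tail.

    This is a ball-in-urn problem: D pattern residues are the red balls,
    the L - D others black, and the cluster is the draw.  No multi-start
    correction applies, so p_adjusted == p_raw.
    """
    x, m, y, n = predefined_counts(cluster, pattern, model)
    L, D = x + y, m + n
    p = ica.hypergeom_tail(m, x, D, L - D)
    members = tuple(sorted(cluster))
    pat_in = tuple(sorted(k for k in cluster
                          if k in {e.residue for e in pattern.entries}))
    return SiprisResult(mode="P", start="predefined", dist=m, init=x, term=y,
                        p_raw=p, p_adjusted=p, starts_tried=1,
                        cluster_members=members, pattern_in_cluster=pat_in,
                        L=L, D=D)


def _build_ordering(source, mode: str, start: ResidueKey, k: int,
                    metric: str, bonds) -> ResidueOrdering:
    if mode == "S":
        return spherical_ordering(source, start, metric=metric)
    if mode == "C":
        return core_ordering(source, start, k=k, metric=metric)
    if mode in ("H", "B"):
        return hbond_ordering(source, start, mode=mode, bonds=bonds,
                              metric=metric)
    if mode == "DS":
        return dca_spherical_ordering(source, start)
    if mode == "DC":
        return dca_core_ordering(source, start, k=k)
    raise ValueError(f"unknown mode {mode!r}; expected one of "
                     f"{sorted(MODE_BUILDERS)}")


def run_optimized(source: Union[StructureModel, DcaScores],
                  pattern: PatternSet, mode: str = "S",
                  starts: Optional[Sequence[ResidueKey]] = None,
                  k: int = 7, metric: str = "min-atom",
                  bonds: Optional[Sequence[HydrogenBond]] = None,
                  empirical: bool = False, reps: int = 10_000,
                  seed: int = 0) -> SiprisResult:
    """Optimize the cluster over nested expansions from each start residue.

    By default every pattern residue present in the structure is used as a
    start in turn; passing ``starts`` (e.g. the single residue nearest a
    focal point) restricts the scan.  The best raw p-value is Bonferroni-
    adjusted by the number of starts actually scanned.  With ``empirical``
    the permutation p-value replaces the analytic one (same optimization).
    """
    model_keys = (source.keys() if isinstance(source, StructureModel)
                  else list(source.keys))
    pat_present = _pattern_keys_in_model(pattern, model_keys)
    if not pat_present:
        raise ValueError("no pattern residue maps onto the structure")
    if starts is None:
        start_list = sorted(pat_present)
    else:
        start_list = list(starts)
        unknown = [s for s in start_list if s not in set(model_keys)]
        if unknown:
            raise KeyError(f"start residue(s) not in model: {unknown}")
    pattern_present = PatternSet(
        entries=tuple(
            type(pattern.entries[0])(residue=e.residue, level=e.level,
                                     rank=i + 1, score=e.score, name=e.name)
            for i, e in enumerate(e2 for e2 in pattern.entries
                                  if e2.residue in pat_present)),
        coordinate_space=pattern.coordinate_space) if len(pat_present) < pattern.D \
        else pattern

    results: List[Tuple[float, ResidueKey, CutResult, ResidueOrdering]] = []
    for i, start in enumerate(start_list):
        ordering = _build_ordering(source, mode, start, k, metric, bonds)
        profile = make_profile(ordering, pattern_present)
        cut = ica.optimal_cut(profile)
        if empirical:
            p_raw = ica.empirical_pvalue(profile, reps=reps,
                                         seed=(seed, i))
        else:
            p_raw = cut.p_analytic
        results.append((p_raw, start, cut, ordering))
    p_best, start_best, cut_best, ord_best = min(
        results, key=lambda r: (r[0], r[1]))
    starts_tried = len(start_list)
    p_adj = ica.bonferroni(p_best, starts_tried)
    members = tuple(ord_best.order[:cut_best.x])
    pat_in = tuple(sorted(set(members) & pat_present))
    per_start = tuple(StartResult(start=s, cut=c, p_raw=p)
                      for p, s, c, _ in results)
    return SiprisResult(mode=mode, start=start_best, dist=cut_best.m,
                        init=cut_best.x, term=cut_best.y, p_raw=p_best,
                        p_adjusted=p_adj, starts_tried=starts_tried,
                        cluster_members=members, pattern_in_cluster=pat_in,
                        L=cut_best.L, D=cut_best.D, per_start=per_start)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def report(result: SiprisResult, pattern: Optional[PatternSet] = None,
           format: str = "text") -> str:
    """Render a result as human-readable text or stable-ordered TSV.

    Columns follow the Dist / Init / Term / p-value convention; the cluster
    member list carries each pattern residue's hierarchy level.
    """
    levels: Dict[ResidueKey, int] = {}
    if pattern is not None:
        for e in pattern.entries:
            if isinstance(e.residue, ResidueKey):
                levels[e.residue] = e.level
    if format == "tsv":
        lines = ["mode\tstart\tdist\tinit\tterm\tp_raw\tp_adjusted\t"
                 "starts_tried\tL\tD"]
        lines.append("\t".join(str(v) for v in (
            result.mode, result.start, result.dist, result.init, result.term,
            repr(result.p_raw), repr(result.p_adjusted), result.starts_tried,
            result.L, result.D)))
        lines.append("# cluster_members\tlevel")
        for kk in result.cluster_members:
            lv = levels.get(kk, "")
            lines.append(f"{kk}\t{lv}")
        return "\n".join(lines) + "\n"
    if format != "text":
        raise ValueError(f"unknown report format {format!r}")
    out = [f"SIPRIS result (mode {result.mode})",
           f"  start residue : {result.start}",
           f"  starts tried  : {result.starts_tried}",
           f"  Dist / Init / Term : {result.dist} / {result.init} / "
           f"{result.term}",
           f"  p-value (raw)      : {ica.format_pvalue(result.p_raw)}",
           f"  p-value (adjusted) : {ica.format_pvalue(result.p_adjusted)}"]
    if result.pattern_in_cluster:
        out.append("  pattern residues in cluster:")
        for kk in result.pattern_in_cluster:
            lv = levels.get(kk)
            tag = f" (level {lv})" if lv is not None else ""
            out.append(f"    {kk}{tag}")
    return "\n".join(out) + "\n"
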