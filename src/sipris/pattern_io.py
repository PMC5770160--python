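"""Pattern-residue sets and the cma (collinear multiple alignment) format.

A pattern set is a ranked list of distinguishing residues, each carrying a
hierarchy level (0 superfamily, 1 family, 2 subfamily, 3 sub-subfamily) and
a log-odds score.  Pattern files are tool-defined TSV; patterns expressed in
alignment-column space can be mapped onto a structure through the aligned
query sequence of a cma alignment.

The cma format stores one or more (hierarchically arranged) MSAs as plain
text: a header line ``[<node>_(<blocks>)=<name>(<nseqs>){<params>}:``, a
column line ``(<ncols>)<mask>``, then one triplet of lines per sequence ---
``$<ordinal>=<length>(<span>):``, a fasta identifier line, and the aligned
string in braces where uppercase letters are match states, lowercase are
insertions, '-' is a deletion, and parenthesized ends are flanking regions
--- and finally a terminator ``_<node>].``.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import pandas as pd

from .structure import ResidueKey, StructureModel

logger = logging.getLogger("sipris.pattern_io")

__all__ = [
    "PatternEntry",
    "PatternSet",
    "CmaSequence",
    "CmaAlignment",
    "CmaFormatError",
    "parse_cma",
    "write_cma",
    "cma_to_fasta",
    "load_pattern_set",
    "write_pattern_set",
    "map_pattern_to_structure",
]

DEFAULT_DEPTH = 25  # pattern residues considered, ranked by log-odds score


# ---------------------------------------------------------------------------
# pattern sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternEntry:
    residue: Union[ResidueKey, int]  # ResidueKey or alignment column (1-based)
    level: int
    rank: int
    score: float
    name: str = ""

    def __post_init__(self):
        if self.level not in (0, 1, 2, 3):
            raise ValueError(f"hierarchy level must be 0-3, got {self.level}")
        if self.rank < 1:
            raise ValueError("ranks start at 1")


@dataclass(frozen=True)
class PatternSet:
    entries: Tuple[PatternEntry, ...]
    coordinate_space: str = "structure"  # or "alignment-column"

    def __post_init__(self):
        ranks = [e.rank for e in self.entries]
        if sorted(ranks) != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be unique and contiguous from 1")
        object.__setattr__(self, "entries",
                           tuple(sorted(self.entries, key=lambda e: e.rank)))

    @property
    def D(self) -> int:
        return len(self.entries)

    def residues(self):
        return [e.residue for e in self.entries]

    def level_of(self, residue) -> int:
        for e in self.entries:
            if e.residue == residue:
                return e.level
        raise KeyError(residue)

    def truncated(self, depth: int) -> "PatternSet":
        return PatternSet(entries=self.entries[:depth],
                          coordinate_space=self.coordinate_space)


PATTERN_COLUMNS = ["chain", "resnum", "icode", "resname", "level", "rank", "score"]


def load_pattern_set(text: str, depth: Optional[int] = DEFAULT_DEPTH) -> PatternSet:
    """Load a pattern TSV (columns chain, resnum, icode, resname, level,
    rank, score); keeps the top ``depth`` entries by rank (default 25)."""
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#",
                     dtype={"chain": str, "icode": str})
    missing = [c for c in PATTERN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pattern file lacks column(s): {missing}")
    if df["rank"].duplicated().any():
        dupes = sorted(df.loc[df["rank"].duplicated(), "rank"])
        raise ValueError(f"duplicate rank(s) in pattern file: {dupes}")
    df = df.sort_values("rank")
    entries = []
    for _, row in df.iterrows():
        icode = "" if pd.isna(row["icode"]) else str(row["icode"]).strip()
        entries.append(PatternEntry(
            residue=ResidueKey(str(row["chain"]), int(row["resnum"]), icode),
            level=int(row["level"]), rank=int(row["rank"]),
            score=float(row["score"]), name=str(row["resname"])))
    ps = PatternSet(entries=tuple(entries))
    if depth is not None and ps.D > depth:
        ps = ps.truncated(depth)
    return ps


def write_pattern_set(pattern: PatternSet) -> str:
    rows = []
    for e in pattern.entries:
        if not isinstance(e.residue, ResidueKey):
            raise ValueError("only structure-space patterns can be written as TSV")
        rows.append({"chain": e.residue.chain, "resnum": e.residue.seqnum,
                     "icode": e.residue.icode, "resname": e.name,
                     "level": e.level, "rank": e.rank, "score": e.score})
    df = pd.DataFrame(rows, columns=PATTERN_COLUMNS)
    return df.to_csv(sep="\t", index=False)


# ---------------------------------------------------------------------------
# cma format
# ---------------------------------------------------------------------------

class CmaFormatError(ValueError):
    pass


@dataclass(frozen=True)
class CmaSequence:
    ordinal: int
    full_length: int
    span_value: int  # residues plus deletions minus insertions (kept verbatim)
    fasta_id: str
    aligned: str  # brace content incl. parenthesized flanks, e.g. "(AB)CD-e(F)"

    _RX = re.compile(r"^(?:\(([A-Za-z]*)\))?([A-Za-z\-]*)(?:\(([A-Za-z]*)\))?$")

    def _parts(self):
        m = self._RX.match(self.aligned)
        if m is None:
            raise CmaFormatError(f"cannot parse aligned string {self.aligned!r}")
        return (m.group(1) or "", m.group(2) or "", m.group(3) or "")

    @property
    def left_flank(self) -> str:
        return self._parts()[0]

    @property
    def right_flank(self) -> str:
        return self._parts()[2]

    @property
    def body(self) -> str:
        return self._parts()[1]

    def match_state_count(self) -> int:
        # uppercase letters are aligned residues, '-' are deletions; both
        # occupy alignment columns
        return sum(1 for c in self.body if c.isupper() or c == "-")

    def insertion_count(self) -> int:
        return sum(1 for c in self.body if c.islower())

    def match_states(self) -> str:
        return "".join(c for c in self.body if c.isupper() or c == "-")

    def ungapped(self) -> str:
        """All residues of the aligned region (match + insertions, no '-')."""
        return "".join(c for c in self.body if c.isalpha()).upper()


@dataclass(frozen=True)
class CmaAlignment:
    node_id: int
    block_count: int
    name: str
    n_seqs: int
    params: str
    n_columns: int
    sampled_columns: str
    sequences: Tuple[CmaSequence, ...]

    def __post_init__(self):
        if self.n_seqs != len(self.sequences):
            raise CmaFormatError(
                f"alignment '{self.name}' declares {self.n_seqs} sequences "
                f"but holds {len(self.sequences)}")
        for s in self.sequences:
            if s.match_state_count() != self.n_columns:
                raise CmaFormatError(
                    f"sequence ${s.ordinal} ({s.fasta_id}) has "
                    f"{s.match_state_count()} match states, expected "
                    f"{self.n_columns}")


_HEADER_RX = re.compile(
    r"^\[(\d+)_\((\d+)\)=(.*?)\((\d+)\)\{(.*)\}:\s*$")
_COLS_RX = re.compile(r"^\((\d+)\)(\S*)\s*$")
_SEQ_RX = re.compile(r"^\$(\d+)\s*=\s*(\d+)\((\d+)\):\s*$")
_ALN_RX = re.compile(r"^\{(.*)\}\*\s*$")
_END_RX = re.compile(r"^_(\d+)\]\.\s*$")


def parse_cma(text: str) -> List[CmaAlignment]:
    """Parse one or more concatenated cma-format MSAs."""
    lines = [ln.rstrip("\n") for ln in text.splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise CmaFormatError("empty cma input")
    out: List[CmaAlignment] = []
    i = 0
    while i < len(lines):
        mh = _HEADER_RX.match(lines[i])
        if mh is None:
            raise CmaFormatError(f"bad cma header at line {i + 1}: {lines[i]!r}")
        node, blocks, name, nseqs = (int(mh.group(1)), int(mh.group(2)),
                                     mh.group(3), int(mh.group(4)))
        params = mh.group(5)
        i += 1
        mc = _COLS_RX.match(lines[i]) if i < len(lines) else None
        if mc is None:
            raise CmaFormatError(f"bad cma column line at line {i + 1}")
        ncols, mask = int(mc.group(1)), mc.group(2)
        i += 1
        seqs: List[CmaSequence] = []
        while i < len(lines) and not _END_RX.match(lines[i]):
            ms = _SEQ_RX.match(lines[i])
            if ms is None:
                raise CmaFormatError(
                    f"bad cma sequence line at line {i + 1}: {lines[i]!r}")
            if i + 2 >= len(lines):
                raise CmaFormatError(
                    f"truncated cma sequence record at line {i + 1}")
            fid = lines[i + 1]
            if not fid.startswith(">"):
                raise CmaFormatError(
                    f"expected fasta identifier at line {i + 2}: {fid!r}")
            ma = _ALN_RX.match(lines[i + 2])
            if ma is None:
                raise CmaFormatError(
                    f"bad cma aligned string at line {i + 3}: {lines[i + 2]!r}")
            seqs.append(CmaSequence(ordinal=int(ms.group(1)),
                                    full_length=int(ms.group(2)),
                                    span_value=int(ms.group(3)),
                                    fasta_id=fid[1:].strip(),
                                    aligned=ma.group(1)))
            i += 3
        if i >= len(lines):
            raise CmaFormatError(f"missing cma terminator for node {node}")
        me = _END_RX.match(lines[i])
        if int(me.group(1)) != node:
            raise CmaFormatError(
                f"terminator node {me.group(1)} does not match header node "
                f"{node} (line {i + 1})")
        i += 1
        out.append(CmaAlignment(node_id=node, block_count=blocks, name=name,
                                n_seqs=nseqs, params=params, n_columns=ncols,
                                sampled_columns=mask, sequences=tuple(seqs)))
    return out


def write_cma(alignments: Sequence[CmaAlignment]) -> str:
    """Render alignments back to cma text; ``parse_cma`` round-trips it."""
    chunks = []
    for a in alignments:
        lines = [f"[{a.node_id}_({a.block_count})={a.name}({a.n_seqs})"
                 f"{{{a.params}}}:",
                 f"({a.n_columns}){a.sampled_columns}"]
        for s in a.sequences:
            lines.append(f"${s.ordinal}={s.full_length}({s.span_value}):")
            lines.append(f">{s.fasta_id}")
            lines.append(f"{{{s.aligned}}}*")
        lines.append(f"_{a.node_id}].")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + ("\n" if chunks else "")


def cma_to_fasta(alignment: CmaAlignment) -> str:
    """FASTA export of the match states of every sequence."""
    recs = []
    for s in alignment.sequences:
        recs.append(f">{s.fasta_id}\n{s.match_states()}")
    return "\n".join(recs) + ("\n" if recs else "")


# ---------------------------------------------------------------------------
# mapping alignment-column patterns onto a structure
# ---------------------------------------------------------------------------

def map_pattern_to_structure(pattern: PatternSet, query_row: CmaSequence,
                             model: StructureModel) -> PatternSet:
    """Map alignment-column pattern entries onto structure residues.

    The query row's residues (match states plus insertions, gaps removed)
    must occur as an exact contiguous substring of the model's one-letter
    sequence; the placement fixes a single constant offset.  Columns that
    are deletions in the query row cannot be mapped and are dropped with a
    warning.
    """
    if pattern.coordinate_space != "alignment-column":
        raise ValueError("pattern is not in alignment-column space")
    qseq = query_row.ungapped()
    mseq = model.sequence()
    pos = mseq.find(qseq)
    if pos < 0:
        raise ValueError(
            "query row sequence not found in the structure; supply a "
            "manually offset pattern in structure space instead")
    # column (1-based among match states) -> index into ungapped query
    col = 0
    res_i = 0
    col_to_resi = {}
    for c in query_row.body:
        if c.isupper():
            col += 1
            col_to_resi[col] = res_i
            res_i += 1
        elif c == "-":
            col += 1
            col_to_resi[col] = None
        elif c.islower():
            res_i += 1
    mapped = []
    dropped = []
    rank = 0
    for e in pattern.entries:
        ri = col_to_resi.get(e.residue)
        if ri is None:
            dropped.append(e.residue)
            continue
        rank += 1
        res = model.residues[pos + ri]
        mapped.append(PatternEntry(residue=res.key, level=e.level, rank=rank,
                                   score=e.score, name=res.name))
    if dropped:
        logger.warning("dropped %d unmappable pattern column(s): %s",
                       len(dropped), dropped)
    return PatternSet(entries=tuple(mapped), coordinate_space="structure")
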