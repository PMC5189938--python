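"""Short protein-change (HGVS-p one-letter) parsing and consequence classification.

The panel reports use the compact one-letter spelling common in targeted-
sequencing papers: ``R130G`` (missense), ``T41T`` (silent), ``W111*``
(stop gain), ``L318fs`` (frameshift), ``Y463del`` / ``T576delT`` (in-frame
deletion) and the range forms ``Y463_L466del`` / ``E775_F776fs``.  A compound
two-residue frameshift anchor (``K780Q781fs``) is also accepted.  Anything
else parses as ``other`` with the raw string preserved.

Full HGVS nomenclature (c./g. syntax, splice notation, insertions) is out of
scope: ``ins`` forms deliberately classify as ``other``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Tuple


class ChangeKind(str, Enum):
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    INFRAME_DEL = "inframe_del"
    SILENT = "silent"
    OTHER = "other"


#: fine-grained classes used in cohort reports
class ConsequenceClass(str, Enum):
    MISSENSE = "missense"
    STOP = "stop"
    FRAMESHIFT = "frameshift"
    INFRAME = "inframe"
    SILENT = "silent"
    OTHER = "other"


AA = "ACDEFGHIKLMNPQRSTVWY"

_RANGE_DEL = re.compile(rf"^([{AA}])(\d+)_([{AA}])(\d+)del$")
_RANGE_FS = re.compile(rf"^([{AA}])(\d+)_([{AA}])(\d+)fs$")
_COMPOUND_FS = re.compile(rf"^([{AA}])(\d+)([{AA}])(\d+)fs$")
_SINGLE_DEL = re.compile(rf"^([{AA}])(\d+)del([{AA}]?)$")
_SINGLE_FS = re.compile(rf"^([{AA}])(\d+)fs$")
_STOP = re.compile(rf"^([{AA}])(\d+)\*$")
_SUBST = re.compile(rf"^([{AA}])(\d+)([{AA}])$")


class ProteinChangeParseError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinChange:
    """A parsed short-form protein change."""

    raw: str
    start_residue: Tuple[str, int]
    change_kind: ChangeKind
    end_residue: Optional[Tuple[str, int]] = None
    new_residue: Optional[str] = None

    @property
    def position(self) -> int:
        return self.start_residue[1]

    @property
    def positions(self) -> range:
        """All residue positions spanned by the change (inclusive)."""
        end = self.end_residue[1] if self.end_residue else self.position
        return range(self.position, end + 1)

    def serialize(self) -> str:
        """Re-emit the canonical short spelling; inverse of :func:`parse_protein_change`."""
        a, p = self.start_residue
        if self.change_kind is ChangeKind.OTHER:
            return self.raw
        if self.end_residue is not None:
            b, q = self.end_residue
            joiner = "_" if "_" in self.raw else ""
            suffix = "del" if self.change_kind is ChangeKind.INFRAME_DEL else "fs"
            return f"{a}{p}{joiner}{b}{q}{suffix}"
        if self.change_kind is ChangeKind.STOP_GAIN:
            return f"{a}{p}*"
        if self.change_kind is ChangeKind.FRAMESHIFT:
            return f"{a}{p}fs"
        if self.change_kind is ChangeKind.INFRAME_DEL:
            return f"{a}{p}del{self.new_residue or ''}"
        return f"{a}{p}{self.new_residue}"


def parse_protein_change(raw: str) -> ProteinChange:
    """Parse a short protein-change string.

    Unknown-but-nonempty forms are preserved as ``ChangeKind.OTHER`` rather
    than rejected, so novel spellings never abort a cohort run; only the empty
    string is an error.
    """
    if not raw or not raw.strip():
        raise ProteinChangeParseError("empty protein-change string")
    raw = raw.strip()

    m = _RANGE_DEL.match(raw)
    if m:
        a, p, b, q = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
        if q < p:
            return ProteinChange(raw, (a, p), ChangeKind.OTHER)
        return ProteinChange(raw, (a, p), ChangeKind.INFRAME_DEL, end_residue=(b, q))
    m = _RANGE_FS.match(raw) or _COMPOUND_FS.match(raw)
    if m:
        a, p, b, q = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
        if q < p:
            return ProteinChange(raw, (a, p), ChangeKind.OTHER)
        return ProteinChange(raw, (a, p), ChangeKind.FRAMESHIFT, end_residue=(b, q))
    m = _SINGLE_DEL.match(raw)
    if m:
        return ProteinChange(raw, (m.group(1), int(m.group(2))), ChangeKind.INFRAME_DEL,
                             new_residue=m.group(3) or None)
    m = _SINGLE_FS.match(raw)
    if m:
        return ProteinChange(raw, (m.group(1), int(m.group(2))), ChangeKind.FRAMESHIFT)
    m = _STOP.match(raw)
    if m:
        return ProteinChange(raw, (m.group(1), int(m.group(2))), ChangeKind.STOP_GAIN)
    m = _SUBST.match(raw)
    if m:
        ref, pos, new = m.group(1), int(m.group(2)), m.group(3)
        kind = ChangeKind.SILENT if new == ref else ChangeKind.MISSENSE
        return ProteinChange(raw, (ref, pos), kind, new_residue=new)
    return ProteinChange(raw, (raw[0] if raw[0] in AA else "X", 0), ChangeKind.OTHER)


_KIND_TO_CLASS = {
    ChangeKind.MISSENSE: ConsequenceClass.MISSENSE,
    ChangeKind.STOP_GAIN: ConsequenceClass.STOP,
    ChangeKind.FRAMESHIFT: ConsequenceClass.FRAMESHIFT,
    ChangeKind.INFRAME_DEL: ConsequenceClass.INFRAME,
    ChangeKind.SILENT: ConsequenceClass.SILENT,
    ChangeKind.OTHER: ConsequenceClass.OTHER,
}


def classify_consequence(change: ProteinChange) -> ConsequenceClass:
    return _KIND_TO_CLASS[change.change_kind]


def is_truncating(cls: ConsequenceClass) -> bool:
    """Truncating = stop gain or frameshift (used by driver nomination)."""
    return cls in (ConsequenceClass.STOP, ConsequenceClass.FRAMESHIFT)


def is_nonsense_bucket(cls: ConsequenceClass) -> bool:
    """The report-level 'nonsense' roll-up: stop, frameshift and in-frame indels."""
    return cls in (ConsequenceClass.STOP, ConsequenceClass.FRAMESHIFT, ConsequenceClass.INFRAME)


def rollup_counts(classes: Iterable[ConsequenceClass]) -> dict:
    """Aggregate fine-grained classes into the report buckets.

    Returns counts for ``missense``, ``nonsense`` (stop+frameshift+inframe)
    and ``silent``; ``other`` entries are counted separately and excluded
    from the three buckets.
    """
    out = {"missense": 0, "nonsense": 0, "silent": 0, "other": 0,
           "stop": 0, "frameshift": 0, "inframe": 0}
    for c in classes:
        if c is ConsequenceClass.OTHER:
            out["other"] += 1
            continue
        if c is ConsequenceClass.MISSENSE:
            out["missense"] += 1
        elif c is ConsequenceClass.SILENT:
            out["silent"] += 1
        else:
            out["nonsense"] += 1
            out[c.value] += 1
    return out
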