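"""HGVS protein-level (p.) descriptions: the `ProteinChange` value type and
its formatter/parser.

All descriptions are predictions from DNA, so the parenthesized form
``p.(...)`` is emitted; the parser tolerates both forms.  Frameshift
numbering follows the fsTer convention: the first changed residue counts as
codon 1 of the shifted frame, so ``fsTer6`` means the new stop is the sixth
codon from (and including) the first changed residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .errors import ParseError, ValidationError

KINDS = {
    "synonymous",
    "missense",
    "nonsense",
    "frameshift",
    "inframe_del",
    "inframe_ins",
    "inframe_dup",
    "inframe_delins",
    "start_loss",
    "stop_loss",
}

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter", "X": "Xaa",
}
_AA1 = {v: k for k, v in _AA3.items()}


def aa1to3(seq: str) -> str:
    """One-letter residue string ('*' allowed) to concatenated 3-letter codes."""
    try:
        return "".join(_AA3[c] for c in seq)
    except KeyError as exc:
        raise ValidationError(f"unknown residue {exc.args[0]!r}") from exc


def aa3to1(seq: str) -> str:
    """Concatenated 3-letter codes to one-letter string."""
    if len(seq) % 3 != 0:
        raise ParseError(f"residue string {seq!r} is not a multiple of 3 letters")
    out = []
    for i in range(0, len(seq), 3):
        tok = seq[i : i + 3]
        if tok not in _AA1:
            raise ParseError(f"unknown 3-letter residue code {tok!r} in {seq!r}")
        out.append(_AA1[tok])
    return "".join(out)


@dataclass(frozen=True)
class ProteinChange:
    """A predicted protein-level consequence.

    Residues are stored as one-letter strings ('*' = Ter).  For ranged
    events (del/dup/delins over more than one residue) `ref_aa` holds the
    first and last residue only, matching what the HGVS string carries.
    `ter_offset` is present iff kind == 'frameshift' and a downstream stop
    was found; `no_stop` marks a frameshift that never reaches a stop.
    """

    kind: str
    start: int
    end: Optional[int] = None
    ref_aa: str = ""
    alt_aa: str = ""
    ter_offset: Optional[int] = None
    no_stop: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown protein change kind {self.kind!r}")
        if self.start < 1:
            raise ValidationError(f"protein position must be >= 1, got {self.start}")
        if self.end is not None and self.end < self.start:
            raise ValidationError(f"range end {self.end} < start {self.start}")
        if self.kind == "frameshift":
            if self.ter_offset is None and not self.no_stop:
                raise ValidationError("frameshift needs ter_offset or no_stop")
            if self.ter_offset is not None and self.ter_offset < 2:
                raise ValidationError(
                    "frameshift ter_offset must be >= 2 (an immediate stop is nonsense)"
                )
        elif self.ter_offset is not None:
            raise ValidationError("ter_offset is only valid for frameshifts")


def format_hgvs_p(pc: ProteinChange, parentheses: bool = True) -> str:
    """Render a ProteinChange as an HGVS p. string, e.g. p.(Glu94AspfsTer6)."""
    k = pc.kind
    if k == "synonymous":
        body = f"{aa1to3(pc.ref_aa)}{pc.start}=" if pc.ref_aa else "="
    elif k == "missense":
        body = f"{aa1to3(pc.ref_aa)}{pc.start}{aa1to3(pc.alt_aa)}"
    elif k == "nonsense":
        body = f"{aa1to3(pc.ref_aa)}{pc.start}Ter"
    elif k == "start_loss":
        body = "Met1?"
    elif k == "stop_loss":
        body = f"Ter{pc.start}{aa1to3(pc.alt_aa)}extTer?"
    elif k == "frameshift":
        alt3 = aa1to3(pc.alt_aa) if pc.alt_aa else ""
        if pc.no_stop:
            tail = f"{alt3}fsTer?" if alt3 else "fs"
        else:
            tail = f"{alt3}fsTer{pc.ter_offset}"
        body = f"{aa1to3(pc.ref_aa)}{pc.start}{tail}"
    elif k in {"inframe_del", "inframe_dup"}:
        suffix = "del" if k == "inframe_del" else "dup"
        if pc.end is None or pc.end == pc.start:
            body = f"{aa1to3(pc.ref_aa[:1])}{pc.start}{suffix}"
        else:
            body = (
                f"{aa1to3(pc.ref_aa[0])}{pc.start}_"
                f"{aa1to3(pc.ref_aa[-1])}{pc.end}{suffix}"
            )
    elif k == "inframe_ins":
        if pc.end is None or len(pc.ref_aa) != 2:
            raise ValidationError("inframe_ins needs two flanking residues and end")
        body = (
            f"{aa1to3(pc.ref_aa[0])}{pc.start}_"
            f"{aa1to3(pc.ref_aa[1])}{pc.end}ins{aa1to3(pc.alt_aa)}"
        )
    elif k == "inframe_delins":
        if pc.end is None or pc.end == pc.start:
            body = f"{aa1to3(pc.ref_aa[:1])}{pc.start}delins{aa1to3(pc.alt_aa)}"
        else:
            body = (
                f"{aa1to3(pc.ref_aa[0])}{pc.start}_"
                f"{aa1to3(pc.ref_aa[-1])}{pc.end}delins{aa1to3(pc.alt_aa)}"
            )
    else:  # pragma: no cover - KINDS is exhaustive
        raise ValidationError(f"unhandled kind {k}")
    return f"p.({body})" if parentheses else f"p.{body}"


_RES = r"(?:[A-Z][a-z]{2})"
_PATTERNS: list[tuple[str, re.Pattern]] = [
    ("start_loss", re.compile(r"^Met1\?$")),
    ("synonymous", re.compile(rf"^(?:({_RES})(\d+))?=$")),
    ("stop_loss", re.compile(rf"^Ter(\d+)({_RES})extTer\?$")),
    (
        "frameshift",
        re.compile(rf"^({_RES})(\d+)(?:({_RES})fsTer(\d+|\?)|fs)$"),
    ),
    ("inframe_ins", re.compile(rf"^({_RES})(\d+)_({_RES})(\d+)ins((?:{_RES})+)$")),
    (
        "inframe_delins",
        re.compile(rf"^({_RES})(\d+)(?:_({_RES})(\d+))?delins((?:{_RES})+)$"),
    ),
    ("inframe_del", re.compile(rf"^({_RES})(\d+)(?:_({_RES})(\d+))?del$")),
    ("inframe_dup", re.compile(rf"^({_RES})(\d+)(?:_({_RES})(\d+))?dup$")),
    ("nonsense", re.compile(rf"^({_RES})(\d+)Ter$")),
    ("missense", re.compile(rf"^({_RES})(\d+)({_RES})$")),
]


def parse_hgvs_p(s: str) -> ProteinChange:
    """Parse an HGVS p. string; inverse of :func:`format_hgvs_p` on its image.

    Tolerates presence or absence of the prediction parentheses.
    """
    body = s.strip()
    if not body.startswith("p."):
        raise ParseError(f"{s!r}: HGVS p. string must start with 'p.'")
    body = body[2:]
    if body.startswith("("):
        if not body.endswith(")"):
            raise ParseError(f"{s!r}: unbalanced parenthesis")
        body = body[1:-1]
    elif body.endswith(")"):
        raise ParseError(f"{s!r}: unbalanced parenthesis")
    if not body:
        raise ParseError(f"{s!r}: empty description")

    for kind, pat in _PATTERNS:
        m = pat.match(body)
        if not m:
            continue
        if kind == "start_loss":
            return ProteinChange("start_loss", 1, ref_aa="M")
        if kind == "synonymous":
            if m.group(1):
                return ProteinChange(
                    "synonymous", int(m.group(2)), ref_aa=aa3to1(m.group(1))
                )
            return ProteinChange("synonymous", 1)
        if kind == "stop_loss":
            return ProteinChange(
                "stop_loss", int(m.group(1)), ref_aa="*", alt_aa=aa3to1(m.group(2))
            )
        if kind == "frameshift":
            ref, pos, alt, ter = m.group(1), int(m.group(2)), m.group(3), m.group(4)
            if ter is None or ter == "?":
                return ProteinChange(
                    "frameshift",
                    pos,
                    ref_aa=aa3to1(ref),
                    alt_aa=aa3to1(alt) if alt else "",
                    no_stop=True,
                )
            n = int(ter)
            if n < 2:
                raise ParseError(f"{s!r}: fsTer{n} is invalid (an immediate stop is Ter)")
            return ProteinChange(
                "frameshift", pos, ref_aa=aa3to1(ref), alt_aa=aa3to1(alt), ter_offset=n
            )
        if kind == "inframe_ins":
            start, end = int(m.group(2)), int(m.group(4))
            if end != start + 1:
                raise ParseError(f"{s!r}: insertion flanks must be adjacent residues")
            return ProteinChange(
                "inframe_ins",
                start,
                end=end,
                ref_aa=aa3to1(m.group(1)) + aa3to1(m.group(3)),
                alt_aa=aa3to1(m.group(5)),
            )
        if kind in {"inframe_del", "inframe_dup", "inframe_delins"}:
            start = int(m.group(2))
            if m.group(3):
                end = int(m.group(4))
                ref_aa = aa3to1(m.group(1)) + aa3to1(m.group(3))
            else:
                end, ref_aa = None, aa3to1(m.group(1))
            alt = aa3to1(m.group(5)) if kind == "inframe_delins" else ""
            return ProteinChange(kind, start, end=end, ref_aa=ref_aa, alt_aa=alt)
        if kind == "nonsense":
            return ProteinChange("nonsense", int(m.group(2)), ref_aa=aa3to1(m.group(1)))
        if kind == "missense":
            pos = int(m.group(2))
            ref_aa, alt_aa = aa3to1(m.group(1)), aa3to1(m.group(3))
            return ProteinChange("missense", pos, ref_aa=ref_aa, alt_aa=alt_aa)
    raise ParseError(f"{s!r}: unrecognized HGVS p. description {body!r}")
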