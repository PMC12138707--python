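"""Sequence bookkeeping for the three built-in 15-mer peptides.

The built-in peptides share the template ``MDVFM-X-GLS-X-A-X-EGV`` with the
variable position X at residues 6, 10 and 12 substituted by lysine
(peptide "1"), arginine ("2") or histidine ("3").  Charged positions are
configuration, not derived chemistry: by default the N-terminus and the
three X positions are treated as cationic (the low-pH regime); callers
working at higher pH supply their own set.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

__all__ = [
    "PeptideSequence",
    "builtin_peptide",
    "residue_label",
    "parse_residue_label",
    "BUILTIN_IDS",
]

_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

_TEMPLATE = "MDVFM-GLS-A-EGV"  # '-' marks the variable X positions
_VARIABLE_POSITIONS = frozenset({6, 10, 12})
_SUBSTITUTION = {"1": "K", "2": "R", "3": "H"}
_DEFAULT_CHARGED = frozenset({1, 6, 10, 12})  # N-terminus + X side chains

BUILTIN_IDS = tuple(sorted(_SUBSTITUTION))

_LABEL_RE = re.compile(r"^(?:(?P<code1>[A-Z])(?P<pos1>\d+)|(?P<pos2>\d+)(?P<code2>[A-Z]))$")


@dataclass(frozen=True)
class PeptideSequence:
    """An annotated peptide sequence with 1-based residue positions."""

    id: str
    residues: tuple[str, ...]
    variable_positions: frozenset[int] = frozenset()
    charged_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("peptide must contain at least one residue")
        bad = [r for r in self.residues if r not in _AA]
        if bad:
            raise ValueError(f"unknown residue codes: {bad}")
        n = len(self.residues)
        for name in ("variable_positions", "charged_positions"):
            positions = getattr(self, name)
            out = [p for p in positions if not 1 <= p <= n]
            if out:
                raise ValueError(f"{name} outside sequence 1..{n}: {sorted(out)}")
        var_res = {self.residues[p - 1] for p in self.variable_positions}
        if len(var_res) > 1:
            raise ValueError(
                f"variable positions must carry one residue type, found {sorted(var_res)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(self.residues)

    def residue(self, position: int) -> str:
        """One-letter code at a 1-based position."""
        if not 1 <= position <= len(self):
            raise ValueError(
                f"position {position} out of range 1..{len(self)} for peptide {self.id!r}"
            )
        return self.residues[position - 1]

    def label(self, position: int) -> str:
        return residue_label(self, position)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "sequence": self.sequence,
            "variable_positions": sorted(self.variable_positions),
            "charged_positions": sorted(self.charged_positions),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PeptideSequence":
        return cls(
            id=str(data["id"]),
            residues=tuple(data["sequence"]),
            variable_positions=frozenset(data.get("variable_positions", ())),
            charged_positions=frozenset(data.get("charged_positions", ())),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PeptideSequence":
        return cls.from_dict(json.loads(text))


def builtin_peptide(id: str, charged_positions: frozenset[int] | None = None) -> PeptideSequence:
    """Return one of the built-in 15-mers ("1" = K, "2" = R, "3" = H).

    ``charged_positions`` defaults to the N-terminus plus the three variable
    side chains; pass an explicit set to model other protonation states.
    """
    if id not in _SUBSTITUTION:
        raise ValueError(f"unknown peptide id {id!r}; valid ids: {', '.join(BUILTIN_IDS)}")
    x = _SUBSTITUTION[id]
    residues = tuple(x if c == "-" else c for c in _TEMPLATE)
    charged = _DEFAULT_CHARGED if charged_positions is None else frozenset(charged_positions)
    return PeptideSequence(
        id=id,
        residues=residues,
        variable_positions=_VARIABLE_POSITIONS,
        charged_positions=charged,
    )


def residue_label(seq: PeptideSequence, position: int) -> str:
    """Letter-then-number residue label, e.g. ``"K12"``."""
    return f"{seq.residue(position)}{position}"


def parse_residue_label(label: str) -> tuple[int, str]:
    """Parse a residue label into ``(position, code)``.

    Accepts both the ``"S9"`` and ``"9S"`` dialects.
    """
    m = _LABEL_RE.match(label.strip().upper())
    if m is None:
        raise ValueError(f"unparseable residue label {label!r}")
    if m.group("code1") is not None:
        return int(m.group("pos1")), m.group("code1")
    return int(m.group("pos2")), m.group("code2")
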