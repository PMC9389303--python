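"""Modified-peptide sequence handling and localization flags.

Two token dialects are normalized to an internal ``(position, name)`` list:

* compact lowercase prefixes: ``RApSPSPRAA`` (``p`` = phospho on the next
  residue), ``oxM`` for oxidized methionine, ``acX`` for acetylation;
* MaxQuant parenthesis tokens following the residue (possibly nested), e.g.
  ``_RAS(Phospho (STY))PSPRAA_`` or ``M(ox)``, with the underscore wrappers
  and protein N-terminal acetyl tokens handled.

Positions are 1-based on the unmodified sequence. When the spectra of one
cluster identify the same peptide with the modification placed on different
residues, the cluster-level result is rendered as a *localization flag*::

    RASPSPRAA.1.p3/p5

i.e. unmodified sequence, total number of modifications carried by each
spectrum, and the union of candidate sites observed across the cluster
(``p`` prefix for phosphorylation, ``mod`` for any other modification type).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

PHOSPHO = "Phospho"
OXIDATION = "Oxidation"
ACETYL = "Acetyl"

_COMPACT_PREFIXES = {"p": PHOSPHO, "ox": OXIDATION, "ac": ACETYL}

_PAREN_NAMES = [
    (re.compile(r"phospho|(^|\W)ph($|\W)", re.I), PHOSPHO),
    (re.compile(r"oxidation|(^|\W)ox($|\W)", re.I), OXIDATION),
    (re.compile(r"acetyl|(^|\W)ac($|\W)", re.I), ACETYL),
]

_FLAG_RE = re.compile(r"^([A-Z]+)\.(\d+)\.((?:(?:p|mod)\d+)(?:/(?:p|mod)\d+)*)$")


class ModifiedSequenceError(ValueError):
    """Raised when a modified-sequence string cannot be parsed."""


@dataclass(frozen=True)
class ParsedModSeq:
    base: str
    mods: tuple[tuple[int, str], ...]  # ((1-based position, modification name), ...)

    def mod_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, name in self.mods:
            counts[name] = counts.get(name, 0) + 1
        return counts

    def positions(self, name: str) -> tuple[int, ...]:
        return tuple(sorted(pos for pos, n in self.mods if n == name))


def _paren_token_name(token: str) -> str:
    for pattern, name in _PAREN_NAMES:
        if pattern.search(token):
            return name
    return token.strip("() ")


def parse_modified_sequence(text: str) -> ParsedModSeq:
    """Normalize a modified-sequence string to base sequence + (pos, mod) list."""
    s = text.strip().strip("_")
    base: list[str] = []
    mods: list[tuple[int, str]] = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "(":
            depth = 1
            j = i + 1
            while j < len(s) and depth:
                if s[j] == "(":
                    depth += 1
                elif s[j] == ")":
                    depth -= 1
                j += 1
            if depth:
                raise ModifiedSequenceError(f"unbalanced parentheses in {text!r}")
            name = _paren_token_name(s[i:j])
            pos = len(base)  # token follows the residue it modifies
            if pos == 0:
                # protein/peptide N-terminal modification: attach to residue 1
                pos = 1
            mods.append((pos, name))
            i = j
        elif ch.isupper():
            base.append(ch)
            i += 1
        elif ch.islower():
            matched = False
            for prefix in sorted(_COMPACT_PREFIXES, key=len, reverse=True):
                if s.startswith(prefix, i) and i + len(prefix) < len(s) and s[i + len(prefix)].isupper():
                    mods.append((len(base) + 1, _COMPACT_PREFIXES[prefix]))
                    i += len(prefix)
                    matched = True
                    break
            if not matched:
                raise ModifiedSequenceError(f"unrecognized token at {s[i:]!r} in {text!r}")
        else:
            raise ModifiedSequenceError(f"unexpected character {ch!r} in {text!r}")
    fixed = [(min(pos, len(base)), name) for pos, name in mods]
    return ParsedModSeq("".join(base), tuple(sorted(fixed)))


def strip_modifications(text: str) -> str:
    return parse_modified_sequence(text).base


@dataclass(frozen=True)
class LocalizationFlag:
    """Cluster-level ambiguous localization of a modified peptide.

    ``candidate_positions`` maps each modification type to the sorted union of
    sites observed among the cluster's identified spectra; ``n_mods`` is the
    number of modifications each individual spectrum carries (identical across
    the cluster by construction).
    """

    base_sequence: str
    n_mods: int
    candidate_positions: tuple[tuple[str, tuple[int, ...]], ...]

    def render(self) -> str:
        tokens: list[str] = []
        for name, positions in self.candidate_positions:
            prefix = "p" if name == PHOSPHO else "mod"
            tokens.extend(f"{prefix}{p}" for p in positions)
        return f"{self.base_sequence}.{self.n_mods}." + "/".join(tokens)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def is_localization_flag(text: str) -> bool:
    return bool(_FLAG_RE.match(text))


def build_localization_flag(modified_sequences: Iterable[str]) -> LocalizationFlag:
    """Union the observed modification sites of PTM-isomeric identifications.

    All inputs must strip to one unmodified sequence and carry identical
    per-type modification counts; violations indicate the cluster should have
    been categorized as ambiguous and raise ``ModifiedSequenceError``.
    """
    parsed = [parse_modified_sequence(m) for m in set(modified_sequences)]
    if not parsed:
        raise ModifiedSequenceError("no modified sequences supplied")
    bases = {p.base for p in parsed}
    if len(bases) > 1:
        raise ModifiedSequenceError(f"multiple unmodified sequences: {sorted(bases)}")
    counts = {tuple(sorted(p.mod_counts().items())) for p in parsed}
    if len(counts) > 1:
        raise ModifiedSequenceError(
            "modification counts differ across isomeric identifications"
        )
    base = parsed[0].base
    names = sorted({name for p in parsed for _, name in p.mods})
    union = tuple(
        (name, tuple(sorted({pos for p in parsed for pos in p.positions(name)})))
        for name in names
    )
    n_mods = sum(dict(counts.pop()).values())
    if n_mods == 0:
        raise ModifiedSequenceError("isomeric flag requested for unmodified peptides")
    return LocalizationFlag(base, n_mods, union)
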