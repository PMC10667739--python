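"""Composite lipid naming grammar.

Identified compounds are reported as composite names in the format
``(headgroup)-(backbone) (carbons):(unsaturations)`` with an optional
`` + (k)O`` hydroxylation suffix, e.g. ``PG-DAG 34:0 + 1O`` — a
phosphatidylglycerol diacylglycerol with 34 total chain carbons, no
double bonds and one chain hydroxylation. Chain totals are composite:
individual chain lengths are deliberately not specified.

Lipids entered as unique full structures (archaeol, GDGTs, GDDs,
ladderanes) use the core label in place of backbone and chain numbers,
with structural modifications appended as signed tokens::

    1G-AR                  unmodified monoglycosyl archaeol
    2G-GDGT-0              diglycosyl GDGT with zero rings/DBE
    1G-AR + 2u + 1O + 1Ip  archaeol, 2 unsaturations, 1 hydroxylation,
                           1 isoprene-unit extension

``format_name``/``parse_name`` are exact inverses over every name the
database generator can emit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["ParsedName", "format_name", "parse_name", "NameError_", "ITERATIVE_BACKBONES"]

# Backbones assembled iteratively from chain states.
ITERATIVE_BACKBONES = ("MAG", "DAG", "TAG", "CL", "AEG", "MEG", "DEG", "Cer", "AD", "FA")

# Core labels for unique (full-structure) components.
_UNIQUE_LABEL_RE = re.compile(
    r"(?:AR|brGDGT|brGDD|GDGT-\d{1,2}|GDD-\d{1,2}|LAD[35]-\d{1,2})$"
)

_CHAIN_STATE_RE = re.compile(r"^(\d+):(\d+)$")
_MOD_RE = re.compile(r"^(\d+)(O|u|Me|Ip)$")


class NameError_(ValueError):
    """Raised for strings that do not follow the composite naming grammar."""


@dataclass(frozen=True)
class ParsedName:
    """Structured fields of a composite lipid name."""

    headgroup: str
    backbone: str
    kind: str = "chain"  # "chain" (iterative) or "unique"
    c: int = 0           # total chain carbons (chain kind only)
    db: int = 0          # total unsaturations (chain kind only)
    oh: int = 0          # hydroxylations
    uns: int = 0         # unique: extra unsaturations
    me: int = 0          # unique: methylations
    ext: int = 0         # unique: isoprene-unit extensions
    abr: int = 0         # unique: isoprene-unit abridgements


def _split_head_backbone(token: str) -> tuple[str, str, str]:
    """Split ``1G-GA-DAG`` into headgroup ``1G-GA`` and backbone ``DAG``.

    Headgroups may themselves contain hyphens, so the backbone/core label
    is matched greedily from the right against the known label grammar.
    Returns (headgroup, backbone, kind).
    """
    for bb in sorted(ITERATIVE_BACKBONES, key=len, reverse=True):
        if token == bb:
            return "", bb, "chain"
        if token.endswith("-" + bb):
            return token[: -len(bb) - 1], bb, "chain"
    m = _UNIQUE_LABEL_RE.search(token)
    if m and (m.start() == 0 or token[m.start() - 1] == "-"):
        label = m.group(0)
        hg = token[: m.start() - 1] if m.start() > 0 else ""
        return hg, label, "unique"
    raise NameError_(f"no known backbone or core label in {token!r}")


def format_name(
    headgroup: str,
    backbone: str,
    c: int = 0,
    db: int = 0,
    oh: int = 0,
    *,
    kind: str = "chain",
    uns: int = 0,
    me: int = 0,
    ext: int = 0,
    abr: int = 0,
) -> str:
    """Build the composite name for a species."""
    stem = f"{headgroup}-{backbone}" if headgroup else backbone
    if kind == "chain":
        name = f"{stem} {c}:{db}"
        if oh:
            name += f" + {oh}O"
        return name
    if kind != "unique":
        raise NameError_(f"unknown species kind {kind!r}")
    parts = [stem]
    if uns:
        parts.append(f"+ {uns}u")
    if oh:
        parts.append(f"+ {oh}O")
    if me:
        parts.append(f"+ {me}Me")
    if ext:
        parts.append(f"+ {ext}Ip")
    if abr:
        parts.append(f"- {abr}Ip")
    return " ".join(parts)


def parse_name(name: str) -> ParsedName:
    """Parse a composite name back into its structured fields."""
    tokens = name.split(" ")
    if not tokens or not tokens[0]:
        raise NameError_(f"empty name {name!r}")
    hg, bb, kind = _split_head_backbone(tokens[0])
    rest = tokens[1:]
    if kind == "chain":
        if not rest:
            raise NameError_(f"missing chain state in {name!r}")
        m = _CHAIN_STATE_RE.match(rest[0])
        if not m:
            raise NameError_(f"bad chain state {rest[0]!r} in {name!r}")
        c, db = int(m.group(1)), int(m.group(2))
        oh = 0
        tail = rest[1:]
        if tail:
            if len(tail) != 2 or tail[0] != "+":
                raise NameError_(f"bad hydroxylation suffix in {name!r}")
            mm = _MOD_RE.match(tail[1])
            if not mm or mm.group(2) != "O":
                raise NameError_(f"bad hydroxylation suffix in {name!r}")
            oh = int(mm.group(1))
        return ParsedName(hg, bb, "chain", c=c, db=db, oh=oh)
    # unique: signed modification tokens
    mods = {"u": 0, "O": 0, "Me": 0, "Ip+": 0, "Ip-": 0}
    i = 0
    while i < len(rest):
        sign = rest[i]
        if sign not in ("+", "-") or i + 1 >= len(rest):
            raise NameError_(f"bad modification token near {rest[i]!r} in {name!r}")
        m = _MOD_RE.match(rest[i + 1])
        if not m:
            raise NameError_(f"bad modification token {rest[i + 1]!r} in {name!r}")
        k, unit = int(m.group(1)), m.group(2)
        if unit == "Ip":
            mods["Ip+" if sign == "+" else "Ip-"] += k
        elif sign == "-":
            raise NameError_(f"negative {unit} modification in {name!r}")
        else:
            mods[unit] += k
        i += 2
    return ParsedName(
        hg,
        bb,
        "unique",
        oh=mods["O"],
        uns=mods["u"],
        me=mods["Me"],
        ext=mods["Ip+"],
        abr=mods["Ip-"],
    )
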