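"""Lipid shorthand nomenclature parsing.

Names follow the common shorthand grammar ``CLASS [O-|P-] C:D[_C:D|/C:D]*``
where ``C:D`` is total carbons : total double bonds, e.g. ``PC 34:1``
(sum composition), ``PC 16:0_18:1`` (molecular species, unknown sn
positions), ``Cer[NS] 42:1``, ``PC O-34:2`` (ether/plasmanyl) or
``plasmenyl-PE 36:4``.  Lyso species are recognised either from an ``L``
class token (LPC, LPE, ...) or a ``Lyso-`` prefix.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

__all__ = ["LipidSpecies", "parse_lipid_name"]

# chain expression at the end of the name, optionally ether-marked
_CHAIN_RE = re.compile(
    r"""^\s*(?P<cls>.+?)\s+(?P<ether>[OP]-)?(?P<chains>\d+:\d+(?:[/_](?:[OP]-)?\d+:\d+)*)\s*$"""
)
_CD_RE = re.compile(r"(?:[OP]-)?(\d+):(\d+)")

# class tokens that are intrinsically lyso (single-chain) species
_LYSO_CLASSES = {"LPC", "LPE", "LPS", "LPI", "LPG", "LPA"}
# class prefixes marking ether (plasmanyl/plasmenyl/alkenyl) lipids
_ETHER_PREFIXES = ("plasmanyl-", "plasmenyl-", "alkenyl-", "alkyl-")


@dataclass
class LipidSpecies:
    """Structured identity parsed from a lipid shorthand name."""

    raw_name: str
    lipid_class: str
    total_carbons: int | None
    total_double_bonds: int | None
    is_lyso: bool = False
    is_ether: bool = False
    sn_chains: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sn_chains:
            carbons = sum(c for c, _ in self.sn_chains)
            dbs = sum(d for _, d in self.sn_chains)
            if self.total_carbons != carbons or self.total_double_bonds != dbs:
                raise ValueError(
                    f"{self.raw_name!r}: totals ({self.total_carbons}:"
                    f"{self.total_double_bonds}) disagree with sn chains {self.sn_chains}"
                )
        if not self.lipid_class:
            raise ValueError(f"{self.raw_name!r}: empty lipid class")


def _class_flags(cls_token: str) -> tuple[bool, bool]:
    lyso = False
    ether = False
    low = cls_token.lower()
    if low.startswith("lyso-") or low.startswith("lyso "):
        lyso = True
        cls_token = cls_token[5:]
        low = low[5:]
    for pref in _ETHER_PREFIXES:
        if low.startswith(pref):
            ether = True
            low = low[len(pref):]
            cls_token = cls_token[len(pref):]
            break
    if cls_token.upper() in _LYSO_CLASSES:
        lyso = True
    return lyso, ether


def parse_lipid_name(raw_name: str) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Sum-composition names (a single ``C:D``) leave ``sn_chains`` empty;
    multi-chain names (``_`` or ``/`` separated) populate ``sn_chains`` and
    derive totals from them.  A name outside the grammar is not an error:
    the whole token becomes the class, totals stay unknown and a warning is
    issued.  Only the empty string is rejected.
    """
    if not raw_name or not raw_name.strip():
        raise ValueError("empty lipid name")
    name = raw_name.strip()

    m = _CHAIN_RE.match(name)
    if m is None or _CD_RE.search(m.group("cls")):
        warnings.warn(f"unrecognised lipid name grammar: {raw_name!r}")
        return LipidSpecies(
            raw_name=raw_name,
            lipid_class=name,
            total_carbons=None,
            total_double_bonds=None,
        )

    cls_token = m.group("cls").strip()
    is_lyso, is_ether = _class_flags(cls_token)
    if m.group("ether"):
        is_ether = True
    chain_str = m.group("chains")
    if "O-" in chain_str or "P-" in chain_str:
        is_ether = True

    pairs = [(int(c), int(d)) for c, d in _CD_RE.findall(chain_str)]
    multi = bool(re.search(r"[/_]", chain_str))
    sn_chains = pairs if multi else []
    total_c = sum(c for c, _ in pairs)
    total_d = sum(d for _, d in pairs)

    return LipidSpecies(
        raw_name=raw_name,
        lipid_class=cls_token,
        total_carbons=total_c,
        total_double_bonds=total_d,
        is_lyso=is_lyso,
        is_ether=is_ether,
        sn_chains=sn_chains,
    )
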