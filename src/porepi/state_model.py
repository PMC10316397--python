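"""Conductance-class decision logic for S6 α/π compositions.

Pore models are named ``<k>pi[_d<i>...]``: the prefix counts the π-helical
S6 helices and the suffixes say which subunits carry them (e.g.
``2pi_d1_d3`` = π in DI-S6 and DIII-S6, α elsewhere).  The decision logic:
with DIII-S6 π-helical (as in every experimentally resolved conformation),
π in both DI-S6 and DIV-S6 gives a fully conductive pore, π in exactly one
of them a subconductance pore, and in neither a nonconducting pore; DII-S6
never changes the class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product

__all__ = [
    "SUBUNITS",
    "PoreStateComposition",
    "ConductanceClass",
    "parse_model_name",
    "format_model_name",
    "classify",
    "assign_functional_state",
    "expected_rank",
    "all_compositions",
]

SUBUNITS = ("DI", "DII", "DIII", "DIV")
_SUBUNIT_TOKEN = {"d1": "DI", "d2": "DII", "d3": "DIII", "d4": "DIV"}
_TOKEN_OF = {v: k for k, v in _SUBUNIT_TOKEN.items()}

_NAME_RE = re.compile(r"^(\d+)pi((?:_d[1-4])*)$")


@dataclass(frozen=True)
class PoreStateComposition:
    """Secondary structure ('alpha' or 'pi') of each subunit's S6 helix."""

    DI: str
    DII: str
    DIII: str
    DIV: str

    def __post_init__(self):
        for sub in SUBUNITS:
            v = getattr(self, sub)
            if v not in ("alpha", "pi"):
                raise ValueError(f"{sub} must be 'alpha' or 'pi', got {v!r}")

    @property
    def pi_subunits(self) -> tuple:
        return tuple(s for s in SUBUNITS if getattr(self, s) == "pi")

    @property
    def n_pi(self) -> int:
        return len(self.pi_subunits)

    @property
    def model_name(self) -> str:
        return format_model_name(self)


@dataclass(frozen=True)
class ConductanceClass:
    conductance_class: str        # fully_conductive | subconductance | nonconducting
    functional_label: str = "none"  # advisory: O / S2 candidacy


def parse_model_name(name: str) -> PoreStateComposition:
    """Parse a model name like ``2pi_d1_d3`` into a composition.

    The count prefix must equal the number of listed subunits; ``4pi`` (and
    ``0pi``) take no suffix because the composition is unambiguous.
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"malformed model name {name!r}; expected <k>pi[_d1-4...]")
    count = int(m.group(1))
    tokens = [t for t in m.group(2).split("_") if t]
    if len(set(tokens)) != len(tokens):
        raise ValueError(f"model name {name!r} repeats a subunit")
    subs = [_SUBUNIT_TOKEN[t] for t in tokens]
    if not subs and count in (0, 4):
        subs = list(SUBUNITS[:count]) if count == 0 else list(SUBUNITS)
    if len(subs) != count:
        raise ValueError(
            f"model name {name!r}: count prefix {count} does not match "
            f"{len(subs)} listed subunit(s)"
        )
    return PoreStateComposition(
        **{s: ("pi" if s in subs else "alpha") for s in SUBUNITS}
    )


def format_model_name(comp: PoreStateComposition) -> str:
    pi = comp.pi_subunits
    if len(pi) == 4:
        return "4pi"
    if not pi:
        return "0pi"
    return f"{len(pi)}pi_" + "_".join(_TOKEN_OF[s] for s in pi)


def classify(comp: PoreStateComposition) -> ConductanceClass:
    """Conductance class from the α/π composition (DIII must be π).

    DI and DIV π → fully conductive; exactly one of them π →
    subconductance; neither → nonconducting.  DII is irrelevant.  A DIII-α
    composition is outside the modeled space and raises.
    """
    if comp.DIII != "pi":
        raise ValueError(
            f"{comp.model_name}: DIII-S6 without a pi-helix is outside the "
            "modeled space (no such conformation has been resolved)"
        )
    n_ends = (comp.DI == "pi") + (comp.DIV == "pi")
    cls = {2: "fully_conductive", 1: "subconductance", 0: "nonconducting"}[n_ends]
    return ConductanceClass(conductance_class=cls,
                            functional_label=_functional_label(comp, cls))


def _functional_label(comp: PoreStateComposition, cls: str) -> str:
    if cls == "fully_conductive":
        return "O (first open) candidate"
    if comp.model_name in ("2pi_d1_d3", "2pi_d3_d4"):
        return "S2 (second open) candidate"
    return "none"


def assign_functional_state(comp: PoreStateComposition) -> str:
    """Advisory functional-state label (O / S2 candidacy) for a composition."""
    return classify(comp).functional_label


_CLASS_ORDER = {"fully_conductive": 2, "subconductance": 1, "nonconducting": 0}


def expected_rank(compositions):
    """Order compositions by expected conductance (class, then π count).

    Returns a list of lists: each inner list is a tie group, highest
    expected conductance first.  Ties (same class and π count) are reported
    as equal rather than resolved.
    """
    comps = [c if isinstance(c, PoreStateComposition) else parse_model_name(c)
             for c in compositions]
    if len(comps) < 2:
        return [[c.model_name for c in comps]]
    keyed = sorted(
        comps,
        key=lambda c: (_CLASS_ORDER[classify(c).conductance_class], c.n_pi),
        reverse=True,
    )
    groups, prev_key = [], None
    for c in keyed:
        key = (_CLASS_ORDER[classify(c).conductance_class], c.n_pi)
        if key == prev_key:
            groups[-1].append(c.model_name)
        else:
            groups.append([c.model_name])
        prev_key = key
    return groups


def all_compositions(require_d3_pi: bool = True):
    """All 8 (or 16) α/π compositions, as PoreStateComposition objects."""
    out = []
    for di, dii, diii, div in product(("alpha", "pi"), repeat=4):
        if require_d3_pi and diii != "pi":
            continue
        out.append(PoreStateComposition(DI=di, DII=dii, DIII=diii, DIV=div))
    return out
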