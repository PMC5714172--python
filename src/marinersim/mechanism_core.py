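"""Shared vocabulary of the cleavage mechanism.

A mariner transposon is excised from its donor plasmid by four strand
nicks, two per transposon end: a 5' nick recessed inside the end and a
3' nick that defines the transferred strand.  The four nicks are labelled
N1..N4: N1/N2 are the 5' nicks at ends A/B, N3/N4 the 3' nicks at ends
A/B.  A cleavage-topology model states which active site of the synaptic
complex is responsible for which nick; the complex is either a single
transposase dimer (two active sites) or a dimer of dimers (four).

The bracket notation of the field, e.g. ``m/m[1+3/2+4]``, lists the nicks
performed by the site(s) before and after the slash and is accepted as an
input alias for the canonical snake_case names used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import FrozenSet, Iterable, Mapping, Sequence, Tuple


class End(str, Enum):
    A = "A"
    B = "B"


class StrandChemistry(str, Enum):
    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"


class NickID(Enum):
    """The four strand nicks of transposon excision."""

    N1 = (End.A, StrandChemistry.FIVE_PRIME)
    N2 = (End.B, StrandChemistry.FIVE_PRIME)
    N3 = (End.A, StrandChemistry.THREE_PRIME)
    N4 = (End.B, StrandChemistry.THREE_PRIME)

    def __init__(self, end: End, chemistry: StrandChemistry):
        self.end = end
        self.chemistry = chemistry

    @property
    def same_end_partner(self) -> "NickID":
        pairs = {NickID.N1: NickID.N3, NickID.N3: NickID.N1,
                 NickID.N2: NickID.N4, NickID.N4: NickID.N2}
        return pairs[self]


FIVE_PRIME_NICKS = frozenset({NickID.N1, NickID.N2})
THREE_PRIME_NICKS = frozenset({NickID.N3, NickID.N4})
ALL_NICKS = frozenset(NickID)

#: nicks required to complete the double-strand break at each end
END_NICKS = {
    End.A: frozenset({NickID.N1, NickID.N3}),
    End.B: frozenset({NickID.N2, NickID.N4}),
}


class CatalyticState(str, Enum):
    """Whether a subunit can catalyse.  Dead subunits (e.g. the D155A
    active-site mutant) bind DNA but never nick."""

    ACTIVE = "active"
    DEAD = "dead"


class ProductClass(str, Enum):
    """Gel-visible species of a supercoiled excision substrate."""

    SC = "SC"   # supercoiled substrate, no nick
    N = "N"     # open circular: >=1 nick, no complete double-strand break
    L = "L"     # linear: double-strand break at exactly one end
    EX = "EX"   # excision complete: backbone + transposon/integration products


PRODUCT_LABELS: Tuple[str, ...] = tuple(p.value for p in ProductClass)


NickStateVector = FrozenSet[NickID]
"""Per-molecule record of which nicks have occurred (monotone in time)."""


def classify_product(nicks: Iterable[NickID]) -> ProductClass:
    """Classify a molecule by its set of nicks.

    Supercoiled if nothing is nicked; fully excised if both ends carry
    both their nicks; linear if exactly one end does; otherwise open
    circular (one or more nicks but no complete double-strand break).
    """
    s = frozenset(nicks)
    if not s:
        return ProductClass.SC
    ends_cut = sum(1 for req in END_NICKS.values() if req <= s)
    if ends_cut == 2:
        return ProductClass.EX
    if ends_cut == 1:
        return ProductClass.L
    return ProductClass.N


class Arity(str, Enum):
    DIMER = "dimer"
    DIMER_OF_DIMERS = "dimer_of_dimers"


@dataclass(frozen=True)
class CleavageModel:
    """Assignment of the four nicks to the active-site slots of a complex.

    ``slots`` lists the nick set each slot is responsible for;
    ``dimer_groups`` groups slot indices into physical dimers (one group
    for dimer models, two for dimer-of-dimers models).  Subunits are
    loaded into the slots of their dimer in either orientation with equal
    probability.
    """

    name: str
    arity: Arity
    slots: Tuple[FrozenSet[NickID], ...]
    dimer_groups: Tuple[Tuple[int, ...], ...]

    def __post_init__(self) -> None:
        union: set = set()
        total = 0
        for s in self.slots:
            union |= s
            total += len(s)
        if union != set(ALL_NICKS) or total != 4:
            raise ValueError(f"model {self.name}: slots must partition N1..N4")
        n_slots = 2 if self.arity is Arity.DIMER else 4
        if len(self.slots) != n_slots:
            raise ValueError(f"model {self.name}: expected {n_slots} slots")
        if sorted(i for g in self.dimer_groups for i in g) != list(range(n_slots)):
            raise ValueError(f"model {self.name}: dimer_groups must cover slots")

    def slot_of(self, nick: NickID) -> int:
        for i, s in enumerate(self.slots):
            if nick in s:
                return i
        raise KeyError(nick)  # pragma: no cover - partition guaranteed


def _fs(*nicks: NickID) -> FrozenSet[NickID]:
    return frozenset(nicks)


_N1, _N2, _N3, _N4 = NickID.N1, NickID.N2, NickID.N3, NickID.N4

#: the six cleavage-topology models
MODELS: Mapping[str, CleavageModel] = {
    m.name: m
    for m in [
        CleavageModel("mm_13_24", Arity.DIMER,
                      (_fs(_N1, _N3), _fs(_N2, _N4)), ((0, 1),)),
        CleavageModel("mm_14_23", Arity.DIMER,
                      (_fs(_N1, _N4), _fs(_N2, _N3)), ((0, 1),)),
        CleavageModel("mm_12_34", Arity.DIMER,
                      (_fs(_N1, _N2), _fs(_N3, _N4)), ((0, 1),)),
        CleavageModel("dd_13_24", Arity.DIMER_OF_DIMERS,
                      (_fs(_N1), _fs(_N3), _fs(_N2), _fs(_N4)),
                      ((0, 1), (2, 3))),
        CleavageModel("dd_14_23", Arity.DIMER_OF_DIMERS,
                      (_fs(_N1), _fs(_N4), _fs(_N2), _fs(_N3)),
                      ((0, 1), (2, 3))),
        CleavageModel("dd_12_34", Arity.DIMER_OF_DIMERS,
                      (_fs(_N1), _fs(_N2), _fs(_N3), _fs(_N4)),
                      ((0, 1), (2, 3))),
    ]
}

_ALIASES = {
    "m/m[1+3/2+4]": "mm_13_24",
    "m/m[1+4/2+3]": "mm_14_23",
    "m/m[1+2/3+4]": "mm_12_34",
    "d/d[1+3/2+4]": "dd_13_24",
    "d/d[1+4/2+3]": "dd_14_23",
    "d/d[1+2/3+4]": "dd_12_34",
}

MODEL_NAMES: Tuple[str, ...] = tuple(MODELS)


def get_model(name: str | CleavageModel) -> CleavageModel:
    """Look up a cleavage model by canonical name or bracket alias."""
    if isinstance(name, CleavageModel):
        return name
    key = _ALIASES.get(name, name)
    try:
        return MODELS[key]
    except KeyError:
        raise ValueError(
            f"unknown cleavage model {name!r}; expected one of "
            f"{sorted(MODELS)} or bracket aliases {sorted(_ALIASES)}"
        ) from None


def nick_assignment(model: str | CleavageModel, slot: int,
                    orientation: int = 0) -> FrozenSet[NickID]:
    """Nicks performed by the physical subunit at position ``slot``.

    ``orientation`` (0 or 1) selects which of the two subunits of the
    dimer containing ``slot`` occupies which of its slots; over both
    orientations each subunit is equally likely to occupy each slot.
    """
    m = get_model(model)
    if not 0 <= slot < len(m.slots):
        raise ValueError(f"slot {slot} invalid for {m.name} ({len(m.slots)} slots)")
    if orientation not in (0, 1):
        raise ValueError("orientation must be 0 or 1")
    if orientation == 0:
        return m.slots[slot]
    for group in m.dimer_groups:
        if slot in group:
            partner = group[1] if slot == group[0] else group[0]
            return m.slots[partner]
    raise AssertionError  # pragma: no cover


class GateMode(str, Enum):
    STRICT = "strict_gate"
    PER_END = "per_end_gate"
    NONE = "none"


@dataclass(frozen=True)
class OrderingRule:
    """Kinetic ordering of nicks.

    Both 5' nicks normally precede either 3' nick.  ``strict_gate``
    blocks a 3' nick until N1 and N2 have both occurred; ``per_end_gate``
    only requires the 5' nick at the same end; ``none`` removes ordering.
    ``leak`` is the rate multiplier applied to gated 3' nicks by the
    kinetic model (the endpoint predictor treats gated nicks as fully
    blocked).
    """

    mode: GateMode = GateMode.STRICT
    leak: float = 0.0

    def __post_init__(self) -> None:
        if self.leak < 0:
            raise ValueError("leak must be nonnegative")

    def permits_at_endpoint(self, nick: NickID, occurred: FrozenSet[NickID]) -> bool:
        """Whether ``nick`` may occur given the nicks in ``occurred``
        (endpoint semantics: gated means never)."""
        if nick in FIVE_PRIME_NICKS:
            return True
        if self.mode is GateMode.NONE:
            return True
        if self.mode is GateMode.STRICT:
            return FIVE_PRIME_NICKS <= occurred
        return nick.same_end_partner in occurred


STRICT_GATE = OrderingRule(GateMode.STRICT)
PER_END_GATE = OrderingRule(GateMode.PER_END)
NO_GATE = OrderingRule(GateMode.NONE)


def get_ordering(rule: str | OrderingRule) -> OrderingRule:
    if isinstance(rule, OrderingRule):
        return rule
    try:
        return OrderingRule(GateMode(rule))
    except ValueError:
        raise ValueError(
            f"unknown ordering rule {rule!r}; expected one of "
            f"{[m.value for m in GateMode]}"
        ) from None


def mirror_model(model: str | CleavageModel) -> CleavageModel:
    """Relabel transposon ends A<->B (N1<->N2, N3<->N4).

    Maps every model onto itself or its mirror within the same family;
    product predictions are invariant under this relabelling.
    """
    m = get_model(model)
    swap = {_N1: _N2, _N2: _N1, _N3: _N4, _N4: _N3}
    slots = tuple(frozenset(swap[n] for n in s) for s in m.slots)
    return CleavageModel(m.name + "_mirrored", m.arity, slots, m.dimer_groups)
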