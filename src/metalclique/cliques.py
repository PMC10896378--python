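"""Domain types for signed exposure cliques.

A *signed feature* is an exposure together with the direction it takes on a
decision path: ``+`` marks the high side of a split (concentration above a
threshold), ``-`` the low side.  A *clique signature* is an order-free set of
signed features; equipping each member with a percentile threshold yields a
*thresholded clique*, whose conjunction induces a binary subgroup indicator on
a cohort.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

#: Metals measured in maternal blood, and the two pregnancy trimesters.
METALS = ("Pb", "As", "Cd", "Cr", "Zn", "Se", "Sb", "Cu", "Cs", "Co", "Mn")
TRIMESTERS = ("T2", "T3")

#: Canonical exposure column names, ``<metal>_<trimester>`` (22 per cohort).
EXPOSURE_KEYS = tuple(f"{m}_{t}" for m in METALS for t in TRIMESTERS)

_SIGNED_RE = re.compile(r"^(?P<exposure>[A-Za-z0-9_]+?)(?P<sign>[+-])$")
_MEMBER_RE = re.compile(r"^(?P<exposure>[A-Za-z0-9_]+?)(?P<sign>[+-])@(?P<pct>[0-9.]+)$")


@dataclass(frozen=True, order=True)
class SignedFeature:
    """An exposure with the direction it takes on a decision path."""

    exposure: str
    sign: str  # "+" (high side) or "-" (low side)

    def __post_init__(self) -> None:
        if self.sign not in ("+", "-"):
            raise ValueError(f"sign must be '+' or '-', got {self.sign!r}")

    def __str__(self) -> str:
        return f"{self.exposure}{self.sign}"

    @classmethod
    def parse(cls, text: str) -> "SignedFeature":
        m = _SIGNED_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse signed feature from {text!r}")
        return cls(m["exposure"], m["sign"])


@dataclass(frozen=True)
class CliqueSignature:
    """An order-free set of signed features (set semantics, order >= 2 typical).

    Two signatures with the same members in any order compare and hash equal;
    the canonical string form sorts members lexicographically.
    """

    members: frozenset[SignedFeature]

    def __init__(self, members: Iterable[SignedFeature]):
        members = frozenset(members)
        exposures = [m.exposure for m in members]
        if len(set(exposures)) != len(exposures):
            raise ValueError("an exposure may appear at most once per signature")
        object.__setattr__(self, "members", members)

    @property
    def order(self) -> int:
        return len(self.members)

    def __str__(self) -> str:
        return " & ".join(str(m) for m in sorted(self.members))

    def __iter__(self):
        return iter(sorted(self.members))

    def __contains__(self, item: SignedFeature) -> bool:
        return item in self.members

    def issubset(self, other: "CliqueSignature") -> bool:
        return self.members <= other.members

    @classmethod
    def parse(cls, text: str) -> "CliqueSignature":
        parts = [p for p in re.split(r"\s*&\s*", text.strip()) if p]
        return cls(SignedFeature.parse(p) for p in parts)


@dataclass(frozen=True)
class ThresholdedClique:
    """A clique signature whose members carry percentile thresholds.

    Indicator semantics: a participant is *in* the clique iff every ``+``
    member's concentration is strictly greater than that member's sample
    percentile, and every ``-`` member's concentration is at or below its
    percentile.  An empty member list is the vacuous conjunction (all in).
    """

    members: tuple[tuple[SignedFeature, float], ...]

    def __init__(self, members: Iterable[tuple[SignedFeature, float]]):
        members = tuple(
            sorted(((sf, float(p)) for sf, p in members), key=lambda m: m[0])
        )
        exposures = [sf.exposure for sf, _ in members]
        if len(set(exposures)) != len(exposures):
            raise ValueError("an exposure may appear at most once per clique")
        for sf, p in members:
            if not (0.0 <= p <= 100.0):
                raise ValueError(f"percentile for {sf} outside [0, 100]: {p}")
        object.__setattr__(self, "members", members)

    @property
    def signature(self) -> CliqueSignature:
        return CliqueSignature(sf for sf, _ in self.members)

    @property
    def order(self) -> int:
        return len(self.members)

    def __str__(self) -> str:
        return " & ".join(f"{sf}@{_fmt_pct(p)}" for sf, p in self.members)

    def to_json(self) -> str:
        return json.dumps(
            [
                {"exposure": sf.exposure, "sign": sf.sign, "percentile": p}
                for sf, p in self.members
            ]
        )

    @classmethod
    def from_json(cls, text: str) -> "ThresholdedClique":
        items = json.loads(text)
        return cls(
            (SignedFeature(d["exposure"], d["sign"]), float(d["percentile"]))
            for d in items
        )

    @classmethod
    def parse(cls, text: str) -> "ThresholdedClique":
        parts = [p for p in re.split(r"\s*&\s*", text.strip()) if p]
        members = []
        for part in parts:
            m = _MEMBER_RE.match(part)
            if m is None:
                raise ValueError(f"cannot parse clique member from {part!r}")
            members.append(
                (SignedFeature(m["exposure"], m["sign"]), float(m["pct"]))
            )
        return cls(members)


def _fmt_pct(p: float) -> str:
    return f"{p:g}"


@dataclass(frozen=True)
class StabilityRecord:
    """A clique signature with its frequency of occurrence across holdouts."""

    signature: CliqueSignature
    stability: float
    mean_prevalence: float
    order: int

    def as_row(self) -> dict:
        return {
            "signature": str(self.signature),
            "order": self.order,
            "stability": self.stability,
            "mean_prevalence": self.mean_prevalence,
        }


def signature_sort_key(rec: StabilityRecord) -> tuple:
    """Deterministic ranking: stability desc, mean prevalence desc, lexicographic."""
    return (-rec.stability, -rec.mean_prevalence, str(rec.signature))


def top_k(records: Sequence[StabilityRecord], k: int) -> list[StabilityRecord]:
    return sorted(records, key=signature_sort_key)[:k]
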